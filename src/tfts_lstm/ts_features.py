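"""Time-space features: fuzzy recurrence plots and their two entropies.

A signal segment is embedded into phase space (dimension ``m``, delay
``tau``; both default to 1, so states are the raw samples), partitioned into
``c`` fuzzy clusters with fuzzy c-means, and turned into a fuzzy recurrence
plot (FRP): the N x N matrix of fuzzy similarity memberships

    R(i, j) = max_q min( u(x_i, v_q), u(x_j, v_q) )

(a single max-min composition of the point-to-centroid memberships), with
the diagonal set to 1. An FRP is reflexive, symmetric and has entries in
[0, 1].

Two scalar entropies summarize an FRP:

* FRIE — Shannon entropy of the gray-level histogram of the FRP viewed as an
  L-level grayscale image (memberships quantized to ``round(mu * (L - 1))``).
* FRE — the fuzzy-set entropy: the sum over all N^2 entries of the binary
  entropy ``-mu log2 mu - (1 - mu) log2(1 - mu)``.

``ts_sequence`` splits a signal into T contiguous segments (matching the
time-frequency sequence length) and computes both entropies per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import SignalSeries

DEFAULT_CLUSTERS = 3
DEFAULT_FUZZIFIER = 2.0
DEFAULT_GRAY_LEVELS = 256
MIN_SEGMENT_LEN = 8


@dataclass
class PhaseSpace:
    """Delay-embedded states: N x m matrix, one row per state vector."""

    X: np.ndarray
    dim: int
    delay: int

    @property
    def n_points(self) -> int:
        return self.X.shape[0]


@dataclass
class FuzzyPartition:
    """Fuzzy c-means result: centroids (c x m) and memberships U (N x c)."""

    centroids: np.ndarray
    U: np.ndarray
    fuzzifier: float
    n_iter: int


@dataclass
class FRPMatrix:
    """Fuzzy recurrence plot: N x N membership matrix in [0, 1]."""

    R: np.ndarray

    @property
    def n(self) -> int:
        return self.R.shape[0]


@dataclass
class TSSequence:
    """Per-segment FRIE and FRE (bits), aligned to the TF sequence length."""

    frie: np.ndarray
    fre: np.ndarray
    segment_bounds: list[tuple[int, int]]

    def __len__(self) -> int:
        return self.frie.size


def embed_phase_space(series: SignalSeries | np.ndarray, m: int = 1, tau: int = 1) -> PhaseSpace:
    """Delay embedding: x_i = (s_i, s_{i+tau}, ..., s_{i+(m-1)tau})."""
    s = series.values if isinstance(series, SignalSeries) else np.asarray(series, dtype=float)
    if m < 1 or tau < 1:
        raise ValueError("embedding dimension and delay must be >= 1")
    n = s.size - (m - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {s.size} too short for dim={m}, delay={tau}"
        )
    cols = [s[k * tau : k * tau + n] for k in range(m)]
    return PhaseSpace(X=np.column_stack(cols), dim=m, delay=tau)


def fuzzy_c_means(
    X: PhaseSpace | np.ndarray,
    c: int = DEFAULT_CLUSTERS,
    w: float = DEFAULT_FUZZIFIER,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int | None = None,
) -> FuzzyPartition:
    """Fuzzy c-means by alternating optimization of the Bezdek objective.

    Memberships follow u_iq = 1 / sum_k (d_iq / d_ik)^(2/(w-1)); points that
    coincide with a centroid get crisp membership there. Centroids are
    initialized on value-range quantiles of the data (deterministic), so the
    seed only matters for degenerate tie-breaking and the result is
    reproducible by construction.
    """
    pts = X.X if isinstance(X, PhaseSpace) else np.asarray(X, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n, m = pts.shape
    if c < 2:
        raise ValueError("need at least 2 clusters")
    if w <= 1:
        raise ValueError("fuzzifier must be > 1")
    n_distinct = np.unique(pts, axis=0).shape[0]
    if n_distinct < c:
        raise ValueError(
            f"only {n_distinct} distinct points for {c} clusters (degenerate data)"
        )

    # Quantile initialization: c centroids spread over the data range.
    qs = np.linspace(0.0, 1.0, c)
    centroids = np.quantile(pts, qs, axis=0)
    # Nudge coincident initial centroids apart so distances differ.
    for q in range(1, c):
        if np.allclose(centroids[q], centroids[q - 1]):
            centroids[q] = centroids[q] + 1e-9 * (1.0 + np.abs(centroids[q]))

    exponent = 2.0 / (w - 1.0)
    U = np.empty((n, c))
    for it in range(1, max_iter + 1):
        d2 = ((pts[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 0.0
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d2 ** (-exponent / 2.0)
            U_new = inv / inv.sum(axis=1, keepdims=True)
        if any_zero.any():
            rows = np.where(any_zero)[0]
            U_new[rows] = 0.0
            z = zero[rows]
            U_new[rows] = z / z.sum(axis=1, keepdims=True)
        delta = np.abs(U_new - U).max() if it > 1 else np.inf
        U = U_new
        uw = U**w
        denom = uw.sum(axis=0)
        centroids = (uw.T @ pts) / np.maximum(denom, 1e-300)[:, None]
        if delta < tol:
            break
    return FuzzyPartition(centroids=centroids, U=U, fuzzifier=w, n_iter=it)


def build_frp(part: FuzzyPartition) -> FRPMatrix:
    """Single max-min composition of memberships; diagonal forced to 1."""
    U = part.U
    # R[i, j] = max_q min(U[i, q], U[j, q])
    R = np.minimum(U[:, None, :], U[None, :, :]).max(axis=2)
    np.fill_diagonal(R, 1.0)
    return FRPMatrix(R=R)


def transitive_closure(frp: FRPMatrix, max_iter: int = 100) -> FRPMatrix:
    """Iterate max-min composition of R with itself until it stops changing.

    Opt-in alternative to the single composition of :func:`build_frp`.
    """
    R = frp.R.copy()
    for _ in range(max_iter):
        R_next = np.minimum(R[:, :, None], R[None, :, :]).max(axis=1)
        R_next = np.maximum(R, R_next)
        np.fill_diagonal(R_next, 1.0)
        if np.abs(R_next - R).max() < 1e-12:
            return FRPMatrix(R=R_next)
        R = R_next
    return FRPMatrix(R=R)


def frie(frp: FRPMatrix, L: int = DEFAULT_GRAY_LEVELS) -> float:
    """Gray-level histogram entropy of the FRP, in bits."""
    if L < 2:
        raise ValueError("need at least 2 gray levels")
    levels = np.rint(frp.R * (L - 1)).astype(np.int64)
    counts = np.bincount(levels.ravel(), minlength=L)
    p = counts[counts > 0] / levels.size
    return float(-(p * np.log2(p)).sum()) + 0.0


def fre(frp: FRPMatrix) -> float:
    """Fuzzy-set entropy: summed binary entropy of every membership, in bits."""
    mu = frp.R
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(mu > 0, mu * np.log2(mu), 0.0)
        t2 = np.where(mu < 1, (1 - mu) * np.log2(1 - mu), 0.0)
    return float(-(t1 + t2).sum()) + 0.0


def segment_bounds(length: int, T: int) -> list[tuple[int, int]]:
    """T near-equal contiguous half-open ranges; earlier ones one longer."""
    base, extra = divmod(length, T)
    bounds = []
    start = 0
    for i in range(T):
        seg = base + (1 if i < extra else 0)
        bounds.append((start, start + seg))
        start += seg
    return bounds


def frp_of_segment(
    seg: np.ndarray,
    c: int = DEFAULT_CLUSTERS,
    m: int = 1,
    tau: int = 1,
    w: float = DEFAULT_FUZZIFIER,
) -> FRPMatrix:
    """Embed a segment, cluster it and build its FRP.

    Segments with fewer distinct states than ``c`` are fully recurrent in the
    limit of identical points: they get an all-ones FRP (so both entropies
    are 0).
    """
    ps = embed_phase_space(np.asarray(seg, dtype=float), m=m, tau=tau)
    try:
        part = fuzzy_c_means(ps, c=c, w=w)
    except ValueError:
        n = ps.n_points
        return FRPMatrix(R=np.ones((n, n)))
    return build_frp(part)


def ts_sequence(
    series: SignalSeries,
    T: int,
    c: int = DEFAULT_CLUSTERS,
    m: int = 1,
    tau: int = 1,
    w: float = DEFAULT_FUZZIFIER,
    L: int = DEFAULT_GRAY_LEVELS,
) -> TSSequence:
    """Per-segment FRIE and FRE over T contiguous near-equal segments."""
    s = series.values
    if T < 1:
        raise ValueError("need at least one segment")
    if s.size // T < MIN_SEGMENT_LEN:
        raise ValueError(
            f"series of length {s.size} too short for {T} segments of at "
            f"least {MIN_SEGMENT_LEN} samples"
        )
    bounds = segment_bounds(s.size, T)
    frie_vals = np.empty(T)
    fre_vals = np.empty(T)
    for i, (a, b) in enumerate(bounds):
        frp = frp_of_segment(s[a:b], c=c, m=m, tau=tau, w=w)
        frie_vals[i] = frie(frp, L=L)
        fre_vals[i] = fre(frp)
    return TSSequence(frie=frie_vals, fre=fre_vals, segment_bounds=bounds)


def write_frp_png(frp: FRPMatrix, path) -> None:
    """Export the FRP as an 8-bit grayscale PNG (membership x 255, rounded)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.rint(frp.R * 255).astype(np.uint8))


def write_ts_csv(ts: TSSequence, path) -> None:
    """Write `segment,start,end,frie_bits,fre_bits` rows."""
    import pandas as pd

    pd.DataFrame(
        {
            "segment": np.arange(len(ts)),
            "start": [a for a, _ in ts.segment_bounds],
            "end": [b for _, b in ts.segment_bounds],
            "frie_bits": ts.frie,
            "fre_bits": ts.fre,
        }
    ).to_csv(path, index=False)
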
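"""Time-frequency features: spectrogram, instantaneous frequency, spectral entropy.

The instantaneous frequency at frame ``t`` is the power-weighted mean
frequency

    IF(t) = sum_m f_m P(t, m) / sum_m P(t, m)

and the spectral entropy is the Shannon entropy of the per-frame normalized
power distribution p(t, m) = P(t, m) / sum_f P(t, f),

    SE(t) = - sum_m p(t, m) log2 p(t, m),

optionally scaled by log2(F) so that a flat spectrum gives SE = 1.

Frames with (near-)zero total power are floored before normalization, which
makes their distribution uniform: IF = fs/4 and scaled SE = 1 in that limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .images import SignalSeries

DEFAULT_WINDOW = 128
DEFAULT_HOP = 64


@dataclass
class Spectrogram:
    """One-sided short-time power spectrum with axis metadata."""

    P: np.ndarray  # T x F power matrix
    times: np.ndarray  # frame centers, seconds
    freqs: np.ndarray  # bin centers, Hz, [0, fs/2]
    fs: float
    window_len: int
    hop_len: int

    @property
    def n_frames(self) -> int:
        return self.P.shape[0]

    @property
    def n_bins(self) -> int:
        return self.P.shape[1]


@dataclass
class TFSequence:
    """Per-frame instantaneous frequency (Hz) and spectral entropy."""

    if_hz: np.ndarray
    se: np.ndarray
    p_tm: np.ndarray  # T x F normalized per-frame power distribution

    def __len__(self) -> int:
        return self.if_hz.size


def compute_spectrogram(
    series: SignalSeries,
    window_len: int = DEFAULT_WINDOW,
    hop_len: int = DEFAULT_HOP,
) -> Spectrogram:
    """Short-time one-sided power spectrum with a Hamming window.

    Frame ``t`` covers samples ``[t*hop, t*hop + window_len)``; the number of
    frames is ``floor((len - window_len) / hop_len) + 1``. The global signal
    mean is subtracted first: image-derived signals carry a large intensity
    offset, and the resulting DC spike would otherwise dominate the
    power-weighted mean frequency without conveying any oscillatory
    information.
    """
    x = series.values
    if window_len < 8:
        raise ValueError(f"window_len must be >= 8, got {window_len}")
    if not (1 <= hop_len <= window_len):
        raise ValueError(f"hop_len must be in [1, window_len], got {hop_len}")
    if x.size < window_len:
        raise ValueError(
            f"series of length {x.size} is shorter than the window "
            f"({window_len}); use a smaller window"
        )
    freqs, times, p = _signal.spectrogram(
        x - x.mean(),
        fs=series.fs,
        window=_signal.get_window("hamming", window_len),
        nperseg=window_len,
        noverlap=window_len - hop_len,
        nfft=window_len,
        detrend=False,
        return_onesided=True,
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(
        P=p.T.astype(float),
        times=times,
        freqs=freqs,
        fs=series.fs,
        window_len=window_len,
        hop_len=hop_len,
    )


def _floored_distribution(spec: Spectrogram) -> np.ndarray:
    """Per-frame distribution p(t, m); zero-power frames become uniform.

    The floor is machine epsilon times max(global peak power, 1), applied
    before normalization so every frame is a proper distribution.
    """
    floor = np.finfo(float).eps * max(float(spec.P.max(initial=0.0)), 1.0)
    p = np.maximum(spec.P, floor)
    return p / p.sum(axis=1, keepdims=True)


def instantaneous_frequency(spec: Spectrogram) -> np.ndarray:
    """Power-weighted mean frequency per frame, in Hz."""
    p = _floored_distribution(spec)
    return p @ spec.freqs


def spectral_entropy(spec: Spectrogram, scaled: bool = True) -> np.ndarray:
    """Shannon entropy of the per-frame spectrum; in [0, 1] when scaled."""
    p = _floored_distribution(spec)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    se = -terms.sum(axis=1)
    if scaled:
        se = se / np.log2(spec.n_bins)
    return se


def tf_sequence(
    series: SignalSeries,
    window_len: int = DEFAULT_WINDOW,
    hop_len: int = DEFAULT_HOP,
    scaled_se: bool = True,
) -> TFSequence:
    """IF and SE sequences from one shared spectrogram (equal length T)."""
    spec = compute_spectrogram(series, window_len=window_len, hop_len=hop_len)
    p = _floored_distribution(spec)
    if_hz = p @ spec.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    se = -terms.sum(axis=1)
    if scaled_se:
        se = se / np.log2(spec.n_bins)
    return TFSequence(if_hz=if_hz, se=se, p_tm=p)


def write_tf_csv(tfseq: TFSequence, spec: Spectrogram, path) -> None:
    """Write `frame,time_s,if_hz,se` rows."""
    import pandas as pd

    pd.DataFrame(
        {
            "frame": np.arange(len(tfseq)),
            "time_s": spec.times,
            "if_hz": tfseq.if_hz,
            "se": tfseq.se,
        }
    ).to_csv(path, index=False)
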
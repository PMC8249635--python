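"""Synthetic texture images with controllable class-separating structure.

Stand-ins for tissue textures: each class is defined by a dominant spatial
structure plus noise, so the full pipeline (vectorization, spectral and
recurrence features, classification) can be exercised without any external
dataset. Gratings vary along image rows, so the column-stacked signal is a
near-sinusoid whose period (in samples) equals the grating period (in
pixels) — which ties a grating's dominant frequency analytically to the
instantaneous-frequency feature: at fs Hz, a period-p grating concentrates
power near fs / p.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import GrayImage

DEFAULT_SIZE = 64


@dataclass
class TextureClassSpec:
    """One texture class: kind, structural parameters, noise level, label."""

    label: object
    kind: str = "grating"  # grating | gaussian_field | checker
    dominant_period: int = 8
    spectral_exponent: float = 0.0
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("grating", "gaussian_field", "checker"):
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.dominant_period < 2:
            raise ValueError("dominant_period must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Labeled grayscale images, fully determined by the generator seed."""

    images: list[GrayImage]
    labels: list
    seed: int
    specs: list[TextureClassSpec] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def generate_grating(
    size: int,
    period: int,
    phase: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrayImage:
    """Horizontal sinusoidal grating: 0.5 + 0.4 sin(2*pi*m/period + phase) + noise.

    Intensity varies along rows only, clipped to [0, 1].
    """
    if period < 2 or size < period:
        raise ValueError(f"need size >= period >= 2, got size={size}, period={period}")
    rng = np.random.default_rng(seed)
    m = np.arange(size)[:, None]
    img = 0.5 + 0.4 * np.sin(2 * np.pi * m / period + phase) * np.ones((1, size))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(size, size))
    return GrayImage(pixels=np.clip(img, 0.0, 1.0))


def generate_checker(
    size: int,
    period: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrayImage:
    """Square-wave checkerboard with cell side ``period // 2`` pixels."""
    if period < 2 or size < period:
        raise ValueError(f"need size >= period >= 2, got size={size}, period={period}")
    rng = np.random.default_rng(seed)
    cell = max(period // 2, 1)
    idx = np.arange(size) // cell
    img = ((idx[:, None] + idx[None, :]) % 2).astype(float)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=(size, size))
    return GrayImage(pixels=np.clip(img, 0.0, 1.0))


def generate_gaussian_field(
    size: int,
    spectral_exponent: float = 2.0,
    seed: int = 0,
) -> GrayImage:
    """Random field with isotropic power-law spectrum, rescaled to [0, 1].

    Fourier amplitudes fall off as (spatial frequency)^(-exponent/2) with
    random phases; exponent 0 gives white noise, larger exponents give
    smoother, more correlated textures.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    radius[0, 0] = radius[radius > 0].min()  # avoid div-by-zero at DC
    amplitude = radius ** (-spectral_exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=(size, size))
    spectrum = amplitude * np.exp(1j * phases)
    fld = np.real(np.fft.ifft2(spectrum))
    lo, hi = fld.min(), fld.max()
    if hi - lo < 1e-300:
        return GrayImage(pixels=np.full((size, size), 0.5))
    return GrayImage(pixels=(fld - lo) / (hi - lo))


def _generate_one(spec: TextureClassSpec, size: int, rng: np.random.Generator) -> GrayImage:
    sub = int(rng.integers(0, 2**31 - 1))
    if spec.kind == "grating":
        phase = float(rng.uniform(0, 2 * np.pi))
        return generate_grating(size, spec.dominant_period, phase, spec.noise_sd, seed=sub)
    if spec.kind == "checker":
        return generate_checker(size, spec.dominant_period, spec.noise_sd, seed=sub)
    return generate_gaussian_field(size, spec.spectral_exponent, seed=sub)


def generate_dataset(
    specs: list[TextureClassSpec],
    n_per_class: int = 40,
    size: int = DEFAULT_SIZE,
    seed: int = 0,
    imbalance: dict | None = None,
) -> SyntheticDataset:
    """Labeled image set: ``n_per_class`` images per spec, phase/seed jittered.

    ``imbalance`` optionally maps a label to its own sample count, to
    exercise the class-modeling scheme on unbalanced data.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 class specs")
    labels_seen = [s.label for s in specs]
    if len(set(labels_seen)) != len(labels_seen):
        raise ValueError("duplicate class labels in specs")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[GrayImage] = []
    labels: list = []
    for spec in specs:
        n = n_per_class if imbalance is None else imbalance.get(spec.label, n_per_class)
        for _ in range(n):
            images.append(_generate_one(spec, size, rng))
            labels.append(spec.label)
    return SyntheticDataset(images=images, labels=labels, seed=seed, specs=list(specs))


def default_two_class_specs() -> list[TextureClassSpec]:
    """Two gratings with well-separated dominant periods (6 vs 16 pixels)."""
    return [
        TextureClassSpec(label="fine", kind="grating", dominant_period=6, noise_sd=0.05),
        TextureClassSpec(label="coarse", kind="grating", dominant_period=16, noise_sd=0.05),
    ]


def write_dataset(dataset: SyntheticDataset, out_dir) -> Path:
    """Write `DIR/<class>/<idx>.png` files plus a `manifest.csv` index."""
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    rows = []
    counters: dict = {}
    for img, label in zip(dataset.images, dataset.labels):
        idx = counters.get(label, 0)
        counters[label] = idx + 1
        cls_dir = out / str(label)
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{idx}.png"
        iio.imwrite(path, np.rint(img.pixels * 255).astype(np.uint8))
        rows.append({"path": str(path.relative_to(out)), "label": label, "seed": dataset.seed})
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return out
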
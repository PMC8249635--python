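"""Image loading, grayscale conversion, resizing and column-major vectorization.

A grayscale M x N image ``I`` is turned into a 1-D signal ``J`` by stacking
its columns top to bottom, left to right::

    J = [I_11, ..., I_M1, I_12, ..., I_M2, ..., I_1N, ..., I_MN]

The signal carries a nominal sampling frequency ``fs`` (images have no
physical time axis; the default 300 Hz is conventional for physiological
signals and only fixes the frequency scale of downstream spectral features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _skimage_resize

DEFAULT_FS = 300.0

#: ITU-R BT.601 luma weights for RGB -> grayscale.
LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])


@dataclass
class RasterImage:
    """Decoded raster image: H x W x C array, C in {1, 3}."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3 or px.shape[2] not in (1, 3):
            raise ValueError(
                f"expected H x W x C pixels with C in {{1, 3}}, got shape {px.shape}"
            )
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2 x 2 pixels")
        px = px.astype(float)
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        self.pixels = px

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class GrayImage:
    """Grayscale image: M x N real matrix."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {px.shape}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError("image must be at least 2 x 2 pixels")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SignalSeries:
    """1-D real signal with a nominal sampling frequency in Hz."""

    values: np.ndarray
    fs: float = DEFAULT_FS
    source: str = ""
    image_shape: tuple[int, int] | None = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValueError("series contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        self.values = v

    def __len__(self) -> int:
        return self.values.size


def load_image(path) -> RasterImage:
    """Read a PNG/TIFF/JPEG file into a :class:`RasterImage`.

    Raises ``OSError`` naming the path if the file is missing or cannot be
    decoded.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise OSError(f"cannot read image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return RasterImage(pixels=arr, source_path=str(path))


def to_grayscale(img: RasterImage) -> GrayImage:
    """Convert to grayscale with BT.601 luma weights; single channel passes through.

    Intensities stay real-valued (no re-quantization), so no precision is lost
    before feature extraction.
    """
    c = img.n_channels
    if c == 1:
        return GrayImage(pixels=img.pixels[:, :, 0])
    if c == 3:
        return GrayImage(pixels=img.pixels @ LUMA_WEIGHTS)
    raise ValueError(f"unsupported channel count {c}; expected 1 or 3")


def resize_image(img: GrayImage, target: tuple[int, int]) -> GrayImage:
    """Bilinear resize to ``target = (rows, cols)``, anti-aliased when shrinking."""
    rows, cols = int(target[0]), int(target[1])
    if rows < 2 or cols < 2:
        raise ValueError(f"target dimensions must be >= 2, got {target}")
    if (rows, cols) == img.shape:
        return GrayImage(pixels=img.pixels.copy())
    shrinking = rows < img.shape[0] or cols < img.shape[1]
    out = _skimage_resize(
        img.pixels,
        (rows, cols),
        order=1,
        mode="edge",
        anti_aliasing=shrinking,
        preserve_range=True,
    )
    return GrayImage(pixels=out)


def vectorize(img: GrayImage, fs: float = DEFAULT_FS, source: str = "") -> SignalSeries:
    """Stack the image's columns into a 1-D signal (column-major flatten)."""
    m, n = img.shape
    values = img.pixels.flatten(order="F")
    return SignalSeries(values=values, fs=fs, source=source, image_shape=(m, n))


def series_to_image(series: SignalSeries) -> GrayImage:
    """Invert :func:`vectorize` using the recorded image shape."""
    if series.image_shape is None:
        raise ValueError("series does not record a source image shape")
    m, n = series.image_shape
    if series.values.size != m * n:
        raise ValueError("series length does not match recorded image shape")
    return GrayImage(pixels=series.values.reshape((m, n), order="F"))


def write_series_csv(series: SignalSeries, path) -> None:
    """Write the signal as a one-column CSV with a JSON sidecar of metadata."""
    import json
    from pathlib import Path

    p = Path(path)
    np.savetxt(p, series.values, fmt="%.10g", header="value", comments="")
    meta = {
        "fs": series.fs,
        "source": series.source,
        "M": None if series.image_shape is None else series.image_shape[0],
        "N": None if series.image_shape is None else series.image_shape[1],
    }
    p.with_suffix(p.suffix + ".json").write_text(json.dumps(meta))
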
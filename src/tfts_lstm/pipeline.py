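"""End-to-end feature extraction: image -> T x 4 feature sequence."""

from __future__ import annotations

from .classifier import FeatureSequence, assemble_features
from .images import DEFAULT_FS, GrayImage, RasterImage, load_image, to_grayscale, vectorize
from .tf_features import DEFAULT_HOP, DEFAULT_WINDOW, tf_sequence
from .ts_features import DEFAULT_CLUSTERS, ts_sequence


def features_from_image(
    img: GrayImage | RasterImage | str,
    fs: float = DEFAULT_FS,
    window_len: int = DEFAULT_WINDOW,
    hop_len: int = DEFAULT_HOP,
    c: int = DEFAULT_CLUSTERS,
    label=None,
    source_id: str = "",
) -> FeatureSequence:
    """Vectorize an image and extract the aligned (IF, SE, FRIE, FRE) sequence.

    The time-space sequence is computed over exactly as many signal segments
    as the time-frequency sequence has frames, so all four channels share T.
    Accepts a file path, a decoded :class:`RasterImage`, or a
    :class:`GrayImage`.
    """
    if isinstance(img, str):
        img = load_image(img)
        if not source_id:
            source_id = img.source_path
    if isinstance(img, RasterImage):
        img = to_grayscale(img)
    series = vectorize(img, fs=fs, source=source_id)
    tfs = tf_sequence(series, window_len=window_len, hop_len=hop_len)
    tss = ts_sequence(series, T=len(tfs), c=c)
    return assemble_features(tfs, tss, label=label, source_id=source_id)
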
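"""Frame pre-processing: nearest-neighbour down-sampling and 8-bit rescale.

Acquisition-resolution frames (352x352 reconstruction over a 350 mm field
of view) are downsized to the network's 128x128 grid with nearest-neighbour
interpolation — chosen so that no new intensity values are created and label
masks survive untouched — and the 16-bit intensity range is windowed to 256
levels using each image's own min/max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import CineSequence, LabelMapSequence


@dataclass
class PreprocessConfig:
    target_size: int = 128
    source_bit_depth: int = 16
    target_levels: int = 256

    def __post_init__(self) -> None:
        if self.target_size < 8:
            raise ValueError("target_size must be >= 8")


def center_crop_square(frame: np.ndarray) -> np.ndarray:
    """Crop a non-square frame to its central square."""
    h, w = frame.shape
    if h == w:
        return frame
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return frame[r0 : r0 + side, c0 : c0 + side]


def resize_nearest(frame: np.ndarray, target_size: int) -> np.ndarray:
    """Resize a square 2-D raster with nearest-neighbour sampling.

    Pixel-center alignment: output pixel i samples source index
    floor((i + 0.5) * src/dst).  The output value set is a subset of the
    input value set (no interpolation), so the same routine is safe for
    label masks.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got shape {frame.shape}")
    frame = center_crop_square(frame)
    src = frame.shape[0]
    if src == target_size:
        return frame.copy()
    scale = src / target_size
    idx = np.minimum((np.arange(target_size) + 0.5) * scale, src - 1).astype(np.intp)
    return frame[np.ix_(idx, idx)]


def rescale_to_8bit(frame: np.ndarray) -> np.ndarray:
    """Window an intensity frame to [0, 255] with its own min/max.

    out = round(255 * (in - min) / (max - min)), round half up.  A constant
    frame has no window; it maps to all zeros with a warning so batch
    processing survives degenerate frames.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    lo, hi = frame.min(), frame.max()
    if hi == lo:
        warnings.warn("constant frame: min == max, output is all zeros")
        return np.zeros(frame.shape, dtype=np.uint8)
    scaled = 255.0 * (frame - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)


def preprocess_cine(cine: CineSequence, config: PreprocessConfig | None = None) -> CineSequence:
    """Down-sample and rescale every frame; update pixel spacing."""
    config = config or PreprocessConfig()
    src = center_crop_square(np.asarray(cine.frames[0])).shape[0]
    frames = np.stack(
        [rescale_to_8bit(resize_nearest(f, config.target_size)) for f in cine.frames]
    )
    new_spacing = cine.pixel_spacing * src / config.target_size
    return CineSequence(frames=frames, pixel_spacing=new_spacing)


def preprocess_labels(labels: LabelMapSequence, config: PreprocessConfig | None = None) -> LabelMapSequence:
    """Down-sample masks with nearest neighbour (labels preserved, never averaged)."""
    config = config or PreprocessConfig()
    src = center_crop_square(np.asarray(labels.masks[0])).shape[0]
    masks = np.stack([resize_nearest(m, config.target_size) for m in labels.masks])
    new_spacing = labels.pixel_spacing * src / config.target_size
    return LabelMapSequence(masks=masks, pixel_spacing=new_spacing)
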
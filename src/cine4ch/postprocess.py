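"""Morphological cleanup of predicted chamber probability maps.

A raw network prediction can contain spurious blood-pool fragments away
from the actual chamber.  Each chamber's (grayscale) class map is closed
with a 3-pixel-radius disk, binarized with Otsu's threshold, and reduced to
its largest connected component; the four cleaned chambers are then
composed into one label raster, any doubly-claimed pixel going to the class
with the higher closed score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk

from .chambers import CHAMBER_CODES, CODE_TO_CHAMBER
from .io import LabelMapSequence


@dataclass
class PostprocessConfig:
    disk_radius_px: int = 3
    threshold_method: str = "otsu"
    connectivity: int = 8  # 4 or 8

    def __post_init__(self) -> None:
        if self.disk_radius_px < 0:
            raise ValueError("disk_radius_px must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method != "otsu":
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def close_map(class_map: np.ndarray, disk_radius_px: int = 3) -> np.ndarray:
    """Grayscale morphological closing with a Euclidean disk element.

    Extensive (output >= input) and idempotent; radius 0 is the identity.
    """
    if disk_radius_px < 0:
        raise ValueError("disk radius must be >= 0")
    arr = np.asarray(class_map, dtype=np.float64)
    if disk_radius_px == 0:
        return arr.copy()
    return closing(arr, footprint=disk(disk_radius_px))


def otsu_threshold(values: np.ndarray) -> float:
    """Exact Otsu threshold: the cut maximizing between-class variance.

    Evaluated over every split between adjacent distinct values (no
    binning, so float-valued probability maps are handled exactly); returns
    the midpoint of the best cut, with foreground = value >= threshold.
    On integer 8-bit data this reproduces the classic histogram method.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    uniq, counts = np.unique(v, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need >= 2 distinct values")
    w0 = np.cumsum(counts)[:-1]
    w1 = v.size - w0
    csum = np.cumsum(uniq * counts)[:-1]
    mu0 = csum / w0
    mu1 = (csum[-1] + uniq[-1] * counts[-1] - csum) / w1
    var = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(var))
    return float((uniq[k] + uniq[k + 1]) / 2.0)


def binarize(class_map: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarize by Otsu's maximal between-class-variance threshold.

    Pixels >= threshold are foreground.  A constant map has no histogram to
    split: it yields an empty mask with a warning.
    """
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    arr = np.asarray(class_map, dtype=np.float64)
    if np.ptp(arr) == 0:
        warnings.warn("constant map: no threshold exists, returning empty mask")
        return np.zeros(arr.shape, dtype=bool)
    return arr >= otsu_threshold(arr)


def largest_component(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected foreground component.

    Empty input stays empty.  Ties go to the component whose first pixel
    comes earliest in row-major scan order (the smallest label id).
    """
    b = np.asarray(binary, dtype=bool)
    if not b.any():
        return b.copy()
    conn = 1 if connectivity == 4 else 2
    lab = cc_label(b, connectivity=conn)
    counts = np.bincount(lab.ravel())
    counts[0] = 0  # background
    keep = int(np.argmax(counts))  # argmax takes the first (smallest) label on ties
    return lab == keep


def postprocess_frame(
    prob_stack: np.ndarray, config: PostprocessConfig | None = None
) -> np.ndarray:
    """Clean one frame's (n_classes, H, W) stack into a label raster."""
    config = config or PostprocessConfig()
    stack = np.asarray(prob_stack, dtype=np.float64)
    if stack.ndim != 3 or stack.shape[0] < 5:
        raise ValueError(f"expected (>=5, H, W) probability stack, got {stack.shape}")
    h, w = stack.shape[1:]
    label_out = np.zeros((h, w), dtype=np.int64)
    best_score = np.full((h, w), -np.inf)
    any_found = False
    for code in sorted(CODE_TO_CHAMBER):
        closed = close_map(stack[code], config.disk_radius_px)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant map → empty, handled below
            comp = largest_component(binarize(closed, config.threshold_method), config.connectivity)
        if not comp.any():
            continue
        any_found = True
        claim = comp & (closed > best_score)
        label_out[claim] = code
        best_score[claim] = closed[claim]
    if not any_found:
        warnings.warn("post-processing found no chamber in this frame")
    return label_out


def postprocess_stack(
    prob_stacks: np.ndarray,
    config: PostprocessConfig | None = None,
    pixel_spacing: float = 1.0,
) -> LabelMapSequence:
    """Clean per-phase probability stacks ``(n_phases, n_classes, H, W)``.

    Per chamber class the output is a single connected component (or
    empty); chamber regions are pairwise disjoint by construction.
    """
    stacks = np.asarray(prob_stacks)
    if stacks.ndim != 4:
        raise ValueError(f"expected (n_phases, n_classes, H, W), got {stacks.shape}")
    masks = np.stack([postprocess_frame(s, config) for s in stacks])
    return LabelMapSequence(masks=masks, pixel_spacing=pixel_spacing)


def one_hot(label_map: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Encode a label raster as a (n_classes, H, W) one-hot stack."""
    lab = np.asarray(label_map, dtype=np.int64)
    return (np.arange(n_classes)[:, None, None] == lab[None]).astype(np.float64)
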
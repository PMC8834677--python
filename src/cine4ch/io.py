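"""In-memory containers and file I/O for cine sequences and label maps.

A *cine* is one heartbeat reconstructed as ``n_phases`` single-slice frames
(20 in the acquisition protocol emulated here).  Frames are stored as 8-bit
grayscale PNGs, masks as 8-bit indexed PNGs with values 0-4; an optional
NIfTI writer stacks the 20 frames into a single volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

try:  # nibabel is optional at import time; NIfTI I/O needs it
    import nibabel as nib
except ImportError:  # pragma: no cover
    nib = None

from .chambers import CHAMBER_CODES


@dataclass
class CineSequence:
    """Ordered per-phase intensity frames with pixel-spacing metadata.

    Parameters
    ----------
    frames
        Array of shape ``(n_phases, H, W)``; 8-bit range after
        preprocessing.
    pixel_spacing
        In-plane pixel size in mm/pixel (isotropic).
    """

    frames: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_phases, H, W)")
        if self.n_phases < 2:
            raise ValueError("a cine needs at least 2 phases")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_phases(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class LabelMapSequence:
    """Per-phase integer chamber masks aligned to a :class:`CineSequence`."""

    masks: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be (n_phases, H, W)")
        bad = set(np.unique(self.masks)) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"labels outside 0-4: {sorted(bad)}")

    @property
    def n_phases(self) -> int:
        return self.masks.shape[0]

    def chamber_mask(self, chamber: str, phase: int) -> np.ndarray:
        """Binary mask of one chamber at one phase."""
        return self.masks[phase] == CHAMBER_CODES[chamber]


@dataclass
class SubjectRecord:
    """Per-subject metadata row: id, sex, BSA and optional truth flags."""

    subject_id: str
    sex: str  # "male" | "female"
    bsa: float  # body surface area, m^2
    enlargement_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.bsa <= 0:
            raise ValueError("BSA must be positive")


# ---------------------------------------------------------------------------
# PNG I/O


def write_png(path: Path | str, array: np.ndarray) -> None:
    """Write a 2-D uint8 array as an 8-bit grayscale PNG."""
    from PIL import Image

    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("array out of 8-bit range")
        arr = arr.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(str(path))


def read_png(path: Path | str) -> np.ndarray:
    """Read an 8-bit grayscale PNG into a 2-D uint8 array."""
    from PIL import Image

    with Image.open(str(path)) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def write_cine_pngs(cine: CineSequence, out_dir: Path | str, subject_id: str) -> list[Path]:
    """Write one PNG per phase as ``<id>_phase<pp>.png``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(cine.n_phases):
        path = out_dir / f"{subject_id}_phase{p:02d}.png"
        write_png(path, cine.frames[p])
        paths.append(path)
    return paths


def read_cine_pngs(frame_dir: Path | str, subject_id: str, pixel_spacing: float) -> CineSequence:
    """Read ``<id>_phase*.png`` frames in phase order."""
    paths = sorted(Path(frame_dir).glob(f"{subject_id}_phase*.png"))
    if not paths:
        raise FileNotFoundError(f"no frames for {subject_id} in {frame_dir}")
    frames = np.stack([read_png(p) for p in paths])
    return CineSequence(frames=frames, pixel_spacing=pixel_spacing)


def write_labelmap_pngs(labels: LabelMapSequence, out_dir: Path | str, subject_id: str) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(labels.n_phases):
        path = out_dir / f"{subject_id}_phase{p:02d}.png"
        write_png(path, labels.masks[p].astype(np.uint8))
        paths.append(path)
    return paths


def read_labelmap_pngs(mask_dir: Path | str, subject_id: str, pixel_spacing: float) -> LabelMapSequence:
    paths = sorted(Path(mask_dir).glob(f"{subject_id}_phase*.png"))
    if not paths:
        raise FileNotFoundError(f"no masks for {subject_id} in {mask_dir}")
    masks = np.stack([read_png(p) for p in paths]).astype(np.int64)
    return LabelMapSequence(masks=masks, pixel_spacing=pixel_spacing)


# ---------------------------------------------------------------------------
# NIfTI I/O (single-file 20-frame stacks)


def write_cine_nifti(cine: CineSequence, path: Path | str) -> None:
    """Write a cine as a (H, W, n_phases) NIfTI volume with mm spacing."""
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required for NIfTI output")
    data = np.moveaxis(np.asarray(cine.frames), 0, -1)
    affine = np.diag([cine.pixel_spacing, cine.pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def read_cine_nifti(path: Path | str) -> CineSequence:
    if nib is None:  # pragma: no cover
        raise ImportError("nibabel is required for NIfTI input")
    img = nib.load(str(path))
    data = np.moveaxis(np.asarray(img.get_fdata()), -1, 0)
    spacing = float(img.header.get_zooms()[0])
    if spacing <= 0:  # defensive: some headers carry zero zooms
        warnings.warn("NIfTI header has no pixel spacing; assuming 1 mm")
        spacing = 1.0
    return CineSequence(frames=data, pixel_spacing=spacing)
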
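"""Synthetic four-chamber cine phantoms with known ground truth.

Each phantom subject is a beating "heart" of four non-overlapping
quasi-elliptical blood pools on a 2-D raster: ventricles (LV, RV) in the
lower half shrink towards mid-cycle, atria (LA, RA) in the upper half expand
towards the same mid-cycle phase, mimicking a 20-phase ECG-gated cine with
end-diastole at phase 0.  Intensities caricature bright-blood SSFP contrast:
bright blood pool, dark myocardial rim, dim background, plus additive
Gaussian noise.

The analytic per-phase area of every chamber is known exactly, so rendered
masks can be validated against the generating curves, and downstream area /
fractional-area-change / enlargement analyses have an exact ground truth.

Chamber sizes are drawn relative to the published sex-specific BSA-indexed
enlargement cut-offs so that "enlarged" and "normal" subjects are separated
by a controlled margin on the indexed end-diastolic area scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .chambers import ATRIA, CHAMBERS, CHAMBER_CODES, chamber_type
from .io import CineSequence, LabelMapSequence, write_cine_pngs, write_labelmap_pngs

#: acquisition field of view in mm (isotropic square)
FIELD_OF_VIEW_MM = 350.0

#: default raster matches the post-preprocessing geometry: 128 px over 350 mm
DEFAULT_RASTER = (128, 128)

#: intensity levels of the piecewise-constant SSFP caricature
BLOOD_INTENSITY = 200.0
MYOCARDIUM_INTENSITY = 60.0
BACKGROUND_INTENSITY = 30.0

# chamber layout on the unit square: (row, col) centers and row/col axis ratio
_CHAMBER_LAYOUT: dict[str, tuple[float, float, float]] = {
    "LV": (0.70, 0.30, 1.55),  # ventricles: elongated along rows
    "RV": (0.70, 0.70, 1.30),
    "LA": (0.28, 0.30, 1.10),  # atria: near-circular
    "RA": (0.28, 0.70, 0.95),
}

# myocardial rim thickness in pixels, ordered as in the real heart
# (LV wall >> RV wall > LA wall >= RA wall): the local-appearance cue a
# reader (or a network) uses to identify a chamber, which position alone
# cannot provide once vertical-flip augmentation is in play
_RIM_PX: dict[str, int] = {"LV": 4, "RV": 3, "LA": 2, "RA": 1}


class PhantomGeometryError(ValueError):
    """Raised when requested chamber sizes cannot fit without overlap."""


@dataclass
class PhantomSubjectParams:
    """Generating parameters of one phantom subject.

    ``chamber_eda`` is the area (cm^2) of each chamber at phase 0;
    ``contraction_fraction`` the peak fractional excursion over the cycle
    (ventricles lose, atria gain that fraction of their EDA at
    ``peak_phase``); ``peak_phase`` the shared phase of ventricular minimum
    and atrial maximum.
    """

    subject_id: str
    sex: str
    bsa: float
    chamber_eda: dict[str, float]
    contraction_fraction: dict[str, float]
    peak_phase: dict[str, int]
    noise_sd: float = 0.0
    enlargement_flags: dict[str, bool] = field(default_factory=dict)
    n_phases: int = 20

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.bsa <= 0:
            raise ValueError("BSA must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for ch in CHAMBERS:
            if self.chamber_eda.get(ch, 0.0) <= 0:
                raise ValueError(f"chamber_eda[{ch}] must be positive")
            cf = self.contraction_fraction.get(ch)
            if cf is None or not (0.0 < cf < 1.0):
                raise ValueError(f"contraction_fraction[{ch}] must be in (0,1)")
            pk = self.peak_phase.get(ch)
            if pk is None or not (1 <= pk <= self.n_phases - 1):
                raise ValueError(f"peak_phase[{ch}] out of [1, n_phases-1]")
        # all chambers beat on the same cardiac cycle
        if len(set(self.peak_phase[ch] for ch in CHAMBERS)) != 1:
            raise ValueError("all chambers must share one peak_phase")


def _cycle_weight(phase: int, peak: int, n_phases: int) -> float:
    """Raised-cosine unimodal weight with w(0)=0 and w(peak)=1.

    Rises over [0, peak], falls over [peak, n_phases] (so the implicit
    phase n_phases, i.e. the next beat's phase 0, returns to 0).
    """
    if phase <= peak:
        return 0.5 * (1.0 - np.cos(np.pi * phase / peak))
    return 0.5 * (1.0 - np.cos(np.pi * (n_phases - phase) / (n_phases - peak)))


def chamber_area_curve(params: PhantomSubjectParams, chamber: str, phase: int) -> float:
    """Analytic area (cm^2) of ``chamber`` at ``phase``.

    area(p) = EDA * (1 - s * cf * w(p)) with s=+1 for ventricles (shrink)
    and s=-1 for atria (expand); w is a raised cosine peaking at
    ``peak_phase`` with w(0)=0, so area(0) equals the EDA exactly.
    """
    if not (0 <= phase < params.n_phases):
        raise ValueError(f"phase {phase} out of range [0, {params.n_phases})")
    eda = params.chamber_eda[chamber]
    cf = params.contraction_fraction[chamber]
    sign = -1.0 if chamber in ATRIA else 1.0
    w = _cycle_weight(phase, params.peak_phase[chamber], params.n_phases)
    return eda * (1.0 - sign * cf * w)


def _chamber_pixels(
    shape: tuple[int, int], chamber: str, n_pixels: int
) -> np.ndarray:
    """Binary mask of the ``n_pixels`` raster pixels closest (in normalized
    elliptical distance) to the chamber's layout center.

    Selecting exactly ``n_pixels`` pins the rendered pixel count to the
    analytic area within a single pixel of rounding; the region is an
    ellipse up to pixelization.
    """
    h, w = shape
    cr_f, cc_f, ratio = _CHAMBER_LAYOUT[chamber]
    cr, cc = cr_f * h, cc_f * w
    # semi-axes of the ellipse containing n_pixels: pi*a*b = n, a/b = ratio
    a_row = np.sqrt(n_pixels * ratio / np.pi)
    a_col = np.sqrt(n_pixels / (np.pi * ratio))
    rows = np.arange(h)[:, None] + 0.0
    cols = np.arange(w)[None, :] + 0.0
    d2 = ((rows - cr) / a_row) ** 2 + ((cols - cc) / a_col) ** 2
    flat = d2.ravel()
    # deterministic tie-break: distance, then row-major position
    order = np.lexsort((np.arange(flat.size), flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_pixels]] = True
    return mask.reshape(shape)


def render_phase(
    params: PhantomSubjectParams,
    phase: int,
    raster_shape: tuple[int, int] = DEFAULT_RASTER,
    pixel_spacing: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one cine phase as (intensity uint8 raster, label raster).

    Deterministic given ``seed`` (the seed drives only the Gaussian noise).
    Raises :class:`PhantomGeometryError` if any two chambers would come
    closer than the 2-pixel septal gap.
    """
    if pixel_spacing is None:
        pixel_spacing = FIELD_OF_VIEW_MM / raster_shape[0]
    px_area_cm2 = pixel_spacing**2 / 100.0

    chamber_masks: dict[str, np.ndarray] = {}
    for ch in CHAMBERS:
        target_cm2 = chamber_area_curve(params, ch, phase)
        n_px = int(round(target_cm2 / px_area_cm2))
        if n_px < 1:
            raise PhantomGeometryError(
                f"{ch} area {target_cm2:.2f} cm^2 is below one pixel at "
                f"{pixel_spacing:.2f} mm spacing"
            )
        chamber_masks[ch] = _chamber_pixels(raster_shape, ch, n_px)

    # septal gap >= 2 px: 1-px dilations of distinct chambers must not touch
    dilated = {
        ch: ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))
        for ch, m in chamber_masks.items()
    }
    for i, a in enumerate(CHAMBERS):
        for b in CHAMBERS[i + 1 :]:
            if np.any(dilated[a] & dilated[b]):
                raise PhantomGeometryError(f"chambers {a} and {b} overlap")

    label = np.zeros(raster_shape, dtype=np.uint8)
    for ch in CHAMBERS:
        label[chamber_masks[ch]] = CHAMBER_CODES[ch]

    frame = np.full(raster_shape, BACKGROUND_INTENSITY, dtype=np.float64)
    blood = label > 0
    rim = np.zeros(raster_shape, dtype=bool)
    for ch in CHAMBERS:
        rim |= ndimage.binary_dilation(chamber_masks[ch], iterations=_RIM_PX[ch])
    rim &= ~blood
    frame[rim] = MYOCARDIUM_INTENSITY
    frame[blood] = BLOOD_INTENSITY
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        frame = frame + rng.normal(0.0, params.noise_sd, size=raster_shape)
    frame = np.clip(np.floor(frame + 0.5), 0, 255).astype(np.uint8)
    return frame, label


def simulate_subject(
    params: PhantomSubjectParams,
    raster_shape: tuple[int, int] = DEFAULT_RASTER,
    pixel_spacing: float | None = None,
    seed: int = 0,
) -> tuple[CineSequence, LabelMapSequence]:
    """Render the full cine (all phases) of one subject."""
    if pixel_spacing is None:
        pixel_spacing = FIELD_OF_VIEW_MM / raster_shape[0]
    frames, labels = [], []
    for p in range(params.n_phases):
        # per-phase noise stream derived from the subject seed
        f, m = render_phase(params, p, raster_shape, pixel_spacing, seed=seed * 1009 + p)
        frames.append(f)
        labels.append(m)
    cine = CineSequence(frames=np.stack(frames), pixel_spacing=pixel_spacing)
    masks = LabelMapSequence(masks=np.stack(labels).astype(np.int64), pixel_spacing=pixel_spacing)
    return cine, masks


# ---------------------------------------------------------------------------
# Cohort sampling


#: BSA-indexed EDA cut-offs (cm^2/m^2) the cohort is sampled around.
#: LA/RV/RA are the published sex-specific reference values; LV uses the
#: ROC-derived area cut-off (the literature LV reference is volumetric and
#: outside a 2-D pipeline's reach).
SAMPLING_CUTOFFS: dict[str, dict[str, float]] = {
    "LV": {"male": 23.8, "female": 23.8},
    "LA": {"male": 11.9, "female": 12.7},
    "RV": {"male": 13.6, "female": 12.6},
    "RA": {"male": 11.1, "female": 11.0},
}

#: normal subjects sit in [0.65, 0.90] x cutoff, enlarged in [1.10, 1.35] x
#: cutoff on the indexed-EDA scale — a >= 20% relative separation.
NORMAL_BAND = (0.65, 0.90)
ENLARGED_BAND = (1.10, 1.35)


def sample_subject_params(
    subject_id: str,
    rng: np.random.Generator,
    enlargement_prevalence: dict[str, float] | None = None,
    noise_sd: float = 10.0,
    n_phases: int = 20,
) -> PhantomSubjectParams:
    """Draw one subject's generating parameters.

    Sex is a fair coin; BSA is Gaussian around 1.7 m^2 (men) / 1.5 m^2
    (women), clipped to [1.3, 2.2]; each chamber's indexed EDA is drawn
    below or above its enlargement cut-off according to the drawn flag;
    contraction fractions are physiologic (ventricular FAC 35-55%, atrial
    reservoir excursion 35-50%); the shared peak phase is mid-cycle.
    """
    prevalence = enlargement_prevalence or {}
    sex = "male" if rng.random() < 0.5 else "female"
    mu, sd = (1.7, 0.2) if sex == "male" else (1.5, 0.15)
    bsa = float(np.clip(rng.normal(mu, sd), 1.3, 2.2))
    peak = int(rng.integers(8, 13))  # mid-cycle of a 20-phase cine

    eda, cf, flags, peaks = {}, {}, {}, {}
    for ch in CHAMBERS:
        enlarged = bool(rng.random() < prevalence.get(ch, 0.0))
        lo, hi = ENLARGED_BAND if enlarged else NORMAL_BAND
        indexed = SAMPLING_CUTOFFS[ch][sex] * rng.uniform(lo, hi)
        eda[ch] = indexed * bsa
        cf[ch] = rng.uniform(0.35, 0.55) if chamber_type(ch) == "ventricle" else rng.uniform(0.35, 0.50)
        flags[ch] = enlarged
        peaks[ch] = peak
    return PhantomSubjectParams(
        subject_id=subject_id,
        sex=sex,
        bsa=bsa,
        chamber_eda=eda,
        contraction_fraction=cf,
        peak_phase=peaks,
        noise_sd=noise_sd,
        enlargement_flags=flags,
        n_phases=n_phases,
    )


def ground_truth_function(params: PhantomSubjectParams) -> dict[str, dict[str, float]]:
    """EDA/ESA/FAC per chamber from the analytic area curves."""
    out: dict[str, dict[str, float]] = {}
    for ch in CHAMBERS:
        areas = [chamber_area_curve(params, ch, p) for p in range(params.n_phases)]
        eda = areas[0]
        if ch in ATRIA:
            esa = max(areas)
        else:
            esa = min(areas)
        out[ch] = {
            "eda_cm2": eda,
            "esa_cm2": esa,
            "fac_pct": 100.0 * abs(eda - esa) / eda,
            "eda_indexed": eda / params.bsa,
        }
    return out


def generate_cohort(
    n_subjects: int,
    enlargement_prevalence: dict[str, float] | None = None,
    seed: int = 0,
    out_dir: Path | str | None = None,
    raster_shape: tuple[int, int] = DEFAULT_RASTER,
    noise_sd: float = 10.0,
    n_phases: int = 20,
    write_images: bool = True,
) -> tuple[pd.DataFrame, list[PhantomSubjectParams]]:
    """Simulate a cohort; optionally write frames/masks PNGs and cohort.csv.

    Returns the manifest (one row per subject with sex, BSA and per-chamber
    ground-truth EDA/ESA/FAC and enlargement flags) plus the generating
    parameters.  Bit-identical for a given seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    pixel_spacing = FIELD_OF_VIEW_MM / raster_shape[0]

    rows = []
    all_params = []
    for i in range(n_subjects):
        sid = f"subj{i:03d}"
        params = sample_subject_params(
            sid, rng, enlargement_prevalence, noise_sd=noise_sd, n_phases=n_phases
        )
        all_params.append(params)
        row: dict[str, object] = {
            "subject_id": sid,
            "sex": params.sex,
            "bsa_m2": round(params.bsa, 4),
        }
        truth = ground_truth_function(params)
        for ch in CHAMBERS:
            row[f"{ch}_eda_cm2"] = round(truth[ch]["eda_cm2"], 4)
            row[f"{ch}_esa_cm2"] = round(truth[ch]["esa_cm2"], 4)
            row[f"{ch}_fac_pct"] = round(truth[ch]["fac_pct"], 4)
            row[f"{ch}_enlarged"] = int(params.enlargement_flags[ch])
        rows.append(row)

        if out_dir is not None and write_images:
            cine, masks = simulate_subject(
                params, raster_shape, pixel_spacing, seed=seed + 7919 * (i + 1)
            )
            write_cine_pngs(cine, Path(out_dir) / "frames", sid)
            write_labelmap_pngs(masks, Path(out_dir) / "masks", sid)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = manifest.copy()
        meta.insert(3, "pixel_spacing_mm", pixel_spacing)
        meta.insert(4, "n_phases", n_phases)
        meta.to_csv(out / "cohort.csv", index=False)
    return manifest, all_params
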
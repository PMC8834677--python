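"""Functional assessment from per-phase chamber masks.

The first cine phase defines the end-diastolic area (EDA); the ventricular
minimum / atrial maximum over the cycle defines the end-systolic area
(ESA); the fractional area change FAC = 100 * |EDA - ESA| / EDA is a 2-D
surrogate of contractile (ventricles) or reservoir (atria) function.  The
absolute difference keeps atrial FAC positive even though atrial ESA
exceeds EDA.

Chamber enlargement is called when the BSA-indexed EDA strictly exceeds a
sex-specific reference cut-off.  LA/RV/RA cut-offs are the published
echo/CMR reference areas; the LV reference is volumetric (EDV/BSA), which a
single-slice pipeline cannot compute, so the LV uses the ROC-derived area
cut-off instead (sex-independent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .chambers import CHAMBERS, CHAMBER_CODES, chamber_type
from .io import LabelMapSequence


@dataclass
class AreaSeries:
    """Per-phase physical areas (cm^2) of one chamber."""

    chamber: str
    areas: np.ndarray
    pixel_spacing: float

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=np.float64)
        if self.areas.ndim != 1 or self.areas.size < 2:
            raise ValueError("areas must be a 1-D series of >= 2 phases")
        if (self.areas < 0).any():
            raise ValueError("areas must be nonnegative")


@dataclass
class FunctionalResult:
    chamber: str
    eda: float  # cm^2, first-phase area
    esa: float  # cm^2, ventricular min / atrial max
    esa_phase: int
    fac: float  # percent
    eda_indexed: float | None = None  # cm^2/m^2, set by classify_enlargement
    enlarged: bool | None = None


#: sex-specific BSA-indexed EDA cut-offs, cm^2/m^2 (strict > calls enlargement)
REFERENCE_CUTOFFS: dict[str, dict[str, float]] = {
    "LV": {"male": 23.8, "female": 23.8},  # ROC-derived area cut-off
    "LA": {"male": 11.9, "female": 12.7},
    "RV": {"male": 13.6, "female": 12.6},
    "RA": {"male": 11.1, "female": 11.0},
}

#: ROC-derived optimal indexed-EDA cut-offs for the automated classifier
ROC_OPTIMAL_CUTOFFS: dict[str, float] = {"LV": 23.8, "LA": 12.9, "RV": 13.4, "RA": 11.2}


@dataclass
class EnlargementCutoffs:
    """BSA-indexed EDA thresholds per chamber and sex."""

    thresholds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in REFERENCE_CUTOFFS.items()}
    )

    def threshold(self, chamber: str, sex: str) -> float:
        try:
            t = self.thresholds[chamber][sex]
        except KeyError as exc:
            raise ValueError(f"no cut-off for chamber={chamber!r}, sex={sex!r}") from exc
        if t <= 0:
            raise ValueError("cut-offs must be positive")
        return t


def area_from_mask(mask: np.ndarray, pixel_spacing: float) -> float:
    """Physical area in cm^2: pixel count * spacing^2 / 100 (mm^2 -> cm^2)."""
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be positive")
    return float(np.count_nonzero(np.asarray(mask))) * pixel_spacing**2 / 100.0


def area_series(labels: LabelMapSequence, chamber: str) -> AreaSeries:
    """Per-phase areas of one chamber from a label-map sequence."""
    code = CHAMBER_CODES[chamber]
    areas = [area_from_mask(labels.masks[p] == code, labels.pixel_spacing) for p in range(labels.n_phases)]
    return AreaSeries(chamber=chamber, areas=np.array(areas), pixel_spacing=labels.pixel_spacing)


def functional_params(series: AreaSeries, chamber_kind: str | None = None) -> FunctionalResult:
    """EDA, ESA (with phase) and FAC of one chamber's area series.

    Ventricles take the minimum area as ESA, atria the maximum; ties go to
    the earliest phase.  A zero EDA leaves FAC undefined (NaN) with a
    warning.
    """
    kind = chamber_kind or chamber_type(series.chamber)
    if kind not in ("ventricle", "atrium"):
        raise ValueError(f"chamber_kind must be ventricle/atrium, got {kind!r}")
    areas = series.areas
    eda = float(areas[0])
    if kind == "ventricle":
        esa_phase = int(np.argmin(areas))
    else:
        esa_phase = int(np.argmax(areas))
    esa = float(areas[esa_phase])
    if eda == 0:
        warnings.warn(f"{series.chamber}: zero EDA, FAC undefined")
        fac = float("nan")
    else:
        fac = 100.0 * abs(eda - esa) / eda
    return FunctionalResult(chamber=series.chamber, eda=eda, esa=esa, esa_phase=esa_phase, fac=fac)


def classify_enlargement(
    result: FunctionalResult,
    sex: str,
    bsa: float,
    cutoffs: EnlargementCutoffs | None = None,
) -> bool:
    """BSA-index the EDA and call enlargement by strict threshold excess.

    Fills ``result.eda_indexed`` and ``result.enlarged`` in place and
    returns the flag.
    """
    if bsa <= 0:
        raise ValueError("BSA must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be male/female, got {sex!r}")
    cutoffs = cutoffs or EnlargementCutoffs()
    result.eda_indexed = result.eda / bsa
    result.enlarged = result.eda_indexed > cutoffs.threshold(result.chamber, sex)
    return result.enlarged


def analyze_labelmaps(
    labels: LabelMapSequence,
    sex: str | None = None,
    bsa: float | None = None,
    cutoffs: EnlargementCutoffs | None = None,
) -> dict[str, FunctionalResult]:
    """Full functional profile (all four chambers) of one subject's masks."""
    out = {}
    for ch in CHAMBERS:
        res = functional_params(area_series(labels, ch))
        if sex is not None and bsa is not None and res.eda > 0:
            classify_enlargement(res, sex, bsa, cutoffs)
        out[ch] = res
    return out
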
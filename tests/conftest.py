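import numpy as np
import pytest
import warnings

from cine4ch.pipeline import PipelineConfig, run_pipeline
from cine4ch.phantom import PhantomSubjectParams


@pytest.fixture
def subject_params() -> PhantomSubjectParams:
    """One noise-free phantom subject with round numbers."""
    return PhantomSubjectParams(
        subject_id="fix0",
        sex="male",
        bsa=1.8,
        chamber_eda={"LV": 30.0, "LA": 16.0, "RV": 20.0, "RA": 15.0},
        contraction_fraction={"LV": 0.45, "LA": 0.40, "RV": 0.40, "RA": 0.40},
        peak_phase={c: 10 for c in ("LV", "LA", "RV", "RA")},
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def desk_bundle():
    """One shared desk-scale end-to-end run: 40/10/20 phantom subjects,
    64x64 frames, depth-2/8-filter U-Net, 5 epochs, CPU only."""
    cfg = PipelineConfig(seed=20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)


def random_mask(rng: np.random.Generator, shape=(16, 16), p=0.3, min_pixels=5) -> np.ndarray:
    """Random binary mask with at least ``min_pixels`` foreground pixels."""
    while True:
        m = rng.random(shape) < p
        if m.sum() >= min_pixels:
            return m
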
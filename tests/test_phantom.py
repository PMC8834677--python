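"""Phantom generator: analytic curves, rendering, cohort sampling."""

import numpy as np
import pytest

from cine4ch.chambers import ATRIA, CHAMBERS, CHAMBER_CODES
from cine4ch.phantom import (
    PhantomGeometryError,
    PhantomSubjectParams,
    chamber_area_curve,
    generate_cohort,
    render_phase,
    simulate_subject,
)


class TestAreaCurve:
    def test_phase_zero_is_eda(self, subject_params):
        for ch in CHAMBERS:
            assert chamber_area_curve(subject_params, ch, 0) == subject_params.chamber_eda[ch]

    def test_ventricle_shrinks_to_peak(self, subject_params):
        subject_params.chamber_eda["LV"] = 20.0
        subject_params.contraction_fraction["LV"] = 0.4
        assert chamber_area_curve(subject_params, "LV", 10) == pytest.approx(12.0)

    def test_atrium_expands_to_peak(self, subject_params):
        subject_params.chamber_eda["LA"] = 10.0
        subject_params.contraction_fraction["LA"] = 0.3
        assert chamber_area_curve(subject_params, "LA", 10) == pytest.approx(13.0)

    def test_unique_extremum_at_peak_phase(self, subject_params):
        for ch in CHAMBERS:
            curve = [chamber_area_curve(subject_params, ch, p) for p in range(20)]
            extremum = np.argmax(curve) if ch in ATRIA else np.argmin(curve)
            assert extremum == subject_params.peak_phase[ch]

    def test_phase_out_of_range(self, subject_params):
        with pytest.raises(ValueError):
            chamber_area_curve(subject_params, "LV", 20)


class TestRenderPhase:
    def test_rendered_area_matches_curve_within_5pct(self, subject_params):
        spacing = 350 / 128
        for phase in (0, 5, 10, 15):
            _, label = render_phase(subject_params, phase, seed=1)
            for ch in CHAMBERS:
                target = chamber_area_curve(subject_params, ch, phase)
                got = (label == CHAMBER_CODES[ch]).sum() * spacing**2 / 100
                assert abs(got - target) / target <= 0.05

    def test_deterministic_given_seed(self, subject_params):
        subject_params.noise_sd = 12.0
        f1, m1 = render_phase(subject_params, 3, seed=9)
        f2, m2 = render_phase(subject_params, 3, seed=9)
        assert np.array_equal(f1, f2) and np.array_equal(m1, m2)
        f3, _ = render_phase(subject_params, 3, seed=10)
        assert not np.array_equal(f1, f3)

    def test_overlapping_chambers_raise_geometry_error(self, subject_params):
        subject_params.chamber_eda["LV"] = 400.0  # absurd: fills the half-raster
        with pytest.raises(PhantomGeometryError):
            render_phase(subject_params, 0, seed=0)

    def test_intensity_model_levels(self, subject_params):
        frame, label = render_phase(subject_params, 0, seed=0)
        assert frame[label > 0].min() == frame[label > 0].max() == 200
        assert (frame == 30).sum() > 0.5 * frame.size  # background dominates

    def test_acquisition_like_raster(self, subject_params):
        frame, label = render_phase(
            subject_params, 0, raster_shape=(352, 352), pixel_spacing=350 / 352, seed=0
        )
        assert frame.shape == (352, 352)
        assert set(np.unique(label)) == {0, 1, 2, 3, 4}


class TestRenderedDynamics:
    def test_extremum_phase_recovered_from_masks(self, subject_params):
        _, labels = simulate_subject(subject_params, seed=4)
        for ch in CHAMBERS:
            counts = [(labels.masks[p] == CHAMBER_CODES[ch]).sum() for p in range(20)]
            extremum = np.argmax(counts) if ch in ATRIA else np.argmin(counts)
            assert extremum == subject_params.peak_phase[ch]

    def test_every_chamber_present_every_phase(self, subject_params):
        _, labels = simulate_subject(subject_params, seed=4)
        for p in range(labels.n_phases):
            assert set(np.unique(labels.masks[p])) == {0, 1, 2, 3, 4}


class TestCohort:
    def test_manifest_self_consistency(self, tmp_path):
        manifest, params = generate_cohort(
            10, {"LA": 0.5}, seed=3, out_dir=tmp_path, raster_shape=(64, 64)
        )
        assert len(manifest) == 10
        assert (tmp_path / "cohort.csv").exists()
        # manifest flags match the realized parameter draws
        for i, p in enumerate(params):
            for ch in CHAMBERS:
                assert manifest.loc[i, f"{ch}_enlarged"] == int(p.enlargement_flags[ch])
        # 20 phases of frames and masks per subject
        assert len(list((tmp_path / "frames").glob("subj000_*.png"))) == 20
        assert len(list((tmp_path / "masks").glob("subj000_*.png"))) == 20

    def test_zero_prevalence_all_normal(self):
        manifest, _ = generate_cohort(8, {c: 0.0 for c in CHAMBERS}, seed=5, out_dir=None)
        for ch in CHAMBERS:
            assert manifest[f"{ch}_enlarged"].sum() == 0

    def test_enlarged_male_la_exceeds_cutoff(self):
        manifest, params = generate_cohort(40, {"LA": 0.6}, seed=6, out_dir=None)
        hits = 0
        for i, p in enumerate(params):
            if p.sex == "male" and p.enlargement_flags["LA"]:
                hits += 1
                assert manifest.loc[i, "LA_eda_cm2"] / p.bsa > 11.9
        assert hits > 0

    def test_same_seed_bit_identical(self):
        m1, _ = generate_cohort(6, {"RV": 0.5}, seed=11, out_dir=None)
        m2, _ = generate_cohort(6, {"RV": 0.5}, seed=11, out_dir=None)
        assert m1.equals(m2)

    def test_invalid_subject_count(self):
        with pytest.raises(ValueError):
            generate_cohort(0, seed=0, out_dir=None)


class TestParamsValidation:
    def test_mismatched_peak_phases_rejected(self, subject_params):
        kwargs = dict(
            subject_id="x",
            sex="male",
            bsa=1.8,
            chamber_eda=subject_params.chamber_eda,
            contraction_fraction=subject_params.contraction_fraction,
            noise_sd=0.0,
        )
        peaks = {c: 10 for c in CHAMBERS}
        peaks["RA"] = 12
        with pytest.raises(ValueError):
            PhantomSubjectParams(peak_phase=peaks, **kwargs)

    def test_contraction_fraction_range(self, subject_params):
        subject_params.contraction_fraction["LV"] = 1.2
        with pytest.raises(ValueError):
            PhantomSubjectParams(**subject_params.__dict__)
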
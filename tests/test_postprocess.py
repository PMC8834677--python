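"""Morphological cleanup: closing, Otsu binarization, component selection."""

import numpy as np
import pytest
from scipy import ndimage

from cine4ch.postprocess import (
    PostprocessConfig,
    binarize,
    close_map,
    largest_component,
    one_hot,
    postprocess_frame,
    postprocess_stack,
)


def brute_force_closing(img: np.ndarray, radius: int) -> np.ndarray:
    """Dilate-then-erode with an explicit Euclidean-disk offset list."""
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]
    h, w = img.shape

    def dilate(a):
        out = np.full_like(a, -np.inf, dtype=float)
        for r in range(h):
            for c in range(w):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < h and 0 <= c + dc < w
                ]
                out[r, c] = max(vals)
        return out

    def erode(a):
        out = np.full_like(a, np.inf, dtype=float)
        for r in range(h):
            for c in range(w):
                vals = [
                    a[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < h and 0 <= c + dc < w
                ]
                out[r, c] = min(vals)
        return out

    return erode(dilate(img))


def brute_force_otsu_partition(values: np.ndarray) -> np.ndarray:
    """Exhaustive between-class-variance maximizer over all partitions.

    Tries every cut between adjacent distinct values and returns the
    foreground membership (value > cut level) of the best split.
    """
    uniq = np.unique(values)
    best_cut, best_var = None, -1.0
    for cut in uniq[:-1]:
        lo, hi = values[values <= cut], values[values > cut]
        var = lo.size * hi.size * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_cut = var, cut
    return values > best_cut


class TestCloseMap:
    def test_radius_zero_identity(self):
        rng = np.random.default_rng(0)
        m = rng.random((12, 12))
        assert np.array_equal(close_map(m, 0), m)

    def test_slit_filled_matches_brute_force(self):
        blob = np.zeros((16, 16))
        blob[4:12, 3:13] = 1.0
        blob[4:12, 7:9] = 0.0  # 2-px-wide slit through the blob
        closed = close_map(blob, 3)
        assert (closed[5:11, 7:9] == 1.0).all()  # slit interior filled
        assert np.allclose(closed, brute_force_closing(blob, 3))

    def test_extensive_and_idempotent(self):
        rng = np.random.default_rng(2)
        m = rng.random((20, 20))
        closed = close_map(m, 3)
        assert (closed >= m - 1e-12).all()
        assert np.allclose(close_map(closed, 3), closed)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            close_map(np.zeros((4, 4)), -1)
        with pytest.raises(ValueError):
            PostprocessConfig(disk_radius_px=-2)


class TestBinarize:
    def test_bimodal_map_recovers_blob(self):
        m = np.full((10, 10), 0.05)
        m[3:7, 3:7] = 0.95
        out = binarize(m)
        assert np.array_equal(out, m > 0.5)

    def test_constant_map_warns_empty(self):
        with pytest.warns(UserWarning):
            out = binarize(np.full((5, 5), 0.4))
        assert not out.any()

    def test_matches_exhaustive_otsu_on_8_level_histogram(self):
        rng = np.random.default_rng(9)
        values = rng.choice(
            [10, 30, 55, 80, 150, 180, 210, 240],
            size=400,
            p=[0.2, 0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1],
        ).astype(float)
        img = values.reshape(20, 20)
        fg_ref = brute_force_otsu_partition(values).reshape(20, 20)
        assert np.array_equal(binarize(img), fg_ref)

    def test_agrees_with_skimage_on_8bit_data(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(13)
        img = np.concatenate(
            [rng.integers(0, 90, 200), rng.integers(160, 256, 200)]
        ).reshape(20, 20).astype(np.uint8)
        ours = binarize(img.astype(float))
        assert np.array_equal(ours, img > threshold_otsu(img))


class TestLargestComponent:
    def test_single_blob_unchanged(self):
        b = np.zeros((8, 8), bool)
        b[2:5, 2:5] = True
        assert np.array_equal(largest_component(b), b)

    def test_speckle_removed(self):
        b = np.zeros((16, 16), bool)
        b[2:12, 2:7] = True  # 50 px blob
        b[14, 13:16] = True  # 3 px speckle
        out = largest_component(b)
        assert out[2:12, 2:7].all() and not out[14, 13:16].any()
        # agrees with an independent flood-fill label count
        lab, n = ndimage.label(b, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(b, lab, range(1, n + 1))
        assert out.sum() == sizes.max()

    def test_tie_goes_to_earliest_scan_order(self):
        b = np.zeros((10, 10), bool)
        b[1:3, 1:6] = True  # 10 px, first pixel (1,1)
        b[6:8, 3:8] = True  # 10 px, first pixel (6,3)
        out = largest_component(b)
        assert out[1, 1] and not out[6, 3]

    def test_empty_stays_empty(self):
        b = np.zeros((4, 4), bool)
        assert not largest_component(b).any()

    def test_connectivity_4_vs_8(self):
        b = np.zeros((6, 6), bool)
        b[1, 1] = b[2, 2] = b[3, 3] = True  # diagonal chain
        b[5, 0] = True
        assert largest_component(b, connectivity=8).sum() == 3
        assert largest_component(b, connectivity=4).sum() == 1


class TestPostprocessStack:
    @staticmethod
    def clean_label_frame() -> np.ndarray:
        lab = np.zeros((32, 32), np.int64)
        lab[20:27, 4:11] = 1  # LV
        lab[4:11, 4:11] = 2  # LA
        lab[20:27, 20:27] = 3  # RV
        lab[4:11, 20:27] = 4  # RA
        return lab

    def test_clean_one_hot_is_fixed_point(self):
        lab = self.clean_label_frame()
        out = postprocess_frame(one_hot(lab))
        assert np.array_equal(out, lab)

    def test_small_false_positive_island_removed(self):
        lab = self.clean_label_frame()
        stack = one_hot(lab)
        stack[1, 14:16, 14:15] = 1.0  # 2-px LV island far from the LV
        stack[0, 14:16, 14:15] = 0.0
        out = postprocess_frame(stack)
        assert np.array_equal(out == 1, lab == 1)
        assert (out[14:16, 14:15] == 0).all()

    def test_all_background_warns(self):
        stack = np.zeros((5, 16, 16))
        stack[0] = 1.0
        with pytest.warns(UserWarning):
            out = postprocess_frame(stack)
        assert not out.any()

    def test_output_single_component_and_disjoint(self):
        rng = np.random.default_rng(4)
        # noisy soft maps around the clean fixture
        stack = one_hot(self.clean_label_frame()) * 0.8 + 0.2 * rng.random((5, 32, 32))
        stack /= stack.sum(axis=0)
        out = postprocess_frame(stack)
        for code in (1, 2, 3, 4):
            m = out == code
            if m.any():
                _, n = ndimage.label(m, structure=np.ones((3, 3)))
                assert n == 1

    def test_idempotent_on_own_output(self):
        lab = self.clean_label_frame()
        once = postprocess_frame(one_hot(lab))
        twice = postprocess_frame(one_hot(once))
        assert np.array_equal(once, twice)

    def test_stack_shape_contract(self):
        with pytest.raises(ValueError):
            postprocess_stack(np.zeros((5, 16, 16)))  # missing phase axis
        seq = postprocess_stack(one_hot(self.clean_label_frame())[None], pixel_spacing=2.0)
        assert seq.n_phases == 1 and seq.pixel_spacing == 2.0
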
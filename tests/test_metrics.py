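"""Dice and Mahalanobis metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from cine4ch.metrics import dice, extract_points, mahalanobis

from conftest import random_mask


def dice_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Set-counting Dice: coordinates as Python sets."""
    sx = {tuple(p) for p in np.argwhere(x)}
    sy = {tuple(p) for p in np.argwhere(y)}
    if not sx and not sy:
        return 1.0
    return 2.0 * len(sx & sy) / (len(sx) + len(sy))


def boundary_oracle(mask: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with a background 4-neighbour, by explicit loop."""
    h, w = mask.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                    pts.append((r, c))
                    break
    return pts


def mahalanobis_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Independent route: explicit sums for mean/covariance, closed-form
    2x2 inverse of the pooled covariance."""

    def stats(pts):
        n = len(pts)
        mr = sum(p[0] for p in pts) / n
        mc = sum(p[1] for p in pts) / n
        srr = sum((p[0] - mr) ** 2 for p in pts) / (n - 1)
        scc = sum((p[1] - mc) ** 2 for p in pts) / (n - 1)
        src = sum((p[0] - mr) * (p[1] - mc) for p in pts) / (n - 1)
        return n, np.array([mr, mc]), np.array([[srr, src], [src, scc]])

    nx, mx, sx = stats(boundary_oracle(x))
    ny, my, sy = stats(boundary_oracle(y))
    s = ((nx - 1) * sx + (ny - 1) * sy) / (nx + ny - 2)
    det = s[0, 0] * s[1, 1] - s[0, 1] * s[1, 0]
    sinv = np.array([[s[1, 1], -s[0, 1]], [-s[1, 0], s[0, 0]]]) / det
    d = mx - my
    return float(np.sqrt(d @ sinv @ d))


class TestDice:
    def test_identity_disjoint_and_half_overlap(self):
        a = np.zeros((4, 4), bool)
        a[0:2, 0:2] = True  # 4 px
        assert dice(a, a) == 1.0
        b = np.zeros((4, 4), bool)
        b[2:4, 2:4] = True
        assert dice(a, b) == 0.0
        c = np.zeros((4, 4), bool)
        c[0:2, 1:3] = True  # 4 px, overlap 2
        assert dice(a, c) == 0.5

    def test_both_empty_warns_and_returns_one(self):
        empty = np.zeros((4, 4), bool)
        with pytest.warns(UserWarning):
            assert dice(empty, empty) == 1.0
        one = empty.copy()
        one[1, 1] = True
        assert dice(empty, one) == 0.0

    def test_monotone_in_intersection(self):
        # growing overlap at fixed sizes never decreases DSC
        rng = np.random.default_rng(5)
        base = random_mask(rng)
        shifted = np.roll(base, 3, axis=0)
        closer = np.roll(base, 1, axis=0)
        assert dice(base, closer) >= dice(base, shifted)

    def test_matches_set_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            x, y = random_mask(rng), random_mask(rng)
            assert dice(x, y) == dice_oracle(x, y)


class TestExtractPoints:
    def test_single_pixel_filled(self):
        m = np.zeros((5, 5), bool)
        m[2, 3] = True
        cloud = extract_points(m, mode="filled")
        assert np.array_equal(cloud.mean, [2, 3])
        assert np.array_equal(cloud.covariance, np.zeros((2, 2)))

    def test_filled_3x3_square(self):
        m = np.zeros((3, 3), bool)
        m[:, :] = True
        cloud = extract_points(m, mode="filled")
        assert cloud.n == 9
        assert np.allclose(cloud.mean, [1.0, 1.0])
        # 9 coords, variance of {0,1,2} each thrice with n-1 denominator
        assert np.allclose(np.diag(cloud.covariance), [0.75, 0.75])

    def test_boundary_of_3x3_square_excludes_center(self):
        m = np.ones((5, 5), bool) * False
        m[1:4, 1:4] = True
        cloud = extract_points(m, mode="boundary")
        assert cloud.n == 8
        assert (2, 2) not in {tuple(p) for p in cloud.points.astype(int)}

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            extract_points(np.zeros((4, 4), bool))


class TestMahalanobis:
    def test_identical_masks_zero(self):
        rng = np.random.default_rng(0)
        m = random_mask(rng)
        assert mahalanobis(m, m) == 0.0

    def test_translation_invariance_and_symmetry(self):
        m = np.zeros((32, 32), bool)
        m[4:10, 5:12] = True
        n = np.zeros((32, 32), bool)
        n[8:13, 9:17] = True
        md = mahalanobis(m, n)
        m2 = np.roll(np.roll(m, 5, axis=0), 7, axis=1)
        n2 = np.roll(np.roll(n, 5, axis=0), 7, axis=1)
        assert mahalanobis(m2, n2) == pytest.approx(md, abs=1e-12)
        assert mahalanobis(n, m) == pytest.approx(md, abs=1e-12)

    def test_congruent_clouds_closed_form(self):
        # congruent (translated) masks share covariance S; MD = sqrt(d'S^-1 d)
        m = np.zeros((40, 40), bool)
        m[5:10, 5:13] = True  # 5x8 rectangle, 20+ boundary points
        n = np.roll(np.roll(m, 6, axis=0), 9, axis=1)
        cloud = extract_points(m, "boundary")
        d = np.array([6.0, 9.0])
        expected = np.sqrt(d @ np.linalg.inv(cloud.covariance) @ d)
        assert mahalanobis(m, n) == pytest.approx(expected, abs=1e-10)

    def test_doubling_offset_doubles_distance(self):
        m = np.zeros((64, 64), bool)
        m[10:16, 10:18] = True
        one = np.roll(m, 4, axis=1)
        two = np.roll(m, 8, axis=1)
        assert mahalanobis(m, two) == pytest.approx(2 * mahalanobis(m, one), rel=1e-10)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x, y = random_mask(rng), random_mask(rng)
            assert mahalanobis(x, y) == pytest.approx(mahalanobis_oracle(x, y), abs=1e-10)

    def test_degenerate_cloud_raises(self):
        tiny = np.zeros((8, 8), bool)
        tiny[2, 2] = True
        big = np.zeros((8, 8), bool)
        big[4:7, 4:7] = True
        with pytest.raises(ValueError):
            mahalanobis(tiny, big)

    def test_collinear_cloud_gets_ridge_with_warning(self):
        line_a = np.zeros((16, 16), bool)
        line_a[3, 2:9] = True  # all points on one row: singular covariance
        line_b = np.zeros((16, 16), bool)
        line_b[8, 2:9] = True
        with pytest.warns(UserWarning):
            md = mahalanobis(line_a, line_b)
        assert np.isfinite(md) and md > 0
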
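"""Segmentation-quality metrics: Dice coefficient and Mahalanobis distance.

DSC = 2|X n Y| / (|X| + |Y|) compares a reference mask X with a prediction
Y.  The Mahalanobis distance treats each mask as a point cloud of pixel
coordinates and measures the separation of the two cloud means in units of
their pooled coordinate covariance:

    MD = sqrt( (x̄ - ȳ)ᵀ S⁻¹ (x̄ - ȳ) ),
    S = ((n_x - 1) S_x + (n_y - 1) S_y) / (n_x + n_y - 2).

By default the point cloud is the mask contour (foreground pixels with at
least one background 4-neighbour); ``mode="filled"`` uses all foreground
pixels instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def dice(reference: np.ndarray, prediction: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks.

    Symmetric; 1 for identical non-empty masks, 0 for disjoint ones.  Two
    empty masks agree perfectly on absence and return 1 with a warning.
    """
    x = np.asarray(reference, dtype=bool)
    y = np.asarray(prediction, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx + ny == 0:
        warnings.warn("both masks empty: DSC undefined, returning 1")
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


@dataclass
class PointCloud:
    """Pixel-coordinate cloud of a mask with mean and (n-1) covariance."""

    points: np.ndarray  # (n, 2) of (row, col)
    mean: np.ndarray  # (2,)
    covariance: np.ndarray  # (2, 2)

    @property
    def n(self) -> int:
        return self.points.shape[0]


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connected


def extract_points(mask: np.ndarray, mode: str = "boundary") -> PointCloud:
    """Point cloud of a mask's contour (default) or filled interior.

    A contour pixel is a foreground pixel with at least one background
    4-neighbour; image-border foreground pixels count as contour.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot extract points from an empty mask")
    if mode == "boundary":
        interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
        sel = m & ~interior
    elif mode == "filled":
        sel = m
    else:
        raise ValueError(f"mode must be boundary/filled, got {mode!r}")
    pts = np.argwhere(sel).astype(np.float64)
    mean = pts.mean(axis=0)
    if pts.shape[0] < 2:
        cov = np.zeros((2, 2))
    else:
        cov = np.cov(pts.T, ddof=1)
    return PointCloud(points=pts, mean=mean, covariance=cov)


def mahalanobis(
    reference: np.ndarray, prediction: np.ndarray, mode: str = "boundary"
) -> float:
    """Mahalanobis distance between the point clouds of two masks.

    Uses the two-sample pooled covariance weighted by (n-1).  Zero for
    identical masks; invariant under a common translation of both.  A
    singular pooled covariance gets a small Tikhonov ridge
    (1e-6 * trace(S)/2 on the diagonal) with a warning.
    """
    cx = extract_points(reference, mode)
    cy = extract_points(prediction, mode)
    if cx.n < 3 or cy.n < 3:
        raise ValueError(
            f"need >= 3 points per cloud for a stable covariance (got {cx.n}, {cy.n})"
        )
    s = ((cx.n - 1) * cx.covariance + (cy.n - 1) * cy.covariance) / (cx.n + cy.n - 2)
    d = cx.mean - cy.mean
    if np.linalg.matrix_rank(s) < 2:
        eps = 1e-6 * np.trace(s) / 2.0
        if eps <= 0:
            eps = 1e-12
        warnings.warn("singular pooled covariance: adding Tikhonov ridge")
        s = s + eps * np.eye(2)
    md2 = float(d @ np.linalg.solve(s, d))
    return float(np.sqrt(max(md2, 0.0)))
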
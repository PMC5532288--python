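"""Geometric upper bounds from feasible samples.

The minimum-volume enclosing (Loewner) ellipsoid and the axis-aligned
bounding box of the feasible samples bound the explored part of the feasible
region from above.  As long as the Loewner ellipsoid keeps growing over a
run, new parts of the region are still being discovered.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .lpball import LpShape, log_unit_ball_volume

__all__ = ["Ellipsoid", "mvee", "ellipsoid_volume", "aabb_volume", "thin_points"]

logger = logging.getLogger(__name__)

MAX_ITER = 100_000


@dataclass
class Ellipsoid:
    """The ellipsoid ``{x : (x - center)' M (x - center) <= 1}``."""

    center: np.ndarray
    shape_matrix: np.ndarray  # symmetric positive definite

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        m = np.asarray(self.shape_matrix, float)
        if not np.allclose(m, m.T, atol=1e-9):
            raise ValueError("shape matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(m) <= 0):
            raise ValueError("shape matrix must be positive definite")
        self.shape_matrix = 0.5 * (m + m.T)

    def contains(self, x: np.ndarray, slack: float = 0.0) -> bool:
        d = np.asarray(x, float) - self.center
        return float(d @ self.shape_matrix @ d) <= 1.0 + slack


def mvee(points: np.ndarray, tolerance: float = 1e-7) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid by Khachiyan's algorithm.

    First-order iterative reweighting on the lifted points, stopped when the
    duality gap drops below ``tolerance``; every input point then lies inside
    the ellipsoid inflated by (1 + tolerance).  Requires at least n + 1
    affinely independent points.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2:
        raise ValueError("points must be a (count, n) array")
    m, n = pts.shape
    if m < n + 1:
        raise ValueError(f"need at least {n + 1} points in {n}-D, got {m}")
    centered = pts - pts.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-10 * max(1.0, np.abs(pts).max()))
    if rank < n:
        _, _, vt = np.linalg.svd(centered, full_matrices=True)
        deficient = vt[rank:]
        raise ValueError(
            "point set is affinely degenerate; no volume in direction(s) "
            f"{np.round(deficient, 4).tolist()}"
        )

    # the MVEE depends only on convex-hull vertices; prune when qhull is cheap
    if n <= 6 and m > 4 * (n + 1):
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
            m = pts.shape[0]
        except Exception:  # qhull degeneracies: fall through to full set
            pass

    q = np.column_stack([pts, np.ones(m)])  # lifted points, (m, n+1)
    u = np.full(m, 1.0 / m)
    d = n + 1
    inv = np.linalg.inv(q.T @ (q * u[:, None]))
    mdist = np.einsum("ij,jk,ik->i", q, inv, q)
    gap = float(np.max(mdist)) / d - 1.0
    for it in range(MAX_ITER):
        j = int(np.argmax(mdist))
        maximum = mdist[j]
        gap = maximum / d - 1.0
        if gap <= tolerance:
            break
        tau = (maximum - d) / (d * (maximum - 1.0))
        u *= 1.0 - tau
        u[j] += tau
        if it % 1000 == 999:  # periodic refresh against rank-one drift
            inv = np.linalg.inv(q.T @ (q * u[:, None]))
            mdist = np.einsum("ij,jk,ik->i", q, inv, q)
        else:
            # Sherman-Morrison update of inv((1-tau) X + tau q_j q_j')
            w = inv @ q[j]
            denom = (1.0 - tau) + tau * maximum
            proj = q @ w
            mdist = (mdist - tau * proj**2 / denom) / (1.0 - tau)
            inv = (inv - np.outer(w, w) * (tau / denom)) / (1.0 - tau)
    else:  # pragma: no cover - cap hit
        logger.warning("MVEE iteration cap (%d) reached; gap %.3e > tol %.3e; "
                       "returning best-so-far", MAX_ITER, gap, tolerance)

    center = pts.T @ u
    cov = pts.T @ (pts * u[:, None]) - np.outer(center, center)
    # recompute the gap exactly (the incremental mdist drifts slightly) and
    # inflate so containment holds even at early stop: the lifted distances
    # satisfy max (p-c)' S^-1 (p-c) = n + gap*(n+1)
    inv = np.linalg.inv(q.T @ (q * u[:, None]))
    gap = float(np.max(np.einsum("ij,jk,ik->i", q, inv, q))) / d - 1.0
    shape_matrix = np.linalg.inv(cov) / (n + max(gap, 0.0) * d)
    shape_matrix = 0.5 * (shape_matrix + shape_matrix.T)
    return Ellipsoid(center=center, shape_matrix=shape_matrix)


def ellipsoid_volume(e: Ellipsoid) -> float:
    """Volume ``vol(unit n-ball) / sqrt(det M)``, computed in log-space."""
    n = e.center.shape[0]
    sign, logdet = np.linalg.slogdet(e.shape_matrix)
    if sign <= 0:
        raise ValueError("shape matrix must be positive definite")
    return math.exp(log_unit_ball_volume(LpShape(p=2.0, n=n)) - 0.5 * logdet)


def aabb_volume(points: np.ndarray) -> float:
    """Volume of the axis-aligned bounding box of a point set (log-space)."""
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.size == 0:
        raise ValueError("point set must be nonempty")
    extents = pts.max(axis=0) - pts.min(axis=0)
    if np.any(extents == 0.0):
        return 0.0
    return math.exp(float(np.sum(np.log(extents))))


def thin_points(points: np.ndarray, cap: int = 5000) -> np.ndarray:
    """Every k-th point, with k chosen so at most ``cap`` points remain.

    Bound computations cost grows with point count; uniform thinning does not
    materially bias an enclosing object at these scales.
    """
    pts = np.asarray(points, float)
    if len(pts) <= cap:
        return pts
    k = int(math.ceil(len(pts) / cap))
    return pts[::k]
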
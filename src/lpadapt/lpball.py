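"""Geometry of n-dimensional Lp-balls.

The unit Lp-ball is the set ``{x : sum(|x_i|**p) <= 1}`` (for ``p = inf``,
``max |x_i| <= 1``).  Proposals used by the adaptation loop are affine images
of the unit ball: ``x = mean + radius * (transform @ s)`` with ``s`` uniform
on the unit ball and ``det(transform) = 1``, so the scalar radius carries all
scale while the transform carries orientation and aspect ratio.

All volume arithmetic is done in log-space internally; 20-dimensional volumes
overflow or underflow double precision otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "LpShape",
    "ProposalState",
    "lp_norm",
    "unit_ball_volume",
    "log_unit_ball_volume",
    "sample_unit_ball",
    "map_to_design_space",
    "proposal_volume",
    "log_proposal_volume",
]


@dataclass(frozen=True)
class LpShape:
    """Shape exponent and dimension of an Lp-ball.

    The supremum norm is represented by ``p = math.inf`` (a dedicated
    sentinel); all formulas branch on it explicitly rather than approximating
    it with a large finite exponent, which would overflow Gamma(1 + n/p).
    """

    p: float
    n: int

    def __post_init__(self) -> None:
        if not (self.p > 0):  # rejects NaN and non-positive p; inf passes
            raise ValueError(f"shape exponent p must be positive or inf, got {self.p}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"dimension n must be a positive integer, got {self.n}")

    @property
    def is_sup(self) -> bool:
        return math.isinf(self.p)


def lp_norm(x: np.ndarray, shape: LpShape) -> float:
    """p-norm of ``x``: ``(sum |x_i|^p)^(1/p)``; ``max |x_i|`` for p = inf.

    Valid for every p > 0 (for p < 1 this is the standard quasi-norm).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (shape.n,):
        raise ValueError(f"expected a vector of length {shape.n}, got shape {x.shape}")
    a = np.abs(x)
    if shape.is_sup:
        return float(a.max())
    return float(np.sum(a ** shape.p) ** (1.0 / shape.p))


def log_unit_ball_volume(shape: LpShape) -> float:
    """log-volume of the unit Lp-ball: ``n log(2 Gamma(1+1/p)) - log Gamma(1+n/p)``."""
    n, p = shape.n, shape.p
    if shape.is_sup:
        return n * math.log(2.0)
    return n * (math.log(2.0) + gammaln(1.0 + 1.0 / p)) - gammaln(1.0 + n / p)


def unit_ball_volume(shape: LpShape) -> float:
    """Volume of the unit Lp-ball, ``(2 Gamma(1+1/p))^n / Gamma(1+n/p)``."""
    return math.exp(log_unit_ball_volume(shape))


def coordinate_second_moment(shape: LpShape) -> float:
    """Per-coordinate second moment E[x_i^2] of the uniform unit-ball law.

    Writing a uniform ball point as ``u^(1/n) * s * y^(1/p)`` with
    ``y ~ Beta(1/p, (n-1)/p)`` marginally gives
    ``E[x_i^2] = n/(n+2) * Gamma(3/p) Gamma(n/p) / (Gamma(1/p) Gamma((n+2)/p))``
    (equal to ``1/(n+2)`` for p = 2); for the supremum ball the coordinates
    are i.i.d. uniform on [-1, 1], so the moment is 1/3.  Used to normalize
    feasible displacements so that an unconstrained batch leaves the adapted
    covariance stationary.
    """
    n, p = shape.n, shape.p
    if shape.is_sup:
        return 1.0 / 3.0
    log_m2 = (math.log(n / (n + 2.0)) + gammaln(3.0 / p) + gammaln(n / p)
              - gammaln(1.0 / p) - gammaln((n + 2.0) / p))
    return math.exp(log_m2)


def sample_unit_ball(shape: LpShape, count: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` i.i.d. points uniform on the unit Lp-ball.

    Generalized-Gamma construction: each coordinate is a sign-symmetric
    variate whose ``|.|^p`` is Gamma(1/p, 1)-distributed; the vector is
    normalized to the unit p-sphere and scaled by ``u^(1/n)`` with
    ``u ~ U(0,1)`` (the radial CDF of the uniform measure is ``t^n``).
    For p = inf, coordinates are i.i.d. uniform on [-1, 1].
    """
    if not (isinstance(count, (int, np.integer)) and count >= 1):
        raise ValueError(f"count must be a positive integer, got {count}")
    n, p = shape.n, shape.p
    if shape.is_sup:
        return rng.uniform(-1.0, 1.0, size=(count, n))
    g = rng.gamma(1.0 / p, 1.0, size=(count, n)) ** (1.0 / p)
    signs = rng.choice([-1.0, 1.0], size=(count, n))
    v = signs * g
    norms = np.sum(np.abs(v) ** p, axis=1) ** (1.0 / p)
    u = rng.uniform(size=count) ** (1.0 / n)
    return v * (u / norms)[:, None]


@dataclass
class ProposalState:
    """The adaptive proposal: an affinely mapped Lp-ball.

    ``mean`` is the current candidate design center, ``radius`` the global
    scale, ``transform`` a full-rank matrix with determinant 1 (the
    lower-triangular factor of the adapted covariance, renormalized after
    every update) and ``shape`` the Lp-ball being mapped.
    """

    mean: np.ndarray
    radius: float
    transform: np.ndarray
    shape: LpShape = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).copy()
        self.transform = np.asarray(self.transform, dtype=float).copy()
        n = self.mean.shape[0]
        if self.shape is None:
            self.shape = LpShape(p=2.0, n=n)
        if self.shape.n != n:
            raise ValueError(f"mean has dimension {n} but shape.n = {self.shape.n}")
        if self.transform.shape != (n, n):
            raise ValueError(f"transform must be {n}x{n}, got {self.transform.shape}")
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        det = np.linalg.det(self.transform)
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"transform determinant must be 1, got {det}")

    @classmethod
    def isotropic(cls, mean: np.ndarray, radius: float = 1.0, p: float = 2.0) -> "ProposalState":
        mean = np.asarray(mean, dtype=float)
        n = mean.shape[0]
        return cls(mean=mean, radius=radius, transform=np.eye(n), shape=LpShape(p=p, n=n))

    def copy(self) -> "ProposalState":
        return ProposalState(
            mean=self.mean.copy(),
            radius=self.radius,
            transform=self.transform.copy(),
            shape=self.shape,
        )


def map_to_design_space(s: np.ndarray, proposal: ProposalState) -> np.ndarray:
    """Affine image ``mean + radius * transform @ s`` of unit-ball point(s).

    Accepts a single n-vector or a (count, n) array of rows.
    """
    s = np.asarray(s, dtype=float)
    n = proposal.shape.n
    if s.shape[-1] != n:
        raise ValueError(f"point dimension {s.shape[-1]} != proposal dimension {n}")
    return proposal.mean + proposal.radius * (s @ proposal.transform.T)


def log_proposal_volume(proposal: ProposalState) -> float:
    """log-volume of the proposal body, ``n log r + log vol(unit ball)``.

    The transform has determinant 1 by invariant, so it contributes nothing.
    """
    n = proposal.shape.n
    return n * math.log(proposal.radius) + log_unit_ball_volume(proposal.shape)


def proposal_volume(proposal: ProposalState) -> float:
    """Volume of the proposal body: ``radius^n * det(transform) * vol(unit ball)``."""
    return math.exp(log_proposal_volume(proposal))
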
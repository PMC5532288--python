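"""The core Lp-Adaptation iteration.

Each step draws a batch of candidates uniformly from the current proposal
(an affinely mapped Lp-ball), asks the oracle for a verdict on each, then
adapts

* the radius per sample (multiplicative expansion on a hit, contraction on a
  miss, balanced so the log-radius drifts exactly zero at the target hitting
  probability),
* the mean and the covariance-derived transform per batch, from the feasible
  samples only, and
* an exponentially weighted empirical hitting probability per sample.

The instantaneous volume estimate is ``empirical P * volume(proposal)``:
the overlap fraction times the proposal volume approximates the measure of
``A`` covered by the proposal, which converges to vol(A) once the proposal
encloses the feasible region.
"""

from __future__ import annotations

import math
import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .lpball import (
    ProposalState,
    coordinate_second_moment,
    log_proposal_volume,
    map_to_design_space,
    sample_unit_ball,
)
from .oracles import Oracle

__all__ = [
    "AdaptConfig",
    "RunTrace",
    "AdaptState",
    "evaluate_batch",
    "radius_factors",
    "update_radius",
    "update_mean",
    "update_transform",
    "update_hitting_probability",
    "instantaneous_volume",
    "step",
]

logger = logging.getLogger(__name__)

#: tolerance on |det(transform) - 1| maintained after every update
DET_TOL = 1e-9


@dataclass(frozen=True)
class AdaptConfig:
    """Learning constants of the adaptation loop.

    Fields left ``None`` resolve to dimension-dependent defaults:
    ``population_size = max(1, 4 + floor(3 ln n))`` and
    ``mean_learning_rate = 1/e`` follow evolution-strategy conventions;
    ``cov_learning_rate = 0.2/n`` balances learning speed against the shape
    noise of low-rank scatter updates (an n^-2 rate cannot learn strongly
    anisotropic regions within practical budgets, while much faster rates
    leave enough shape noise to spoil coverage of pointed bodies such as
    L1 balls); ``radius_expansion_beta = 0.08/n`` keeps the stationary log-radius
    fluctuations — and with them the upward Jensen bias of the volume
    estimator, which scales like n * beta — at the few-percent level in
    every dimension; ``hit_smoothing_memory = 40 n`` averages the hit
    indicator over several radius-reversion times.
    """

    target_hitting_probability: float = 0.35
    population_size: Optional[int] = None
    mean_learning_rate: Optional[float] = None
    cov_learning_rate: Optional[float] = None
    radius_expansion_beta: Optional[float] = None
    hit_smoothing_memory: Optional[float] = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_hitting_probability < 1.0:
            raise ValueError("target_hitting_probability must lie in (0, 1)")
        for name in ("mean_learning_rate", "cov_learning_rate"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.population_size is not None and self.population_size < 1:
            raise ValueError("population_size must be >= 1")
        b = self.radius_expansion_beta
        if b is not None and not b > 0:
            raise ValueError("radius_expansion_beta must be positive")
        m = self.hit_smoothing_memory
        if m is not None and not m > 0:
            raise ValueError("hit_smoothing_memory must be positive")

    def resolve(self, n: int) -> "AdaptConfig":
        """Fill dimension-dependent defaults for an n-dimensional problem."""
        return replace(
            self,
            population_size=self.population_size
            if self.population_size is not None
            else max(1, 4 + int(math.floor(3.0 * math.log(n)))),
            mean_learning_rate=self.mean_learning_rate
            if self.mean_learning_rate is not None
            else 1.0 / math.e,
            cov_learning_rate=self.cov_learning_rate
            if self.cov_learning_rate is not None
            else 0.2 / n,
            radius_expansion_beta=self.radius_expansion_beta
            if self.radius_expansion_beta is not None
            else 0.08 / n,
            hit_smoothing_memory=self.hit_smoothing_memory
            if self.hit_smoothing_memory is not None
            else 40.0 * n,
        )


class RunTrace:
    """Per-evaluation history of a run.

    One record per oracle evaluation: the sampled point, its verdict, the
    radius and smoothed empirical hitting probability after the per-sample
    updates, the instantaneous volume estimate, and the proposal mean.
    """

    def __init__(self, n: int) -> None:
        self.n = n
        self.eval_index: List[int] = []
        self.points: List[np.ndarray] = []
        self.feasible: List[bool] = []
        self.radius: List[float] = []
        self.empirical_p: List[float] = []
        self.volume_estimate: List[float] = []
        self.means: List[np.ndarray] = []
        self.phase: List[int] = []

    def append(self, idx: int, point: np.ndarray, feasible: bool, radius: float,
               empirical_p: float, volume_estimate: float, mean: np.ndarray,
               phase: int = 0) -> None:
        if self.eval_index and idx <= self.eval_index[-1]:
            raise ValueError("evaluation indices must be strictly increasing")
        self.eval_index.append(idx)
        self.points.append(np.asarray(point, float).copy())
        self.feasible.append(bool(feasible))
        self.radius.append(float(radius))
        self.empirical_p.append(float(empirical_p))
        self.volume_estimate.append(float(volume_estimate))
        self.means.append(np.asarray(mean, float).copy())
        self.phase.append(int(phase))

    def __len__(self) -> int:
        return len(self.eval_index)

    @property
    def feasible_points(self) -> np.ndarray:
        """All feasible sampled points, as a (k, n) array."""
        if not self.points:
            return np.empty((0, self.n))
        pts = np.asarray(self.points)
        return pts[np.asarray(self.feasible, bool)]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"evaluation": self.eval_index}
        pts = np.asarray(self.points) if self.points else np.empty((0, self.n))
        for j in range(self.n):
            cols[f"x{j + 1}"] = pts[:, j] if len(pts) else []
        cols["feasible"] = np.asarray(self.feasible, dtype=int)
        cols["radius"] = self.radius
        cols["empirical_P"] = self.empirical_p
        cols["volume_estimate"] = self.volume_estimate
        cols["phase"] = self.phase
        return pd.DataFrame(cols)


@dataclass
class AdaptState:
    """Mutable state threaded through adaptation steps."""

    proposal: ProposalState
    empirical_p: float
    trace: RunTrace
    n_evals: int = 0

    @classmethod
    def initial(cls, mean: np.ndarray, config: AdaptConfig, p: float = 2.0,
                radius: float = 1.0) -> "AdaptState":
        prop = ProposalState.isotropic(mean, radius=radius, p=p)
        return cls(proposal=prop,
                   empirical_p=config.target_hitting_probability,
                   trace=RunTrace(prop.shape.n))


def evaluate_batch(proposal: ProposalState, oracle: Oracle, lam: int,
                   rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
    """Draw ``lam`` candidates from the proposal and query the oracle.

    Returns the design-space points and their feasibility flags; the
    oracle's counter advances by ``lam``.  Oracle exceptions are re-raised
    with the offending point attached.
    """
    if lam < 1:
        raise ValueError(f"batch size must be >= 1, got {lam}")
    s = sample_unit_ball(proposal.shape, lam, rng)
    points = map_to_design_space(s, proposal)
    flags = np.empty(lam, dtype=bool)
    for i, x in enumerate(points):
        try:
            flags[i] = oracle(x)
        except Exception as exc:
            raise RuntimeError(f"oracle failed on point {x.tolist()}") from exc
    return points, flags


def radius_factors(target_p: float, beta: float) -> Tuple[float, float]:
    """Expansion/contraction pair ``(f_e, f_c)`` for the radius control.

    ``f_e = 1 + beta (1 - P)`` and ``f_c = f_e^(-P/(1-P))`` so that
    ``f_e^P * f_c^(1-P) = 1``: the expected log-radius drift vanishes exactly
    when the hit rate equals the target hitting probability P.
    """
    f_e = 1.0 + beta * (1.0 - target_p)
    f_c = f_e ** (-target_p / (1.0 - target_p))
    return f_e, f_c


def update_radius(radius: float, hit: bool, config: AdaptConfig) -> float:
    """One per-sample multiplicative radius update."""
    if not radius > 0:
        raise ValueError("radius must be positive")
    f_e, f_c = radius_factors(config.target_hitting_probability,
                              config.radius_expansion_beta)
    return radius * (f_e if hit else f_c)


def update_mean(mean: np.ndarray, feasible_points: np.ndarray,
                config: AdaptConfig) -> np.ndarray:
    """Relax the mean toward the average of the batch's feasible points.

    With no feasible points the mean is returned unchanged.
    """
    feasible_points = np.atleast_2d(np.asarray(feasible_points, float)) \
        if np.size(feasible_points) else np.empty((0, len(mean)))
    if feasible_points.shape[0] == 0:
        return np.asarray(mean, float)
    eta = config.mean_learning_rate
    return (1.0 - eta) * np.asarray(mean, float) + eta * feasible_points.mean(axis=0)


def update_transform(transform: np.ndarray, displacements: np.ndarray,
                     config: AdaptConfig,
                     weights: Optional[np.ndarray] = None) -> np.ndarray:
    """Rank-k covariance update from feasible displacement directions.

    ``displacements`` are the feasible samples' displacements from the mean,
    normalized by the radius (so a stationary isotropic hit pattern leaves
    the shape unchanged).  The implied covariance ``C = T T'`` is relaxed
    toward the weighted scatter of the displacements, refactored (lower
    Cholesky) and renormalized to determinant 1 — the scalar radius carries
    all scale.
    """
    transform = np.asarray(transform, float)
    displacements = np.atleast_2d(np.asarray(displacements, float)) \
        if np.size(displacements) else np.empty((0, transform.shape[0]))
    k = displacements.shape[0]
    eta = config.cov_learning_rate
    if k == 0 or eta == 0.0:
        return transform
    if weights is None:
        weights = np.full(k, 1.0 / k)
    else:
        weights = np.asarray(weights, float)
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("weights must be nonnegative and sum to 1")
    cov = transform @ transform.T
    scatter = (displacements * weights[:, None]).T @ displacements
    cov = (1.0 - eta) * cov + eta * scatter
    cov = 0.5 * (cov + cov.T)
    try:
        lower = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # repair a non-PD intermediate by flooring eigenvalues
        w, v = np.linalg.eigh(cov)
        floor = 1e-12 * float(w.max())
        logger.warning("covariance update lost positive definiteness; "
                       "flooring eigenvalues at %.3e", floor)
        w = np.maximum(w, floor)
        lower = np.linalg.cholesky((v * w) @ v.T)
    # renormalize to determinant 1 in log-space
    log_det = float(np.sum(np.log(np.diag(lower))))
    return lower * math.exp(-log_det / transform.shape[0])


def update_hitting_probability(estimate: float, hits: np.ndarray,
                               config: AdaptConfig) -> float:
    """EWMA of the hit indicator with effective memory ``hit_smoothing_memory``."""
    if not 0.0 <= estimate <= 1.0:
        raise ValueError("hitting-probability estimate must lie in [0, 1]")
    alpha = 1.0 / config.hit_smoothing_memory
    for h in np.atleast_1d(hits):
        estimate = (1.0 - alpha) * estimate + alpha * float(h)
    return estimate


def instantaneous_volume(proposal: ProposalState, empirical_p: float) -> float:
    """Volume estimate ``empirical P * vol(proposal)`` (log-space product)."""
    if not 0.0 <= empirical_p <= 1.0:
        raise ValueError("empirical hitting probability must lie in [0, 1]")
    if empirical_p == 0.0:
        return 0.0
    return math.exp(math.log(empirical_p) + log_proposal_volume(proposal))


def step(state: AdaptState, oracle: Oracle, config: AdaptConfig,
         rng: np.random.Generator, phase: int = 0) -> AdaptState:
    """One adaptation step: a batch of evaluations plus all updates.

    The batch is drawn at the batch-start proposal.  Radius and empirical
    hitting probability are updated per sample (fastest feedback loop, and
    each sample appends a trace record); mean and transform are updated once
    per batch from the feasible samples.  Deterministic given (state, rng).
    """
    cfg = config if config.population_size is not None else config.resolve(state.proposal.shape.n)
    prop = state.proposal
    lam = cfg.population_size
    points, flags = evaluate_batch(prop, oracle, lam, rng)

    radius = prop.radius
    emp = state.empirical_p
    f_e, f_c = radius_factors(cfg.target_hitting_probability, cfg.radius_expansion_beta)
    alpha = 1.0 / cfg.hit_smoothing_memory
    n = prop.shape.n
    log_unit = log_proposal_volume(prop) - n * math.log(prop.radius)
    for i in range(lam):
        radius *= f_e if flags[i] else f_c
        emp = (1.0 - alpha) * emp + alpha * float(flags[i])
        state.n_evals += 1
        vol = 0.0 if emp == 0.0 else math.exp(
            math.log(emp) + n * math.log(radius) + log_unit)
        state.trace.append(state.n_evals, points[i], flags[i], radius, emp,
                           vol, prop.mean, phase=phase)

    feas = points[flags]
    # displacements normalized by the batch-start radius and by the unit-ball
    # coordinate scale, so an unconstrained batch leaves the shape stationary
    scale = prop.radius * math.sqrt(coordinate_second_moment(prop.shape))
    disp = (feas - prop.mean) / scale
    new_mean = update_mean(prop.mean, feas, cfg)
    new_transform = update_transform(prop.transform, disp, cfg)
    state.proposal = ProposalState(mean=new_mean, radius=radius,
                                   transform=new_transform, shape=prop.shape)
    state.empirical_p = emp
    assert abs(np.linalg.det(state.proposal.transform) - 1.0) <= DET_TOL
    return state
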
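"""Task-level drivers: design centering and volume estimation.

Both tasks run the same adaptation loop under a staged target-hitting-
probability schedule:

* **Centering** successively *raises* the target P.  A high hitting
  probability forces the proposal inside the feasible region, so its mean is
  driven toward a robust interior point; the reported center is the proposal
  mean averaged over the final window, then verified against the oracle.
* **Volume estimation** successively *lowers* the target P until the volume
  estimate no longer changes.  A low hitting probability inflates the
  proposal past the region boundary so the estimate ``P * vol(proposal)``
  approaches vol(A) from below; the final estimate averages the
  instantaneous estimates over the last window.

Robustness across models of different dimensionality is compared on the
normalized volume ``V**(1/n)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .adaptation import AdaptConfig, AdaptState, RunTrace, step
from .bounds import aabb_volume, ellipsoid_volume, mvee, thin_points
from .lpball import ProposalState
from .oracles import Oracle

__all__ = [
    "Schedule",
    "VolumeReport",
    "CenterReport",
    "InfeasibleStartError",
    "find_design_center",
    "estimate_feasible_volume",
    "normalized_volume",
    "compare_models",
    "ModelComparison",
]

logger = logging.getLogger(__name__)


class InfeasibleStartError(ValueError):
    """The supplied start point is not feasible; nothing was run."""


@dataclass(frozen=True)
class Schedule:
    """Staged target-hitting-probability plan.

    ``targets`` must be strictly monotone (decreasing for volume estimation,
    increasing for centering) and within (0, 1).  A phase ends when its
    budget share is exhausted or when the windowed mean of the instantaneous
    volume estimate changes by less than ``rel_tol`` between two consecutive
    non-overlapping windows of ``stationarity_window`` evaluations; the final
    phase always consumes the remaining budget so the averaging window is
    well defined.
    """

    targets: Tuple[float, ...]
    phase_budget: Optional[int] = None  # evals per phase; None = equal split
    stationarity_window: int = 100
    rel_tol: float = 0.02

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.targets)
        object.__setattr__(self, "targets", t)
        if not t:
            raise ValueError("schedule needs at least one target")
        if any(not 0.0 < v < 1.0 for v in t):
            raise ValueError("all targets must lie in (0, 1)")
        diffs = np.diff(t)
        if len(t) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("targets must be strictly monotone")
        if self.stationarity_window < 1:
            raise ValueError("stationarity_window must be >= 1")

    @classmethod
    def volume_default(cls) -> "Schedule":
        """Decreasing plan 0.35 -> 0.15 -> 0.06 -> 0.03 -> 0.01."""
        return cls(targets=(0.35, 0.15, 0.06, 0.03, 0.01))

    @classmethod
    def centering_default(cls) -> "Schedule":
        """Increasing plan 0.35 -> 0.55 -> 0.75 -> 0.90."""
        return cls(targets=(0.35, 0.55, 0.75, 0.90))

    @property
    def increasing(self) -> bool:
        return len(self.targets) > 1 and self.targets[-1] > self.targets[0]


@dataclass
class VolumeReport:
    """Final volume estimate with geometric upper bounds."""

    volume: float
    normalized_volume: float
    mvee_volume: Optional[float]
    aabb_volume: Optional[float]
    n_evals: int
    n_extra_checks: int
    phase_means: List[float] = field(default_factory=list)
    window: int = 0
    aborted: bool = False


@dataclass
class CenterReport:
    """Design center, its oracle verdict, and the final proposal."""

    center: np.ndarray
    feasible: bool
    proposal: ProposalState
    n_evals: int
    n_extra_checks: int
    window: int = 0


def _check_start(oracle: Oracle, x0: np.ndarray) -> np.ndarray:
    x0 = np.asarray(x0, float)
    if not oracle(x0):
        raise InfeasibleStartError(f"start point {x0.tolist()} is infeasible")
    return x0


def _run_phases(oracle: Oracle, x0: np.ndarray, p: float, r0: float,
                config: AdaptConfig, schedule: Schedule, budget: int,
                rng: np.random.Generator) -> Tuple[AdaptState, List[float]]:
    """Run the adaptation through all schedule phases; returns state and
    per-phase means of the instantaneous volume estimate."""
    n = len(x0)
    cfg = config.resolve(n)
    state = AdaptState.initial(x0, cfg, p=p, radius=r0)
    n_phases = len(schedule.targets)
    per_phase = schedule.phase_budget or max(1, budget // n_phases)
    w = schedule.stationarity_window
    phase_means: List[float] = []

    for k, target in enumerate(schedule.targets):
        # the hit EWMA must average over at least one radius-reversion time,
        # ~1/(n beta P); too short a memory couples the empirical P to the
        # radius random walk and biases P_emp * vol(proposal) upward
        memory = max(cfg.hit_smoothing_memory,
                     1.0 / (n * cfg.radius_expansion_beta * target))
        phase_cfg = replace(cfg, target_hitting_probability=target,
                            hit_smoothing_memory=memory)
        final_phase = k == n_phases - 1
        # the final phase absorbs whatever budget earlier phases left unused
        phase_cap = (budget - state.n_evals) if final_phase \
            else min(per_phase, budget - state.n_evals)
        if phase_cap < 3 * memory:
            logger.warning(
                "phase %d budget (%d evals) is short against the hit-smoothing "
                "memory (%.0f) needed at target P=%.3g; estimates may not "
                "equilibrate", k, phase_cap, memory, target)
        phase_start = state.n_evals
        phase_vols: List[float] = []
        any_feasible = False
        extended = False
        # the stationarity windows must span at least one smoothing memory,
        # otherwise slowly equilibrating phases look stationary immediately
        w_k = max(w, int(math.ceil(memory)))
        while state.n_evals - phase_start < phase_cap:
            before = len(state.trace)
            state = step(state, oracle, phase_cfg, rng, phase=k)
            new = state.trace.feasible[before:]
            any_feasible = any_feasible or any(new)
            phase_vols.extend(state.trace.volume_estimate[before:])
            if not final_phase and len(phase_vols) >= max(2 * w_k, 4 * int(memory)):
                recent = float(np.mean(phase_vols[-w_k:]))
                previous = float(np.mean(phase_vols[-2 * w_k:-w_k]))
                denom = max(abs(previous), 1e-300)
                # a phase is stationary only once the smoothed hitting
                # probability has actually reached its target; the volume
                # estimate is biased while P_emp still lags the switch
                p_settled = abs(state.empirical_p - target) <= 0.25 * target
                if p_settled and abs(recent - previous) / denom < schedule.rel_tol:
                    logger.info("phase %d (target P=%.3g) stationary after %d evals",
                                k, target, state.n_evals - phase_start)
                    break
            if (state.n_evals - phase_start >= phase_cap and not any_feasible
                    and not extended and budget - state.n_evals > 0):
                logger.warning("no feasible sample in phase %d; extending once", k)
                phase_cap = min(2 * phase_cap, phase_cap + (budget - state.n_evals))
                extended = True
        # mean over the stationary tail: the head of a phase holds the
        # re-equilibration transient after the target switch
        tail = max(w_k, len(phase_vols) // 2)
        stationary = phase_vols[-tail:]
        phase_means.append(float(np.mean(stationary)) if stationary else math.nan)
        logger.info("phase %d done: target P=%.3g, %d evals, windowed volume mean %.6g",
                    k, target, state.n_evals - phase_start, phase_means[-1])
        if extended and not any_feasible:
            logger.warning("still no feasible sample after extension; aborting run")
            state.aborted = True  # type: ignore[attr-defined]
            break
        if state.n_evals >= budget:
            break
    return state, phase_means


def _resolve_window(window: Optional[int], trace: RunTrace) -> int:
    """Final averaging window: absolute count, or last 25% of the final phase."""
    total = len(trace)
    if window is not None:
        return max(1, min(int(window), total))
    phases = np.asarray(trace.phase)
    final_len = int(np.sum(phases == phases[-1])) if total else 0
    return max(1, final_len // 4)


def estimate_feasible_volume(
    oracle: Oracle,
    x0: Sequence[float],
    p: float = 2.0,
    config: Optional[AdaptConfig] = None,
    schedule: Optional[Schedule] = None,
    budget: int = 5000,
    window: Optional[int] = None,
    r0: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[VolumeReport, RunTrace]:
    """Estimate vol(A) with a decreasing hitting-probability schedule.

    The final estimate is the mean of the instantaneous estimates over the
    last ``window`` evaluations (default: last quarter of the final phase);
    MVEE and bounding-box upper bounds are computed from all feasible samples
    seen (thinned).  Raises :class:`InfeasibleStartError` if ``x0`` fails the
    oracle.
    """
    config = config or AdaptConfig()
    schedule = schedule or Schedule.volume_default()
    if schedule.increasing:
        raise ValueError("volume estimation needs a non-increasing schedule")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    x0 = _check_start(oracle, x0)
    n_checks = 1
    state, phase_means = _run_phases(oracle, x0, p, r0, config, schedule, budget, rng)
    trace = state.trace
    w = _resolve_window(window, trace)
    vol = float(np.mean(trace.volume_estimate[-w:]))

    feas = thin_points(trace.feasible_points)
    mvee_vol = aabb_vol = None
    if len(feas):
        aabb_vol = aabb_volume(feas)
        if len(feas) >= len(x0) + 1:
            try:
                # diagnostic bound: a loose duality gap is ample and much cheaper
                mvee_vol = ellipsoid_volume(mvee(feas, tolerance=1e-4))
            except ValueError as exc:
                logger.warning("MVEE unavailable: %s", exc)

    report = VolumeReport(
        volume=vol,
        normalized_volume=normalized_volume(vol, len(x0)),
        mvee_volume=mvee_vol,
        aabb_volume=aabb_vol,
        n_evals=len(trace),
        n_extra_checks=n_checks,
        phase_means=phase_means,
        window=w,
        aborted=bool(getattr(state, "aborted", False)),
    )
    return report, trace


def find_design_center(
    oracle: Oracle,
    x0: Sequence[float],
    p: float = 2.0,
    config: Optional[AdaptConfig] = None,
    schedule: Optional[Schedule] = None,
    budget: int = 5000,
    window: Optional[int] = None,
    r0: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[CenterReport, RunTrace]:
    """Find a robust design center with an increasing hitting-probability
    schedule.

    The center is the proposal mean averaged over the final window; one extra
    oracle call records whether the averaged center is itself feasible (in
    strongly non-convex regions it may not be).
    """
    config = config or AdaptConfig()
    schedule = schedule or Schedule.centering_default()
    if len(schedule.targets) > 1 and not schedule.increasing:
        raise ValueError("centering needs a non-decreasing schedule")
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    x0 = _check_start(oracle, x0)
    n_checks = 1
    state, _ = _run_phases(oracle, x0, p, r0, config, schedule, budget, rng)
    trace = state.trace
    w = _resolve_window(window, trace)
    center = np.mean(np.asarray(trace.means[-w:]), axis=0)
    feasible = oracle(center)
    n_checks += 1
    report = CenterReport(center=center, feasible=feasible,
                          proposal=state.proposal, n_evals=len(trace),
                          n_extra_checks=n_checks, window=w)
    return report, trace


def multi_start(driver, oracle_factory, starts, seeds=None, **kwargs):
    """Run a driver from several start points; one fresh oracle per run.

    ``driver`` is :func:`find_design_center` or
    :func:`estimate_feasible_volume`; ``oracle_factory`` builds a new counted
    oracle for each run (so per-run traces match per-run counters).  Returns
    the list of (report, trace) pairs; centers are deliberately not merged
    across runs — in non-convex regions different runs legitimately find
    different centers.
    """
    starts = [np.asarray(s, float) for s in starts]
    if seeds is None:
        seeds = range(len(starts))
    out = []
    for x0, seed in zip(starts, seeds):
        kw = dict(kwargs)
        cfg = kw.pop("config", None) or AdaptConfig()
        cfg = replace(cfg, rng_seed=int(seed))
        out.append(driver(oracle_factory(), x0, config=cfg, **kw))
    return out


def normalized_volume(volume: float, n: int) -> float:
    """Dimension-normalized volume ``V**(1/n)`` (log-space; V = 0 gives 0)."""
    if volume < 0:
        raise ValueError("volume must be nonnegative")
    if n < 1:
        raise ValueError("dimension must be >= 1")
    if volume == 0.0:
        return 0.0
    return math.exp(math.log(volume) / n)


@dataclass
class ModelComparison:
    """Robustness fractions of two models (they sum to 1)."""

    fraction_a: float
    fraction_b: float
    spread_a: Optional[float] = None  # bootstrap SD, when replicates given


def _norm_vols(reports, n: int) -> np.ndarray:
    if isinstance(reports, VolumeReport):
        reports = [reports]
    return np.array([normalized_volume(r.volume, n) for r in reports])


def compare_models(reports_a, n_a: int, reports_b, n_b: int,
                   rng: Optional[np.random.Generator] = None,
                   n_boot: int = 1000) -> ModelComparison:
    """Fraction of total normalized volume attributable to each model.

    Robustness-based model selection: the model whose feasible region has the
    larger normalized volume ``V**(1/n)`` tolerates parameter perturbations
    more robustly.  With replicate reports per model a bootstrap standard
    deviation of the fraction is attached.
    """
    va = _norm_vols(reports_a, n_a)
    vb = _norm_vols(reports_b, n_b)
    ma, mb = float(va.mean()), float(vb.mean())
    if ma + mb == 0.0:
        raise ValueError("both models have zero estimated volume")
    frac_a = ma / (ma + mb)
    spread = None
    if len(va) > 1 or len(vb) > 1:
        rng = rng if rng is not None else np.random.default_rng(0)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            sa = float(np.mean(rng.choice(va, size=len(va))))
            sb = float(np.mean(rng.choice(vb, size=len(vb))))
            boots[i] = sa / (sa + sb) if sa + sb > 0 else 0.5
        spread = float(np.std(boots))
    return ModelComparison(fraction_a=frac_a, fraction_b=1.0 - frac_a,
                           spread_a=spread)
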
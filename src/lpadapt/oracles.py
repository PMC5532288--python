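"""Membership oracles: benchmark regions, adapters, baselines and fixtures.

An oracle is a black-box predicate taking a flat parameter vector and
returning whether the design meets the specifications.  The feasible region
``A`` is the oracle's acceptance set; it is accessible only through calls.
All benchmark regions here are closed (boundary points count as feasible;
every defining inequality is non-strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import quad

from .lpball import LpShape, log_unit_ball_volume

__all__ = [
    "Oracle",
    "storn_region",
    "handle_region",
    "folium_region",
    "storn_oracle",
    "handle_oracle",
    "folium_oracle",
    "handle_true_area",
    "folium_true_area",
    "anisotropic_lpball_region",
    "band_spec_oracle",
    "brute_force_volume",
    "random_fixture",
    "builtin_oracle",
    "BUILTIN_ORACLES",
]

logger = logging.getLogger(__name__)


class Oracle:
    """A counted membership predicate.

    Wraps a pure boolean predicate over n-vectors and counts every
    evaluation.  Benchmarks and fixtures may carry their exact volume and a
    bounding box for baselines; user oracles need neither.
    """

    def __init__(
        self,
        predicate: Callable[[np.ndarray], bool],
        n: int,
        name: str = "oracle",
        batch_predicate: Optional[Callable[[np.ndarray], np.ndarray]] = None,
        true_volume: Optional[float] = None,
        bounding_box: Optional[np.ndarray] = None,
    ) -> None:
        self._predicate = predicate
        self._batch = batch_predicate
        self.n = int(n)
        self.name = name
        self.true_volume = true_volume
        # bounding_box: (n, 2) array of [low, high] per dimension
        self.bounding_box = None if bounding_box is None else np.asarray(bounding_box, float)
        self.n_evals = 0

    def __call__(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise ValueError(f"oracle '{self.name}' expects vectors of length {self.n}, got shape {x.shape}")
        self.n_evals += 1
        return bool(self._predicate(x))

    def evaluate_many(self, points: np.ndarray) -> np.ndarray:
        """Vectorized evaluation; the counter advances by one per point."""
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != self.n:
            raise ValueError(f"expected (count, {self.n}) array, got shape {points.shape}")
        self.n_evals += points.shape[0]
        if self._batch is not None:
            return np.asarray(self._batch(points), dtype=bool)
        return np.array([bool(self._predicate(p)) for p in points], dtype=bool)

    def reset_counter(self) -> None:
        self.n_evals = 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"Oracle({self.name!r}, n={self.n}, evals={self.n_evals})"


# ---------------------------------------------------------------------------
# 2-D benchmark regions
# ---------------------------------------------------------------------------

def storn_region(x: Sequence[float]) -> bool:
    """Storn test region: a 5x20 rectangle with a thin arm attached.

    Feasible iff (x1 in [5,10] and x2 in [-10,10]) or
    (x1 in [0,5] and x2 in [-0.1,0.1]).  Area is exactly 101.0.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError(f"storn_region expects a 2-vector, got shape {x.shape}")
    x1, x2 = x
    return bool((5.0 <= x1 <= 10.0 and -10.0 <= x2 <= 10.0)
                or (0.0 <= x1 <= 5.0 and -0.1 <= x2 <= 0.1))


def _storn_batch(pts: np.ndarray) -> np.ndarray:
    x1, x2 = pts[:, 0], pts[:, 1]
    rect = (x1 >= 5.0) & (x1 <= 10.0) & (x2 >= -10.0) & (x2 <= 10.0)
    arm = (x1 >= 0.0) & (x1 <= 5.0) & (x2 >= -0.1) & (x2 <= 0.1)
    return rect | arm


def handle_region(x: Sequence[float]) -> bool:
    """"Handle" region: feasible iff ``x^6 + y^6 - 1.925 x^3 y^3 <= 1``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError(f"handle_region expects a 2-vector, got shape {x.shape}")
    a, b = x
    return bool(a**6 + b**6 - 1.925 * a**3 * b**3 <= 1.0)


def _handle_batch(pts: np.ndarray) -> np.ndarray:
    a, b = pts[:, 0], pts[:, 1]
    return a**6 + b**6 - 1.925 * a**3 * b**3 <= 1.0


def folium_region(x: Sequence[float]) -> bool:
    """"Folium" region: feasible iff ``-(x^2+y^2)^3 + 4 x^2 y^2 >= 0``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (2,):
        raise ValueError(f"folium_region expects a 2-vector, got shape {x.shape}")
    a, b = x
    return bool(-((a**2 + b**2) ** 3) + 4.0 * a**2 * b**2 >= 0.0)


def _folium_batch(pts: np.ndarray) -> np.ndarray:
    a, b = pts[:, 0], pts[:, 1]
    return -((a**2 + b**2) ** 3) + 4.0 * a**2 * b**2 >= 0.0


# Brute-force boxes: both bodies provably fit (documented constants).
_STORN_BOX = np.array([[0.0, 10.0], [-10.0, 10.0]])
_HANDLE_BOX = np.array([[-1.6, 1.6], [-1.6, 1.6]])
_FOLIUM_BOX = np.array([[-1.1, 1.1], [-1.1, 1.1]])


def storn_oracle() -> Oracle:
    return Oracle(storn_region, n=2, name="storn", batch_predicate=_storn_batch,
                  true_volume=101.0, bounding_box=_STORN_BOX)


def handle_oracle() -> Oracle:
    return Oracle(handle_region, n=2, name="handle", batch_predicate=_handle_batch,
                  true_volume=handle_true_area(), bounding_box=_HANDLE_BOX)


def folium_oracle() -> Oracle:
    return Oracle(folium_region, n=2, name="folium", batch_predicate=_folium_batch,
                  true_volume=folium_true_area(), bounding_box=_FOLIUM_BOX)


def handle_true_area() -> float:
    """Area of the Handle by quadrature of its polar radius.

    In polar coordinates the boundary is ``r^6 f(theta) = 1`` with
    ``f = cos^6 + sin^6 - 1.925 cos^3 sin^3`` (f > 0 everywhere, so the body
    is star-shaped about the origin); area = 1/2 * int f^(-1/3) dtheta.
    """

    def integrand(theta: float) -> float:
        c, s = math.cos(theta), math.sin(theta)
        f = c**6 + s**6 - 1.925 * c**3 * s**3
        return f ** (-1.0 / 3.0)

    val, _ = quad(integrand, 0.0, 2.0 * math.pi, limit=200)
    return 0.5 * val


def folium_true_area() -> float:
    """Area of the Folium: the polar boundary is ``r = |sin(2 theta)|``,
    giving area ``1/2 int sin^2(2 theta) dtheta = pi/2`` exactly."""
    return math.pi / 2.0


# ---------------------------------------------------------------------------
# Synthetic Lp-ball regions (benchmarks and fixtures)
# ---------------------------------------------------------------------------

def anisotropic_lpball_region(n: int, p: float, aspect: float = math.sqrt(1000.0)) -> Oracle:
    """Axis-aligned anisotropic Lp-ball with known volume.

    Semi-axes are logarithmically spaced from 1 to ``aspect`` (the longest
    axis is ``aspect`` times the shortest).  Membership is
    ``||D^-1 x||_p <= 1``; the exact volume ``vol(unit Lp-ball) * prod(d_i)``
    is attached, computed in log-space.
    """
    shape = LpShape(p=p, n=n)
    if n < 2:
        raise ValueError("anisotropic region needs n >= 2")
    d = np.logspace(0.0, math.log10(aspect), n)
    inv_d = 1.0 / d
    log_vol = log_unit_ball_volume(shape) + float(np.sum(np.log(d)))

    if math.isinf(p):
        def member(x: np.ndarray) -> bool:
            return bool(np.max(np.abs(x) * inv_d) <= 1.0)

        def member_batch(pts: np.ndarray) -> np.ndarray:
            return np.max(np.abs(pts) * inv_d, axis=1) <= 1.0
    else:
        def member(x: np.ndarray) -> bool:
            return bool(np.sum(np.abs(x * inv_d) ** p) <= 1.0)

        def member_batch(pts: np.ndarray) -> np.ndarray:
            return np.sum(np.abs(pts * inv_d) ** p, axis=1) <= 1.0

    box = np.stack([-d, d], axis=1)
    return Oracle(member, n=n, name=f"aniso-lpball(n={n},p={p})",
                  batch_predicate=member_batch,
                  true_volume=math.exp(log_vol), bounding_box=box)


def random_fixture(n: int, p: float, condition_number: float,
                   rng: np.random.Generator) -> Oracle:
    """Randomly rotated, anisotropically scaled Lp-ball with exact volume.

    Semi-axes are log-spaced from 1 to ``condition_number``, the rotation is
    Haar-random (QR of a Gaussian matrix), and the center is drawn uniformly
    in [-1, 1]^n.  The center (a feasible interior point), the exact volume
    and a bounding box are attached; equal seeds give identical regions.
    """
    shape = LpShape(p=p, n=n)
    d = np.logspace(0.0, math.log10(condition_number), n) if n > 1 else np.array([float(condition_number)])
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    q *= np.sign(np.diag(r))  # unique-ized rotation
    center = rng.uniform(-1.0, 1.0, size=n)
    inv_d = 1.0 / d
    log_vol = log_unit_ball_volume(shape) + float(np.sum(np.log(d)))

    def member(x: np.ndarray) -> bool:
        z = inv_d * (q.T @ (np.asarray(x, float) - center))
        if math.isinf(p):
            return bool(np.max(np.abs(z)) <= 1.0)
        return bool(np.sum(np.abs(z) ** p) <= 1.0)

    def member_batch(pts: np.ndarray) -> np.ndarray:
        z = (pts - center) @ q * inv_d
        if math.isinf(p):
            return np.max(np.abs(z), axis=1) <= 1.0
        return np.sum(np.abs(z) ** p, axis=1) <= 1.0

    # body fits inside center +- max(d) in every direction
    half = float(np.max(d))
    box = np.stack([center - half, center + half], axis=1)
    oracle = Oracle(member, n=n, name=f"fixture(n={n},p={p})",
                    batch_predicate=member_batch,
                    true_volume=math.exp(log_vol), bounding_box=box)
    oracle.center = center  # feasible interior point
    return oracle


# ---------------------------------------------------------------------------
# Trajectory-band adapter and brute-force baseline
# ---------------------------------------------------------------------------

def band_spec_oracle(response: Callable[[np.ndarray], np.ndarray],
                     lower: np.ndarray, upper: np.ndarray, n: int,
                     name: str = "band-spec") -> Oracle:
    """Oracle accepting parameters whose response curve stays inside a band.

    ``response`` maps a parameter vector to an output curve evaluated on the
    same grid as ``lower`` and ``upper``; a design is feasible iff the curve
    lies within [lower, upper] at every grid point.  Non-finite response
    values mark the design infeasible (logged), they do not raise.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.shape != upper.shape:
        raise ValueError("lower and upper bands must share a grid")
    if np.any(lower > upper):
        raise ValueError("lower band exceeds upper band somewhere")

    def member(x: np.ndarray) -> bool:
        y = np.asarray(response(x), dtype=float)
        if y.shape != lower.shape:
            raise ValueError(f"response shape {y.shape} != band shape {lower.shape}")
        if not np.all(np.isfinite(y)):
            logger.warning("band_spec_oracle: non-finite response at %s; marked infeasible", x)
            return False
        return bool(np.all((y >= lower) & (y <= upper)))

    return Oracle(member, n=n, name=name)


@dataclass
class VolumeEstimate:
    """Brute-force volume estimate with its binomial standard error."""

    volume: float
    stderr: float
    n_samples: int
    acceptance_fraction: float


def brute_force_volume(oracle: Oracle, n_samples: int,
                       rng: np.random.Generator) -> VolumeEstimate:
    """Rejection baseline: acceptance fraction times bounding-box volume."""
    if oracle.bounding_box is None:
        raise ValueError(f"oracle '{oracle.name}' has no known bounding box")
    box = oracle.bounding_box
    widths = box[:, 1] - box[:, 0]
    box_vol = float(np.prod(widths))
    pts = box[:, 0] + rng.uniform(size=(n_samples, oracle.n)) * widths
    hits = oracle.evaluate_many(pts)
    frac = float(np.mean(hits))
    se = box_vol * math.sqrt(max(frac * (1.0 - frac), 0.0) / n_samples)
    return VolumeEstimate(volume=frac * box_vol, stderr=se,
                          n_samples=n_samples, acceptance_fraction=frac)


# ---------------------------------------------------------------------------
# Registry and plugin loading (used by the CLI)
# ---------------------------------------------------------------------------

BUILTIN_ORACLES = {
    "storn": storn_oracle,
    "handle": handle_oracle,
    "folium": folium_oracle,
}


def builtin_oracle(name: str) -> Oracle:
    """Instantiate a builtin benchmark oracle, or load ``module:callable``.

    A plugin path is any name containing a colon; the named callable must
    accept a flat numeric vector and return a boolean, and is wrapped with a
    counter.  The dimension for plugins is resolved at first call by the
    caller supplying the start point.
    """
    if name in BUILTIN_ORACLES:
        return BUILTIN_ORACLES[name]()
    if ":" in name:
        import importlib

        mod_name, attr = name.split(":", 1)
        fn = getattr(importlib.import_module(mod_name), attr)
        return fn  # caller wraps with Oracle once the dimension is known
    raise KeyError(
        f"unknown oracle '{name}'; builtins are {sorted(BUILTIN_ORACLES)} "
        "or use a 'module:callable' plugin path"
    )
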
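"""Parameter-space definition and the iterative range-exploration procedure.

A parameter space is a 6-D hypercube of rate-constant ranges.  The published
"realistic" hypercube (shipped here as :data:`TABLE1_SPACE`) was obtained by
an iterative procedure that tests each range boundary: hold one parameter at
its bound, sample the remaining five, simulate under all five canonical
initial conditions over a 10-minute window, and count simulations whose
protein output is *saturated* (>= 7 concentration units) or *undetectable*
(<= 0.01 at the end of the window).  Bounds whose tests fail the 5% criterion
are nudged by a small step; the procedure stops when a joint test over all
six free parameters passes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .model import (
    PARAM_NAMES,
    GridSpec,
    InitialConditionSpec,
    SimulationResult,
    build_initial_condition,
    simulate_batch,
)

__all__ = [
    "ParameterRange",
    "ParameterSpace",
    "ExplorationConfig",
    "ExplorationResult",
    "TABLE1_SPACE",
    "SEED_SPACE",
    "EXPLORATION_ICS",
    "classify_simulation",
    "boundary_failure_rate",
    "joint_failure_rate",
    "explore",
]

logger = logging.getLogger(__name__)

SATURATED = "saturated"
UNDETECTABLE = "undetectable"
VALID = "valid"


@dataclass(frozen=True)
class ParameterRange:
    """A closed range ``[lower, upper]`` for one named rate constant."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.name!r}; expected one of {PARAM_NAMES}")
        if not (0.0 <= self.lower <= self.upper):
            raise ValueError(
                f"range for {self.name!r} must satisfy 0 <= lower <= upper, "
                f"got [{self.lower}, {self.upper}]"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ParameterSpace:
    """The 6-D sampling hypercube, one range per parameter in canonical order."""

    ranges: tuple[ParameterRange, ...]

    def __post_init__(self) -> None:
        names = tuple(r.name for r in self.ranges)
        if names != PARAM_NAMES:
            raise ValueError(
                f"ranges must cover {PARAM_NAMES} in order, got {names}"
            )

    @classmethod
    def from_bounds(cls, lower: Sequence[float], upper: Sequence[float]) -> "ParameterSpace":
        return cls(
            tuple(
                ParameterRange(name, float(lo), float(hi))
                for name, lo, hi in zip(PARAM_NAMES, lower, upper, strict=True)
            )
        )

    @classmethod
    def from_dict(cls, mapping: dict[str, Sequence[float]]) -> "ParameterSpace":
        return cls(
            tuple(ParameterRange(name, *map(float, mapping[name])) for name in PARAM_NAMES)
        )

    def to_dict(self) -> dict[str, list[float]]:
        return {r.name: [r.lower, r.upper] for r in self.ranges}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ParameterSpace":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @property
    def lower(self) -> np.ndarray:
        return np.array([r.lower for r in self.ranges])

    @property
    def upper(self) -> np.ndarray:
        return np.array([r.upper for r in self.ranges])

    def __getitem__(self, name: str) -> ParameterRange:
        return self.ranges[PARAM_NAMES.index(name)]

    def with_range(self, name: str, lower: float, upper: float) -> "ParameterSpace":
        idx = PARAM_NAMES.index(name)
        ranges = list(self.ranges)
        ranges[idx] = ParameterRange(name, lower, upper)
        return ParameterSpace(tuple(ranges))


#: The published realistic hypercube used for all sensitivity analyses.
TABLE1_SPACE = ParameterSpace.from_bounds(
    lower=(0.012, 0.0, 0.0, 0.125, 0.0, 0.4),
    upper=(2.0, 1.5, 0.8, 1.0, 1.5, 0.9),
)

#: The seed ranges that start the exploration procedure.
SEED_SPACE = ParameterSpace.from_bounds(
    lower=(0.0, 0.0, 0.0, 0.012, 0.0, 0.2248),
    upper=(1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
)

#: The five canonical initial conditions used by the exploration tests:
#: ubiquitous at levels 0, 1/2 and 1, plus anterior and posterior deposits.
EXPLORATION_ICS: tuple[InitialConditionSpec, ...] = (
    InitialConditionSpec("ubiquitous", 0.0),
    InitialConditionSpec("ubiquitous", 0.5),
    InitialConditionSpec("ubiquitous", 1.0),
    InitialConditionSpec("anterior", 1.0),
    InitialConditionSpec("posterior", 1.0),
)


@dataclass(frozen=True)
class ExplorationConfig:
    """Tunables of the exploration procedure.

    ``saturation_mode`` / ``undetectable_mode`` select whether each threshold
    is judged over every recorded time (``"any_time"``) or at the end of the
    window only (``"final_time"``).  The defaults treat saturation as a
    transient-safe ceiling and undetectability as an endpoint failure.
    """

    saturation_threshold: float = 7.0
    undetectable_threshold: float = 0.01
    failure_fraction: float = 0.05
    adjust_min: float = 0.001
    adjust_max: float = 0.1
    adjust_step: float = 0.05
    n_test_samples: int = 500
    t_end: float = 10.0
    dt: float = 0.01
    record_every: float = 0.1
    max_sweeps: int = 200
    saturation_mode: str = "any_time"
    undetectable_mode: str = "final_time"
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.adjust_min <= self.adjust_max):
            raise ValueError("need 0 < adjust_min <= adjust_max")
        if not (self.adjust_min <= self.adjust_step <= self.adjust_max):
            raise ValueError("adjust_step must lie within [adjust_min, adjust_max]")
        if not (0.0 < self.failure_fraction < 1.0):
            raise ValueError("failure_fraction must lie in (0, 1)")
        if self.n_test_samples < 1:
            raise ValueError("n_test_samples must be >= 1")
        for mode in (self.saturation_mode, self.undetectable_mode):
            if mode not in ("any_time", "final_time"):
                raise ValueError(f"unknown classification mode {mode!r}")


def _classify_protein(protein: np.ndarray, cfg: ExplorationConfig) -> np.ndarray:
    """Classify batched protein trajectories, shape (B, T, n) -> labels (B,)."""
    if cfg.saturation_mode == "any_time":
        sat = (protein >= cfg.saturation_threshold).any(axis=(1, 2))
    else:
        sat = (protein[:, -1, :] >= cfg.saturation_threshold).any(axis=1)
    if cfg.undetectable_mode == "final_time":
        undet = (protein[:, -1, :] <= cfg.undetectable_threshold).all(axis=1)
    else:
        undet = (protein <= cfg.undetectable_threshold).all(axis=(1, 2))
    labels = np.full(protein.shape[0], VALID, dtype=object)
    labels[undet] = UNDETECTABLE
    labels[sat] = SATURATED  # saturation takes precedence
    return labels


def classify_simulation(result: SimulationResult, cfg: ExplorationConfig) -> str:
    """Label one trajectory ``saturated``, ``undetectable`` or ``valid``."""
    if result.times[-1] < cfg.t_end - 1e-9:
        raise ValueError(
            f"trajectory ends at t={result.times[-1]} but the classification "
            f"window is [0, {cfg.t_end}]"
        )
    return str(_classify_protein(result.protein[None, :, :], cfg)[0])


def _sobol_matrix(n: int, space: ParameterSpace) -> np.ndarray:
    # local import avoids a circular dependency (hdmr imports ParameterSpace)
    from .hdmr import scale_to_space, sobol_unit_samples

    return scale_to_space(sobol_unit_samples(n, 6), space)


def _failure_rate_for_params(P: np.ndarray, cfg: ExplorationConfig) -> float:
    """Fraction of (parameter set, IC) simulations that fail classification."""
    grid = cfg.grid
    n_rec = int(round(cfg.t_end / cfg.record_every))
    record_times = [k * cfg.record_every for k in range(n_rec + 1)]
    failures = 0
    total = 0
    for ic in EXPLORATION_ICS:
        y0 = build_initial_condition(ic, grid)
        _, states = simulate_batch(y0, P, cfg.t_end, record_times, dt=cfg.dt, grid=grid)
        labels = _classify_protein(states[:, :, grid.n_nuclei :], cfg)
        failures += int((labels != VALID).sum())
        total += len(labels)
    return failures / total


def boundary_failure_rate(
    space: ParameterSpace, param: str, side: str, cfg: ExplorationConfig
) -> float:
    """Failure fraction with one parameter pinned at a range boundary.

    The parameter of interest is held at its lower or upper bound while the
    other five vary over their current ranges (Sobol design); every sampled
    set is simulated under all five canonical initial conditions.
    """
    if side not in ("lower", "upper"):
        raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")
    idx = PARAM_NAMES.index(param)
    P = _sobol_matrix(cfg.n_test_samples, space)
    P[:, idx] = space[param].lower if side == "lower" else space[param].upper
    return _failure_rate_for_params(P, cfg)


def joint_failure_rate(space: ParameterSpace, cfg: ExplorationConfig) -> float:
    """Failure fraction with all six parameters varying over their ranges."""
    P = _sobol_matrix(cfg.n_test_samples, space)
    return _failure_rate_for_params(P, cfg)


@dataclass
class ExplorationResult:
    """Outcome of :func:`explore`: the final space plus convergence metadata."""

    space: ParameterSpace
    converged: bool
    n_sweeps: int
    joint_failure_rate: float
    history: list[dict] = field(default_factory=list)


def explore(initial_space: ParameterSpace, cfg: ExplorationConfig) -> ExplorationResult:
    """Iteratively nudge range boundaries until the joint 5% criterion holds.

    Each sweep first runs the joint test; if it passes the current space is
    returned as converged.  Otherwise every boundary of every parameter is
    tested in canonical order and failing boundaries are moved inward by
    ``cfg.adjust_step`` (a failing lower bound moves up, a failing upper bound
    moves down; lower bounds never go below 0 and bounds never cross).  A
    space that never passes within ``cfg.max_sweeps`` sweeps is returned
    flagged as non-converged, never silently.
    """
    space = initial_space
    history: list[dict] = []
    rate = float("nan")
    for sweep in range(cfg.max_sweeps):
        rate = joint_failure_rate(space, cfg)
        logger.info("sweep %d: joint failure rate %.4f", sweep, rate)
        history.append({"sweep": sweep, "joint_failure_rate": rate, "space": space.to_dict()})
        if rate <= cfg.failure_fraction:
            return ExplorationResult(space, True, sweep, rate, history)
        for param in PARAM_NAMES:
            for side in ("lower", "upper"):
                rng = space[param]
                if rng.width == 0.0 and side == "upper":
                    continue  # degenerate range: a single boundary test suffices
                r = boundary_failure_rate(space, param, side, cfg)
                if r <= cfg.failure_fraction:
                    continue
                lower, upper = rng.lower, rng.upper
                if side == "lower":
                    lower = min(lower + cfg.adjust_step, upper)
                else:
                    upper = max(upper - cfg.adjust_step, lower)
                lower = max(lower, 0.0)
                logger.info(
                    "sweep %d: %s %s bound failed (%.3f) -> [%g, %g]",
                    sweep, param, side, r, lower, upper,
                )
                space = space.with_range(param, lower, upper)
    rate = joint_failure_rate(space, cfg)
    logger.warning(
        "exploration did not converge after %d sweeps (joint rate %.4f)",
        cfg.max_sweeps, rate,
    )
    return ExplorationResult(space, False, cfg.max_sweeps, rate, history)
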
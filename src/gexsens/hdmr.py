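"""Quasi-random sampling designs and the HDMR variance decomposition.

High Dimensional Model Representation (HDMR) expands a scalar model output
``f(u)`` over the unit hypercube into a mean, univariate and bivariate
component functions::

    f(u) = f0 + sum_i f_i(u_i) + sum_{i<j} f_ij(u_i, u_j) + ...

Each component is approximated in an orthonormal basis of shifted Legendre
polynomials; because the basis is orthonormal under the uniform measure on
[0, 1], the variance of each component is the sum of its squared expansion
coefficients, and dividing by the total output variance yields the first-
and second-order sensitivity indices S_i and S_ij.

Coefficients are estimated by Monte Carlo projection on a Sobol
low-discrepancy design.  Because a sum of squared noisy coefficients is
positively biased, coefficients that are not statistically distinguishable
from zero (|estimate| below a multiple of its standard error) are screened
out before squaring; parameters the output genuinely does not depend on then
receive exactly zero indices.  Screening is configurable and can be disabled.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import eval_sh_legendre
from scipy.stats import qmc

from .explore import ParameterSpace
from .model import (
    DEFAULT_DT,
    GridSpec,
    InitialConditionSpec,
    ObjectiveSpec,
    build_initial_condition,
    simulate_batch,
    _spatial_reduce,
)

__all__ = [
    "SobolDesign",
    "HDMRConfig",
    "HDMR",
    "HDMRResults",
    "sobol_unit_samples",
    "scale_to_space",
    "shifted_legendre",
    "evaluate_objective_batch",
    "hdmr_decompose",
]

logger = logging.getLogger(__name__)

_MAX_SOBOL_DIM = 21201  # direction-number limit of scipy's Sobol generator


def sobol_unit_samples(n_points: int, dim: int) -> np.ndarray:
    """First ``n_points`` of the standard (unscrambled) Sobol sequence.

    The all-zeros origin point is skipped.  The result is deterministic:
    identical arguments reproduce the matrix bit-for-bit.
    """
    if n_points < 1 or dim < 1:
        raise ValueError("n_points and dim must be >= 1")
    if dim > _MAX_SOBOL_DIM:
        raise ValueError(f"dim={dim} exceeds the supported Sobol dimension {_MAX_SOBOL_DIM}")
    sampler = qmc.Sobol(d=dim, scramble=False)
    sampler.fast_forward(1)
    return sampler.random(n_points)


def scale_to_space(unit_points: np.ndarray, space: ParameterSpace) -> np.ndarray:
    """Affine map from the unit hypercube into parameter units, per column."""
    unit_points = np.asarray(unit_points, dtype=float)
    if unit_points.ndim != 2 or unit_points.shape[1] != len(space.ranges):
        raise ValueError(
            f"unit_points shape {unit_points.shape} does not match the "
            f"{len(space.ranges)}-D space"
        )
    if (unit_points < 0).any() or (unit_points > 1).any():
        raise ValueError("unit coordinates must lie in [0, 1]")
    return space.lower + unit_points * (space.upper - space.lower)


@dataclass(frozen=True)
class SobolDesign:
    """A Sobol design in both unit and parameter coordinates."""

    unit_points: np.ndarray
    scaled_points: np.ndarray
    space: ParameterSpace

    @classmethod
    def generate(cls, n_points: int, space: ParameterSpace) -> "SobolDesign":
        unit = sobol_unit_samples(n_points, len(space.ranges))
        return cls(unit_points=unit, scaled_points=scale_to_space(unit, space), space=space)

    @property
    def n(self) -> int:
        return self.unit_points.shape[0]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.space.ranges)


def evaluate_objective_batch(
    design: SobolDesign,
    ic: InitialConditionSpec,
    obj: ObjectiveSpec,
    grid: GridSpec = GridSpec(),
    dt: float = DEFAULT_DT,
) -> np.ndarray:
    """One scalar model output per design row, order-aligned with the design.

    Simulates every sampled parameter set from the given initial condition and
    extracts the protein objective at ``obj.time``.  Non-finite trajectories
    abort with the offending row index rather than being dropped.
    """
    y0 = build_initial_condition(ic, grid)
    _, states = simulate_batch(
        y0, design.scaled_points, obj.time, [obj.time], dt=dt, grid=grid
    )
    protein = states[:, -1, grid.n_nuclei :]
    return np.asarray(_spatial_reduce(protein, obj.spatial, grid), dtype=float)


def shifted_legendre(degree: int, u: np.ndarray) -> np.ndarray:
    """Shifted Legendre polynomial of given degree, orthonormal on [0, 1]."""
    return np.sqrt(2 * degree + 1) * eval_sh_legendre(degree, u)


@dataclass(frozen=True)
class HDMRConfig:
    """HDMR estimator settings.

    ``n_samples`` is the Sobol design size, ``poly_order`` the maximum
    polynomial degree per component function, ``coef_screen`` the
    significance threshold in standard-error multiples (0 disables
    screening).
    """

    n_samples: int = 8192
    poly_order: int = 3
    include_second_order: bool = True
    coef_screen: float = 3.0

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError("n_samples must be >= 64")
        if not (1 <= self.poly_order <= 10):
            raise ValueError("poly_order must lie in [1, 10]")
        if self.coef_screen < 0:
            raise ValueError("coef_screen must be >= 0")


class HDMR:
    """HDMR variance-decomposition model for one set of sampled outputs.

    Parameters
    ----------
    outputs : array-like, shape (N,)
        Scalar model outputs, one per sample.
    unit_points : array-like, shape (N, d)
        The sample coordinates on the unit hypercube (quasi-random design).
    poly_order : int
        Maximum shifted-Legendre degree per component function.
    include_second_order : bool
        Whether to fit bivariate component functions.
    coef_screen : float
        Significance threshold for expansion coefficients, in multiples of
        the coefficient's Monte Carlo standard error; 0 disables screening.
    names : sequence of str, optional
        Parameter names (defaults to ``x1..xd``).

    Examples
    --------
    >>> import numpy as np
    >>> from gexsens.hdmr import HDMR, sobol_unit_samples
    >>> u = sobol_unit_samples(4096, 2)
    >>> res = HDMR(u[:, 0] * u[:, 1], u).fit()
    >>> round(float(res.first_order["x1"]), 2)
    0.43
    """

    def __init__(
        self,
        outputs,
        unit_points,
        poly_order: int = 3,
        include_second_order: bool = True,
        coef_screen: float = 3.0,
        names: Sequence[str] | None = None,
    ) -> None:
        self.outputs = np.asarray(outputs, dtype=float)
        self.unit_points = np.asarray(unit_points, dtype=float)
        if self.unit_points.ndim != 2:
            raise ValueError("unit_points must be 2-D (N, d)")
        if self.outputs.shape != (self.unit_points.shape[0],):
            raise ValueError(
                f"outputs length {self.outputs.shape} does not match design "
                f"size {self.unit_points.shape[0]}"
            )
        if not np.isfinite(self.outputs).all():
            raise ValueError("outputs contain non-finite values")
        if poly_order >= self.outputs.size:
            raise ValueError("poly_order must be smaller than the sample size")
        self.poly_order = int(poly_order)
        self.include_second_order = bool(include_second_order)
        self.coef_screen = float(coef_screen)
        d = self.unit_points.shape[1]
        self.names = tuple(names) if names is not None else tuple(
            f"x{i + 1}" for i in range(d)
        )
        if len(self.names) != d:
            raise ValueError("names length does not match the design dimension")

    def _project(self, z: np.ndarray) -> float:
        """Screened Monte Carlo projection: mean of z, zeroed if insignificant."""
        a = float(z.mean())
        if self.coef_screen > 0:
            se = float(z.std()) / np.sqrt(z.size)
            if abs(a) < self.coef_screen * se:
                if a != 0.0:
                    logger.debug("screened coefficient %.3e (se %.3e)", a, se)
                return 0.0
        return a

    def fit(self) -> "HDMRResults":
        y = self.outputs
        u = self.unit_points
        d = u.shape[1]
        k = self.poly_order
        names = self.names
        f0 = float(y.mean())
        g = y - f0
        D = float(g.var())

        pairs = [(i, j) for i in range(d) for j in range(i + 1, d)]
        if D <= 1e-24 * max(1.0, f0 * f0):
            # Degenerate output (e.g. the t=0 convention): all indices are 0.
            return HDMRResults(
                f0=f0,
                total_variance=0.0,
                first_order=pd.Series(0.0, index=list(names)),
                second_order=pd.Series(
                    0.0, index=[(names[i], names[j]) for i, j in pairs]
                ) if self.include_second_order else pd.Series(dtype=float),
                alpha=pd.DataFrame(
                    0.0, index=list(names), columns=[f"deg{r}" for r in range(1, k + 1)]
                ),
                beta={},
                n_samples=y.size,
                poly_order=k,
            )

        # cache basis evaluations: phi[r-1][i] = phi_r(u_i)
        phi = np.empty((k, y.size, d))
        for r in range(1, k + 1):
            phi[r - 1] = shifted_legendre(r, u)

        alpha = np.zeros((d, k))
        fi = np.zeros((y.size, d))
        for i in range(d):
            for r in range(k):
                a = self._project(g * phi[r, :, i])
                alpha[i, r] = a
                if a != 0.0:
                    fi[:, i] += a * phi[r, :, i]
        S1 = (alpha**2).sum(axis=1) / D

        beta: dict[tuple[str, str], np.ndarray] = {}
        S2 = {}
        if self.include_second_order:
            resid = g - fi.sum(axis=1)
            for i, j in pairs:
                b = np.zeros((k, k))
                for p in range(k):
                    basis_p = phi[p, :, i]
                    for q in range(k):
                        b[p, q] = self._project(resid * basis_p * phi[q, :, j])
                key = (names[i], names[j])
                beta[key] = b
                S2[key] = float((b**2).sum() / D)

        return HDMRResults(
            f0=f0,
            total_variance=D,
            first_order=pd.Series(np.clip(S1, 0.0, None), index=list(names)),
            second_order=pd.Series(S2, dtype=float)
            if S2
            else pd.Series(dtype=float),
            alpha=pd.DataFrame(
                alpha, index=list(names), columns=[f"deg{r}" for r in range(1, k + 1)]
            ),
            beta=beta,
            n_samples=y.size,
            poly_order=k,
        )


@dataclass
class HDMRResults:
    """Fitted HDMR decomposition: mean, variance and sensitivity indices.

    ``first_order`` maps parameter name to S_i; ``second_order`` maps the
    ordered pair ``(name_i, name_j)`` (i before j in canonical order) to
    S_ij.  ``totals`` adds each parameter's pairwise indices to its
    first-order index.  ``alpha``/``beta`` keep the fitted expansion
    coefficients for diagnostics.
    """

    f0: float
    total_variance: float
    first_order: pd.Series
    second_order: pd.Series
    alpha: pd.DataFrame
    beta: dict
    n_samples: int
    poly_order: int

    @property
    def totals(self) -> pd.Series:
        return pd.Series(
            {name: self.first_order[name] + self.pairwise_sum(name) for name in self.first_order.index}
        )

    def pairwise_sum(self, name: str) -> float:
        """Sum of all second-order indices involving ``name``."""
        return float(
            sum(v for pair, v in self.second_order.items() if name in pair)
        )

    def second_order_index(self, a: str, b: str) -> float:
        """S_ab regardless of argument order (S_ij is symmetric)."""
        if (a, b) in self.second_order.index:
            return float(self.second_order[(a, b)])
        if (b, a) in self.second_order.index:
            return float(self.second_order[(b, a)])
        raise KeyError((a, b))

    def summary(self) -> str:
        lines = [
            "HDMR variance decomposition",
            f"  samples: {self.n_samples}   polynomial order: {self.poly_order}",
            f"  f0 (mean output):   {self.f0:.6g}",
            f"  total variance D:   {self.total_variance:.6g}",
            "",
            f"  {'parameter':<10}{'S_i':>8}{'sum S_ij':>10}{'total':>8}",
        ]
        for name in self.first_order.index:
            lines.append(
                f"  {name:<10}{self.first_order[name]:>8.3f}"
                f"{self.pairwise_sum(name):>10.3f}{self.totals[name]:>8.3f}"
            )
        lines.append("")
        lines.append(f"  sum first-order:          {float(self.first_order.sum()):.3f}")
        if len(self.second_order):
            lines.append(f"  sum second-order:         {float(self.second_order.sum()):.3f}")
            lines.append(
                f"  first + second order:     {float(self.first_order.sum() + self.second_order.sum()):.3f}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "f0": self.f0,
            "total_variance": self.total_variance,
            "first_order": {str(k): float(v) for k, v in self.first_order.items()},
            "second_order": {
                f"{a}:{b}": float(v) for (a, b), v in self.second_order.items()
            },
            "totals": {str(k): float(v) for k, v in self.totals.items()},
            "n_samples": int(self.n_samples),
            "poly_order": int(self.poly_order),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "HDMRResults":
        first = pd.Series(data["first_order"], dtype=float)
        second_items = {
            tuple(key.split(":")): float(v) for key, v in data["second_order"].items()
        }
        return cls(
            f0=float(data["f0"]),
            total_variance=float(data["total_variance"]),
            first_order=first,
            second_order=pd.Series(second_items, dtype=float)
            if second_items
            else pd.Series(dtype=float),
            alpha=pd.DataFrame(),
            beta={},
            n_samples=int(data["n_samples"]),
            poly_order=int(data["poly_order"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def hdmr_decompose(
    design: SobolDesign, outputs: np.ndarray, cfg: HDMRConfig = HDMRConfig()
) -> HDMRResults:
    """Decompose sampled outputs over a Sobol design into sensitivity indices."""
    outputs = np.asarray(outputs, dtype=float)
    if outputs.shape != (design.n,):
        raise ValueError(
            f"outputs length {outputs.shape} does not match design size {design.n}"
        )
    model = HDMR(
        outputs,
        design.unit_points,
        poly_order=cfg.poly_order,
        include_second_order=cfg.include_second_order,
        coef_screen=cfg.coef_screen,
        names=design.names,
    )
    return model.fit()
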
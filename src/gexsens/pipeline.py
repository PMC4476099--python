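"""Full sensitivity-analysis grid, reference comparison and time series.

The analysis grid crosses five initial conditions (ubiquitous at levels 0,
1/2 and 1; anterior and posterior maternal deposits), four spatial objectives
(anterior, middle and posterior nucleus, and the spatial mean) and eleven
evenly spaced analysis times on a 20-minute window.  Each cell is an HDMR
decomposition of the protein output over the sampling hypercube; the t=0
cells use the zero-variance convention (every output equals the initial
condition, so all indices are defined as 0) without running any simulation.

Computed first-order indices are compared against experimentally derived
contribution-to-variance percentages for mammalian housekeeping genes
(transcription 38%, mRNA decay 18%, translation 30%, protein decay 14%);
diffusion has no experimental counterpart and is paired with 0 in the
six-way comparison mode.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .explore import ParameterSpace
from .hdmr import HDMR, HDMRConfig, HDMRResults, SobolDesign
from .model import (
    DEFAULT_DT,
    PARAM_NAMES,
    SPATIAL_OBJECTIVES,
    GridSpec,
    InitialConditionSpec,
    build_initial_condition,
    simulate_batch,
    _spatial_reduce,
)

__all__ = [
    "ReferenceContributions",
    "REFERENCE_CONTRIBUTIONS",
    "TABLE2_FIRST_ORDER",
    "ComparisonResult",
    "SensitivityTimeSeries",
    "DEFAULT_ANALYSIS_TIMES",
    "DEFAULT_ICS",
    "compare_to_reference",
    "run_sensitivity_grid",
    "time_series",
    "sensitivity_budget",
    "full_analysis",
]

logger = logging.getLogger(__name__)

#: Analysis times in minutes: eleven evenly distributed points on [0, 20].
DEFAULT_ANALYSIS_TIMES: tuple[float, ...] = tuple(float(t) for t in range(0, 21, 2))

#: The five canonical initial conditions of the study.
DEFAULT_ICS: tuple[InitialConditionSpec, ...] = (
    InitialConditionSpec("ubiquitous", 0.0),
    InitialConditionSpec("ubiquitous", 0.5),
    InitialConditionSpec("ubiquitous", 1.0),
    InitialConditionSpec("anterior", 1.0),
    InitialConditionSpec("posterior", 1.0),
)


@dataclass(frozen=True)
class ReferenceContributions:
    """Experimental contribution-to-variance fractions used as the reference.

    Values are the corrected estimates for 4,212 mammalian housekeeping
    genes; there is no experimental diffusion measurement, so six-way
    comparisons pair the two diffusion parameters with 0.
    """

    transcription: float = 0.38
    mrna_decay: float = 0.18
    translation: float = 0.30
    protein_decay: float = 0.14

    def __post_init__(self) -> None:
        total = self.transcription + self.mrna_decay + self.translation + self.protein_decay
        if abs(total - 1.0) > 1e-3:
            raise ValueError(f"reference contributions must sum to 1, got {total}")

    def as_series(self, mode: str = "six_way") -> pd.Series:
        """Reference vector aligned with the model parameters.

        ``four_way`` covers (sigma, lam, tau, gamma); ``six_way`` additionally
        pairs d and delta with 0.
        """
        four = {
            "sigma": self.transcription,
            "lam": self.mrna_decay,
            "tau": self.translation,
            "gamma": self.protein_decay,
        }
        if mode == "four_way":
            return pd.Series(four)
        if mode == "six_way":
            return pd.Series({name: four.get(name, 0.0) for name in PARAM_NAMES})
        raise ValueError(f"unknown comparison mode {mode!r}")


REFERENCE_CONTRIBUTIONS = ReferenceContributions()

#: Published first-order sensitivities for the headline cell (ubiquitous
#: level-1.0 IC, middle nucleus, t = 4 min); used as a zero-simulation oracle
#: for the comparison statistics.
TABLE2_FIRST_ORDER: dict[str, float] = {
    "sigma": 0.32,
    "d": 0.00,
    "lam": 0.17,
    "tau": 0.32,
    "delta": 0.00,
    "gamma": 0.05,
}


@dataclass(frozen=True)
class ComparisonResult:
    """Pearson correlation and maximum absolute difference of a comparison."""

    pearson_r: float
    max_abs_diff: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.pearson_r <= 1.0 + 1e-12):
            raise ValueError(f"pearson_r out of range: {self.pearson_r}")
        if self.max_abs_diff < 0:
            raise ValueError("max_abs_diff must be >= 0")


def compare_to_reference(
    first_order: Mapping[str, float],
    ref: ReferenceContributions = REFERENCE_CONTRIBUTIONS,
    mode: str = "six_way",
) -> ComparisonResult:
    """Compare computed first-order indices with the reference contributions.

    ``six_way`` (the default) pairs all six parameters, with the diffusion
    references set to 0; ``four_way`` restricts both statistics to
    (sigma, lam, tau, gamma).
    """
    ref_vec = ref.as_series(mode)
    missing = [name for name in ref_vec.index if name not in first_order]
    if missing:
        raise ValueError(f"first_order is missing parameters: {missing}")
    values = np.array([float(first_order[name]) for name in ref_vec.index])
    r = float(np.corrcoef(values, ref_vec.to_numpy())[0, 1])
    mad = float(np.max(np.abs(values - ref_vec.to_numpy())))
    return ComparisonResult(pearson_r=r, max_abs_diff=mad)


def _zero_cell(design: SobolDesign, ic: InitialConditionSpec, spatial: str,
               grid: GridSpec, cfg: HDMRConfig) -> HDMRResults:
    """The t=0 convention: every output equals the IC, all indices are 0."""
    y0 = build_initial_condition(ic, grid)
    f0 = float(_spatial_reduce(y0[None, grid.n_nuclei:], spatial, grid)[0])
    outputs = np.full(design.n, f0)
    return HDMR(
        outputs,
        design.unit_points,
        poly_order=cfg.poly_order,
        include_second_order=cfg.include_second_order,
        coef_screen=cfg.coef_screen,
        names=design.names,
    ).fit()


GridKey = tuple[str, str, float]


def run_sensitivity_grid(
    space: ParameterSpace,
    cfg: HDMRConfig = HDMRConfig(),
    ics: Sequence[InitialConditionSpec] = DEFAULT_ICS,
    spatials: Sequence[str] = SPATIAL_OBJECTIVES,
    times: Sequence[float] = DEFAULT_ANALYSIS_TIMES,
    grid: GridSpec = GridSpec(),
    dt: float = DEFAULT_DT,
    cache_dir=None,
) -> dict[GridKey, HDMRResults]:
    """One HDMR decomposition per (initial condition, spatial objective, time).

    Each initial condition is simulated once for the whole batch with every
    nonzero analysis time recorded, then decomposed per (spatial, time) cell.
    If ``cache_dir`` is given, each cell is stored as JSON keyed by cell and
    reloaded on rerun, making partial grids resumable.  Failures are re-raised
    with the offending cell key.
    """
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    design = SobolDesign.generate(cfg.n_samples, space)
    results: dict[GridKey, HDMRResults] = {}
    sim_times = sorted({float(t) for t in times if t > 0})
    for ic in ics:
        traj = None
        for spatial in spatials:
            for t in times:
                t = float(t)
                key: GridKey = (ic.key, spatial, t)
                if cache is not None:
                    path = cache / f"cell_{ic.key}_{spatial}_t{t:g}.json"
                    if path.exists():
                        with open(path) as fh:
                            results[key] = HDMRResults.from_dict(json.load(fh))
                        continue
                tic = _time.perf_counter()
                try:
                    if t == 0.0:
                        results[key] = _zero_cell(design, ic, spatial, grid, cfg)
                    else:
                        if traj is None:
                            y0 = build_initial_condition(ic, grid)
                            rec, states = simulate_batch(
                                y0, design.scaled_points, sim_times[-1], sim_times,
                                dt=dt, grid=grid,
                            )
                            traj = (rec, states[:, :, grid.n_nuclei:])
                        rec, protein = traj
                        ti = int(np.argmin(np.abs(rec - t)))
                        outputs = _spatial_reduce(protein[:, ti, :], spatial, grid)
                        results[key] = HDMR(
                            outputs,
                            design.unit_points,
                            poly_order=cfg.poly_order,
                            include_second_order=cfg.include_second_order,
                            coef_screen=cfg.coef_screen,
                            names=design.names,
                        ).fit()
                except Exception as exc:
                    raise RuntimeError(f"grid cell {key} failed: {exc}") from exc
                logger.info(
                    "cell %s done in %.2fs", key, _time.perf_counter() - tic
                )
                if cache is not None:
                    results[key].to_json(path)
    return results


@dataclass
class SensitivityTimeSeries:
    """First-order sensitivity of every parameter across the analysis times.

    ``series`` is a DataFrame with parameters as rows and time points as
    columns, matching the figure-ready CSV layout.
    """

    ic_key: str
    spatial: str
    time_points: tuple[float, ...]
    series: pd.DataFrame

    def to_csv(self, path) -> None:
        self.series.to_csv(path, index_label="parameter")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, row in self.series.iterrows():
            ax.plot(self.time_points, row.to_numpy(), marker="o", label=name)
        ax.set_xlabel("analysis time (min)")
        ax.set_ylabel("first-order sensitivity $S_i$")
        ax.set_title(f"{self.ic_key}, {self.spatial}")
        ax.legend()
        return ax


def time_series(
    results: Mapping[GridKey, HDMRResults],
    ic_key: str,
    spatial: str,
    times: Iterable[float] = DEFAULT_ANALYSIS_TIMES,
) -> SensitivityTimeSeries:
    """Reshape grid cells into per-parameter first-order series over time."""
    times = tuple(float(t) for t in times)
    data = {}
    for t in times:
        key = (ic_key, spatial, t)
        if key not in results:
            raise KeyError(f"missing grid cell {key}")
        data[t] = results[key].first_order
    frame = pd.DataFrame(data)
    return SensitivityTimeSeries(ic_key=ic_key, spatial=spatial, time_points=times, series=frame)


def sensitivity_budget(result: HDMRResults) -> dict[str, float]:
    """Summary of how output variance splits across expansion orders.

    Returns ``first_order_share`` (sum of all S_i), ``first_plus_second_share``
    (adds all S_ij) and ``max_pairwise_share_of_total``: the largest, over
    parameters, of a parameter's summed pairwise indices as a fraction of the
    total (first- plus second-order) model sensitivity, with 0/0 -> 0.
    """
    s1 = float(result.first_order.sum())
    s2 = float(result.second_order.sum()) if len(result.second_order) else 0.0
    total = s1 + s2
    if total <= 0:
        return {
            "first_order_share": 0.0,
            "first_plus_second_share": 0.0,
            "max_pairwise_share_of_total": 0.0,
        }
    max_share = max(result.pairwise_sum(name) / total for name in result.first_order.index)
    return {
        "first_order_share": s1,
        "first_plus_second_share": total,
        "max_pairwise_share_of_total": float(max_share),
    }


def full_analysis(
    space: ParameterSpace,
    cfg: HDMRConfig,
    out_dir,
    ics: Sequence[InitialConditionSpec] = DEFAULT_ICS,
    spatials: Sequence[str] = SPATIAL_OBJECTIVES,
    times: Sequence[float] = DEFAULT_ANALYSIS_TIMES,
    grid: GridSpec = GridSpec(),
    dt: float = DEFAULT_DT,
) -> dict[GridKey, HDMRResults]:
    """Run the whole grid and write figure-ready outputs to ``out_dir``.

    Writes ``grid.json`` (all decompositions), one
    ``timeseries_<ic>_<spatial>.csv`` per series, ``table2.csv`` (the headline
    cell next to the reference contributions) and ``comparison.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = run_sensitivity_grid(
        space, cfg, ics=ics, spatials=spatials, times=times, grid=grid, dt=dt,
        cache_dir=out / "cells",
    )
    with open(out / "grid.json", "w") as fh:
        json.dump(
            {f"{k[0]}|{k[1]}|{k[2]:g}": v.to_dict() for k, v in results.items()},
            fh, indent=2,
        )
    for ic in ics:
        for spatial in spatials:
            ts = time_series(results, ic.key, spatial, times)
            ts.to_csv(out / f"timeseries_{ic.key}_{spatial}.csv")
    headline_key = ("ubiquitous_1", "middle_nucleus", 4.0)
    comparison: dict[str, object] = {}
    if headline_key in results:
        head = results[headline_key]
        table = pd.DataFrame(
            {
                "first_order_sensitivity": head.first_order,
                "reference_contribution": REFERENCE_CONTRIBUTIONS.as_series("six_way"),
            }
        )
        table.to_csv(out / "table2.csv", index_label="parameter")
        cmp6 = compare_to_reference(head.first_order, mode="six_way")
        cmp4 = compare_to_reference(head.first_order, mode="four_way")
        comparison = {
            "six_way": {"pearson_r": cmp6.pearson_r, "max_abs_diff": cmp6.max_abs_diff},
            "four_way": {"pearson_r": cmp4.pearson_r, "max_abs_diff": cmp4.max_abs_diff},
            "budget": sensitivity_budget(head),
        }
        with open(out / "comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=2)
    return results
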
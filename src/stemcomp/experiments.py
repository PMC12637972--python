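"""Reproducible experiment sweeps over the well-mixed and lattice models.

Four studies, each returning a tidy :class:`pandas.DataFrame` (one row per
condition) suitable for direct CSV export:

* dose-rate sweep -- simulated mean absorption time versus ``lam`` for a
  list of cost matrices, next to the low-dose-rate approximation and the
  exact chain solve, plus their ratio;
* pool-size study -- the lam-free normalised absorption time
  ``f(n) = 1/(n pi_1)`` over a pool-size grid, with its shape label;
* shape diagram -- the shape label over a (c_di, c_dd) grid at fixed
  c_ii and c_id, with the two boundary indicators;
* lattice comparison -- paired lattice and well-mixed simulated means at
  matched pool sizes (perfect squares), next to the analytic curve.

Replicate seeding: every condition draws its generator from a
``SeedSequence`` spawned off the study seed, so runs are reproducible and
conditions are independent.  Censored replicates are counted and excluded
from means, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analytic import (
    DEFAULT_N_GRID,
    Shape,
    approx_absorption_time,
    classify_shape,
    exact_expected_absorption_time,
    large_n_increase,
    log_normalized_absorption_time,
    normalized_absorption_time,
    small_n_decrease,
)
from .cost_model import CostMatrix, validate_cost_matrix
from .lattice import LatticeConfig, simulate_lattice_absorption_time
from .wellmixed import SimulationConfig, batch_absorption_times

__all__ = [
    "SweepRecord",
    "PoolSizeResult",
    "DEFAULT_DOSE_GRID",
    "DEFAULT_MATRICES",
    "run_dose_rate_sweep",
    "run_pool_size_study",
    "run_shape_diagram",
    "run_lattice_comparison",
]

#: Dose-rate grid spanning "very low" through "high": log-spaced 1e-4..10.
DEFAULT_DOSE_GRID: tuple[float, ...] = tuple(np.logspace(-4, 1, 11))

#: Benchmark cost matrices: neutral; frequency-independent damage advantage
#: and disadvantage; and a frequency-dependent mixed case.
DEFAULT_MATRICES: tuple[CostMatrix, ...] = (
    CostMatrix(1.0, 1.0, 1.0, 1.0),
    CostMatrix(1.0, 1.0, 0.8, 0.8),
    CostMatrix(1.0, 1.0, 1.25, 1.25),
    CostMatrix(1.0, 1.5, 1.16, 0.8),
)


@dataclass(frozen=True)
class SweepRecord:
    """One experimental condition: parameters plus summary statistics.

    ``mean``/``sd``/``se`` summarise uncensored replicates; ``censored``
    counts the replicates that hit the step cap.  Analytic records carry
    ``reps = 0`` and empty dispersion fields.
    """

    scenario: str
    model: str  # "well_mixed" | "lattice" | "analytic"
    n: int
    lam: float
    cost_ii: float
    cost_id: float
    cost_di: float
    cost_dd: float
    reps: int
    mean: float
    sd: float = math.nan
    se: float = math.nan
    censored: int = 0
    seed: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "scenario": self.scenario,
            "model": self.model,
            "n": self.n,
            "lam": self.lam,
            "cost_ii": self.cost_ii,
            "cost_id": self.cost_id,
            "cost_di": self.cost_di,
            "cost_dd": self.cost_dd,
            "reps": self.reps,
            "mean": self.mean,
            "sd": self.sd,
            "se": self.se,
            "censored": self.censored,
            "seed": self.seed,
        }
        row.update(self.extra)
        return row


def _summarise(times: np.ndarray, censored: np.ndarray) -> tuple[float, float, float, int]:
    ok = times[~censored]
    n_cens = int(censored.sum())
    if ok.size == 0:
        return math.nan, math.nan, math.nan, n_cens
    mean = float(ok.mean())
    sd = float(ok.std(ddof=1)) if ok.size > 1 else math.nan
    se = sd / math.sqrt(ok.size) if ok.size > 1 else math.nan
    return mean, sd, se, n_cens


def _matrix_label(cm: CostMatrix) -> str:
    return f"cm({cm.c_ii:g},{cm.c_id:g},{cm.c_di:g},{cm.c_dd:g})"


def run_dose_rate_sweep(
    cms: Sequence[CostMatrix] = DEFAULT_MATRICES,
    lam_grid: Sequence[float] = DEFAULT_DOSE_GRID,
    n: int = 20,
    reps: int = 1000,
    seed: int = 0,
    max_cycles: Optional[float] = None,
) -> pd.DataFrame:
    """Simulated mean absorption time versus dose rate, per cost matrix.

    Each (matrix, lam) condition runs ``reps`` replicates and is reported
    next to the low-dose-rate approximation, the exact chain mean (for
    n <= 100), and the simulation/approximation ratio, which approaches 1
    as ``lam`` becomes small.
    """
    if any(lam <= 0 for lam in lam_grid):
        raise ValueError("all dose rates in the grid must be positive")
    for cm in cms:
        validate_cost_matrix(cm)
    children = np.random.SeedSequence(seed).spawn(len(cms) * len(lam_grid))
    rows = []
    idx = 0
    for cm in cms:
        for lam in lam_grid:
            cfg = SimulationConfig(n=n, lam=float(lam), cm=cm, max_cycles=max_cycles, seed=seed)
            rng = np.random.default_rng(children[idx])
            times, cens = batch_absorption_times(cfg, reps, rng)
            mean, sd, se, n_cens = _summarise(times, cens)
            approx = approx_absorption_time(n, float(lam), cm)
            exact = exact_expected_absorption_time(n, float(lam), cm) if n <= 100 else math.nan
            rows.append(
                SweepRecord(
                    scenario=_matrix_label(cm),
                    model="well_mixed",
                    n=n,
                    lam=float(lam),
                    cost_ii=cm.c_ii,
                    cost_id=cm.c_id,
                    cost_di=cm.c_di,
                    cost_dd=cm.c_dd,
                    reps=reps,
                    mean=mean,
                    sd=sd,
                    se=se,
                    censored=n_cens,
                    seed=seed,
                    extra={
                        "approx_t_abs": approx,
                        "exact_t_abs": exact,
                        "ratio_sim_approx": mean / approx,
                    },
                ).to_row()
            )
            idx += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PoolSizeResult:
    """Normalised absorption-time curve over pool size plus its shape."""

    records: pd.DataFrame
    shape: Shape
    small_n_decrease: bool
    large_n_increase: bool


def run_pool_size_study(
    cm: CostMatrix, n_grid: Sequence[int] = DEFAULT_N_GRID
) -> PoolSizeResult:
    """Evaluate f(n) = 1/(n pi_1) over a pool-size grid and classify its shape.

    The curve is normalised so the neutral matrix sits at 1 for every n;
    values are reported both directly and in log form (the direct value
    can overflow to inf for strongly selected regimes at n = 1e5).
    """
    validate_cost_matrix(cm)
    grid = [int(x) for x in n_grid]
    if not grid:
        raise ValueError("pool-size grid must not be empty")
    rows = [
        {
            "n": n,
            "t_abs_normalized": normalized_absorption_time(n, cm),
            "log_t_abs_normalized": log_normalized_absorption_time(n, cm),
            "cost_ii": cm.c_ii,
            "cost_id": cm.c_id,
            "cost_di": cm.c_di,
            "cost_dd": cm.c_dd,
        }
        for n in grid
    ]
    shape = classify_shape(cm, grid)
    return PoolSizeResult(
        records=pd.DataFrame(rows),
        shape=shape,
        small_n_decrease=small_n_decrease(cm),
        large_n_increase=large_n_increase(cm),
    )


def run_shape_diagram(
    c_id: float = 1.0,
    c_di_range: tuple[float, float] = (0.5, 1.5),
    c_dd_range: tuple[float, float] = (0.5, 1.5),
    resolution: int = 20,
    c_ii: float = 1.0,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
) -> pd.DataFrame:
    """Shape label over a (c_di, c_dd) grid at fixed c_ii and c_id.

    The diagram's axes cross at ``c_di = c_ii`` (who pays more against an
    intact partner) and ``c_dd = c_id`` (against a damaged partner); the
    upper-right quadrant is intact dominant and monotone increasing, the
    lower-left damaged dominant and monotone decreasing, while the two
    frequency-dependent quadrants mix monotone and convex-down shapes.
    The two boundary indicator columns mark where the small-n dip and the
    large-n rise switch on.
    """
    if resolution < 2:
        raise ValueError(f"resolution must be at least 2, got {resolution}")
    c_di_values = np.linspace(*c_di_range, resolution)
    c_dd_values = np.linspace(*c_dd_range, resolution)
    rows = []
    for c_di in c_di_values:
        for c_dd in c_dd_values:
            cm = CostMatrix(c_ii, c_id, float(c_di), float(c_dd))
            rows.append(
                {
                    "cost_di": float(c_di),
                    "cost_dd": float(c_dd),
                    "cost_id": c_id,
                    "cost_ii": c_ii,
                    "shape_label": classify_shape(cm, n_grid).value,
                    "small_n_decrease": small_n_decrease(cm),
                    "large_n_increase": large_n_increase(cm),
                }
            )
    return pd.DataFrame(rows)


def run_lattice_comparison(
    cm_list: Sequence[CostMatrix] = DEFAULT_MATRICES,
    n_list: Sequence[int] = (16, 36, 64, 100),
    lam: float = 0.002,
    reps: int = 50,
    seed: int = 0,
    max_cycles: Optional[float] = None,
) -> pd.DataFrame:
    """Paired lattice and well-mixed absorption times at matched pool sizes.

    Pool sizes must be perfect squares (>= 16) so the lattice side is
    integral; the runner refuses to approximate otherwise.  Every (matrix,
    n) condition contributes a well-mixed simulation row, a lattice
    simulation row, and an analytic low-dose-rate row.
    """
    if lam <= 0:
        raise ValueError(f"dose-rate parameter must be positive, got {lam}")
    sides = []
    for n in n_list:
        side = math.isqrt(int(n))
        if side * side != n or n < 16:
            raise ValueError(f"pool sizes must be perfect squares >= 16, got {n}")
        sides.append(side)
    for cm in cm_list:
        validate_cost_matrix(cm)
    children = np.random.SeedSequence(seed).spawn(2 * len(cm_list) * len(n_list))
    rows = []
    idx = 0
    for cm in cm_list:
        label = _matrix_label(cm)
        common = dict(
            cost_ii=cm.c_ii, cost_id=cm.c_id, cost_di=cm.c_di, cost_dd=cm.c_dd
        )
        for n, side in zip(n_list, sides):
            wm_cfg = SimulationConfig(n=n, lam=lam, cm=cm, max_cycles=max_cycles, seed=seed)
            rng = np.random.default_rng(children[idx])
            idx += 1
            times, cens = batch_absorption_times(wm_cfg, reps, rng)
            mean, sd, se, n_cens = _summarise(times, cens)
            rows.append(
                SweepRecord(
                    scenario=label, model="well_mixed", n=n, lam=lam, reps=reps,
                    mean=mean, sd=sd, se=se, censored=n_cens, seed=seed,
                    extra={"side": side}, **common,
                ).to_row()
            )
            lat_cfg = LatticeConfig(side=side, lam=lam, cm=cm, max_cycles=max_cycles, seed=seed)
            rng = np.random.default_rng(children[idx])
            idx += 1
            lat_times = np.empty(reps)
            lat_cens = np.zeros(reps, dtype=bool)
            for r in range(reps):
                res = simulate_lattice_absorption_time(lat_cfg, rng)
                lat_times[r] = res.time_cycles
                lat_cens[r] = res.censored
            mean, sd, se, n_cens = _summarise(lat_times, lat_cens)
            rows.append(
                SweepRecord(
                    scenario=label, model="lattice", n=n, lam=lam, reps=reps,
                    mean=mean, sd=sd, se=se, censored=n_cens, seed=seed,
                    extra={"side": side}, **common,
                ).to_row()
            )
            rows.append(
                SweepRecord(
                    scenario=label, model="analytic", n=n, lam=lam, reps=0,
                    mean=approx_absorption_time(n, lam, cm), seed=seed,
                    extra={"side": side}, **common,
                ).to_row()
            )
    return pd.DataFrame(rows)
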
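"""Closed-form and exact-numeric analysis of the well-mixed model.

Three layers of machinery:

* **Fixation probability.** With radiation off, the damaged count is a
  birth-death chain absorbed at 0 and ``n``.  The probability that a
  single damaged cell sweeps the pool is

      pi_1 = 1 / (1 + sum_{j=1}^{n-1} prod_{k=1}^{j} G_k / F_k),

  evaluated in log space (cumulative sums of ``log(G_k/F_k)`` aggregated
  with log-sum-exp) so pool sizes up to 1e5 are reachable without
  overflow even in strongly selected regimes.  A dense linear-solve of
  the hitting-probability system serves as an independent cross-check.

* **Very-low-dose-rate absorption time.** When hits are rare each hit's
  lineage resolves (extinction or sweep) before the next hit arrives, so

      T_abs ~= 1 / (n * lam * pi_1)         [cell cycles].

  The lam-free normalised form ``f(n) = 1/(n * pi_1)`` equals 1 for a
  neutral matrix at every ``n``; its shape over ``n`` (constant,
  monotone, or dipping then rising) is the pool-size analysis.

* **Exact mean absorption time.** For modest ``n`` the full chain with
  radiation (binomial upward jumps, then the Moran step) is built
  explicitly and the mean-hitting-time system ``(I - Q) t = 1`` solved,
  giving an oracle the stochastic engine is checked against.

The dosimetry helpers convert an occupational exposure scenario
(dose rate in mGy/h, exposure hours per cell cycle, elemental dose per
radiation track, damage probability per hit) into the model's dose-rate
parameter ``lam``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

from .cost_model import CostMatrix, validate_cost_matrix
from .wellmixed import _step_tables

__all__ = [
    "Shape",
    "OccupationalScenario",
    "DEFAULT_N_GRID",
    "fixation_probability",
    "fixation_probability_bruteforce",
    "approx_absorption_time",
    "exact_expected_absorption_time",
    "log_normalized_absorption_time",
    "normalized_absorption_time",
    "classify_shape",
    "small_n_decrease",
    "large_n_increase",
    "occupational_lambda",
    "dose_rate_from_annual",
    "working_days_per_elemental_dose",
]

#: Pool sizes used by default for shape analysis: log-ish spacing that
#: resolves both the small-n dip and the large-n recovery of the
#: convex-down regimes.
DEFAULT_N_GRID: tuple[int, ...] = (
    2, 3, 4, 6, 8, 12, 16, 24, 32, 48, 64, 100, 200, 500, 1000, 10_000, 100_000,
)


class Shape(str, Enum):
    """Qualitative shape of the normalised absorption time over pool size."""

    CONSTANT = "constant"
    MONOTONE_INCREASING = "monotone_increasing"
    MONOTONE_DECREASING = "monotone_decreasing"
    CONVEX_DOWN = "convex_down"
    OTHER = "other"


def _log_cost_ratio_cumsum(n: int, cm: CostMatrix) -> np.ndarray:
    """Cumulative sums of log(G_k / F_k) for k = 1..n-1."""
    k = np.arange(1, n, dtype=np.float64)
    f = (cm.c_ii * (n - k - 1) + cm.c_id * k) / (n - 1)
    g = (cm.c_di * (n - k) + cm.c_dd * (k - 1)) / (n - 1)
    return np.cumsum(np.log(g) - np.log(f))


def _log_inv_fixation(n: int, cm: CostMatrix) -> float:
    """log(1 / pi_1) = log(1 + sum_j prod_k G_k/F_k), overflow-free."""
    if n < 2:
        raise ValueError(f"pool size must be at least 2, got {n}")
    cum = _log_cost_ratio_cumsum(n, cm)
    return float(logsumexp(np.concatenate(([0.0], cum))))


def fixation_probability(n: int, cm: CostMatrix) -> float:
    """Probability that one damaged cell's lineage sweeps a pool of ``n``.

    Radiation is off for this quantity; it is the birth-death fixation
    probability of the competition chain, computed in log space.  For a
    neutral matrix it equals ``1/n`` exactly.
    """
    validate_cost_matrix(cm)
    return math.exp(-_log_inv_fixation(n, cm))


def fixation_probability_bruteforce(n: int, cm: CostMatrix) -> float:
    """Independent route to the fixation probability via a dense linear solve.

    Solves the first-step hitting-probability system of the radiation-free
    birth-death chain for absorption at ``k = n`` starting from ``k = 1``.
    Kept deliberately separate from :func:`fixation_probability` so the
    two can cross-validate each other.
    """
    validate_cost_matrix(cm)
    if n < 2:
        raise ValueError(f"pool size must be at least 2, got {n}")
    if n > 200:
        raise ValueError("dense hitting-probability solve is limited to n <= 200")
    up, down = _step_tables(n, cm)
    m = n - 1  # transient states 1..n-1
    a = np.zeros((m, m))
    for i, k in enumerate(range(1, n)):
        a[i, i] = up[k] + down[k]  # I - P restricted: 1 - stay = up + down
        if k - 1 >= 1:
            a[i, i - 1] = -down[k]
        if k + 1 <= n - 1:
            a[i, i + 1] = -up[k]
    b = np.zeros(m)
    b[-1] = up[n - 1]
    h = np.linalg.solve(a, b)
    return float(h[0])


def approx_absorption_time(n: int, lam: float, cm: CostMatrix) -> float:
    """Very-low-dose-rate absorption time, 1 / (n * lam * pi_1), in cell cycles.

    Exact in the limit where damaging hits are so rare that each hit's
    lineage resolves before the next hit; at higher ``lam`` it can serve
    as a bound rather than an estimate.
    """
    if lam <= 0:
        raise ValueError(f"dose-rate parameter must be positive, got {lam}")
    return math.exp(_log_inv_fixation(n, cm) - math.log(n) - math.log(lam))


def log_normalized_absorption_time(n: int, cm: CostMatrix) -> float:
    """log of f(n) = 1/(n * pi_1), the lam-free normalised absorption time.

    The neutral matrix gives f(n) = 1 for every n, so f > 1 means
    competition delays damage takeover and f < 1 means it accelerates it.
    Working in logs keeps pool sizes up to 1e5 in range for strongly
    selected matrices.
    """
    return _log_inv_fixation(n, cm) - math.log(n)


def normalized_absorption_time(n: int, cm: CostMatrix) -> float:
    """f(n) = 1/(n * pi_1); may overflow to inf for huge n in selected regimes."""
    lf = log_normalized_absorption_time(n, cm)
    try:
        return math.exp(lf)
    except OverflowError:
        return math.inf


def exact_expected_absorption_time(n: int, lam: float, cm: CostMatrix) -> float:
    """Exact mean time (cell cycles) for damage to take over, from all intact.

    Builds the one-elementary-step transition matrix of the composite
    process on ``k = 0..n`` -- a binomial radiation jump (each intact cell
    converts with probability ``1 - exp(-lam/n)``) followed by the Moran
    division/elimination step -- and solves the mean-hitting-time system
    ``(I - Q) t = 1`` for the transient states.  Requires ``lam > 0``
    (otherwise ``k = 0`` is absorbing too and the target is unreachable).
    """
    validate_cost_matrix(cm)
    if n < 2:
        raise ValueError(f"pool size must be at least 2, got {n}")
    if n > 100:
        raise ValueError("exact absorption-time solve is limited to n <= 100")
    if lam <= 0:
        raise ValueError(f"dose-rate parameter must be positive, got {lam}")
    p_hit = -math.expm1(-lam / n)
    states = np.arange(n + 1)

    # Radiation kernel: from k, the damaged count jumps to k + Binom(n-k, p).
    rad = np.zeros((n + 1, n + 1))
    for k in states:
        j = np.arange(0, n - k + 1)
        rad[k, k + j] = binom.pmf(j, n - k, p_hit)

    up, down = _step_tables(n, cm)
    moran = np.zeros((n + 1, n + 1))
    moran[states, states] = 1.0 - up - down
    moran[states[:-1], states[:-1] + 1] = up[:-1]
    moran[states[1:], states[1:] - 1] = down[1:]

    full = rad @ moran
    q = full[:n, :n]
    t = np.linalg.solve(np.eye(n) - q, np.ones(n))
    return float(t[0] / n)


def _shape_signs(log_f: np.ndarray, rel_tol: float) -> np.ndarray:
    d = np.diff(log_f)
    return np.where(d > rel_tol, 1, np.where(d < -rel_tol, -1, 0))


def classify_shape(
    cm: CostMatrix,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
    rel_tol: float = 1e-9,
) -> Shape:
    """Classify the shape of f(n) = 1/(n * pi_1) over a pool-size grid.

    Successive differences of ``log f`` (i.e. relative changes of ``f``)
    are thresholded at ``rel_tol``: all flat -> constant; no significant
    rise -> monotone_decreasing; no significant fall -> monotone_increasing;
    a falling prefix followed by a rising suffix with exactly one sign
    change -> convex_down; anything else -> other.  The tolerance keeps
    the neutral matrix from classifying as noise-monotone while f is
    evaluated in double precision.
    """
    validate_cost_matrix(cm)
    grid = [int(n) for n in n_grid]
    if len(grid) < 3:
        raise ValueError("pool-size grid needs at least 3 points")
    if min(grid) < 2:
        raise ValueError("pool sizes must be at least 2")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("pool-size grid must be strictly increasing")
    log_f = np.array([log_normalized_absorption_time(n, cm) for n in grid])
    signs = _shape_signs(log_f, rel_tol)
    if not signs.any():
        return Shape.CONSTANT
    if (signs <= 0).all():
        return Shape.MONOTONE_DECREASING
    if (signs >= 0).all():
        return Shape.MONOTONE_INCREASING
    first_pos = int(np.argmax(signs > 0))
    prefix, suffix = signs[:first_pos], signs[first_pos:]
    if (prefix <= 0).all() and (prefix < 0).any() and (suffix >= 0).all():
        return Shape.CONVEX_DOWN
    return Shape.OTHER


def small_n_decrease(cm: CostMatrix) -> bool:
    """True iff the normalised absorption time drops from n = 2 to n = 3.

    One of the two boundary indicators of the shape diagram (the other is
    :func:`large_n_increase`); together they separate monotone from
    convex-down regions without needing an unbounded grid.
    """
    validate_cost_matrix(cm)
    return log_normalized_absorption_time(3, cm) < log_normalized_absorption_time(2, cm)


def large_n_increase(cm: CostMatrix, n_large: int = 100_000) -> bool:
    """True iff the normalised absorption time is rising at very large n.

    Compares f at ``n_large`` against f at ``n_large / 2`` through the
    log-space evaluator, so the default of 1e5 cells is reachable in any
    regime without overflow.
    """
    validate_cost_matrix(cm)
    half = max(2, round(n_large / 2))
    return log_normalized_absorption_time(n_large, cm) > log_normalized_absorption_time(half, cm)


@dataclass(frozen=True)
class OccupationalScenario:
    """Chronic exposure scenario to convert into the dose-rate parameter.

    ``dose_rate_mgy_per_h``: ambient dose rate in mGy/h.
    ``exposed_hours_per_cycle``: hours of exposure within one cell-cycle
    length (e.g. an 8 h workday for a 24 h cycle).
    ``elemental_dose_mgy``: the lowest dose one radiation track deposits
    in a cell nucleus (~1 mGy for gamma rays in a typical mammalian
    nucleus), i.e. the dose per hit.
    ``hit_to_damage_prob``: probability H that a hit converts an intact
    cell; repair is folded into H.
    """

    dose_rate_mgy_per_h: float
    exposed_hours_per_cycle: float
    elemental_dose_mgy: float = 1.0
    hit_to_damage_prob: float = 1.0

    def __post_init__(self) -> None:
        for name in ("dose_rate_mgy_per_h", "exposed_hours_per_cycle", "elemental_dose_mgy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.hit_to_damage_prob <= 1.0:
            raise ValueError("hit_to_damage_prob must lie in [0, 1]")


def occupational_lambda(sc: OccupationalScenario) -> float:
    """Expected damaging hits per cell per cell cycle for a scenario.

    lam = dose_rate * exposed_hours * H / elemental_dose.  The worker
    benchmark (0.01 mGy/h over an 8 h day, 1 mGy per hit, H = 1) gives
    lam = 0.08: one damaging hit per cell per 12.5 cell cycles.
    """
    if sc.elemental_dose_mgy == 0:
        raise ValueError("elemental dose per hit must be positive")
    return (
        sc.dose_rate_mgy_per_h
        * sc.exposed_hours_per_cycle
        * sc.hit_to_damage_prob
        / sc.elemental_dose_mgy
    )


def dose_rate_from_annual(
    annual_dose_mgy: float = 20.0,
    working_days: float = 250.0,
    hours_per_day: float = 8.0,
) -> float:
    """Ambient dose rate (mGy/h) that accumulates an annual dose over work hours.

    The occupational default -- 20 mGy spread over 250 eight-hour days --
    gives 0.01 mGy/h.
    """
    if working_days <= 0 or hours_per_day <= 0:
        raise ValueError("working days and hours per day must be positive")
    return annual_dose_mgy / (working_days * hours_per_day)


def working_days_per_elemental_dose(
    dose_rate_mgy_per_h: float,
    hours_per_day: float = 8.0,
    elemental_dose_mgy: float = 1.0,
) -> float:
    """Workdays needed to accumulate one elemental dose (one hit per cell).

    At 0.01 mGy/h and 8 h days this is 12.5 days per 1 mGy hit, the
    waiting time behind lam = 0.08 for a 24 h cell cycle.
    """
    if dose_rate_mgy_per_h <= 0 or hours_per_day <= 0:
        raise ValueError("dose rate and hours per day must be positive")
    return elemental_dose_mgy / (dose_rate_mgy_per_h * hours_per_day)
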
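"""Well-mixed Moran process with chronic radiation damage influx.

The pool holds ``n`` stem cells, each intact or damaged.  Time advances in
elementary steps; ``n`` steps make one cell cycle.  Each elementary step
has two sub-events:

1. *Radiation*: each intact cell independently becomes damaged with
   probability ``1 - exp(-lam/n)``, where ``lam`` is the expected number
   of damaging hits per cell per cell cycle (the dose-rate parameter).
   Damage is irreversible; hits on damaged cells change nothing.
2. *Moran competition*: one cell is chosen uniformly to divide and one
   cell is chosen for elimination with probability proportional to its
   expected cost (F_k for intact, G_k for damaged), simultaneously.  The
   damaged count ``k`` moves by at most one:

       P(k -> k+1) = (k/n) * (n-k) F_k / [(n-k) F_k + k G_k]
       P(k -> k-1) = ((n-k)/n) * k G_k / [(n-k) F_k + k G_k]

With ``lam > 0`` the unique absorbing state is the all-damaged pool; the
absorption time ``T_abs`` (in cell cycles, i.e. steps / n) starting from
an all-intact pool is the model's measure of damage accumulation speed.

Because the pool is exchangeable, ``k`` is a sufficient statistic and the
composite (divider-type, eliminated-type) event is sampled directly from
the transition probabilities rather than tracking individual cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cost_model import CostMatrix, expected_cost_damaged, expected_cost_intact

__all__ = [
    "WellMixedState",
    "TransitionProbs",
    "SimulationConfig",
    "AbsorptionResult",
    "transition_probabilities",
    "radiation_substep",
    "moran_substep",
    "simulate_absorption_time",
    "batch_absorption_times",
]


@dataclass(frozen=True)
class WellMixedState:
    """Damaged-cell count plus elapsed elementary steps."""

    k: int
    steps: int = 0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"damaged count must be non-negative, got {self.k}")
        if self.steps < 0:
            raise ValueError(f"step count must be non-negative, got {self.steps}")


@dataclass(frozen=True)
class TransitionProbs:
    """One-step Moran transition probabilities for the damaged count."""

    up: float
    down: float
    stay: float


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one well-mixed run.

    ``max_cycles`` caps the simulated cell cycles; runs that exceed it are
    reported as censored rather than hanging (damage-disadvantaged regimes
    at tiny ``lam`` can be astronomically slow).  The default cap is
    ``1e7 / n`` cycles, i.e. 1e7 elementary steps.
    """

    n: int
    lam: float
    cm: CostMatrix
    max_cycles: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"pool size must be at least 2, got {self.n}")
        if self.lam < 0:
            raise ValueError(f"dose-rate parameter must be non-negative, got {self.lam}")
        if self.max_cycles is None:
            object.__setattr__(self, "max_cycles", 1e7 / self.n)
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")

    @property
    def hit_probability(self) -> float:
        """Per-intact-cell damage probability per elementary step, 1 - exp(-lam/n)."""
        return -math.expm1(-self.lam / self.n)


@dataclass(frozen=True)
class AbsorptionResult:
    """Absorption time in cell cycles, or a censoring flag if the cap was hit."""

    time_cycles: float
    censored: bool


def transition_probabilities(k: int, n: int, cm: CostMatrix) -> TransitionProbs:
    """Moran one-step probabilities for the damaged count at state ``k``.

    Both ``k = 0`` and ``k = n`` are fixed points of the competition
    sub-event (only radiation can move the chain off ``k = 0``).
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if k == 0 or k == n:
        return TransitionProbs(0.0, 0.0, 1.0)
    f = expected_cost_intact(k, n, cm)
    g = expected_cost_damaged(k, n, cm)
    total = (n - k) * f + k * g
    up = (k / n) * (n - k) * f / total
    down = ((n - k) / n) * k * g / total
    return TransitionProbs(up, down, 1.0 - up - down)


def _step_tables(n: int, cm: CostMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised up/down probability tables over k = 0..n."""
    up = np.zeros(n + 1)
    down = np.zeros(n + 1)
    k = np.arange(1, n)
    f = (cm.c_ii * (n - k - 1) + cm.c_id * k) / (n - 1)
    g = (cm.c_di * (n - k) + cm.c_dd * (k - 1)) / (n - 1)
    total = (n - k) * f + k * g
    up[1:n] = (k / n) * (n - k) * f / total
    down[1:n] = ((n - k) / n) * k * g / total
    return up, down


def radiation_substep(
    state: WellMixedState, cfg: SimulationConfig, rng: np.random.Generator
) -> WellMixedState:
    """Expose every intact cell to one elementary step of radiation.

    Each intact cell independently converts with probability
    ``1 - exp(-lam/n)`` (Poisson thinning of ``lam`` hits per cell per
    cycle over the ``n`` elementary steps of a cycle), so the expected
    number of conversions per step approaches ``lam`` in a mostly intact
    pool.  ``k`` never decreases; the step counter is untouched.
    """
    m = cfg.n - state.k
    if m < 0:
        raise ValueError(f"damaged count {state.k} exceeds pool size {cfg.n}")
    if m == 0 or cfg.lam == 0:
        return state
    hits = int(rng.binomial(m, cfg.hit_probability))
    return replace(state, k=state.k + hits)


def moran_substep(
    state: WellMixedState, cfg: SimulationConfig, rng: np.random.Generator
) -> WellMixedState:
    """One simultaneous division/elimination event; increments the step count."""
    tp = transition_probabilities(state.k, cfg.n, cfg.cm)
    u = rng.random()
    if u < tp.up:
        k = state.k + 1
    elif u < tp.up + tp.down:
        k = state.k - 1
    else:
        k = state.k
    return WellMixedState(k=k, steps=state.steps + 1)


def simulate_absorption_time(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> AbsorptionResult:
    """Simulate one trajectory from an all-intact pool to all-damaged.

    Alternates the radiation and competition sub-events until ``k = n``,
    returning the elapsed time in cell cycles (steps / n).  If the
    ``max_cycles`` cap is reached first the result is censored.
    """
    if cfg.lam <= 0:
        raise ValueError("absorption from an all-intact pool is unreachable at lam = 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    up, down = _step_tables(n, cfg.cm)
    p_hit = cfg.hit_probability
    max_steps = int(cfg.max_cycles * n)
    k = 0
    for step in range(1, max_steps + 1):
        if k < n:
            k += int(rng.binomial(n - k, p_hit))
        u = rng.random()
        if u < up[k]:
            k += 1
        elif u < up[k] + down[k]:
            k -= 1
        if k == n:
            return AbsorptionResult(step / n, False)
    return AbsorptionResult(math.nan, True)


def batch_absorption_times(
    cfg: SimulationConfig, reps: int, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Run ``reps`` independent absorption-time replicates in lock-step.

    All replicates advance together through vectorised radiation and
    competition sub-events, with finished replicates dropped from the
    working set; this is the engine behind the experiment sweeps.  Returns
    ``(times, censored)`` where censored replicates carry NaN times.

    Statistically identical in law to repeated
    :func:`simulate_absorption_time` calls, but draws from a single random
    stream (seeded from ``cfg.seed`` when no generator is given).
    """
    if reps < 1:
        raise ValueError("need at least one replicate")
    if cfg.lam <= 0:
        raise ValueError("absorption from an all-intact pool is unreachable at lam = 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    up, down = _step_tables(n, cfg.cm)
    p_hit = cfg.hit_probability
    max_steps = int(cfg.max_cycles * n)
    k = np.zeros(reps, dtype=np.int64)
    times = np.full(reps, np.nan)
    alive = np.arange(reps)
    step = 0
    while alive.size and step < max_steps:
        step += 1
        ka = k[alive]
        ka = ka + rng.binomial(n - ka, p_hit)
        u = rng.random(alive.size)
        ka = ka + (u < up[ka]) - ((u >= up[ka]) & (u < up[ka] + down[ka]))
        k[alive] = ka
        done = ka == n
        if done.any():
            times[alive[done]] = step / n
            alive = alive[~done]
    return times, np.isnan(times)
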
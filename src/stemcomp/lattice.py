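"""Spatial variant: stem cells on a periodic square lattice.

Each site of an L x L torus holds one cell, intact (0) or damaged (1).
A cell interacts with its 8 Moore neighbours; a cell of a given type
surrounded by ``l`` damaged neighbours pays the averaged cost

    intact:  phi = (c_ii * (8 - l) + c_id * l) / 8
    damaged: phi = (c_di * (8 - l) + c_dd * l) / 8

Each elementary competition step eliminates one cell with probability
proportional to its cost, then refills the vacated site with a copy of a
cell drawn uniformly from the 9-candidate set {the removed cell's former
occupant} union {its 8 neighbours} -- so the removed type can reappear in
place.  Radiation is the same per-intact-cell conversion scheme as the
well-mixed model with pool size N = L^2.  L**2 elementary steps make one
cell cycle.

The public sub-step operations recompute costs from scratch; the internal
simulator keeps the cost field incrementally (only the flipped site and
its neighbours change) and the two paths are checked against each other
in the test suite.

L = 3 is permitted but degenerate -- with periodic wrap every site then
neighbours every other site, so the model collapses toward well-mixed; a
log record flags it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cost_model import CostMatrix, validate_cost_matrix
from .wellmixed import AbsorptionResult

__all__ = [
    "LatticeState",
    "LatticeConfig",
    "INTACT",
    "DAMAGED",
    "neighbor_table",
    "damaged_neighbor_counts",
    "cost_field",
    "cell_cost",
    "elimination_distribution",
    "lattice_substep",
    "lattice_radiation_substep",
    "simulate_lattice_absorption_time",
    "estimate_fixation_probability_lattice",
]

logger = logging.getLogger(__name__)

INTACT = 0
DAMAGED = 1

#: Moore-neighbourhood offsets: the 8 combinations of {-1,0,1}^2 minus (0,0).
_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
)


@dataclass
class LatticeState:
    """L x L grid of cell types (row-major, periodic) plus elapsed steps."""

    grid: np.ndarray
    steps: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise ValueError(f"grid must be square, got shape {self.grid.shape}")
        if self.grid.shape[0] < 3:
            raise ValueError("lattice side must be at least 3 for a Moore neighbourhood")
        if not np.isin(self.grid, (INTACT, DAMAGED)).all():
            raise ValueError("grid entries must be 0 (intact) or 1 (damaged)")
        if self.steps < 0:
            raise ValueError("step count must be non-negative")

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cells(self) -> int:
        return self.grid.size

    @property
    def n_damaged(self) -> int:
        return int(self.grid.sum())


@dataclass(frozen=True)
class LatticeConfig:
    """Parameters of one lattice run; the pool size is ``side ** 2``."""

    side: int
    lam: float
    cm: CostMatrix
    max_cycles: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side < 3:
            raise ValueError(f"lattice side must be at least 3, got {self.side}")
        if self.side == 3:
            logger.warning(
                "side=3 lattice: with periodic wrap every site neighbours every "
                "other, degenerating toward the well-mixed model"
            )
        if self.lam < 0:
            raise ValueError(f"dose-rate parameter must be non-negative, got {self.lam}")
        if self.max_cycles is None:
            object.__setattr__(self, "max_cycles", 1e7 / self.side**2)
        if self.max_cycles <= 0:
            raise ValueError("max_cycles must be positive")

    @property
    def n_cells(self) -> int:
        return self.side**2

    @property
    def hit_probability(self) -> float:
        return -math.expm1(-self.lam / self.n_cells)


def neighbor_table(side: int) -> np.ndarray:
    """(N, 8) flat indices of each site's Moore neighbours on the torus."""
    if side < 3:
        raise ValueError(f"lattice side must be at least 3, got {side}")
    rows, cols = np.divmod(np.arange(side * side), side)
    table = np.empty((side * side, 8), dtype=np.int64)
    for j, (dr, dc) in enumerate(_OFFSETS):
        table[:, j] = ((rows + dr) % side) * side + (cols + dc) % side
    return table


def damaged_neighbor_counts(grid: np.ndarray) -> np.ndarray:
    """Number of damaged Moore neighbours of every site (periodic wrap)."""
    counts = np.zeros_like(grid, dtype=np.int64)
    for dr, dc in _OFFSETS:
        counts += np.roll(np.roll(grid, dr, axis=0), dc, axis=1)
    return counts


def cost_field(grid: np.ndarray, cm: CostMatrix) -> np.ndarray:
    """Cost phi of every site, recomputed from scratch (reference path)."""
    l = damaged_neighbor_counts(grid)
    intact_phi = (cm.c_ii * (8 - l) + cm.c_id * l) / 8.0
    damaged_phi = (cm.c_di * (8 - l) + cm.c_dd * l) / 8.0
    return np.where(grid == DAMAGED, damaged_phi, intact_phi)


def cell_cost(state: LatticeState, site: tuple[int, int], cm: CostMatrix) -> float:
    """Cost phi of the cell at ``site`` = (row, col), with periodic wrap."""
    side = state.side
    r, c = site
    if not (0 <= r < side and 0 <= c < side):
        raise ValueError(f"site {site} outside a {side}x{side} lattice")
    l = sum(int(state.grid[(r + dr) % side, (c + dc) % side] == DAMAGED) for dr, dc in _OFFSETS)
    if state.grid[r, c] == DAMAGED:
        return (cm.c_di * (8 - l) + cm.c_dd * l) / 8.0
    return (cm.c_ii * (8 - l) + cm.c_id * l) / 8.0


def elimination_distribution(state: LatticeState, cm: CostMatrix) -> np.ndarray:
    """Per-site elimination probabilities phi_i / sum(phi), flattened row-major."""
    validate_cost_matrix(cm)
    phi = cost_field(state.grid, cm).ravel()
    return phi / phi.sum()


def _draw_elimination_and_replacer(
    phi_flat: np.ndarray, nbrs: np.ndarray, grid_flat: np.ndarray, rng: np.random.Generator
) -> tuple[int, int]:
    """Common draw sequence for both the reference and incremental paths.

    Samples the eliminated site cost-proportionally, then the replacer
    uniformly from the site itself plus its 8 neighbours; keeping the
    draw order identical in both paths makes them trajectory-equivalent
    under a shared random stream.
    """
    cum = np.cumsum(phi_flat)
    site = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    site = min(site, phi_flat.size - 1)
    pick = int(rng.integers(9))
    source = site if pick == 8 else int(nbrs[site, pick])
    return site, int(grid_flat[source])


def lattice_substep(
    state: LatticeState, cm: CostMatrix, rng: np.random.Generator
) -> LatticeState:
    """One elimination/replacement event (reference full-recompute path).

    Returns a new state with the eliminated site rewritten to the type of
    a uniformly chosen candidate from {itself} union {8 neighbours} and
    the step counter incremented.
    """
    validate_cost_matrix(cm)
    phi = cost_field(state.grid, cm).ravel()
    nbrs = neighbor_table(state.side)
    site, new_type = _draw_elimination_and_replacer(phi, nbrs, state.grid.ravel(), rng)
    grid = state.grid.copy()
    grid.flat[site] = new_type
    return LatticeState(grid=grid, steps=state.steps + 1)


def lattice_radiation_substep(
    state: LatticeState, lam: float, rng: np.random.Generator
) -> LatticeState:
    """One elementary step of radiation over the lattice.

    Each intact site independently converts with probability
    ``1 - exp(-lam / L^2)``, mirroring the well-mixed scheme at pool size
    N = L^2; the step counter is untouched.
    """
    if lam < 0:
        raise ValueError(f"dose-rate parameter must be non-negative, got {lam}")
    if lam == 0:
        return LatticeState(grid=state.grid.copy(), steps=state.steps)
    p = -math.expm1(-lam / state.n_cells)
    grid = state.grid.copy()
    intact = grid == INTACT
    flips = intact & (rng.random(grid.shape) < p)
    grid[flips] = DAMAGED
    return LatticeState(grid=grid, steps=state.steps)


class _LatticeSim:
    """Fast trajectory engine with an incrementally maintained cost field.

    Only the flipped site and its 8 neighbours can change cost after an
    event, so phi is patched locally; sampling still pays O(N) per step
    for the cumulative sum, which dominates at the pool sizes used here.
    """

    def __init__(self, side: int, cm: CostMatrix, rng: np.random.Generator):
        self.side = side
        self.n = side * side
        self.cm = cm
        self.rng = rng
        self.nbrs = neighbor_table(side)
        self.grid = np.zeros(self.n, dtype=np.int8)
        self.l = np.zeros(self.n, dtype=np.int64)  # damaged Moore-neighbour counts
        self.phi = np.full(self.n, cm.c_ii)
        self.n_damaged = 0
        self.steps = 0

    def seed_damaged(self, site: int) -> None:
        self._flip(site, DAMAGED)

    def _site_phi(self, i: int) -> float:
        l = self.l[i]
        cm = self.cm
        if self.grid[i] == DAMAGED:
            return (cm.c_di * (8 - l) + cm.c_dd * l) / 8.0
        return (cm.c_ii * (8 - l) + cm.c_id * l) / 8.0

    def _flip(self, i: int, new_type: int) -> None:
        old = self.grid[i]
        if old == new_type:
            return
        self.grid[i] = new_type
        delta = 1 if new_type == DAMAGED else -1
        self.n_damaged += delta
        nb = self.nbrs[i]
        self.l[nb] += delta
        self.phi[i] = self._site_phi(i)
        for j in nb:
            self.phi[j] = self._site_phi(j)

    def radiation_step(self, p_hit: float) -> None:
        n_intact = self.n - self.n_damaged
        if p_hit == 0.0 or n_intact == 0:
            return
        hits = int(self.rng.binomial(n_intact, p_hit))
        if hits:
            intact_sites = np.flatnonzero(self.grid == INTACT)
            for s in self.rng.choice(intact_sites, size=hits, replace=False):
                self._flip(int(s), DAMAGED)

    def competition_step(self) -> None:
        site, new_type = _draw_elimination_and_replacer(self.phi, self.nbrs, self.grid, self.rng)
        self._flip(site, new_type)
        self.steps += 1

    def state(self) -> LatticeState:
        return LatticeState(grid=self.grid.reshape(self.side, self.side).copy(), steps=self.steps)


def simulate_lattice_absorption_time(
    cfg: LatticeConfig, rng: Optional[np.random.Generator] = None
) -> AbsorptionResult:
    """Simulate one trajectory from all-intact to all-damaged on the torus.

    Alternates the radiation and competition sub-events; returns the time
    in cell cycles (steps / L^2) or a censored result if ``max_cycles``
    is exceeded.
    """
    validate_cost_matrix(cfg.cm)
    if cfg.lam <= 0:
        raise ValueError("absorption from an all-intact lattice is unreachable at lam = 0")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sim = _LatticeSim(cfg.side, cfg.cm, rng)
    n = cfg.n_cells
    p_hit = cfg.hit_probability
    max_steps = int(cfg.max_cycles * n)
    for step in range(1, max_steps + 1):
        sim.radiation_step(p_hit)
        sim.competition_step()
        if sim.n_damaged == n:
            return AbsorptionResult(step / n, False)
    return AbsorptionResult(math.nan, True)


def estimate_fixation_probability_lattice(
    cfg: LatticeConfig, n_reps: int, rng: Optional[np.random.Generator] = None
) -> tuple[float, float]:
    """Estimate the single-invader fixation probability by simulation.

    Radiation is off for this quantity.  Each replicate seeds one damaged
    cell at a uniformly random site (translation invariance of the torus
    makes the placement irrelevant) and runs competition steps until the
    grid is uniform; the estimate is the fraction of damaged-fixation
    outcomes, returned with its binomial standard error.
    """
    validate_cost_matrix(cfg.cm)
    if n_reps < 1:
        raise ValueError(f"need at least one replicate, got {n_reps}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    fixed = 0
    for _ in range(n_reps):
        sim = _LatticeSim(cfg.side, cfg.cm, rng)
        sim.seed_damaged(int(rng.integers(n)))
        while 0 < sim.n_damaged < n:
            sim.competition_step()
        fixed += sim.n_damaged == n
    p_hat = fixed / n_reps
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_reps)
    return p_hat, se
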
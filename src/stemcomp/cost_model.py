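"""Pairwise interaction costs in a two-type stem-cell pool.

A stem-cell pool holds intact cells and radiation-damaged cells.  Every
cell pays a cost determined by which cells it interacts with; cells with
higher expected cost are more likely to be eliminated, so cost acts as an
inverse fitness.  The four pairwise costs form a 2x2 matrix:

    ``c_ii`` -- intact cell interacting with an intact cell,
    ``c_id`` -- intact cell interacting with a damaged cell,
    ``c_di`` -- damaged cell interacting with an intact cell,
    ``c_dd`` -- damaged cell interacting with a damaged cell.

With ``k`` damaged cells in a well-mixed pool of ``n``, the expected cost
of an intact cell is the mixture over its ``n - 1`` possible interaction
partners,

    F_k = c_ii * (n - k - 1)/(n - 1) + c_id * k/(n - 1),

and the expected cost of a damaged cell is

    G_k = c_di * (n - k)/(n - 1) + c_dd * (k - 1)/(n - 1).

If ``c_ii == c_id`` the intact cost is frequency independent (constant in
``k``); likewise ``c_di == c_dd`` for the damaged cost.  The sign
structure of the matrix decides the game-theoretic regime -- dominance,
coordination (positive frequency dependence) or hawk-dove (negative
frequency dependence) -- which in turn shapes how the time for damage to
take over the pool depends on pool size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from enum import Enum

__all__ = [
    "CostMatrix",
    "Regime",
    "validate_cost_matrix",
    "regime",
    "expected_cost_intact",
    "expected_cost_damaged",
]


class Regime(str, Enum):
    """Game-theoretic regime of a two-type cost matrix.

    The comparisons ``c_ii`` vs ``c_di`` (who pays more against an intact
    partner) and ``c_id`` vs ``c_dd`` (who pays more against a damaged
    partner) split the parameter plane into four quadrants.  Ties that are
    not full neutrality are reported as ``BOUNDARY`` rather than being
    silently folded into a quadrant, because those ties are exactly the
    axes of the shape diagram.
    """

    NEUTRAL = "neutral"
    INTACT_DOMINANT = "intact_dominant"
    DAMAGED_DOMINANT = "damaged_dominant"
    POSITIVE_FREQUENCY_DEPENDENT = "positive_frequency_dependent"
    NEGATIVE_FREQUENCY_DEPENDENT = "negative_frequency_dependent"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class CostMatrix:
    """The four pairwise interaction costs, all strictly positive and finite.

    Costs are kept as plain positive reals; no normalisation to
    ``c_ii == 1`` is enforced (use :meth:`normalized` to rescale).  The
    process law only depends on cost ratios, so a common positive scale
    factor is irrelevant.
    """

    c_ii: float
    c_id: float
    c_di: float
    c_dd: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"cost matrix entry {f.name} must be a real number, got {v!r}")
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"cost matrix entry {f.name} must be strictly positive and finite, got {v!r}"
                )

    @property
    def is_frequency_independent(self) -> bool:
        """True iff neither cell type's expected cost depends on the mix."""
        return self.c_ii == self.c_id and self.c_di == self.c_dd

    @property
    def is_neutral(self) -> bool:
        """True iff all four entries are equal (no selection at all)."""
        return self.c_ii == self.c_id == self.c_di == self.c_dd

    def normalized(self) -> "CostMatrix":
        """Rescale so the intact-intact cost equals 1 (divides by ``c_ii``)."""
        return CostMatrix(1.0, self.c_id / self.c_ii, self.c_di / self.c_ii, self.c_dd / self.c_ii)

    def scaled(self, factor: float) -> "CostMatrix":
        """Multiply every entry by ``factor`` (> 0); leaves the process law unchanged."""
        return CostMatrix(
            self.c_ii * factor, self.c_id * factor, self.c_di * factor, self.c_dd * factor
        )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.c_ii, self.c_id, self.c_di, self.c_dd)


def validate_cost_matrix(cm: CostMatrix) -> CostMatrix:
    """Check positivity and finiteness of every entry, returning ``cm`` unchanged.

    ``CostMatrix`` already validates on construction; this re-runs the same
    checks for instances built through other paths (e.g. ``replace`` on a
    subclass, deserialisation).
    """
    CostMatrix(cm.c_ii, cm.c_id, cm.c_di, cm.c_dd)
    return cm


def regime(cm: CostMatrix) -> Regime:
    """Classify the cost matrix into its game-theoretic regime.

    intact_dominant: intact cells pay less against every partner type;
    damaged_dominant: the reverse; positive frequency dependence
    (coordination): each type pays more against the *other* type; negative
    frequency dependence (hawk-dove): each type pays more against its
    *own* type.  Full equality is neutral, any other tie is boundary.
    """
    validate_cost_matrix(cm)
    if cm.is_neutral:
        return Regime.NEUTRAL
    if cm.c_ii < cm.c_di and cm.c_id < cm.c_dd:
        return Regime.INTACT_DOMINANT
    if cm.c_ii > cm.c_di and cm.c_id > cm.c_dd:
        return Regime.DAMAGED_DOMINANT
    if cm.c_ii < cm.c_di and cm.c_id > cm.c_dd:
        return Regime.POSITIVE_FREQUENCY_DEPENDENT
    if cm.c_ii > cm.c_di and cm.c_id < cm.c_dd:
        return Regime.NEGATIVE_FREQUENCY_DEPENDENT
    return Regime.BOUNDARY


def _check_pool(n: int) -> None:
    if n < 2:
        raise ValueError(f"pool size must be at least 2, got {n}")


def expected_cost_intact(k: int, n: int, cm: CostMatrix) -> float:
    """Expected cost F_k of an intact cell when ``k`` of ``n`` cells are damaged.

    Requires at least one intact cell (``k <= n - 1``); an intact cell has
    ``n - k - 1`` intact and ``k`` damaged potential partners.
    """
    _check_pool(n)
    if not 0 <= k <= n - 1:
        raise ValueError(f"need 0 <= k <= n-1 for an intact cell to exist, got k={k}, n={n}")
    return (cm.c_ii * (n - k - 1) + cm.c_id * k) / (n - 1)


def expected_cost_damaged(k: int, n: int, cm: CostMatrix) -> float:
    """Expected cost G_k of a damaged cell when ``k`` of ``n`` cells are damaged.

    Requires at least one damaged cell (``k >= 1``); a damaged cell has
    ``n - k`` intact and ``k - 1`` damaged potential partners.
    """
    _check_pool(n)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n for a damaged cell to exist, got k={k}, n={n}")
    return (cm.c_di * (n - k) + cm.c_dd * (k - 1)) / (n - 1)
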
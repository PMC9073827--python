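"""Interval numbers and the gain/loss payoff calculus against an interval reference point.

An uncertain quantity is expressed by its bounds, ``[lo, hi]``.  Both the
attribute values of an alternative's outcomes and the (collective) reference
point separating gains from losses are interval numbers.  The payoff of an
attribute interval ``C`` relative to a reference interval ``R`` depends on
which of six positional relations holds between the two intervals:

=====  =====================================  ==========================
case   relation                               interpretation
=====  =====================================  ==========================
1      ``C.hi < R.lo``                        C entirely below R
2      ``C.lo > R.hi``                        C entirely above R
3      ``C.lo < R.lo <= C.hi < R.hi``         partial overlap, C shifted low
4      ``R.lo < C.lo <= R.hi < C.hi``         partial overlap, C shifted high
5      ``C.lo < R.lo < R.hi < C.hi``          R nested inside C
6      ``R.lo <= C.lo < C.hi <= R.hi``        C nested inside R
=====  =====================================  ==========================

For a benefit criterion (larger is better) values above the reference are
gains; for a cost criterion (smaller is better) the roles are mirrored.
Case 1 and 2 payoffs are the expectation of ``x - R`` bound under a uniform
density on ``C``; cases 3-5 use the half-differences of the overhanging
bounds; a nested attribute (case 6) is payoff-neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum, IntEnum

from scipy.integrate import quad

__all__ = [
    "Interval",
    "CriterionType",
    "RelationCase",
    "PayoffPair",
    "classify_relation",
    "payoff",
    "uniform_expected_payoff_oracle",
]


class CriterionType(str, Enum):
    """Direction of preference for a criterion."""

    BENEFIT = "benefit"
    COST = "cost"


@dataclass(frozen=True)
class Interval:
    """Closed interval number ``[lo, hi]``; degenerate ``lo == hi`` is allowed."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        lo = float(self.lo)
        hi = float(self.hi)
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError(f"interval bounds must be finite, got [{self.lo}, {self.hi}]")
        if lo > hi:
            raise ValueError(f"interval lower bound {lo} exceeds upper bound {hi}")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def as_pair(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    @classmethod
    def coerce(cls, value: "Interval | tuple[float, float] | list[float]") -> "Interval":
        if isinstance(value, Interval):
            return value
        lo, hi = value
        return cls(float(lo), float(hi))


class RelationCase(IntEnum):
    """The six positional relations of an attribute interval C to a reference R."""

    BELOW = 1
    ABOVE = 2
    OVERLAP_LOW = 3
    OVERLAP_HIGH = 4
    REFERENCE_NESTED = 5
    ATTRIBUTE_NESTED = 6


@dataclass(frozen=True)
class PayoffPair:
    """Gain/loss decomposition of a payoff: ``gain >= 0``, ``loss <= 0``.

    Both components can be nonzero at once (the reference nested inside the
    attribute interval, case 5).  ``net`` is the sum, for reporting; gains and
    losses are valued separately downstream because prospect theory treats
    them asymmetrically.
    """

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError(f"gain must be nonnegative, got {self.gain}")
        if self.loss > 0:
            raise ValueError(f"loss must be nonpositive, got {self.loss}")

    @property
    def net(self) -> float:
        return self.gain + self.loss


def classify_relation(c: Interval, r: Interval) -> RelationCase:
    """Classify the position of attribute interval ``c`` relative to reference ``r``.

    The strict inequalities of the six textbook cases do not cover boundary
    equalities, so classification applies a fixed precedence: 1, 2, 6, 5, 3, 4.
    Nested-equal intervals therefore land in case 6 (zero payoff), and point
    intervals reduce to the crisp sign comparison.
    """
    c = Interval.coerce(c)
    r = Interval.coerce(r)
    if c.hi < r.lo:
        return RelationCase.BELOW
    if c.lo > r.hi:
        return RelationCase.ABOVE
    if r.lo <= c.lo and c.hi <= r.hi:
        return RelationCase.ATTRIBUTE_NESTED
    if c.lo <= r.lo and r.hi <= c.hi:
        return RelationCase.REFERENCE_NESTED
    if c.lo < r.lo:
        return RelationCase.OVERLAP_LOW
    return RelationCase.OVERLAP_HIGH


def _benefit_payoff(c: Interval, r: Interval, case: RelationCase) -> tuple[float, float]:
    if case is RelationCase.BELOW:
        return 0.0, c.midpoint - r.lo
    if case is RelationCase.ABOVE:
        return c.midpoint - r.hi, 0.0
    if case is RelationCase.OVERLAP_LOW:
        return 0.0, 0.5 * (c.lo - r.lo)
    if case is RelationCase.OVERLAP_HIGH:
        return 0.5 * (c.hi - r.hi), 0.0
    if case is RelationCase.REFERENCE_NESTED:
        return 0.5 * (c.hi - r.hi), 0.5 * (c.lo - r.lo)
    return 0.0, 0.0  # attribute nested in reference: neutral


def payoff(
    c: Interval,
    r: Interval,
    criterion_type: CriterionType | str = CriterionType.BENEFIT,
) -> PayoffPair:
    """Gain/loss payoff of attribute interval ``c`` against reference ``r``.

    For a cost criterion the benefit payoff is mirrored (negate and swap the
    two components), so an attribute below the reference is a gain and gains
    stay nonnegative, losses nonpositive, in every case.
    """
    c = Interval.coerce(c)
    r = Interval.coerce(r)
    ctype = CriterionType(criterion_type)
    case = classify_relation(c, r)
    gain, loss = _benefit_payoff(c, r, case)
    if ctype is CriterionType.COST:
        gain, loss = -loss, -gain
    # guard against sign noise from exact-zero boundaries
    return PayoffPair(gain=max(gain, 0.0), loss=min(loss, 0.0))


def uniform_expected_payoff_oracle(c: Interval, r: Interval) -> float:
    """Expected benefit payoff of ``x - R`` bound under a uniform density on ``c``.

    Numerical-integration oracle for the disjoint cases (1 and 2), where the
    payoff is defined as the expectation of ``x - R.lo`` (case 1) or
    ``x - R.hi`` (case 2) with ``x`` uniform on ``c``; the closed form is the
    interval midpoint minus the relevant reference bound.  Not applicable to
    overlapping cases or to a degenerate attribute interval (no density).
    """
    c = Interval.coerce(c)
    r = Interval.coerce(r)
    if c.lo >= c.hi:
        raise ValueError("uniform density undefined for a degenerate interval")
    case = classify_relation(c, r)
    if case is RelationCase.BELOW:
        bound = r.lo
    elif case is RelationCase.ABOVE:
        bound = r.hi
    else:
        raise ValueError(f"oracle applies only to disjoint intervals (cases 1-2), got case {int(case)}")
    density = 1.0 / (c.hi - c.lo)
    value, _ = quad(lambda x: (x - bound) * density, c.lo, c.hi)
    return value
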
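"""Cumulative prospect theory engine: value function, probability weighting,
rank-dependent decision weights, and multi-attribute prospect aggregation.

Outcomes are valued as gains or losses relative to the collective reference
point through the two-piece power value function

    v(z) = z**alpha          if z >= 0
    v(z) = -lam * (-z)**beta if z < 0

with loss aversion ``lam >= 1``.  Valued payoffs are normalized per criterion
by the maximum absolute valued payoff so criteria on different scales can be
aggregated.  Probabilities are distorted by the neo-additive (piecewise
linear) weighting function w(p) = mu*p + (1-mu)/2 on (0,1), w(0)=0, w(1)=1,
which overweights small and underweights large probabilities; decision
weights are cumulative differences of w over the rank-ordered outcomes,
computed separately for gains (from the best outcome down) and losses (from
the worst outcome up).  The prospect value of an alternative is the
attribute-weighted sum of its per-criterion weighted normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CPTParams",
    "DecisionWeights",
    "value_function",
    "normalize_values",
    "probability_weight",
    "decision_weights",
    "prospect_value",
    "rank",
]


@dataclass(frozen=True)
class CPTParams:
    """Behavioral parameters of the prospect-value model.

    alpha, beta : float in (0, 1]
        Curvature of the value function on gains / losses (1 = linear).
    lam : float >= 1
        Loss aversion: a loss weighs ``lam`` times an equal gain.
    mu : float in (0, 1]
        Slope of the neo-additive probability weighting function; mu = 1
        leaves probabilities undistorted.
    """

    alpha: float = 1.0
    beta: float = 1.0
    lam: float = 2.0
    mu: float = 0.6

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError(f"beta must lie in (0, 1], got {self.beta}")
        if self.lam < 1.0:
            raise ValueError(f"loss aversion lam must be >= 1, got {self.lam}")
        if not (0.0 < self.mu <= 1.0):
            raise ValueError(f"mu must lie in (0, 1], got {self.mu}")


def value_function(z: float, params: CPTParams) -> float:
    """Two-piece power value of a payoff relative to the reference point."""
    if z >= 0:
        return float(z) ** params.alpha if z != 0 else 0.0
    return -params.lam * (-float(z)) ** params.beta


def normalize_values(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalize valued payoffs per criterion by the max absolute valued payoff.

    ``values`` has shape (M, N, K): alternatives x outcomes x criteria,
    already passed through the value function (so loss aversion is inside the
    normalizer).  Returns ``(vtilde, vstar)`` where ``vstar[k] = max_{m,n}
    |values[m,n,k]|`` and ``vtilde = values / vstar`` in [-1, 1]; an all-zero
    criterion normalizes to zeros.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must have shape (alternatives, outcomes, criteria)")
    vstar = np.abs(values).max(axis=(0, 1))
    safe = np.where(vstar == 0, 1.0, vstar)
    return values / safe, vstar


def probability_weight(p: float, mu: float) -> float:
    """Neo-additive probability weighting: w(0)=0, w(1)=1, else mu*p + (1-mu)/2."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    return mu * p + 0.5 * (1.0 - mu)


@dataclass(frozen=True)
class DecisionWeights:
    """Rank-dependent decision weights for one (alternative, criterion) prospect.

    ``pi`` is aligned with the input outcome order; ``is_gain`` flags the
    outcomes treated as gains (normalized value >= 0).  For the neo-additive
    family the weights telescope: sum(pi) == 1 for any gain/loss split.
    """

    pi: np.ndarray
    is_gain: np.ndarray

    @property
    def n_gains(self) -> int:
        return int(self.is_gain.sum())


def decision_weights(
    probabilities: Sequence[float],
    normalized_values: Sequence[float],
    params: CPTParams,
) -> DecisionWeights:
    """Cumulative-difference decision weights over rank-ordered outcomes.

    Outcomes are sorted by normalized value, best first (stable, ties by
    input index; zero values count as gains).  The n-th ranked gain receives
    w(p_1+...+p_n) - w(p_1+...+p_{n-1}); ranking losses from the worst
    upward, a loss receives w(p_n+...+p_N) - w(p_{n+1}+...+p_N).  A single
    weighting function serves both sides.
    """
    p = np.asarray(probabilities, dtype=float)
    v = np.asarray(normalized_values, dtype=float)
    if p.shape != v.shape or p.ndim != 1:
        raise ValueError("probabilities and values must be 1-d and the same length")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"outcome probabilities must sum to 1, got {p.sum()}")

    order = np.argsort(-v, kind="stable")  # best outcome first
    n = len(p)
    n_gains = int(np.sum(v[order] >= 0.0))
    p_sorted = p[order]
    # cumulative probability from the best outcome down; the grand total is
    # pinned to exactly 1 so the w(1) = 1 endpoint (and with it the
    # telescoping identity sum(pi) = 1) survives floating-point summation
    prefix = np.concatenate(([0.0], np.cumsum(p_sorted)))
    prefix[-1] = 1.0
    prefix = np.clip(prefix, 0.0, 1.0)
    suffix = 1.0 - prefix  # suffix[i] = probability of outcomes ranked i..N-1
    w = lambda q: probability_weight(q, params.mu)
    pi_ranked = np.empty(n)
    for i in range(n_gains):
        pi_ranked[i] = w(prefix[i + 1]) - w(prefix[i])
    for i in range(n - 1, n_gains - 1, -1):  # losses, worst upward
        pi_ranked[i] = w(suffix[i]) - w(suffix[i + 1])
    pi = np.empty(n)
    pi[order] = pi_ranked
    is_gain = np.zeros(n, dtype=bool)
    is_gain[order[:n_gains]] = True
    return DecisionWeights(pi=pi, is_gain=is_gain)


def prospect_value(
    probabilities: Sequence[float],
    normalized_values: np.ndarray,
    criterion_weights: Sequence[float],
    params: CPTParams,
) -> float:
    """Multi-attribute prospect value of one alternative.

    ``normalized_values`` has shape (N, K).  Decision weights are computed
    per criterion (an outcome may rank as a gain on one criterion and a loss
    on another); the per-criterion weighted sums are combined with the
    attribute weights, which must be nonnegative and sum to one.
    """
    vt = np.asarray(normalized_values, dtype=float)
    wj = np.asarray(criterion_weights, dtype=float)
    if vt.ndim != 2:
        raise ValueError("normalized_values must have shape (outcomes, criteria)")
    if wj.shape != (vt.shape[1],):
        raise ValueError("criterion_weights length must match the criterion count")
    if np.any(wj < -1e-12):
        raise ValueError("criterion weights must be nonnegative")
    if abs(wj.sum() - 1.0) > 1e-9:
        raise ValueError(f"criterion weights must sum to 1, got {wj.sum()}")
    total = 0.0
    for k in range(vt.shape[1]):
        dw = decision_weights(probabilities, vt[:, k], params)
        total += wj[k] * float(dw.pi @ vt[:, k])
    return total


def rank(prospect_values: Sequence[float]) -> list[int]:
    """Indices of alternatives by descending prospect value; ties keep input order."""
    pv = np.asarray(prospect_values, dtype=float)
    if pv.size == 0:
        raise ValueError("at least one alternative is required")
    return list(np.argsort(-pv, kind="stable"))
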
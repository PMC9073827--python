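"""End-to-end solver for interval-valued group emergency decision problems.

The five-step procedure: (1) fix criteria and the expert panel, (2) collect
interval outcome values per alternative, (3) weight experts by similarity of
their normalized reference points to the mean opinion, (4) aggregate the raw
reference intervals into a collective reference point per criterion, and
(5) score each alternative by its multi-attribute CPT prospect value and rank
descending.  Every intermediate (expert weights, collective reference,
payoff table, valued/normalized tables, decision weights, prospect values)
is retained in the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import consensus
from .cpt import CPTParams, normalize_values, prospect_value, rank, value_function
from .intervals import CriterionType, Interval, PayoffPair, payoff

__all__ = [
    "Criterion",
    "Outcome",
    "Alternative",
    "SolveOptions",
    "DecisionProblem",
    "RunReport",
    "solve",
    "single_criterion_run",
    "expert_weight_scenarios",
]

_TOL = 1e-9


@dataclass(frozen=True)
class Criterion:
    name: str
    ctype: CriterionType
    weight: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ctype", CriterionType(self.ctype))
        if self.weight < 0:
            raise ValueError(f"criterion {self.name!r}: weight must be nonnegative")


@dataclass(frozen=True)
class Outcome:
    """One possible consequence of an alternative: a probability and an
    interval attribute value per criterion."""

    probability: float
    values: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"outcome probability must lie in [0, 1], got {self.probability}")
        object.__setattr__(self, "values", tuple(Interval.coerce(v) for v in self.values))


@dataclass(frozen=True)
class Alternative:
    name: str
    outcomes: tuple[Outcome, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        if not self.outcomes:
            raise ValueError(f"alternative {self.name!r} has no outcomes")
        psum = sum(o.probability for o in self.outcomes)
        if abs(psum - 1.0) > _TOL:
            raise ValueError(
                f"alternative {self.name!r}: outcome probabilities sum to {psum}, expected 1"
            )


@dataclass(frozen=True)
class SolveOptions:
    """Switches for the comparative experiments.

    probability_weighting : "neo_additive" (default) or "identity" — the
        latter scores outcomes by their objective probabilities.
    expert_weights : optional explicit weight vector that bypasses the
        similarity-based weighting when aggregating the collective reference.
    """

    probability_weighting: str = "neo_additive"
    expert_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.probability_weighting not in ("neo_additive", "identity"):
            raise ValueError(
                f"unknown probability_weighting {self.probability_weighting!r}; "
                "expected 'neo_additive' or 'identity'"
            )
        if self.expert_weights is not None:
            w = tuple(float(x) for x in self.expert_weights)
            if any(x < 0 for x in w):
                raise ValueError("explicit expert weights must be nonnegative")
            if abs(sum(w) - 1.0) > _TOL:
                raise ValueError(f"explicit expert weights sum to {sum(w)}, expected 1")
            object.__setattr__(self, "expert_weights", w)


@dataclass(frozen=True)
class DecisionProblem:
    criteria: tuple[Criterion, ...]
    panel: consensus.ExpertPanel
    alternatives: tuple[Alternative, ...]
    params: CPTParams = field(default_factory=CPTParams)
    options: SolveOptions = field(default_factory=SolveOptions)
    meta: dict | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        k = len(self.criteria)
        if k == 0:
            raise ValueError("at least one criterion is required")
        if not self.alternatives:
            raise ValueError("at least one alternative is required")
        wsum = sum(c.weight for c in self.criteria)
        if abs(wsum - 1.0) > _TOL:
            raise ValueError(f"criterion weights sum to {wsum}, expected 1")
        if self.panel.n_criteria != k:
            raise ValueError(
                f"expert panel covers {self.panel.n_criteria} criteria, problem has {k}"
            )
        n = len(self.alternatives[0].outcomes)
        for alt in self.alternatives:
            if len(alt.outcomes) != n:
                raise ValueError("all alternatives must have the same number of outcomes")
            for o in alt.outcomes:
                if len(o.values) != k:
                    raise ValueError(
                        f"alternative {alt.name!r}: each outcome needs a value per criterion"
                    )
        if self.options.expert_weights is not None and len(self.options.expert_weights) != self.panel.n_experts:
            raise ValueError("explicit expert weights length must match the expert count")

    @property
    def criterion_types(self) -> list[CriterionType]:
        return [c.ctype for c in self.criteria]

    @property
    def criterion_weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.criteria], dtype=float)

    def with_options(self, **changes) -> "DecisionProblem":
        return dataclasses.replace(self, options=dataclasses.replace(self.options, **changes))

    def with_params(self, **changes) -> "DecisionProblem":
        return dataclasses.replace(self, params=dataclasses.replace(self.params, **changes))


@dataclass(frozen=True)
class RunReport:
    """All intermediates of one solve, in input order throughout."""

    problem: DecisionProblem
    expert_weights: np.ndarray  # (H,)
    collective_reference: tuple[Interval, ...]  # (K,)
    payoffs: tuple[tuple[tuple[PayoffPair, ...], ...], ...]  # (M, N, K)
    net_payoffs: np.ndarray  # (M, N, K)
    values: np.ndarray  # (M, N, K) after the value function
    vstar: np.ndarray  # (K,) per-criterion normalizers
    normalized_values: np.ndarray  # (M, N, K) in [-1, 1]
    combined_values: np.ndarray  # (M, N) criterion-weighted normalized values
    transition_weights: np.ndarray  # (M, N) w(p_mn), reporting aid
    prospect_values: np.ndarray  # (M,)
    ranking: tuple[int, ...]
    provenance: dict

    @property
    def ranked_names(self) -> tuple[str, ...]:
        return tuple(self.problem.alternatives[i].name for i in self.ranking)

    @property
    def best(self) -> str:
        return self.ranked_names[0]


def _problem_digest(problem: DecisionProblem) -> str:
    from .problem_io import problem_to_dict  # local import to avoid a cycle

    blob = json.dumps(problem_to_dict(problem), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _effective_params(problem: DecisionProblem) -> CPTParams:
    if problem.options.probability_weighting == "identity":
        # neo-additive weighting with unit slope is exactly w(p) = p
        return dataclasses.replace(problem.params, mu=1.0)
    return problem.params


def solve(problem: DecisionProblem) -> RunReport:
    """Run the full five-step procedure and return every intermediate."""
    panel = problem.panel
    if problem.options.expert_weights is not None:
        ew = consensus.ExpertWeights(w_h=np.array(problem.options.expert_weights))
    else:
        ew = consensus.derive_expert_weights(panel, problem.criterion_types)
    collective = consensus.collective_reference(panel, ew)

    m = len(problem.alternatives)
    n = len(problem.alternatives[0].outcomes)
    k = len(problem.criteria)
    pay: list[list[list[PayoffPair]]] = []
    values = np.zeros((m, n, k))
    net = np.zeros((m, n, k))
    for i, alt in enumerate(problem.alternatives):
        rows = []
        for j, out in enumerate(alt.outcomes):
            cells = []
            for q, (cval, crit) in enumerate(zip(out.values, problem.criteria)):
                pp = payoff(cval, collective.r_k[q], crit.ctype)
                cells.append(pp)
                net[i, j, q] = pp.net
                # gains and losses valued separately, then summed (PT is
                # asymmetric; with a single nonzero component this equals
                # valuing the net payoff)
                values[i, j, q] = value_function(pp.gain, problem.params) + value_function(
                    pp.loss, problem.params
                )
            rows.append(tuple(cells))
        pay.append(rows)

    vtilde, vstar = normalize_values(values)
    wj = problem.criterion_weights
    combined = np.einsum("k,ink->in", wj, vtilde)

    params = _effective_params(problem)
    probs = np.array([[o.probability for o in alt.outcomes] for alt in problem.alternatives])
    from .cpt import probability_weight

    transition = np.array([[probability_weight(p, params.mu) for p in row] for row in probs])
    pv = np.array(
        [
            prospect_value(probs[i], vtilde[i], wj, params)
            for i in range(m)
        ]
    )
    order = tuple(rank(pv))
    provenance = {
        "params": dataclasses.asdict(problem.params),
        "options": {
            "probability_weighting": problem.options.probability_weighting,
            "expert_weights": problem.options.expert_weights,
        },
        "input_digest": _problem_digest(problem),
    }
    return RunReport(
        problem=problem,
        expert_weights=ew.w_h,
        collective_reference=collective.r_k,
        payoffs=tuple(tuple(r) for r in pay),
        net_payoffs=net,
        values=values,
        vstar=vstar,
        normalized_values=vtilde,
        combined_values=combined,
        transition_weights=transition,
        prospect_values=pv,
        ranking=order,
        provenance=provenance,
    )


def single_criterion_run(problem: DecisionProblem, criterion_index: int) -> RunReport:
    """Re-solve with full attribute weight on one criterion (weight vector e_k)."""
    k = len(problem.criteria)
    if not (0 <= criterion_index < k):
        raise ValueError(f"criterion index {criterion_index} out of range for {k} criteria")
    new_criteria = tuple(
        dataclasses.replace(c, weight=1.0 if j == criterion_index else 0.0)
        for j, c in enumerate(problem.criteria)
    )
    return solve(dataclasses.replace(problem, criteria=new_criteria))


def expert_weight_scenarios(
    problem: DecisionProblem, scenarios: Sequence[Sequence[float]]
) -> list[RunReport]:
    """Re-solve the problem under explicit expert-weight vectors.

    Each scenario bypasses the similarity-based weighting: the given weights
    feed the collective-reference aggregation directly, and the downstream
    payoff and CPT stages re-run unchanged, so differences across scenarios
    isolate the influence of whose reference point counts.
    """
    reports = []
    for ws in scenarios:
        reports.append(solve(problem.with_options(expert_weights=tuple(float(x) for x in ws))))
    return reports
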
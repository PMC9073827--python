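"""Reading and writing decision-problem documents and run reports.

A problem document is JSON or YAML (dispatched on file extension) with the
shape::

    {
      "criteria":     [{"name": "C1", "type": "benefit", "weight": 0.4}, ...],
      "experts":      [{"name": "E1", "reference_points": [[40, 48], ...]}, ...],
      "alternatives": [{"name": "A1",
                        "outcomes": [{"probability": 0.75,
                                      "values": [[60, 70], ...]}, ...]}, ...],
      "cpt":          {"alpha": 1, "beta": 1, "lambda": 2, "mu": 0.6},
      "options":      {"probability_weighting": "neo_additive",
                       "expert_weights": null},
      "meta":         {...}            # optional free-form provenance
    }

Documents are schema-validated before any computation; unknown fields and
invariant violations are rejected with the offending document path (e.g.
``alternatives[2].outcomes[0].probability``).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .consensus import ExpertPanel
from .cpt import CPTParams
from .intervals import Interval
from .pipeline import (
    Alternative,
    Criterion,
    DecisionProblem,
    Outcome,
    RunReport,
    SolveOptions,
)

__all__ = [
    "ProblemFormatError",
    "load_problem",
    "parse_problem",
    "problem_to_dict",
    "save_problem",
    "write_report",
    "report_to_dict",
    "format_report_text",
]


class ProblemFormatError(ValueError):
    """A document failed parsing, schema validation, or an invariant check."""


class _CriterionDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    type: Literal["benefit", "cost"]
    weight: float = Field(ge=0)


class _ExpertDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    reference_points: list[list[float]]


class _OutcomeDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    probability: float = Field(ge=0, le=1)
    values: list[list[float]]


class _AlternativeDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    outcomes: list[_OutcomeDoc]


class _CPTDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 1.0
    beta: float = 1.0
    lam: float = Field(default=2.0, alias="lambda")
    mu: float = 0.6


class _OptionsDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    probability_weighting: Literal["neo_additive", "identity"] = "neo_additive"
    expert_weights: Optional[list[float]] = None


class _ProblemDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    criteria: list[_CriterionDoc]
    experts: list[_ExpertDoc]
    alternatives: list[_AlternativeDoc]
    cpt: _CPTDoc = _CPTDoc()
    options: _OptionsDoc = _OptionsDoc()
    meta: Optional[dict] = None


def _format_loc(loc: tuple) -> str:
    parts = []
    for item in loc:
        if isinstance(item, int):
            parts.append(f"[{item}]")
        else:
            parts.append(f".{item}" if parts else str(item))
    return "".join(parts) or "<document root>"


def parse_problem(data: dict) -> DecisionProblem:
    """Validate a raw document dict and build a :class:`DecisionProblem`."""
    try:
        doc = _ProblemDoc.model_validate(data)
    except ValidationError as exc:
        msgs = "; ".join(f"{_format_loc(e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ProblemFormatError(f"invalid problem document: {msgs}") from exc

    def interval(pair: list[float], where: str) -> Interval:
        if len(pair) != 2:
            raise ProblemFormatError(f"{where}: an interval needs exactly two bounds, got {pair}")
        try:
            return Interval(pair[0], pair[1])
        except ValueError as exc:
            raise ProblemFormatError(f"{where}: {exc}") from exc

    k = len(doc.criteria)
    try:
        criteria = tuple(Criterion(c.name, c.type, c.weight) for c in doc.criteria)
        panel = ExpertPanel(
            entries=tuple(
                tuple(
                    interval(pair, f"experts[{h}].reference_points[{j}]")
                    for j, pair in enumerate(e.reference_points)
                )
                for h, e in enumerate(doc.experts)
            ),
            experts=tuple(e.name for e in doc.experts),
            criteria=tuple(c.name for c in doc.criteria),
        )
        for h, e in enumerate(doc.experts):
            if len(e.reference_points) != k:
                raise ProblemFormatError(
                    f"experts[{h}].reference_points: expected {k} intervals, got {len(e.reference_points)}"
                )
        alternatives = []
        for i, a in enumerate(doc.alternatives):
            outcomes = []
            for j, o in enumerate(a.outcomes):
                if len(o.values) != k:
                    raise ProblemFormatError(
                        f"alternatives[{i}].outcomes[{j}].values: expected {k} intervals, got {len(o.values)}"
                    )
                outcomes.append(
                    Outcome(
                        probability=o.probability,
                        values=tuple(
                            interval(pair, f"alternatives[{i}].outcomes[{j}].values[{q}]")
                            for q, pair in enumerate(o.values)
                        ),
                    )
                )
            alternatives.append(Alternative(name=a.name, outcomes=tuple(outcomes)))
        params = CPTParams(alpha=doc.cpt.alpha, beta=doc.cpt.beta, lam=doc.cpt.lam, mu=doc.cpt.mu)
        options = SolveOptions(
            probability_weighting=doc.options.probability_weighting,
            expert_weights=tuple(doc.options.expert_weights)
            if doc.options.expert_weights is not None
            else None,
        )
        return DecisionProblem(
            criteria=criteria,
            panel=panel,
            alternatives=tuple(alternatives),
            params=params,
            options=options,
            meta=doc.meta,
        )
    except ProblemFormatError:
        raise
    except ValueError as exc:
        raise ProblemFormatError(f"invalid problem document: {exc}") from exc


def load_problem(path: str | Path) -> DecisionProblem:
    """Load and validate a problem document from a JSON or YAML file."""
    path = Path(path)
    if not path.exists():
        raise ProblemFormatError(f"no such file: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ProblemFormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ProblemFormatError(f"{path}: document root must be a mapping")
    return parse_problem(data)


def problem_to_dict(problem: DecisionProblem) -> dict:
    """Serialize a problem back to its canonical document form."""
    doc = {
        "criteria": [
            {"name": c.name, "type": c.ctype.value, "weight": c.weight} for c in problem.criteria
        ],
        "experts": [
            {
                "name": problem.panel.experts[h],
                "reference_points": [list(cell.as_pair()) for cell in row],
            }
            for h, row in enumerate(problem.panel.entries)
        ],
        "alternatives": [
            {
                "name": a.name,
                "outcomes": [
                    {"probability": o.probability, "values": [list(v.as_pair()) for v in o.values]}
                    for o in a.outcomes
                ],
            }
            for a in problem.alternatives
        ],
        "cpt": {
            "alpha": problem.params.alpha,
            "beta": problem.params.beta,
            "lambda": problem.params.lam,
            "mu": problem.params.mu,
        },
        "options": {
            "probability_weighting": problem.options.probability_weighting,
            "expert_weights": list(problem.options.expert_weights)
            if problem.options.expert_weights is not None
            else None,
        },
    }
    if problem.meta is not None:
        doc["meta"] = problem.meta
    return doc


def save_problem(problem: DecisionProblem, path: str | Path) -> None:
    path = Path(path)
    doc = problem_to_dict(problem)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def report_to_dict(report: RunReport) -> dict:
    """Machine-readable report with every pipeline intermediate."""
    prob = report.problem
    return {
        "provenance": report.provenance,
        "expert_weights": {
            name: w for name, w in zip(prob.panel.experts, report.expert_weights.tolist())
        },
        "collective_reference": {
            c.name: list(r.as_pair()) for c, r in zip(prob.criteria, report.collective_reference)
        },
        "payoffs": [
            {
                "alternative": a.name,
                "outcomes": [
                    {
                        "probability": o.probability,
                        "per_criterion": [
                            {
                                "criterion": c.name,
                                "gain": pp.gain,
                                "loss": pp.loss,
                                "net": pp.net,
                            }
                            for c, pp in zip(prob.criteria, report.payoffs[i][j])
                        ],
                    }
                    for j, o in enumerate(a.outcomes)
                ],
            }
            for i, a in enumerate(prob.alternatives)
        ],
        "value_normalizers": {
            c.name: v for c, v in zip(prob.criteria, report.vstar.tolist())
        },
        "normalized_values": report.normalized_values.tolist(),
        "combined_values": report.combined_values.tolist(),
        "transition_weights": report.transition_weights.tolist(),
        "prospect_values": {
            a.name: pv for a, pv in zip(prob.alternatives, report.prospect_values.tolist())
        },
        "ranking": list(report.ranked_names),
    }


def format_report_text(report: RunReport) -> str:
    """Aligned plain-text report mirroring the payoff and prospect tables."""
    prob = report.problem
    crit_names = [c.name for c in prob.criteria]
    lines: list[str] = []
    lines.append("Expert weights")
    lines.append(
        "  " + "  ".join(f"{n}={w:.3f}" for n, w in zip(prob.panel.experts, report.expert_weights))
    )
    lines.append("")
    lines.append("Collective reference points")
    for c, r in zip(prob.criteria, report.collective_reference):
        lines.append(f"  {c.name} ({c.ctype.value}, w={c.weight:g}): [{r.lo:.3f}, {r.hi:.3f}]")
    lines.append("")
    lines.append("Net payoffs per (alternative, outcome, criterion)")
    header = f"  {'alternative':<14}{'outcome':>8}  " + "".join(f"{n:>12}" for n in crit_names)
    lines.append(header)
    for i, a in enumerate(prob.alternatives):
        for j, o in enumerate(a.outcomes):
            cells = "".join(f"{report.net_payoffs[i, j, q]:>12.3f}" for q in range(len(crit_names)))
            lines.append(f"  {a.name:<14}{f'p={o.probability:g}':>8}  {cells}")
    lines.append("")
    lines.append("Combined normalized values and transition weights")
    lines.append(f"  {'alternative':<14}" + "".join(f"{f'outcome {j+1}':>22}" for j in range(len(prob.alternatives[0].outcomes))))
    for i, a in enumerate(prob.alternatives):
        cells = "".join(
            f"{report.combined_values[i, j]:>12.3f} (w={report.transition_weights[i, j]:.2f})"
            for j in range(report.combined_values.shape[1])
        )
        lines.append(f"  {a.name:<14}{cells}")
    lines.append("")
    lines.append("Prospect values")
    for a, pv in zip(prob.alternatives, report.prospect_values):
        lines.append(f"  {a.name:<14}{pv:>8.3f}")
    lines.append("")
    lines.append("Ranking: " + " > ".join(report.ranked_names))
    return "\n".join(lines) + "\n"


def write_report(report: RunReport, path: str | Path, format: str = "json") -> None:
    """Write a run report as machine-readable JSON or an aligned text table."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(report_to_dict(report), indent=2) + "\n")
    elif format == "text":
        path.write_text(format_report_text(report))
    else:
        raise ValueError(f"unknown report format {format!r}; expected 'json' or 'text'")
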
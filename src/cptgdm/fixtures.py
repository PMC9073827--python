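"""Packaged surgical-emergency example and a seeded random problem generator.

:func:`worked_example` builds the canonical demonstration problem: four
physicians state interval reference points over three benefit criteria
(immediate treatment effect, long-run post-surgery effect, ripple effect on
the hospital) and three response alternatives (traditional method, standard
treatment, new therapy) each either succeed or fail with known probability.

:func:`generate` draws arbitrary well-formed problems for property-based
testing: interval reference points and outcome values per criterion scale,
probabilities on the simplex, and a configurable benefit/cost mix so the
cost-criterion branch is exercised continuously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consensus import ExpertPanel
from .cpt import CPTParams
from .intervals import Interval
from .pipeline import Alternative, Criterion, DecisionProblem, Outcome

__all__ = ["worked_example", "GeneratorConfig", "generate"]


def worked_example() -> DecisionProblem:
    """The packaged surgical-emergency decision problem (H=4, K=3, M=3, N=2)."""
    criteria = (
        Criterion("C1", "benefit", 0.40),  # main immediate treatment effect
        Criterion("C2", "benefit", 0.35),  # potential long-run effect after surgery
        Criterion("C3", "benefit", 0.25),  # positive ripple effect on the hospital
    )
    panel = ExpertPanel(
        entries=(
            (Interval(40, 48), Interval(50, 55), Interval(0.48, 0.58)),
            (Interval(38, 46), Interval(48, 54), Interval(0.45, 0.54)),
            (Interval(45, 50), Interval(52, 56), Interval(0.50, 0.60)),
            (Interval(48, 52), Interval(50, 54), Interval(0.55, 0.62)),
        ),
        experts=("E1", "E2", "E3", "E4"),
        criteria=("C1", "C2", "C3"),
    )
    alternatives = (
        Alternative(
            "A1",  # traditional method
            outcomes=(
                Outcome(0.75, (Interval(60, 70), Interval(80, 85), Interval(0.75, 0.80))),
                Outcome(0.25, (Interval(30, 40), Interval(40, 45), Interval(0.35, 0.40))),
            ),
        ),
        Alternative(
            "A2",  # standard treatment method
            outcomes=(
                Outcome(0.80, (Interval(70, 75), Interval(72, 80), Interval(0.75, 0.85))),
                Outcome(0.20, (Interval(32, 42), Interval(46, 48), Interval(0.45, 0.50))),
            ),
        ),
        Alternative(
            "A3",  # new therapy method
            outcomes=(
                Outcome(0.70, (Interval(82, 88), Interval(75, 80), Interval(0.80, 0.84))),
                Outcome(0.30, (Interval(36, 44), Interval(35, 40), Interval(0.48, 0.50))),
            ),
        ),
    )
    return DecisionProblem(
        criteria=criteria,
        panel=panel,
        alternatives=alternatives,
        params=CPTParams(alpha=1.0, beta=1.0, lam=2.0, mu=0.6),
        meta={"label": "surgical emergency response, four-physician panel"},
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape and distributional settings for random well-formed problems.

    Defaults mirror the packaged example's scale (4 experts, 3 criteria,
    3 alternatives, 2 outcomes).  ``benefit_fraction`` of the criteria are
    benefit-type (the leading ones after rounding); criterion scales are
    drawn in ``scale_range`` and intervals get half-widths up to
    ``max_width_fraction`` of the scale.  The same config and seed always
    produce the identical problem document.
    """

    seed: int
    n_experts: int = 4
    n_criteria: int = 3
    n_alternatives: int = 3
    n_outcomes: int = 2
    benefit_fraction: float = 2.0 / 3.0
    scale_range: tuple[float, float] = (10.0, 100.0)
    max_width_fraction: float = 0.2

    def __post_init__(self) -> None:
        for name in ("n_experts", "n_criteria", "n_alternatives", "n_outcomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.benefit_fraction <= 1.0):
            raise ValueError("benefit_fraction must lie in [0, 1]")
        lo, hi = self.scale_range
        if not (0 < lo < hi):
            raise ValueError("scale_range must be an increasing positive pair")
        if not (0 < self.max_width_fraction <= 1):
            raise ValueError("max_width_fraction must lie in (0, 1]")


def _random_interval(rng: np.random.Generator, center_lo: float, center_hi: float, max_width: float) -> Interval:
    center = rng.uniform(center_lo, center_hi)
    half = 0.5 * rng.uniform(0.0, max_width)
    return Interval(center - half, center + half)


def generate(config: GeneratorConfig) -> DecisionProblem:
    """Draw a random well-formed decision problem from the given config."""
    rng = np.random.default_rng(config.seed)
    k = config.n_criteria
    n_benefit = round(config.benefit_fraction * k)
    types = ["benefit"] * n_benefit + ["cost"] * (k - n_benefit)
    weights = rng.dirichlet(np.ones(k))
    weights = weights / weights.sum()
    criteria = tuple(
        Criterion(f"C{j + 1}", types[j], float(weights[j])) for j in range(k)
    )
    scales = rng.uniform(*config.scale_range, size=k)
    max_widths = config.max_width_fraction * scales

    panel = ExpertPanel(
        entries=tuple(
            tuple(
                _random_interval(rng, 0.3 * scales[j], 0.7 * scales[j], max_widths[j])
                for j in range(k)
            )
            for _ in range(config.n_experts)
        ),
        experts=tuple(f"E{h + 1}" for h in range(config.n_experts)),
        criteria=tuple(c.name for c in criteria),
    )
    alternatives = []
    for i in range(config.n_alternatives):
        probs = rng.dirichlet(np.ones(config.n_outcomes))
        probs = probs / probs.sum()
        outcomes = tuple(
            Outcome(
                probability=float(p),
                values=tuple(
                    _random_interval(rng, 0.0, scales[j], max_widths[j]) for j in range(k)
                ),
            )
            for p in probs
        )
        alternatives.append(Alternative(f"A{i + 1}", outcomes=outcomes))
    return DecisionProblem(
        criteria=criteria,
        panel=panel,
        alternatives=tuple(alternatives),
        params=CPTParams(),
        meta={"generator": {"seed": config.seed, "config": repr(config)}},
    )
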
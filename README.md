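# cptgdm

Interval-valued, multi-attribute cumulative prospect theory (CPT) for group
emergency decision-making.

When a medical emergency demands choosing among response alternatives
(surgical approaches, therapies), the choice is a risk decision: each
alternative can succeed or fail with some probability, its consequences span
several criteria (immediate effect, long-run effect, institutional impact),
and the physicians judging it are not risk-neutral. `cptgdm` implements a
decision-support pipeline that

1. collects each expert's *interval* reference point per criterion
   (E_hk = [E^L, E^H]),
2. weights experts by how close their normalized reference intervals sit to
   the panel mean (similarity weighting), and aggregates the raw intervals
   into a collective reference point r_k per criterion,
3. converts each alternative's interval outcome values x_mnk into gains and
   losses relative to r_k via a six-case interval payoff calculus (for
   disjoint intervals the payoff is the uniform-density expectation
   0.5(C^L + C^H) − R bound; overlapping cases use half-differences of the
   overhanging bounds; a nested value is neutral),
4. values payoffs with the two-piece power value function
   v(z) = z^α for gains, v(z) = −λ(−z)^β for losses (loss aversion λ ≥ 1),
   normalizes per criterion by the maximum absolute valued payoff, and
5. weights probabilities with the neo-additive distortion
   w(p) = μp + (1−μ)/2 on (0,1) (w(0)=0, w(1)=1), forms rank-dependent
   cumulative decision weights π± separately for gains and losses per
   criterion, and ranks alternatives by the attribute-weighted prospect
   value PV_i.

Benefit and cost criteria are both supported (for a cost criterion a value
below the reference is the gain), and a seeded generator produces arbitrary
well-formed problems for property-based testing.

## Worked example

The packaged demonstration problem has four physicians, three benefit
criteria with weights (0.4, 0.35, 0.25), and three response alternatives
that succeed or fail with probabilities (0.75, 0.8, 0.7); α = β = 1, λ = 2,
μ = 0.6.

```python
from cptgdm import worked_example, solve

report = solve(worked_example())
print(report.expert_weights.round(3))    # [0.277 0.227 0.261 0.236]
print(report.collective_reference[0])    # Interval(lo=42.738..., hi=49.012...)
print(report.prospect_values.round(3))   # [0.257 0.431 0.422]
print(" > ".join(report.ranked_names))   # A2 > A3 > A1
```

or from the shell:

```
$ cptgdm demo
Expert weights
  E1=0.277  E2=0.227  E3=0.261  E4=0.236
...
Prospect values
  A1               0.257
  A2               0.431
  A3               0.422

Ranking: A2 > A3 > A1
```

The standard treatment (A2) wins: its smaller failure loss (−0.252 after
normalization) outweighs the new therapy's larger success value once the
0.3 failure probability is overweighted to 0.38. Switching to objective
probabilities and λ = 1 (`cptgdm solve problem.json
--no-probability-weighting --lambda 1`) flips the ranking to A3 — risk
attitudes, not the data, decide this case.

`cptgdm solve` handles your own JSON/YAML problem documents (see
`cptgdm solve --help` for parameter overrides, single-criterion runs and
explicit expert weights); `cptgdm generate --seed N -o problem.json` writes
a random well-formed document.

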
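# seqopt

Simulation-based optimization of interim-analysis schemes for event-driven,
two-arm survival trials.

Late-phase trials in diseases with low historical success rates (the
motivating setting is ALS) spend most of their calendar time confirming
futility. `seqopt` searches over group-sequential monitoring schemes —
the number and timing of futility looks plus power-family (Kim-DeMets)
α- and β-spending exponents — and selects the scheme with the best
expected operating characteristics when the treatment effect is drawn
from a mixture prior: a narrow "the drug works" component weighted by the
historical success probability, and a wide variance-inflated "it doesn't"
component. It also applies a chosen scheme retrospectively to published
per-look summaries (hazard ratio + CI) and computes conditional power.

## What is in the box

| module | responsibility |
|---|---|
| `seqopt.designs` | power-family error spending, boundary computation by recursive Gaussian integration, crossing probabilities, Schoenfeld event counts, event-count inflation |
| `seqopt.priors` | historical-cohort expected events (Weibull), SE of the log-HR, mixture prior over the treatment effect |
| `seqopt.simulate` | event-driven trial simulation (Weibull PH, uniform accrual, no dropout), signed sequential log-rank z-trajectories |
| `seqopt.search` | scheme enumeration, max-duration exclusion, common-random-number evaluation, selection |
| `seqopt.monitor` | z reconstruction from HR/CI, retrospective boundary decisions, B-value conditional power |
| `seqopt.config` / `seqopt.fixtures` / `seqopt.sweep` / `seqopt.cli` | YAML configuration, ready-made example configs, treatment-effect sweeps, command line |

Conventions: one-sided testing, z > 0 favors the treated arm, upper
boundary stops for superiority, lower *nonbinding* boundary stops for
futility, efficacy is tested at one interim look (default 60% of maximum
events) and at the final analysis; the final look tests efficacy only.

## Command line

```bash
seqopt fixture toy --out toy.yaml       # write a small, fast configuration
seqopt optimize toy.yaml --out results  # enumerate, evaluate, rank schemes
seqopt evaluate toy.yaml --design results/optimum.json
seqopt sweep toy.yaml results/optimum.json --hr-grid 0.4,0.7,1.0,1.3
seqopt monitor looks.csv design.json    # looks.csv: hr,lo,hi or z,events
```

`optimize` writes `schemes_ranked.csv` (all candidates, retained and
excluded, with operating characteristics), `optimum.json`,
`optimum_boundaries.csv` and the resolved configuration + seed, so every
run is reproducible from its own outputs. Parallel evaluation
(`execution.workers`) is bitwise identical to serial execution:
replicates use independent child streams keyed by replicate index.

The `dipals`, `respistimals` and `ceftriaxone` fixtures carry the
published planning quantities (historical medians 21.4/37.5 months with
43 patients per arm and 24-month follow-up, success probability
2/28 = 7.1%, SEs 0.335 / 1.06 / 0.147, Weibull shape 2) but use clearly
labeled placeholder values for protocol-level inputs that are not public
(planned n, accrual, α, power); replace those before drawing quantitative
conclusions about the real trials.

## Known caveats

- The "ineffective" mixture component defaults to being centered on the
  design effect (differing from the success component only in spread);
  pass `futility_hr: 1.0` in the prior block for a null-centered variant.
- Conditional power is the standard B-value formulation with the drift
  implied by a user-supplied hazard ratio at the design's maximum event
  count; published conditional-power figures can differ if they were
  computed against other planned event counts.
- Scheme evaluation scores every scheme on the same simulated trials, so
  comparisons are paired; the winner's mean criterion still carries the
  usual (small) selection optimism — re-simulate the selected scheme for
  an unbiased estimate.
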
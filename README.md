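# cardiocea

Decision-analytic cost-effectiveness engine comparing the two standard
revascularization strategies for coronary artery disease — coronary artery
bypass grafting (CABG) and percutaneous coronary intervention (PCI) with a
drug-eluting stent — from the patient's perspective, in 2014 Iranian cost
data (USD at 26,509 rials/dollar).

It is written for health economists and HTA analysts: a six-state Markov
cohort model with per-cycle cost and utility rewards, QALY/ICER/ACER/net
monetary benefit computation, deterministic (tornado) and probabilistic
(Monte Carlo) sensitivity analysis, plus a synthetic patient-cohort
generator so the costing and questionnaire-scoring stages run end-to-end
without any protected patient data.

## The model

The cohort enters at age 59 in the *Stable* state of its assigned arm and
advances in 6-month cycles through six states: Stable, repeat CABG, repeat
PCI, cerebrovascular accident (CVA), coronary death and death from other
causes (both deaths absorbing). Per-cycle transition probabilities,
per-state utilities (measured with SF-36 and the Seattle Angina
Questionnaire) and per-state costs come from a packaged base-case table,
each with a low–high range treated as a 95% CI. Rates convert to
probabilities via `p = 1 − e^(−rt)`.

Discounted totals over the horizon (default 30 cycles = 15 years, 3%/year)
feed the usual decision statistics:

- ICER = ΔCost / ΔEffect, ACER = Cost / Effect, NMB = λ·QALY − Cost
- cost-effectiveness threshold λ = 3 × GDP per capita = $24,987/QALY
- a strategy is *dominant* when it is cheaper **and** more effective

Probabilistic sensitivity analysis redraws every ranged parameter per trial
(gamma for costs, beta for probabilities and utilities, moment-matched to
the range) and summarizes the CE plane, the acceptability curve (CEAC) and
the acceptance fraction at λ.

## Worked example

```python
from cardiocea import AnalysisSettings, Instrument, cea, compare_arms, default_parameters

params = default_parameters()
cabg, pci = compare_arms(params, Instrument.SAQ, AnalysisSettings())
result = cea.from_traces(cabg, pci, wtp=24987)
print(result.to_frame())
```

Running `python examples/base_case.py` prints:

```
--- SAQ utilities ---
CABG:  2.029 QALYs  $    38,620   ACER 19,030 $/QALY
PCI :  0.264 QALYs  $    65,006   ACER 246,665 $/QALY
incremental (CABG - PCI): +1.766 QALYs, $-26,386
ICER -14,942 $/QALY -> dominant
```

Surgery accrues more quality-adjusted life *and* costs less over the
15-year horizon, so the ICER is negative and CABG dominates — the same
verdict under the SF-36 utilities. The absolute QALY/cost levels depend on
the chosen horizon (see `docs/methods.md`); the dominance verdict does not.

Other examples: `examples/sensitivity_analysis.py` (tornado + PSA + CEAC),
`examples/synthetic_cohort.py` (cohort generation and cost-ledger round
trip), `examples/costing_and_sample_size.py` (wage formula, medication
present value, NMB sample size).

A thin CLI wraps the same calls:

```bash
cardiocea base --out out/            # base-case tables and traces
cardiocea psa --seed 1 --out out/    # PSA trials, CEAC, CE-plane plots
cardiocea synth --seed 1 --out out/  # synthetic cohort + round-trip report
cardiocea report --out out/          # everything, assembled into report.md
```

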
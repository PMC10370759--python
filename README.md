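# sahcea

Decision-analytic cost-effectiveness model of **repeat delayed CTA
imaging** for patients with spontaneous subarachnoid hemorrhage (SAH)
whose initial CTA + DSA was negative.

About 15–17% of these patients harbor an occult aneurysm that the
initial imaging missed, leaving them at risk of re-bleeding.  Some UK
centres therefore repeat a CT angiogram seven days after the initial
work-up.  This package implements, as tested Python, the
decision-tree + Markov cohort model used to ask whether that practice
is value for money from an NHS perspective: it compares *no repeat
delayed imaging* against *repeat delayed CTA* for a cohort of
55-year-olds over a lifetime horizon, in 2020 UK pounds, with costs and
QALYs discounted at 3.5% per year.

It is intended for health-economics researchers and students who want a
transparent, scriptable version of this kind of diagnostic-pathway
model: every parameter, transition rule and accounting convention is
explicit, configurable and unit-tested, and a vectorized
individual-level microsimulation provides an independent cross-check of
the cohort engine.

## Model

Each strategy's short-term decision tree resolves into an upfront cost
and an entry distribution over four health states:

* **at-risk** — occult aneurysm, no re-bleed yet (utility 0.60, no cost);
* **favorable** — mRS 0–2 (utility 0.87);
* **unfavorable** — mRS 3–5 (utility 0.44, £84,346/year nursing);
* **dead** — mRS 6 (absorbing, utility 0).

In the repeat-CTA arm everyone pays a 7-day hospital stay plus the CTA;
screen-positives get a confirmatory DSA (100% specific) and elective
repair, false negatives stay at risk.  The Markov engine then iterates
one-year cycles: at-risk patients re-bleed according to a
years-since-presentation schedule (triggering emergency repair and the
re-bleed outcome split), and every state combines its own annual death
probability with age-indexed background mortality as independent
hazards, `1 − (1 − p)(1 − qx)`.

Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE (£/QALY) and net monetary benefit NMB = λ·ΔE − ΔC at
willingness-to-pay λ.  Uncertainty is explored three ways: one-way
sweeps and tornado ordering, willingness-to-pay threshold search
(bisection on the NMB sign change), and probabilistic sensitivity
analysis (Beta/Gamma/Dirichlet draws, 5,000 Monte-Carlo iterations,
cost-effectiveness acceptability curves).

Two inputs of the original analysis were never published (the 10-year
re-bleed schedule and the background-mortality table); the package
ships clearly-labelled synthetic stand-ins (`sahcea.fixtures`) and
accepts user CSVs in their place — see `docs/methods.md`.

## Worked example

```python
import sahcea as s

p = s.default_parameters()          # published base-case values
tm = s.default_transition_fixture() # synthetic life table + re-bleed schedule

ref = s.evaluate_strategy("no_repeat", p, tm)
comp = s.evaluate_strategy("repeat_cta", p, tm)
cmp_ = s.incremental_analysis(ref, comp, wtp=20_000)
print(f"no repeat : £{ref.expected_cost:8,.2f}  {ref.expected_qaly:.3f} QALYs")
print(f"repeat CTA: £{comp.expected_cost:8,.2f}  {comp.expected_qaly:.3f} QALYs")
print(f"ICER £{cmp_.icer:,.0f}/QALY, NMB £{cmp_.nmb:,.0f} at £20,000/QALY")
```

prints

```
no repeat : £6,176.27  3.885 QALYs
repeat CTA: £8,548.05  4.167 QALYs
ICER £8,414/QALY, NMB £3,266 at £20,000/QALY
```

Repeat imaging costs £2,372 more per patient and yields 0.282 extra
QALYs, so each QALY gained costs about £8,400 — well under the NICE
£20,000–30,000 band, i.e. repeat delayed CTA is cost-effective under
the base-case inputs.  The same analyses are available from the shell:

```bash
sahcea base-case --json
sahcea dsa --all --out-dir dsa_out          # sweeps + tornado.csv
sahcea psa --n 5000 --seed 1 --out-dir psa_out
sahcea threshold --param cta_sensitivity --wtp 20000
sahcea fixtures write --out-dir fixtures    # emit the packaged inputs
```

Pass `--config my.yaml` to override any parameter (flat YAML keyed by
`ParameterSet` field names) and `--life-table/--rebleed-schedule/
--transitions` to replace the synthetic inputs with real tables.

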
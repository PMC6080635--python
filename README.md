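# sensewin

Sensitive-period analysis of childhood maltreatment exposure with
conditional-inference random forests.

## The problem

When a regional brain measure (for example, a gray-matter eigenvariate
extracted from a significant VBM cluster) is reduced in children exposed to
maltreatment, the scientific question is often not *whether* exposure matters
but *when* and *what kind*: is there a developmental age window during which
exposure is maximally associated with the outcome, and which maltreatment
type drives it?  With a cohort of a few dozen children, annual 0/1 exposure
indicators from birth onward, four maltreatment-type indicators, and strong
collinearity between early onset and long duration, ordinary regression is
hopeless.  This package implements the machinery used for such analyses:

- **Conditional inference trees** as base learners.  At each node the split
  variable is chosen by a permutation-test association statistic
  `T = Σᵢ xᵢ(yᵢ − ȳ)`, standardized by its exact permutation moments
  (`E[T] = 0`, `Var[T] = n/(n−1) · mean((y−ȳ)²) · Σ(x−x̄)²`) and referred
  to the standard normal.  This removes the selection bias toward predictors
  with many cutpoints that impurity-based trees suffer from.
- **A forest** of such trees (default 200 trees, `mtry = 4` candidate
  variables per node, 0.632 subsampling without replacement), aggregated as
  the unweighted mean, with out-of-bag (OOB) bookkeeping.
- **Permutation importance**: the increase in a tree's OOB mean squared
  error after permuting one predictor among its OOB cases, averaged over
  trees.  Permuting an important predictor degrades the fit; an unused
  predictor's importance is exactly zero.
- **Re-randomization tests**: to ask whether the *peak* importance (at any
  age) could have occurred by chance, the whole forest is refit `B` times
  (default 10,000) on response vectors reshuffled across subjects; the
  observed maximum is compared with the null distribution of the same
  maximum.  Marginal per-age p-values from the same null are
  Benjamini–Hochberg FDR-adjusted, and a combined-window test sums the
  importance of a contiguous block of ages against the null maximum over
  all same-length windows.
- **A synthetic cohort generator** reproducing the exposure structure of
  such cohorts (contiguous multi-year episodes, realistic type prevalences
  33.3% physical / 52.4% emotional / 9.5% sexual / 76.2% neglect, mean
  duration ≈ 7.7 years) with a response whose depressive effect is
  concentrated in a configurable age window — so every stage is testable
  end-to-end without any clinical data.

## Worked example

```python
from sensewin import SimConfig, simulate_cohort, run_timing_analysis, RunConfig

# 21 subjects, a 1.5-SD-per-year effect at ages 5-7
cohort = simulate_cohort(SimConfig(n_subjects=21, effect_size=1.5, seed=964939189))
report = run_timing_analysis(
    cohort, "gm_signal",
    RunConfig(n_rerand=500, window=(5, 6), seed=2062878228),
)
print(f"p_max = {report.rerand.p_max:.3f}")
print(f"combined window p = {report.rerand.combined['p']:.3f}")
print(f"OOB prediction r = {report.prediction_r:.3f}")
```

prints

```
p_max = 0.002
combined window p = 0.002
OOB prediction r = 0.669
```

i.e. the maximal age-bin importance exceeds everything seen in 500
response-reshuffled forests (`p = (1+0)/(500+1) ≈ 0.002`), the summed
importance of the injected 5–7-year window is likewise never matched under
the null, and the forest's out-of-bag predictions correlate 0.67 with the
actual scaled signal.  The same cohort analysed with the type design
(`run_type_analysis`) gives `p_max ≈ 0.49` — correctly unremarkable, since
this cohort's response carries no type effect.

The same analyses are available from a shell:

```bash
sensewin simulate --out cohort.csv --seed 42
sensewin timing --cohort cohort.csv --B 10000 --seed 1 --out report.json
sensewin types  --cohort cohort.csv --B 10000 --seed 1 --out types.json
```

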
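# vsmulti

Multiverse and distributional-regression-tree analysis of visual-search
experiments.

Feature-search studies in complex populations — here, school-aged children
with a vision impairment versus sighted controls searching for an ellipse
among circles at set sizes 4, 16 and 24 — produce reaction-time and
accuracy data in which many covariates (group, set size, target presence,
gender, age, nystagmus, acuity) may act on the *location, scale or shape*
of the response distribution, not just its mean. `vsmulti` implements a
four-step analysis for exactly this situation:

1. **Screen** candidate covariates with the Boruta shadow-feature algorithm
   and the One Rule baseline.
2. **Fit the full model** `DV ~ G × S × T + n + a + g` under three analytic
   universes — median quantile regression, Huber robust regression, and
   distributional (GAMLSS-type) regression in which every distribution
   parameter gets its own linear predictor — on a byte-identical design
   matrix.
3. **Reduce** to an explainable model (covariates confirmed by the screen
   or consistently significant across universes) and test it with the
   rank-based ANOVA-type statistic (ATS) for all-categorical designs, or
   median regression otherwise.
4. **Grow distributional regression trees**: every node fits a full
   parametric family by maximum likelihood — Ex-Gaussian
   `f(x; μ, σ, ν)` (Normal⋆Exponential, the standard right-skewed RT
   model) for reaction times, generalized beta type 1 for accuracy rates —
   and splits where the per-observation scores `∂ log f/∂θ` show
   significant parameter instability along a covariate (chi-square
   fluctuation statistics for factors, a supLM scan for numeric
   covariates, Bonferroni across covariates).

A synthetic-experiment generator reproduces the study's structure (two
cohorts, 8 practice + 72 test presentations, 8–15 presentations per
condition, Ex-Gaussian RT cells calibrated to reference node medians,
age-dependent accuracy), so the whole pipeline can be exercised and tested
without access to raw data.

## Worked example

Simulate a default experiment and run the full pipeline:

```sh
vsmulti simulate --seed 7 --out demo
vsmulti run demo/trials.csv --seed 7 --out demo/report
```

which prints

```
wrote demo/trials.csv (5760 rows)
report hash d9e3c3ee3285
RT retained: ['gender', 'group', 'set_size', 'target']
accuracy retained: ['age', 'set_size', 'target']
```

The retained sets are the explainable reduced models: reaction time depends
on group, set size, target and gender (nystagmus and age are screened out);
accuracy depends on set size, target and age (group does not impair
accuracy). The report directory contains every intermediate artifact. The
reaction-time tree (`tree_rt.dot`, summarised from `report.json`) is:

```
node 1: n = 3436, 1.94 [1.89, 1.99]   split: set_size (adj. p = 7.9e-241)
  node 2: n = 1150, 1.32 [1.28, 1.35]   split: group
    node 3: n = 527, 1.00 [0.97, 1.03]    split: target
      node 4: n = 263, 1.08 [1.04, 1.12]      (control, set 4, absent)
      node 5: n = 264, 0.90 [0.87, 0.94]      (control, set 4, present)
    node 6: n = 623, 1.56 [1.52, 1.61]        (impaired, set 4)
  node 7: n = 2286, 2.37 [2.32, 2.43]   split: target
    node 8: n = 1150, 3.03 [2.95, 3.11]   split: group
      node 9: n = 528, 2.52 [2.41, 2.61]      (control, 16/24, absent)
      node 10: n = 622, 3.67 [3.51, 3.80]  split: gender
        node 11: n = 255, 4.50 [4.21, 4.67]   (impaired female, absent)
        node 12: n = 367, 3.12 [3.00, 3.22]   (impaired male, absent)
    node 13: n = 1136, 1.87 [1.82, 1.91]  split: group
      node 14: n = 520, 1.50 [1.46, 1.53]  split: gender
        node 15: n = 187, 1.38 [1.30, 1.47]   (control female, present)
        node 16: n = 333, 1.53 [1.49, 1.59]   (control male, present)
      node 17: n = 616, 2.15 [2.09, 2.20]     (impaired, 16/24, present)
```

Each label is `n, median [approximate 95% CI]` in seconds. The hierarchy
reads directly: set size splits first ({4} versus {16, 24}); at the small
set size the groups differ (1.0 s vs 1.6 s) and only controls show a
target-present advantage; at large set sizes target absence is the dominant
cost, impaired females are slowest of all in absent search (4.5 s vs 3.1 s
for impaired males), while in present search it is control *males* who are
slower (1.53 s vs 1.38 s).

The ATS on the reduced factorial confirms the same structure, e.g.
`group F(1.00, 197) = 886.7, p < 1e-74`, `set_size F(1.97, 197) = 1002.8`,
`target F(1.00, 197) = 838.7`, with `gender × group` (F = 15.0, p = .00015)
and `set_size × target` (F = 175.8) interactions. Acuity correlates
positively with median search time (Kendall τ = 0.46, percentage bend
r = 0.82): worse vision, slower search.

## Library use

```python
from vsmulti import preprocessing, disttree
from vsmulti.distributions import EXGAUSSIAN
from vsmulti.synthetic_data import SimConfig, simulate_experiment

sim = simulate_experiment(SimConfig(), seed=7)
rt, conditions = preprocessing.preprocess(sim.trials)
cfg = disttree.TreeConfig(
    family=EXGAUSSIAN,
    covariates={"group": "nominal", "set_size": "ordinal",
                "target": "nominal", "gender": "nominal"})
tree = disttree.grow(rt.rename(columns={"rt_s": "rt"}), "rt", cfg)
print(disttree.to_dot(tree))
```

See `docs/methods.md` for the statistical details: family
parameterisations and links, the score-based instability tests and their
simulated asymptotic null, the retention rule, the ATS construction, and
what the generator does and does not emulate.

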
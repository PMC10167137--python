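# Methods

`vsmulti` analyses trial-level visual-search experiments — reaction times
(RT) and accuracy in a case-control design — with a four-step procedure
built around distributional regression, and ships a synthetic-experiment
generator with the same statistical structure so that every stage is
testable without raw study data.

## Data model and preprocessing

A raw experiment is a tidy table with one row per stimulus presentation
(participant, group `c`/`i`, gender, age, nystagmus flag, binocular acuity
in LogMAR, set size 4/16/24, target `ab`/`p`, reaction time in seconds,
correctness, presentation order 1..80). Preprocessing applies, in order:

1. the first eight presentations are practice and are dropped;
2. test trials with RT strictly greater than 10 s are removed (an RT of
   exactly 10 s is retained);
3. per participant × set size × target condition, only the first eight
   correct reaction times (in presentation order) are retained;
4. condition accuracy is `n_correct / n_presented`; a condition observation
   with accuracy ≤ 50% (chance) is excluded entirely.

The accuracy definition deserves a note: two conventions circulate for
this design — "8 divided by the number of presentations needed for the
eighth correct response", and the plain proportion of correct responses,
which is what the canonical worked example (10 correct of 12 presentations
= 83%) computes. We default to the proportion, which that example pins
down, and expose the other rule as
`accuracy_rule="eight_over_trials_to_eighth"`. Exclusion is applied per
condition observation, not per participant: a participant who fails one
condition still contributes their other conditions.

`visual_angle(extent_cm, distance_cm)` is the exact formula
`2·arctan(extent / 2·distance)` in degrees; at the 40-cm viewing distance
the 0.8-cm distractor circle subtends 1.15°, and the 0.7 × 1.0-cm target
ellipse 1.00° × 1.43°.

## Distribution families

* **Ex-Gaussian** `(mu, sigma, nu)` — Normal(mu, sigma) convolved with an
  Exponential of mean `nu`; mean `mu + nu`, variance `sigma² + nu²`. The
  log-density uses two stable branches: a scaled-erfcx form left of the
  exponential tail and a log-Φ form inside it, so it is finite for all
  arguments and all positive parameters. Scores (∂ log f/∂θ) are analytic.
* **Generalized beta type 1** `(mu, sigma, nu, tau)` on (0, 1), in the
  location/dispersion convention `a = mu(1−σ²)/σ²`, `b = (1−mu)(1−σ²)/σ²`;
  at `nu = tau = 1` it is exactly the Beta(a, b) with mean `mu`. Scores are
  analytic via digamma. Because the family has open support, accuracies are
  first squeezed by `v ↦ v(1−2ε)+ε` with ε = 0.005.
* **Normal** as the classical reference family.

`fit_mle` maximises the likelihood on the link scale (identity for
unbounded, log for positive, logit for unit-interval parameters) with
L-BFGS-B inside a wide box (|η| ≤ 18), method-of-moments starts, seeded
jittered restarts (deterministic by default), and a Nelder-Mead polish when
line searches fail. Convergence tolerance is 1e-12 on the relative
objective; a link-scale coordinate beyond ±15 raises a separate `boundary`
flag.

**A genuine degeneracy.** Per-condition accuracies are discretised (small
trial counts) and pile up at the squeezed maximum. Continuous ML then has a
ridge — GB1 can push `nu → ∞`, `mu → 0` to spike at the atom — so the
"optimum" sits on the link-scale box. We keep such boundary fits: they are
deterministic, their log-likelihoods are comparable across candidate
splits, and their score matrices still discriminate between covariate
groups. Inference on ridge directions is neutralised rather than faked (see
the distributional regression notes below). This is a property of ML on
discretised rates, not of the optimiser.

## Distributional regression trees

Each tree node fits one family to the node's response by ML
(intercept-only: covariates act through splits only, so a node is a plain
distribution, which is what the usual tree displays show). Splitting
follows the score-based parameter-instability (M-fluctuation) approach:

* **nominal/ordinal covariates** — decorrelate the per-observation scores
  with the inverse square root of their empirical covariance and compute a
  chi-square fluctuation statistic over level-wise score sums,
  df = (k−1)·p;
* **numeric covariates** — a supLM scan of the squared decorrelated
  cumulative-score process over ordered cutpoints inside a trimmed range
  (trim = 0.1). The asymptotic null — the supremum of a squared tied-down
  Bessel process over the trimmed interval — is simulated once per
  (p, trim) pair (20,000 paths on a 1,000-point grid, fixed internal seed,
  cached), so p-values are floored at 1/20,000.

P-values are Bonferroni-multiplied by the number of covariates showing
variation (the supLM already accounts for scanning cutpoints); the most
unstable covariate splits the node iff its adjusted p < `alpha`
(default 0.05). The split point maximises the sum of the two children's
maximised log-likelihoods: numeric covariates scan thresholds midway
between adjacent observed values (exhaustively up to 40 boundaries, an
evenly spaced subset beyond that), ordinal covariates (set size) try
contiguous-level bipartitions only, nominal covariates try all
2^(k−1)−1 bipartitions. Recursion stops at `min_node` (default 20, at
least 5× the parameter count), `max_depth` (default 5), or no significant
instability. Node ids are assigned depth-first in reporting order.

Node summaries report n, the median, and an approximate 95% CI of the
median from the binomial order-statistic ranks ⌊(n − 1.96√n)/2⌋ and
⌈(n + 1.96√n)/2⌉, clamped to the sample range (for n < 6 the sample range
is reported with a width warning). Trees serialise to nested JSON and to
Graphviz DOT with labels `n = xx, median [lo, hi]` and significance glyphs
(● p < .05, ♦ p < .001).

## Step 1 — variable importance

**Boruta.** Each iteration appends a permuted shadow copy of every
covariate, fits a random forest regressor (150 trees) on the augmented
table, and computes permutation importances — by construction the right
importance measure for a shadow comparison. A covariate scores a hit when
its importance exceeds the most important shadow; two-sided binomial tests
on hit counts (level 0.01, Bonferroni over the iteration budget, default 30)
confirm or reject; anything undecided stays tentative.

Two estimator choices matter and are deliberate:

* importances are evaluated on a held-out 25% split refit each iteration,
  not on the training rows — training-set permutation importance rewards
  memorisation and systematically inflates high-cardinality or weakly
  confounded covariates;
* the holdout is **group-wise** (whole participants held out) when repeated
  observations share a participant: a participant's exact age labels their
  six rows, and a row-wise split would let that leak.

**One Rule.** Numeric responses and covariates are discretised by
quartiles; each variable's single majority-class rule is scored by training
accuracy (always at least the majority-class baseline). The ranking is a
cheap cross-check of the Boruta ordering.

## Step 2 — the multiverse

The full model is `DV ~ G × S × T + n + a + g` (full factorial block in
group, set size, target; main effects of nystagmus, age, gender), built as
one treatment-coded design matrix with fixed reference levels (control, set
size 4, target absent, female, no nystagmus) and hash-checked so all
universes consume byte-identical inputs. Three lenses:

* **quantile** — median regression (statsmodels QuantReg, asymptotic
  kernel inference). Note: on atom-dominated accuracy data the conditional
  median is pinned to the atom and this universe is structurally
  uninformative — an honest property of median regression, reported as
  such, not patched.
* **robust** — Huber M-estimation, tuning constant 1.345 (statsmodels RLM).
* **distributional** — the regression form of GAMLSS: joint ML over linear
  predictors for `mu` and `sigma` (full design each) with intercepts for
  remaining shape parameters, through the links. Optimised in two stages
  (location first) with analytic score-based gradients; standard errors
  come from the observed information with an eigenvalue floor (condition
  cap 1e6), so directions flattened by the GB1 ridge get large,
  conservative variances instead of spuriously small or undefined ones.

## Step 3 — the reduced explainable model

A covariate is retained when it is **confirmed by Boruta**, OR when a
design column involving it is significant with a consistent sign in at
least 2 of the 3 universes. Two qualifications, prominently flagged because
the reduction rule is this package's operationalisation of "patterns found
across lenses":

* the vote's per-column threshold is `alpha / (n_vars · m_v)` (m_v = number
  of columns involving the variable): the three universes are strongly
  correlated, so "2 of 3" is barely stricter than one test, and without
  familywise control each variable would get many ~5% chances;
* a variable **actively rejected** by the screen is not resurrected by the
  vote — rejection is an all-relevant decision with accumulated evidence,
  and the two steps are intended to rectify each other.

The reduced model is then analysed by the rank-based **ANOVA-type
statistic** when every retained covariate is categorical and the crossed
design is feasible, else by median quantile regression on the reduced
design (falling back to main effects if the interaction block is aliased,
e.g. nystagmus nested in group).

## Rank and correlation statistics

The ANOVA-type statistic follows the standard between-subjects
construction: pooled midranks, per-cell relative effects, Kronecker-built
centering/averaging projections per effect, statistic
`N·p̂'Tp̂ / tr(TV̂)` with Box-approximated numerator df
`tr(TV̂)²/tr(TV̂TV̂)` and the usual finite denominator df (an `F(df1, ∞)`
variant is available). Kendall's tau is tau-b (tie-corrected; scipy).
The percentage bend correlation implements the standard recipe: bend
constant from the (1−β) quantile of absolute deviations from the median
(β = 0.2), clipped ψ-scores around the percentage-bend location, normalised
cross-product.

## The synthetic experiment generator

The generator emulates the study conditions: 39 vision-impaired children
(82% with nystagmus, acuity ~Normal(0.63, 0.31) LogMAR truncated to
[0.2, 1.5], age ~Normal(11.6, 3.1) years truncated to [5, 18], 56% male)
and 33 controls (acuity ≈ 0, age ~Normal(13.0, 2.9), 61% male); ages and
acuities reconstruct the cohort SDs from standard errors of the mean
(SD = SEM·√n). Each
participant gets 8 practice trials plus a 72-trial schedule drawn iid over
the six conditions and resampled until every condition count lies in
[8, 15] (mean 12).

Reaction times are Ex-Gaussian per group × set-band × target × gender cell.
Set sizes 16 and 24 share parameters — the band, not the individual large
set size, differentiates performance. Cell medians are calibration targets
(seconds): control set-4 0.91 present / 1.08 absent; impaired set-4 1.59;
control 16/24 absent 2.43; impaired 16/24 absent 4.37 (female) / 3.10
(male); impaired 16/24 present 2.15; control 16/24 present 1.51 (male) /
1.38 (female). For each cell, `sigma = 0.12·m` and `nu = 0.35·m` (RT spread
grows with slowness; the skew fraction is a conventional choice for
search-task RTs) and `mu` is solved numerically so the Ex-Gaussian median
equals the target exactly.

Per-trial correctness is Bernoulli from an accuracy map: 0.97 at set size
4; at set sizes 16/24, target-present 0.88 below age 14 and 0.98 at or
above 14, target-absent 0.98 for all ages. This places the age effect in
the target-present branch only and makes the absent-minus-present gap in
the (dominant) younger band about 0.10, the magnitude of the emulated
set-size × target accuracy interaction; the 14-year age boundary and the
0.88/0.98 band probabilities are the emulated study conditions.

Optional couplings (off by default, since the emulated analysis models
have none): a linear acuity → RT-location slope and a participant-level
random intercept. Even with the slope off, acuity correlates positively
with RT across participants because the impaired cohort is both slower and
has higher LogMAR.

**What the generator does not emulate:** within-participant
autocorrelation and fatigue/practice drift; RT–accuracy coupling at the
trial level (speed–accuracy trade-offs); diagnostic subgroups within the
impaired cohort; non-Ex-Gaussian RT shapes. Passing tests therefore show
that the pipeline recovers the planted structure under clean conditions,
not that it would behave identically on real data with those features.

## Known limitations, and two honest failure modes

End-to-end recovery of the reduced variable sets ({G, S, T, g} for RT and
{S, T, a} for accuracy) succeeds in roughly 85–90% of default simulations.
The residual failures are properties of the emulated design, not bugs:

* nystagmus is nested in group at 82% prevalence, so in some draws the
  handful of non-nystagmus impaired participants are atypical by chance and
  nystagmus becomes *genuinely* informative — an all-relevant screen is
  right to flag it in that sample;
* the age-accuracy signal lives in one band of one condition (~10
  percentage points on ~12-trial accuracies) and in occasional draws is too
  weak for either arm of the retention rule.

Problem sizes in the test suite and acceptance script (replication counts,
simulation grid sizes, numbers of seeds) are chosen as the smallest sizes
at which the Monte-Carlo error is comfortably below the tested margins.
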
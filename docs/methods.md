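# Methods

## Discrete time bins

Follow-up in months is discretised into half-open intervals
`I_j = [t_{j-1}, t_j)`, `j = 1..J`, with `t_0 = 0` and, at the default unit
(monthly) width, `t_J = floor(max duration) + 1`. "floor + 1" guarantees the
grid strictly covers the longest observed duration, so every subject maps to
exactly one bin and nothing is "beyond" the grid at training time. Bin width
is configurable, but every default and every reported result uses monthly
bins. Membership is half-open throughout: a duration of exactly 1.0 month
falls in bin 2, and the bin containing an event counts as post-event.

## Supervised targets

The supervised model regresses per-bin survival probabilities. For a subject
with an event in bin `e`, the target row is 1 before `e` and 0 from `e`
onward. For a subject censored in bin `c`, the row is 1 before `c` and, from
`c` onward, the cohort Kaplan–Meier curve conditioned on survival to the
censoring bin, `S_j / S_{c-1}`. Two open choices were resolved as follows:

- **Conditional vs marginal continuation.** The conditional form keeps every
  row non-increasing, continuous with its pre-censoring 1s, and bounded by
  1. The marginal form (`S_j` unconditioned) is available behind the
  `censored_continuation="marginal"` flag.
- **Decay start.** Censored rows begin decaying in the censoring bin itself
  (bin `c` gets `S_c / S_{c-1}`), consistent with the event convention that
  the bin containing the exit is no longer "fully survived".

With no censoring, the column mean of the target matrix telescopes exactly
to the Kaplan–Meier curve; this conservation identity is asserted in tests.

## Per-bin partial likelihood

The partial-likelihood model emits one score per subject per bin. Each event
in bin `j` contributes a softmax term of its own bin-`j` score against the
bin-`j` scores of the at-risk set `R_j` (everyone whose duration falls in
bin `j` or later). Events tied within a bin share the risk set, i.e. the
Breslow convention. Censored subjects never contribute an event term but
stay in risk sets through their censoring bin — that is precisely how the
loss uses all samples. The loss is computed with log-sum-exp stabilisation
and is finite for any finite scores; its gradient is the standard
softmax-minus-indicator form, verified against finite differences.

**Cox equivalence.** When the network is restricted to a linear score that
is constant across bins, the loss coincides term-for-term with the Breslow
Cox negative log partial likelihood on the *binned* event times. This is the
package's main correctness anchor: the loss is checked to 1e-8 against a
direct Breslow enumeration, and the L-BFGS minimiser of the linear model is
checked to 1e-3 against an independent Breslow Cox implementation
(scikit-survival) on the identical design matrix.

**Predicted duration for bin-constant fits.** A flat score profile carries
no timing information, so softmax-over-bins weighting would degenerate to
the same duration for every subject. Bin-constant fits therefore estimate
the Breslow baseline hazard `h0_j = d_j / sum_{k in R_j} exp(s_k)` at fit
time and predict durations from the implied discrete survival curve
`S_i(j) = exp(-H0_j e^{s_i})`, mirroring how a Cox model predicts expected
survival time.

## Architectures and training

No autodiff framework is used: the networks are small dense nets (at most
two hidden layers) with hand-written analytic backprop and full-batch Adam,
deterministic given the seed.

- **Supervised model:** no hidden layer, sigmoid head of width `J`, RMSE
  loss; defaults 1000 epochs, learning rate 1e-2, no weight decay (RMSE is
  already a mean over `n x J` cells, so even small decay would swamp its
  gradients).
- **Partial-likelihood MLP:** one hidden layer of 32 ReLU units, linear head
  of width `J`; defaults 500 epochs, learning rate 3e-3, weight decay 0.3
  on the summed NLLH. The decay matters: with ~30% event rates a free score
  per bin overfits quickly (train C-index 0.75+ against test 0.55 without
  it), and the chosen default roughly halves that generalisation gap on
  held-out splits of the clinical-scale synthetic cohort. Wider/deeper
  configurations are available through `ModelConfig` but were not better at
  these cohort sizes.
- **Linear bin-constant variant:** solved exactly with L-BFGS (the objective
  is convex); no decay, so the estimate is the pure partial-likelihood
  maximiser.

The NLLH requires full-batch training because risk sets span the whole
cohort; a batch size on that loss is rejected rather than silently
subsampling risk sets. A non-finite loss aborts with the epoch number.

## Preprocessing

Missing categorical values are filled with the sentinel level "10000", which
one-hot encoding then treats as an ordinary category — the same information
the sentinel carries as a raw numeral, without injecting a spurious numeric
magnitude. Missing continuous values take the training mean. Continuous
features are z-scored on training statistics (unscaled clinical covariates
such as white-cell counts in the thousands would otherwise dominate gradient
training); a zero-variance feature encodes as zeros with a warning. All
statistics are fitted on the training portion only and applied unchanged to
held-out or external data — asserted by a leakage test that plants an absurd
held-out value and checks the stored statistics do not move.

The Cox baseline uses the same encoder but drops each categorical group's
first level: the partial likelihood is shift-invariant, so a full one-hot
is exactly non-identifiable for a linear model (the networks, being
non-linear and regularised, keep the full encoding). Ties use lifelines'
Efron default, recorded in the results metadata.

## Evaluation

A subject's scalar predicted duration is the weighted average of bin
midpoints, weighted by per-bin event mass: successive differences of the
survival curve for probability outputs (any unspent mass goes to the last
bin), softmax over bins for unconstrained scores. Midpoints rather than
right edges minimise discretisation bias; the choice is exposed in code.

- **C-index:** Harrell's convention — a pair is comparable when the strictly
  earlier observed time belongs to an event subject; prediction ties count
  0.5; censored-censored pairs and pairs whose earlier time is censored are
  skipped. Computed on raw (unbinned) observed durations. Verified exactly
  against a brute-force O(n^2) enumeration.
- **3-year AUC:** subjects censored before 36 months are excluded (their
  label is unknowable); the risk score is `sigmoid(36 - predicted duration)`
  and the AUC is the usual rank statistic. Since the sigmoid is strictly
  monotone this equals the AUC of the negated duration — asserted as a test.
  The exclusion applies to the AUC/threshold/confusion pipeline only, never
  to the C-index.
- **Threshold:** the ROC point farthest from the chance diagonal, i.e. the
  Youden-maximal point (perpendicular distance is `(TPR-FPR)/sqrt(2)`); ties
  break toward the higher threshold.
- **Kaplan–Meier + log-rank** are delegated to lifelines.

## Cross-validation protocol

Five folds stratified on the censoring indicator (event and censored strata
are shuffled and split independently, remainders round-robin by fold), ten
iterations by default, iteration `i` seeded `base_seed + i` and every fold's
model fit seeded `base_seed + 1000*i + fold`. Imputation, encoding and the
bin grid are re-fitted inside every fold. Scores aggregate in two levels —
fold-mean per iteration, then mean ± SD across iterations — and both levels
are stored so either convention can be recomputed. Fold-level failures are
recorded as missing cells with the reason rather than raised.

## Feature selection

"Erasing" importance refits the model from scratch with one feature removed
at a time (all of its encoded columns vanish together); importance is the
drop in cross-validated C-index versus the all-features baseline, signs
preserved. The Cox log(p) selector ranks by ascending p-value from the
multivariable fit, taking a categorical feature's minimum over its columns.
Ranking ties break lexicographically by feature name. Top-k curves start at
k = 2 by default and end at the full feature count, where they reproduce the
all-features score exactly (same seeds); the comparison table sorts pairs by
the trapezoidal area under the curve and appends each column's SD.

## Synthetic cohorts

The generator emulates the profile of a resected-cancer cohort: ~1,000
subjects, ~28 mixed features, recurrence-free survival in months with ~70%
right censoring and a 60-month administrative horizon. Continuous covariates
are standard normal; categorical covariates are multinomial with
centred level-index effects; event times are exponential with rate
`lambda0 * exp(lp)` where the log-hazard `lp` may include quadratic,
interaction and threshold terms; censoring is an independent exponential
whose rate is bisected (deterministically, in log space) until the achieved
censored fraction is within ±0.05 of target, on top of the administrative
horizon; missingness is injected completely at random. The ground truth
(true linear predictor, uncensored event time) is returned alongside for
oracle tests. `make_paper_shaped_cohort` freezes one clinical-scale scenario
(n = 1022, 28 features, 73% censoring target, baseline hazard 0.012/month so
the median follow-up lands near 40 months, mild non-linearities, 3%
missingness).

What the generator does *not* emulate: correlated covariates, informative
censoring, non-exponential baseline shapes, missingness that depends on the
data, or the joint distribution of any real clinical cohort. Passing tests
therefore demonstrate correctness of the machinery and qualitative model
behaviour (e.g. the MLP's edge under a quadratic hazard), not clinical
performance levels.

## Problem sizes used in checks

Simulation-backed checks run at deliberately modest sizes chosen as the
smallest that give stable verdicts: coefficient recovery uses 20 replicates
of n = 500 with two covariates at 70% censoring; the non-linearity
comparison uses n = 400 with a quadratic hazard over 10 iterations of
5-fold CV; selector checks use 20 cohorts of n = 250 with one informative
and five noise features; the clinical-scale integration run uses the
n = 1022 cohort with one CV iteration.

## Known limitations

- No competing risks, time-varying covariates, left truncation, or
  IPCW-style time-dependent AUC (the simpler exclusion rule is used).
- The per-bin MLP needs event counts well above what a 300-subject, 70%-
  censored cohort provides; at that scale the linear variants dominate it.
- Mini-batch training is unsupported for the partial-likelihood loss.
- Serialisation covers the bin grid (JSON) and tabular outputs (CSV); full
  model-weight serialisation is limited to in-memory `get_params` /
  `set_params` round trips.
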
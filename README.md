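# binsurv — binned-time neural survival analysis

`binsurv` implements discrete-time survival modelling over a grid of monthly
time bins, for tabular clinical cohorts with heavy right censoring (think
recurrence-free survival after cancer surgery, where 70% of patients never
show the event during follow-up). It is aimed at biostatisticians and
ML-for-health researchers who want neural alternatives to the Cox
proportional-hazards model that use *every* subject — censored ones included
— without the PH assumption.

## The models

The follow-up axis is cut into half-open intervals
*I<sub>j</sub> = [t<sub>j−1</sub>, t<sub>j</sub>)*, *j = 1..J*, with
*t<sub>0</sub> = 0* and *t<sub>J</sub> = ⌊max duration⌋ + 1* (a cohort whose
longest follow-up is 36 months spans 37 unit bins). Two networks share this
grid:

- **Supervised binned-time model (`SupervisedBTS`)** — a single-layer
  perceptron with a sigmoid head of width *J*, trained by RMSE against
  per-subject target vectors *y<sub>1</sub>..y<sub>J</sub>*: 1 while the
  subject is known event-free, 0 from the event bin onward, and for censored
  subjects the cohort Kaplan–Meier curve *S<sub>j</sub>/S<sub>c−1</sub>*
  continued past the censoring bin *c*.
- **Partial-likelihood binned-time model (`PartialLikelihoodBTS`)** — an MLP
  emitting one unconstrained risk score *s<sub>ij</sub>* per subject per bin,
  trained by the per-bin negative log partial likelihood

  NLLH = −Σ<sub>j</sub> Σ<sub>i∈E<sub>j</sub></sub>
  log( e<sup>s<sub>ij</sub></sup> / Σ<sub>k∈R<sub>j</sub></sub> e<sup>s<sub>kj</sub></sup> ),

  where *R<sub>j</sub>* is the at-risk set and *E<sub>j</sub>* the events of
  bin *j* (ties share the risk set, Breslow-style). No target vector is
  needed; censored subjects inform the fit through risk-set membership.
  Restricted to a linear, bin-constant score this loss **is** the Breslow
  Cox partial likelihood on binned event times — the package's central
  correctness anchor, tested against an independent Breslow implementation.

A Cox PH baseline (lifelines), Harrell's C-index, a 3-year-recurrence ROC
AUC with censoring exclusion, Youden-optimal thresholding, Kaplan–Meier +
log-rank reporting, leave-one-feature-out ("erasing") selection with
area-under-the-curve pair comparison, repeated censoring-stratified
cross-validation, and a proportional-hazards cohort simulator round out the
toolkit.

## Worked example

```python
import binsurv as bs

scenario = bs.SimulationScenario(
    n_subjects=300, n_continuous=3, n_categorical=1,
    beta={"x1": 0.8}, censoring_rate_target=0.70, missing_rate=0.05, seed=42,
)
cohort, truth = bs.simulate(scenario)
print(cohort)

linear = bs.PartialLikelihoodBTS(
    cohort, config=bs.ModelConfig.linear_partial_likelihood()
).fit()
print("beta[x1] =", round(float(linear.beta_[0]), 3))

pred = linear.predicted_duration(cohort)
report = bs.evaluate_predictions(pred, cohort.durations, cohort.events)
print(f"C-index: {report.c_index:.3f}")
print(f"3-year AUC: {report.auc_3yr:.3f} "
      f"(excluded {report.n_excluded_for_auc} subjects censored early)")
print(f"log-rank p, high vs low predicted risk: {report.logrank_p:.2e}")
```

prints

```
SurvivalData(n=300, features=4, events=91, censored=69.7%)
beta[x1] = 0.553
C-index: 0.657
3-year AUC: 0.728 (excluded 189 subjects censored early)
log-rank p, high vs low predicted risk: 6.38e-08
```

The cohort has a single real prognostic covariate (`x1`, log hazard ratio
0.8); the fitted coefficient 0.553 is on the z-scored design scale
(≈ 0.56 per sample SD). The in-sample C-index 0.657 says the model orders
65.7% of comparable patient pairs correctly; the 3-year AUC scores
recurrence-within-36-months classification after dropping the 189 subjects
censored too early to label; the log-rank p-value confirms the
threshold-split risk groups have separated survival curves.

Cross-validated model comparison on the same cohort:

```python
models = {
    "su_linear": bs.ModelConfig.linear_partial_likelihood(),
    "su_mlp": bs.ModelConfig.partial_likelihood(),
    "s_bts": bs.ModelConfig.supervised(),
    "cox": bs.ModelConfig.cox(),
}
table = bs.run_cv(cohort, models, bs.CVSpec(n_folds=5, n_iterations=3, base_seed=0))
print(table.aggregate().to_string(index=False))
```

```
    model cohort  metric     mean       sd  n_iterations
      cox   test     auc 0.691969 0.015646             3
      cox   test c_index 0.633494 0.007043             3
    s_bts   test     auc 0.656926 0.009608             3
    s_bts   test c_index 0.619291 0.009461             3
su_linear   test     auc 0.692189 0.019713             3
su_linear   test c_index 0.634586 0.007438             3
   su_mlp   test     auc 0.500442 0.062182             3
   su_mlp   test c_index 0.527635 0.029745             3
```

On a small linear-hazard cohort the linear partial-likelihood model ties the
Cox baseline exactly as theory predicts, while the MLP variant needs more
events to shine — its advantage appears on non-linear hazards (see
`docs/methods.md`).

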
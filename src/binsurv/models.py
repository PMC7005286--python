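"""Binned-time neural survival models and the Cox baseline.

Two networks share the discrete interval grid:

* :class:`SupervisedBTS` -- a single-layer perceptron with a sigmoid head of
  width J, trained by RMSE against the Kaplan-Meier-derived
  :class:`~binsurv.targets.TargetMatrix`.  Its outputs are per-bin survival
  probabilities.
* :class:`PartialLikelihoodBTS` -- an MLP emitting one unconstrained risk
  score per subject per bin, trained by a per-bin negative log partial
  likelihood: each event in bin j contributes a softmax term of its bin-j
  score against the scores of everyone still at risk in bin j (events tied
  within a bin share the risk set, Breslow-style).  Censored subjects never
  contribute an event term but stay in the risk sets through their censoring
  bin, which is how the model uses every sample.  When the network is
  restricted to a linear, bin-constant score this loss *is* the Breslow Cox
  negative log partial likelihood on the binned event times -- the central
  correctness anchor of the package.

The classical Cox proportional-hazards model (via lifelines) serves as the
linear baseline and supplies per-feature p-values for the log(p) selector.

Models follow a statsmodels-like shape: construct from a
:class:`~binsurv.data.SurvivalData`, call :meth:`fit` to obtain a Results
object carrying the learned weights, preprocessing state, training history
and prediction methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from ._nn import DenseNet, TrainingError, train_adam
from .binning import TimeBinning
from .data import FeatureEncoder, Imputer, SurvivalData
from .targets import TargetMatrix, build_targets

__all__ = [
    "ModelConfig",
    "AtRiskStructure",
    "RiskOutput",
    "build_at_risk",
    "nllh_loss",
    "rmse_loss",
    "SupervisedBTS",
    "PartialLikelihoodBTS",
    "CoxPHBaseline",
    "fit_cox_baseline",
    "make_model",
    "TrainingError",
]


# ---------------------------------------------------------------------------
# Config


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters for one model.

    ``kind`` selects the model class; the supervised model pairs a
    single-layer architecture with the RMSE loss, the partial-likelihood
    model pairs an MLP (or linear) architecture with the NLLH loss.
    """

    kind: str = "partial_likelihood"  # supervised | partial_likelihood | cox
    architecture: str = "mlp"  # single_layer | mlp | linear
    hidden_sizes: tuple = (32,)
    loss: str = "nllh"  # rmse | nllh
    epochs: int = 500
    learning_rate: float = 3e-3
    batch_size: int | None = None
    l2_penalty: float = 0.3  # weight decay against per-bin overfitting at ~30% event rates
    bin_constant: bool = False
    solver: str = "adam"  # adam | lbfgs (lbfgs: linear bin-constant only)
    seed: int = 0

    def __post_init__(self):
        if self.kind == "supervised" and (self.architecture, self.loss) != ("single_layer", "rmse"):
            raise ValueError("the supervised model pairs single_layer with rmse")
        if self.kind == "partial_likelihood" and self.loss != "nllh":
            raise ValueError("the partial-likelihood model uses the nllh loss")
        if self.solver == "lbfgs" and not (self.architecture == "linear" and self.bin_constant):
            raise ValueError("lbfgs applies only to the linear bin-constant model")

    @classmethod
    def supervised(cls, **kw) -> "ModelConfig":
        kw.setdefault("epochs", 1000)
        kw.setdefault("learning_rate", 1e-2)
        kw.setdefault("l2_penalty", 0.0)  # RMSE is already a mean; decay would swamp it
        return cls(kind="supervised", architecture="single_layer", hidden_sizes=(),
                   loss="rmse", **kw)

    @classmethod
    def partial_likelihood(cls, **kw) -> "ModelConfig":
        return cls(kind="partial_likelihood", loss="nllh", **kw)

    @classmethod
    def linear_partial_likelihood(cls, **kw) -> "ModelConfig":
        """Linear bin-constant NLLH model; equivalent to Breslow Cox on binned times."""
        kw.setdefault("solver", "lbfgs")
        kw.setdefault("l2_penalty", 0.0)  # exact partial-likelihood fit, no decay
        return cls(kind="partial_likelihood", architecture="linear", hidden_sizes=(),
                   loss="nllh", bin_constant=True, **kw)

    @classmethod
    def cox(cls, **kw) -> "ModelConfig":
        return cls(kind="cox", architecture="linear", hidden_sizes=(), loss="nllh", **kw)


# ---------------------------------------------------------------------------
# At-risk structure and losses


@dataclass(frozen=True)
class AtRiskStructure:
    """Per-bin risk sets R_j and event sets E_j (0-based subject indices)."""

    risk_sets: tuple  # of np.ndarray, length J
    event_sets: tuple  # of np.ndarray, length J

    @property
    def n_bins(self) -> int:
        return len(self.risk_sets)

    @property
    def n_events(self) -> int:
        return int(sum(len(e) for e in self.event_sets))


def build_at_risk(ds: SurvivalData, binning: TimeBinning) -> AtRiskStructure:
    """R_j = subjects whose duration falls in bin j or later; E_j = events in j."""
    bins = binning.bin_indices(ds.durations)
    risk, events = [], []
    for j in range(1, binning.n_bins + 1):
        risk.append(np.flatnonzero(bins >= j))
        events.append(np.flatnonzero((bins == j) & ds.events))
    return AtRiskStructure(tuple(risk), tuple(events))


def _nllh_and_grad(scores: np.ndarray, risk: AtRiskStructure):
    """Total NLLH and its gradient w.r.t. the score matrix (log-sum-exp stable)."""
    scores = np.asarray(scores, dtype=float)
    grad = np.zeros_like(scores)
    total = 0.0
    for j, (r_set, e_set) in enumerate(zip(risk.risk_sets, risk.event_sets)):
        if e_set.size == 0:
            continue
        col = scores[r_set, j]
        lse = logsumexp(col)
        total += e_set.size * lse - scores[e_set, j].sum()
        grad[r_set, j] += e_set.size * softmax(col)
        grad[e_set, j] -= 1.0
    return total, grad


def nllh_loss(bin_scores: np.ndarray, risk: AtRiskStructure) -> float:
    """Negative log partial likelihood of per-bin scores (Breslow-style ties)."""
    if risk.n_events == 0:
        raise ValueError("nllh is undefined with no events in any bin")
    bin_scores = np.asarray(bin_scores, dtype=float)
    if bin_scores.ndim != 2 or bin_scores.shape[1] != risk.n_bins:
        raise ValueError("bin_scores must be n_subjects x n_bins for this risk structure")
    return float(_nllh_and_grad(bin_scores, risk)[0])


def rmse_loss(predicted: np.ndarray, targets) -> float:
    """Root mean squared error over all subject-bin cells."""
    target_values = targets.values if isinstance(targets, TargetMatrix) else np.asarray(targets)
    predicted = np.asarray(predicted, dtype=float)
    if predicted.shape != target_values.shape:
        raise ValueError(
            f"shape mismatch: predictions {predicted.shape} vs targets {target_values.shape}"
        )
    return float(np.sqrt(np.mean((predicted - target_values) ** 2)))


def _rmse_and_grad(predicted: np.ndarray, target_values: np.ndarray):
    diff = predicted - target_values
    value = np.sqrt(np.mean(diff**2))
    if value == 0.0:
        return 0.0, np.zeros_like(diff)
    return float(value), diff / (diff.size * value)


def _linear_nllh_and_grad(beta: np.ndarray, x: np.ndarray, risk: AtRiskStructure):
    """NLLH of a bin-constant linear score Xb, with gradient in beta."""
    lp = x @ beta
    grad = np.zeros_like(beta)
    total = 0.0
    for r_set, e_set in zip(risk.risk_sets, risk.event_sets):
        if e_set.size == 0:
            continue
        col = lp[r_set]
        total += e_set.size * logsumexp(col) - lp[e_set].sum()
        weights = softmax(col)
        grad += e_set.size * (weights @ x[r_set]) - x[e_set].sum(axis=0)
    return total, grad


# ---------------------------------------------------------------------------
# Shared fitting scaffolding


@dataclass
class RiskOutput:
    """Per-subject per-bin model scores.

    ``kind`` is "survival" for probability outputs (supervised model) and
    "risk" for unconstrained scores (partial-likelihood model).
    ``predicted_duration`` is filled by the evaluation layer's
    hazard-weighted average.
    """

    bin_scores: np.ndarray
    kind: str
    binning: TimeBinning
    predicted_duration: np.ndarray | None = None


class _PreprocessingState:
    """Imputer + encoder fitted on the training cohort."""

    def __init__(self, train: SurvivalData):
        self.schema = train.schema
        self.imputer = Imputer().fit(train)
        self.encoder = FeatureEncoder().fit(self.imputer.transform(train))

    def design(self, ds: SurvivalData) -> np.ndarray:
        if ds.schema.names != self.schema.names:
            raise ValueError("dataset schema does not match the fitted model's schema")
        return self.encoder.transform(self.imputer.transform(ds)).to_numpy()


class _BTSModelBase:
    """Common constructor: raw data in, preprocessing fitted on it."""

    def __init__(self, data: SurvivalData, binning: TimeBinning | None = None,
                 config: ModelConfig | None = None, **overrides):
        if data.n_events == 0:
            raise ValueError("model fitting requires at least one event-positive record")
        self.data = data
        base = config or self._default_config()
        self.config = replace(base, **overrides) if overrides else base
        self.binning = binning or TimeBinning.from_durations(data.durations)
        self.prep = _PreprocessingState(data)
        self.design_ = self.prep.design(data)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, schema, duration_col="duration",
                       event_col="event", **kw):
        from .data import FeatureSchema

        schema = schema if hasattr(schema, "names") else FeatureSchema.from_pairs(schema)
        ds = SurvivalData(frame, frame[duration_col].to_numpy(float),
                          frame[event_col].to_numpy(bool), schema)
        return cls(ds, **kw)


class BTSResults:
    """Fitted binned-time network: weights, history, preprocessing, binning."""

    def __init__(self, model: _BTSModelBase, net: DenseNet, history: list,
                 output_kind: str):
        self.model = model
        self.net = net
        self.history = history
        self.output_kind = output_kind
        self.config = model.config
        self.binning = model.binning
        #: Breslow baseline cumulative hazard per bin; set for bin-constant
        #: fits, where the flat score profile carries no timing information
        #: of its own and durations come from the implied survival curve.
        self.baseline_cumhaz_ = None

    @property
    def final_loss(self) -> float:
        return self.history[-1] if self.history else float("nan")

    def predict_bins(self, ds: SurvivalData | None = None) -> RiskOutput:
        """Score a cohort: one value per subject per training bin."""
        ds = ds if ds is not None else self.model.data
        x = self.model.prep.design(ds)
        if len(ds) == 0:
            scores = np.zeros((0, self.binning.n_bins))
        else:
            raw = self.net.predict(x)
            scores = np.repeat(raw, self.binning.n_bins, axis=1) \
                if self.config.bin_constant else raw
        return RiskOutput(scores, self.output_kind, self.binning)

    def predicted_duration(self, ds: SurvivalData | None = None) -> np.ndarray:
        from .metrics import predicted_duration

        out = self.predict_bins(ds)
        if self.config.bin_constant and self.baseline_cumhaz_ is not None \
                and out.bin_scores.shape[0] > 0:
            # discrete proportional hazards: S_i(j) = exp(-H0_j * exp(s_i))
            s = np.clip(out.bin_scores[:, 0], -50.0, 50.0)
            survival = np.exp(-np.outer(np.exp(s), self.baseline_cumhaz_))
            out = RiskOutput(survival, "survival", self.binning)
        return predicted_duration(out)

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(w.size for w in self.net.weights) + sum(b.size for b in self.net.biases)
        lines = [
            f"{type(self.model).__name__} results",
            "=" * 40,
            f"n subjects            {len(self.model.data)}",
            f"n events              {self.model.data.n_events}",
            f"n features            {len(self.model.data.schema.names)}",
            f"design columns        {self.model.design_.shape[1]}",
            f"time bins (J)         {self.binning.n_bins}",
            f"architecture          {cfg.architecture} {cfg.hidden_sizes or ''}".rstrip(),
            f"loss                  {cfg.loss}",
            f"solver                {cfg.solver}",
            f"epochs                {len(self.history)}",
            f"n parameters          {n_params}",
            f"final training loss   {self.final_loss:.6f}",
            f"seed                  {cfg.seed}",
        ]
        return "\n".join(lines)


class SupervisedBTS(_BTSModelBase):
    """Single-layer sigmoid network trained on KM-derived survival targets."""

    @staticmethod
    def _default_config() -> ModelConfig:
        return ModelConfig.supervised(learning_rate=1e-2)

    def fit(self, seed: int | None = None) -> BTSResults:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        targets = build_targets(self.data, self.binning)
        net = DenseNet(self.design_.shape[1], cfg.hidden_sizes, self.binning.n_bins,
                       sigmoid_head=True, seed=cfg.seed)
        target_values = targets.values

        def loss_grad(out, index):
            return _rmse_and_grad(out, target_values[index])

        history = train_adam(net, self.design_, loss_grad, epochs=cfg.epochs,
                             learning_rate=cfg.learning_rate, l2_penalty=cfg.l2_penalty,
                             batch_size=cfg.batch_size, seed=cfg.seed)
        result = BTSResults(self, net, history, output_kind="survival")
        result.targets_ = targets
        return result


class PartialLikelihoodBTS(_BTSModelBase):
    """MLP trained by the per-bin negative log partial likelihood.

    With ``architecture="linear"`` and ``bin_constant=True`` the model is a
    discrete-time Cox model with Breslow ties, and can be solved exactly with
    L-BFGS (``solver="lbfgs"``); the fitted coefficients are then exposed as
    ``results.beta_``.
    """

    @staticmethod
    def _default_config() -> ModelConfig:
        return ModelConfig.partial_likelihood()

    def fit(self, seed: int | None = None) -> BTSResults:
        cfg = self.config if seed is None else replace(self.config, seed=seed)
        if cfg.batch_size is not None:
            raise ValueError("the partial-likelihood loss requires full-batch training "
                             "(risk sets span the whole cohort)")
        risk = build_at_risk(self.data, self.binning)
        if risk.n_events == 0:
            raise ValueError("nllh is undefined with no events")
        n_out = 1 if cfg.bin_constant else self.binning.n_bins

        if cfg.solver == "lbfgs":
            return self._fit_lbfgs(cfg, risk)

        def loss_grad(out, index):
            scores = np.repeat(out, self.binning.n_bins, axis=1) if cfg.bin_constant else out
            value, grad = _nllh_and_grad(scores, risk)
            if cfg.bin_constant:
                grad = grad.sum(axis=1, keepdims=True)
            return value, grad

        net = DenseNet(self.design_.shape[1], cfg.hidden_sizes, n_out,
                       sigmoid_head=False, seed=cfg.seed)
        history = train_adam(net, self.design_, loss_grad, epochs=cfg.epochs,
                             learning_rate=cfg.learning_rate, l2_penalty=cfg.l2_penalty,
                             batch_size=None, seed=cfg.seed)
        result = BTSResults(self, net, history, output_kind="risk")
        if cfg.bin_constant:
            result.baseline_cumhaz_ = self._breslow_cumhaz(net.predict(self.design_)[:, 0], risk)
        return result

    def _fit_lbfgs(self, cfg: ModelConfig, risk: AtRiskStructure) -> BTSResults:
        x = self.design_
        beta0 = np.zeros(x.shape[1])
        opt = minimize(_linear_nllh_and_grad, beta0, args=(x, risk), jac=True,
                       method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-12,
                                                   "gtol": 1e-9})
        net = DenseNet(x.shape[1], (), 1, sigmoid_head=False, seed=cfg.seed)
        net.set_params([opt.x[:, None]], [np.zeros(1)])
        result = BTSResults(self, net, [float(opt.fun)], output_kind="risk")
        result.beta_ = opt.x.copy()
        result.converged_ = bool(opt.success)
        result.baseline_cumhaz_ = self._breslow_cumhaz(x @ opt.x, risk)
        return result

    @staticmethod
    def _breslow_cumhaz(scores: np.ndarray, risk: AtRiskStructure) -> np.ndarray:
        """Breslow estimate of the per-bin baseline hazard, accumulated."""
        scores = np.clip(scores, -50.0, 50.0)
        hazard = np.zeros(risk.n_bins)
        for j, (r_set, e_set) in enumerate(zip(risk.risk_sets, risk.event_sets)):
            if e_set.size and r_set.size:
                hazard[j] = e_set.size / np.exp(scores[r_set]).sum()
        return np.cumsum(hazard)


# ---------------------------------------------------------------------------
# Cox proportional-hazards baseline (lifelines adapter)


class CoxPHBaseline:
    """Linear hazard baseline on the encoded design matrix.

    One-hot groups drop their first level (the partial likelihood is
    shift-invariant, so a full one-hot would be non-identifiable).  The
    partial-likelihood fit is delegated to lifelines (Efron ties, recorded
    in the results metadata).
    """

    def __init__(self, data: SurvivalData, penalizer: float = 0.0):
        if data.n_events == 0:
            raise ValueError("Cox fitting requires at least one event")
        self.data = data
        self.penalizer = penalizer
        self.prep = _PreprocessingState(data)

    def _design_frame(self, ds: SurvivalData) -> pd.DataFrame:
        frame = self.prep.encoder.transform(self.prep.imputer.transform(ds))
        drop = []
        for name in ds.schema.categorical:
            cols = self.prep.encoder.feature_columns(name)
            if len(cols) > 1:
                drop.append(cols[0])  # reference level
        frame = frame.drop(columns=drop)
        # constant columns carry no partial-likelihood information
        keep = [c for c in frame.columns if frame[c].nunique() > 1]
        self._kept_columns = keep
        return frame

    def fit(self) -> "CoxResults":
        import lifelines
        from lifelines.exceptions import ConvergenceError

        frame = self._design_frame(self.data)
        frame = frame.loc[:, self._kept_columns]
        frame = frame.assign(_duration=self.data.durations,
                             _event=self.data.events.astype(int))
        fitter = lifelines.CoxPHFitter(penalizer=self.penalizer)
        try:
            fitter.fit(frame, duration_col="_duration", event_col="_event")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox partial-likelihood fit did not converge: {exc}") from exc
        return CoxResults(self, fitter)


class CoxResults:
    """Fitted Cox baseline: coefficients, p-values, linear predictor."""

    ties_method = "efron"  # lifelines default

    def __init__(self, model: CoxPHBaseline, fitter):
        self.model = model
        self.fitter = fitter
        self.params = fitter.params_.copy()
        self.p_values = fitter.summary["p"].copy()
        self.standard_errors = fitter.summary["se(coef)"].copy()

    def feature_p_values(self) -> pd.Series:
        """Per schema feature: minimum p-value over its design columns."""
        enc = self.model.prep.encoder
        out = {}
        for name in self.model.data.schema.names:
            cols = [c for c in enc.feature_columns(name) if c in self.p_values.index]
            out[name] = float(self.p_values[cols].min()) if cols else float("nan")
        return pd.Series(out)

    def linear_predictor(self, ds: SurvivalData | None = None) -> np.ndarray:
        ds = ds if ds is not None else self.model.data
        frame = self.model.prep.encoder.transform(self.model.prep.imputer.transform(ds))
        frame = frame.loc[:, self.params.index]
        return frame.to_numpy() @ self.params.to_numpy()

    def predicted_duration(self, ds: SurvivalData | None = None) -> np.ndarray:
        """Expected survival time under the fitted model (months)."""
        ds = ds if ds is not None else self.model.data
        frame = self.model.prep.encoder.transform(self.model.prep.imputer.transform(ds))
        frame = frame.loc[:, self.params.index]
        return self.fitter.predict_expectation(frame).to_numpy()

    def summary(self) -> str:
        return self.fitter.summary.to_string()


def fit_cox_baseline(ds: SurvivalData, penalizer: float = 0.0) -> CoxResults:
    """Convenience: construct and fit the Cox baseline in one call."""
    return CoxPHBaseline(ds, penalizer=penalizer).fit()


# ---------------------------------------------------------------------------
# Factory used by the cross-validation harness and selectors


def make_model(config: ModelConfig, data: SurvivalData, binning: TimeBinning | None = None):
    """Instantiate the model class named by ``config.kind`` on a cohort."""
    if config.kind == "supervised":
        return SupervisedBTS(data, binning=binning, config=config)
    if config.kind == "partial_likelihood":
        return PartialLikelihoodBTS(data, binning=binning, config=config)
    if config.kind == "cox":
        return CoxPHBaseline(data)
    raise ValueError(f"unknown model kind {config.kind!r}")
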
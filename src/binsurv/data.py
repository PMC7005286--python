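"""Survival dataset container, validation, imputation, encoding and splitting.

The central object is :class:`SurvivalData`: a covariate table (mixed
continuous/categorical, missing values allowed) together with a follow-up
duration in months and a binary event indicator per subject.  Preprocessing
(sentinel/mean imputation, one-hot + z-score encoding) is always *fitted on
training data* and applied unchanged to held-out data, so the transformer
objects here carry state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Sentinel level injected for missing categorical values.  Kept as the
#: literal numeral string so it round-trips through CSV unchanged.
CATEGORICAL_SENTINEL = "10000"


class SchemaError(ValueError):
    """A required column is absent or a feature kind is unknown."""


class ValidationError(ValueError):
    """A row violates a dataset invariant (e.g. negative duration)."""


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with their kinds."""

    fields: tuple  # of (name, kind)

    def __post_init__(self):
        for name, kind in self.fields:
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise SchemaError(f"unknown feature kind {kind!r} for {name!r}")
        if len({n for n, _ in self.fields}) != len(self.fields):
            raise SchemaError("duplicate feature names in schema")

    @classmethod
    def from_pairs(cls, pairs) -> "FeatureSchema":
        return cls(tuple((str(n), str(k)) for n, k in pairs))

    @property
    def names(self):
        return [n for n, _ in self.fields]

    def kind(self, name: str) -> str:
        for n, k in self.fields:
            if n == name:
                return k
        raise SchemaError(f"feature {name!r} not in schema")

    @property
    def continuous(self):
        return [n for n, k in self.fields if k == CONTINUOUS]

    @property
    def categorical(self):
        return [n for n, k in self.fields if k == CATEGORICAL]

    def drop(self, names) -> "FeatureSchema":
        names = set(names)
        return FeatureSchema(tuple(f for f in self.fields if f[0] not in names))


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: covariates, follow-up duration (months), event flag."""

    covariates: dict
    duration: float
    event: bool

    def __post_init__(self):
        if not np.isfinite(self.duration) or self.duration < 0:
            raise ValidationError(f"duration must be a non-negative real, got {self.duration}")
        if not isinstance(self.event, (bool, np.bool_)):
            raise ValidationError("event must be boolean (no missing outcomes)")


class SurvivalData:
    """A cohort of survival records sharing one feature schema.

    Parameters
    ----------
    covariates : pandas.DataFrame
        One column per schema feature, one row per subject.  Missing values
        are ``NaN``; categorical columns hold level labels as strings.
    durations : array-like of float
        Follow-up in months, non-negative.
    events : array-like of bool
        True where the event (recurrence) was observed, False if censored.
    schema : FeatureSchema
    """

    def __init__(self, covariates: pd.DataFrame, durations, events, schema: FeatureSchema):
        durations = np.asarray(durations, dtype=float)
        events = np.asarray(events, dtype=bool)
        if not set(schema.names) <= set(covariates.columns):
            missing = set(schema.names) - set(covariates.columns)
            raise SchemaError(f"covariate table lacks schema features: {sorted(missing)}")
        covariates = covariates.loc[:, schema.names].reset_index(drop=True)
        if len(covariates) != durations.size or durations.size != events.size:
            raise ValidationError("covariates, durations and events must have equal length")
        bad = np.flatnonzero(~np.isfinite(durations) | (durations < 0))
        if bad.size:
            raise ValidationError(f"row {bad[0]}: duration must be a non-negative real")
        self.covariates = covariates
        self.durations = durations
        self.events = events
        self.schema = schema

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.covariates)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @property
    def censored_fraction(self) -> float:
        return 1.0 - self.events.mean() if len(self) else float("nan")

    @property
    def records(self):
        """Materialise per-subject :class:`SurvivalRecord` views."""
        rows = self.covariates.to_dict("records")
        return [
            SurvivalRecord(row, float(d), bool(e))
            for row, d, e in zip(rows, self.durations, self.events)
        ]

    def subset(self, index) -> "SurvivalData":
        index = np.asarray(index)
        return SurvivalData(
            self.covariates.iloc[index], self.durations[index], self.events[index], self.schema
        )

    def drop_features(self, names) -> "SurvivalData":
        names = [names] if isinstance(names, str) else list(names)
        return SurvivalData(
            self.covariates.drop(columns=names), self.durations, self.events, self.schema.drop(names)
        )

    def select_features(self, names) -> "SurvivalData":
        keep = set(names)
        return self.drop_features([n for n in self.schema.names if n not in keep])

    def to_csv(self, path, duration_col: str = "duration", event_col: str = "event") -> None:
        frame = self.covariates.copy()
        frame[duration_col] = self.durations
        frame[event_col] = self.events.astype(int)
        frame.to_csv(path, index=False)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SurvivalData(n={len(self)}, features={len(self.schema.names)}, "
            f"events={self.n_events}, censored={self.censored_fraction:.1%})"
        )


def load_dataset(path, schema: FeatureSchema, duration_col: str = "duration",
                 event_col: str = "event") -> SurvivalData:
    """Read a delimited-text cohort into a :class:`SurvivalData`.

    Unparseable continuous cells become missing; rows with a missing or
    invalid duration/event are rejected with an error naming the row.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=True)
    for col in (duration_col, event_col):
        if col not in frame.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    for name in schema.names:
        if name not in frame.columns:
            raise SchemaError(f"schema feature {name!r} not found in {path}")

    durations = pd.to_numeric(frame[duration_col], errors="coerce")
    events_raw = pd.to_numeric(frame[event_col], errors="coerce")
    for idx in range(len(frame)):
        if pd.isna(durations.iloc[idx]) or pd.isna(events_raw.iloc[idx]):
            raise ValidationError(f"row {idx}: missing or unparseable duration/event")
        if durations.iloc[idx] < 0:
            raise ValidationError(f"row {idx}: duration must be a non-negative real")
        if events_raw.iloc[idx] not in (0, 1):
            raise ValidationError(f"row {idx}: event indicator must be 0 or 1")

    cov = pd.DataFrame(index=frame.index)
    for name in schema.continuous:
        cov[name] = pd.to_numeric(frame[name], errors="coerce")
    for name in schema.categorical:
        col = frame[name].astype("string")
        cov[name] = col.where(~col.isna(), np.nan).astype(object)
    return SurvivalData(cov, durations.to_numpy(float), events_raw.to_numpy(float).astype(bool), schema)


# ---------------------------------------------------------------------------
# Imputation


@dataclass(frozen=True)
class ImputationPolicy:
    """How missing covariates are filled.

    Continuous gaps take the mean of the *training* values; categorical gaps
    take a fixed sentinel level (default the literal "10000"), which the
    encoder later treats as an ordinary category.
    """

    categorical_sentinel: str = CATEGORICAL_SENTINEL
    continuous_strategy: str = "mean"

    def __post_init__(self):
        if self.continuous_strategy != "mean":
            raise ValueError("only mean imputation of continuous features is supported")


class ImputationError(ValueError):
    """Imputation statistics could not be computed from the training data."""


class Imputer:
    """Stateful imputer: fit on training data, apply anywhere."""

    def __init__(self, policy: ImputationPolicy | None = None):
        self.policy = policy or ImputationPolicy()
        self.continuous_means_: dict | None = None

    def fit(self, train: SurvivalData) -> "Imputer":
        means = {}
        for name in train.schema.continuous:
            observed = train.covariates[name].dropna()
            if observed.empty:
                raise ImputationError(
                    f"continuous feature {name!r} has no observed training values"
                )
            means[name] = float(observed.mean())
        self.continuous_means_ = means
        return self

    def transform(self, ds: SurvivalData) -> SurvivalData:
        if self.continuous_means_ is None:
            raise RuntimeError("Imputer must be fitted before transform")
        cov = ds.covariates.copy()
        for name in ds.schema.continuous:
            cov[name] = cov[name].fillna(self.continuous_means_[name])
        for name in ds.schema.categorical:
            col = cov[name]
            cov[name] = col.where(col.notna(), self.policy.categorical_sentinel)
        return SurvivalData(cov, ds.durations, ds.events, ds.schema)


def impute(train: SurvivalData, apply_to: SurvivalData | None = None,
           policy: ImputationPolicy | None = None) -> SurvivalData:
    """Fill missing values of ``apply_to`` (default: the training set itself)
    using statistics computed from ``train`` only."""
    imp = Imputer(policy).fit(train)
    return imp.transform(train if apply_to is None else apply_to)


# ---------------------------------------------------------------------------
# Encoding


class FeatureEncoder:
    """Design-matrix encoder with training-set statistics.

    Continuous features are z-standardised with the training mean and
    population standard deviation; categorical features are one-hot encoded
    over the training levels (the missing-value sentinel becomes its own
    level).  Every design column records its originating schema feature so
    that feature-level erasure can drop all derived columns at once.
    """

    def __init__(self):
        self.stats_: dict | None = None
        self.levels_: dict | None = None
        self.columns_: list | None = None
        self.column_feature_: list | None = None

    def fit(self, ds: SurvivalData) -> "FeatureEncoder":
        stats, levels = {}, {}
        columns, col_feat = [], []
        for name, kind in ds.schema.fields:
            if kind == CONTINUOUS:
                values = ds.covariates[name].to_numpy(float)
                if np.isnan(values).any():
                    raise ValidationError(f"encode after imputation: {name!r} still missing")
                mean = float(values.mean())
                std = float(values.std())  # population (ddof=0)
                if std == 0.0:
                    warnings.warn(
                        f"continuous feature {name!r} has zero variance; encoding as zeros",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                stats[name] = (mean, std)
                columns.append(name)
                col_feat.append(name)
            else:
                observed = sorted(map(str, ds.covariates[name].dropna().unique()))
                levels[name] = observed
                for level in observed:
                    columns.append(f"{name}={level}")
                    col_feat.append(name)
        self.stats_, self.levels_ = stats, levels
        self.columns_, self.column_feature_ = columns, col_feat
        return self

    def transform(self, ds: SurvivalData) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("FeatureEncoder must be fitted before transform")
        out = np.zeros((len(ds), len(self.columns_)))
        pos = {c: i for i, c in enumerate(self.columns_)}
        for name, kind in ds.schema.fields:
            if kind == CONTINUOUS:
                if name not in self.stats_:
                    raise SchemaError(f"feature {name!r} unseen at fit time")
                mean, std = self.stats_[name]
                values = ds.covariates[name].to_numpy(float)
                out[:, pos[name]] = 0.0 if std == 0.0 else (values - mean) / std
            else:
                if name not in self.levels_:
                    raise SchemaError(f"feature {name!r} unseen at fit time")
                values = ds.covariates[name].astype(str)
                for level in self.levels_[name]:
                    out[:, pos[f"{name}={level}"]] = (values == level).to_numpy(float)
                # unseen test-time levels encode as all-zero across the group
        return pd.DataFrame(out, columns=self.columns_)

    def fit_transform(self, ds: SurvivalData) -> pd.DataFrame:
        return self.fit(ds).transform(ds)

    def feature_columns(self, feature: str):
        """Design-matrix column names derived from one schema feature."""
        return [c for c, f in zip(self.columns_, self.column_feature_) if f == feature]


def encode_features(ds: SurvivalData):
    """One-shot encoding of an (imputed) dataset.

    Returns the design matrix as a DataFrame plus the fitted encoder, whose
    ``column_feature_`` maps every design column back to its schema feature.
    """
    enc = FeatureEncoder()
    return enc.fit_transform(ds), enc


# ---------------------------------------------------------------------------
# Censoring-stratified folds


class ConfigurationError(ValueError):
    pass


def stratified_folds(ds_or_events, k: int, seed: int):
    """Partition subject indices into ``k`` folds preserving the censored
    fraction.

    Event and censored subjects are shuffled and split independently, with
    remainder subjects assigned round-robin by fold index, then merged.
    Deterministic given ``seed``; folds are disjoint and exhaustive.
    """
    events = ds_or_events.events if isinstance(ds_or_events, SurvivalData) else np.asarray(
        ds_or_events, dtype=bool
    )
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    n_event = int(events.sum())
    n_cens = int((~events).sum())
    if n_event < k or n_cens < k:
        raise ConfigurationError(
            f"k={k} exceeds a stratum size (events={n_event}, censored={n_cens})"
        )
    rng = np.random.default_rng(seed)
    folds = [[] for _ in range(k)]
    for stratum in (np.flatnonzero(events), np.flatnonzero(~events)):
        order = rng.permutation(stratum)
        for fold_idx, chunk in enumerate(np.array_split(order, k)):
            folds[fold_idx].extend(chunk.tolist())
    return [np.array(sorted(f), dtype=int) for f in folds]
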
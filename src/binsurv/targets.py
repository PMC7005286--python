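"""Per-bin supervised target vectors and the binned Kaplan-Meier curve.

The supervised binned-time model is trained against one row per subject
over the interval grid: 1 while the subject is known recurrence-free, 0
from the event bin onward for subjects with an observed event, and -- for
censored subjects -- the cohort Kaplan-Meier survival continued past the
censoring bin.  The continuation is conditional on having survived to the
censoring bin (``S_j / S_{c-1}``), so rows stay continuous at 1 and then
decay by the population hazard; the marginal alternative ``S_j`` is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import TimeBinning
from .data import SurvivalData

CONDITIONAL = "conditional"
MARGINAL = "marginal"


def km_survival_curve(ds: SurvivalData, binning: TimeBinning) -> np.ndarray:
    """Product-limit survival probabilities S_1..S_J over the bin grid.

    ``S_j = prod_{i<=j} (1 - d_i / n_i)`` with ``n_i`` the subjects still at
    risk at the start of bin i (duration falling in bin i or later) and
    ``d_i`` the events occurring inside bin i.  Bins with an empty risk set
    contribute a factor of 1.
    """
    if len(ds) == 0:
        raise ValueError("cannot compute a survival curve from an empty dataset")
    bins = binning.bin_indices(ds.durations)
    n_bins = binning.n_bins
    at_risk = np.array([(bins >= j).sum() for j in range(1, n_bins + 1)], dtype=float)
    events = np.array(
        [np.sum((bins == j) & ds.events) for j in range(1, n_bins + 1)], dtype=float
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = np.where(at_risk > 0, 1.0 - events / np.maximum(at_risk, 1.0), 1.0)
    return np.cumprod(factors)


@dataclass(frozen=True)
class TargetMatrix:
    """Subjects-by-bins supervised outputs with their interval grid."""

    values: np.ndarray
    binning: TimeBinning

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != self.binning.n_bins:
            raise ValueError("target matrix must be n_subjects x n_bins")
        object.__setattr__(self, "values", values)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin_{j}" for j in range(1, self.binning.n_bins + 1)]
        return pd.DataFrame(self.values, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_targets(ds: SurvivalData, binning: TimeBinning,
                  censored_continuation: str = CONDITIONAL) -> TargetMatrix:
    """Build the supervised TargetMatrix for a cohort.

    Event subjects with the event in bin ``e`` get ``y_j = 1`` for ``j < e``
    and ``0`` for ``j >= e`` (the event bin itself counts as post-relapse).
    Censored subjects censored in bin ``c`` get 1 before ``c`` and, from
    ``c`` onward, the cohort KM curve -- conditional on survival to ``c``
    by default.
    """
    if censored_continuation not in (CONDITIONAL, MARGINAL):
        raise ValueError(f"unknown continuation mode {censored_continuation!r}")
    try:
        bins = binning.bin_indices(ds.durations)
    except ValueError as exc:
        raise ValueError("subject duration beyond the binning range") from exc
    n_bins = binning.n_bins
    survival = km_survival_curve(ds, binning)
    # S_0 = 1 prepended so S[c-1] indexes survival to the start of bin c
    s_full = np.concatenate([[1.0], survival])
    values = np.zeros((len(ds), n_bins))
    bin_axis = np.arange(1, n_bins + 1)
    for i, (b, event) in enumerate(zip(bins, ds.events)):
        if event:
            values[i] = (bin_axis < b).astype(float)
        else:
            row = np.ones(n_bins)
            tail = bin_axis >= b
            if censored_continuation == CONDITIONAL:
                denom = s_full[b - 1]
                row[tail] = survival[tail] / denom if denom > 0 else 0.0
            else:
                row[tail] = survival[tail]
            values[i] = np.clip(row, 0.0, 1.0)
    return TargetMatrix(values, binning)
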
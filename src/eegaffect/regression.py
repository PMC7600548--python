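"""Emotional-state-specific leave-one-participant-out regression.

For each IC cluster, four separate OLS models predict the normative rating
from the four log band powers: valence in the high-valence state (ratings
> 5), valence in the low-valence state (< 5), and likewise for arousal.
All independent and dependent variables are standardized per participant
(mean 0, variance 1, population denominator) before fitting; folds leave
one participant out entirely, train on the pooled epochs of the others and
report per-fold Pearson r, MSE and band coefficients on the held-out
participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .bandpower import BAND_NAMES
from .stimuli import NEUTRAL, StimulusSet

AXES = ("valence", "arousal")
STATES = ("high", "low")
STATE_KEYS = tuple((a, s) for a in AXES for s in STATES)


@dataclass
class StateSubset:
    """Feature rows of one (axis, state) half of the rating axis."""

    axis: str
    state: str
    table: pd.DataFrame = field(repr=False)   # features + 'rating' column
    n_excluded_neutral: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class RegressionOutcome:
    """Per-fold LOPO results for one (cluster, axis, state)."""

    cluster_index: int
    axis: str
    state: str
    fold_participants: list[str]
    pearson_r: np.ndarray            # one per valid fold
    mse: np.ndarray
    coefficients: np.ndarray         # (n_folds, 4) in band order
    intercepts: np.ndarray
    undefined_folds: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_participants)


class BandPowerOLS(BaseEstimator, RegressorMixin):
    """Ordinary least squares on the four band-power features.

    A deliberately transparent estimator: ``fit`` solves the normal
    equations for [theta, alpha, beta, gamma] + intercept; ``coef_`` and
    ``intercept_`` follow sklearn conventions.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        A = np.column_stack([X, np.ones(len(X))])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        self.coef_ = beta[:-1]
        self.intercept_ = float(beta[-1])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def split_by_state(
    features: pd.DataFrame,
    ratings: StimulusSet,
    neutral_policy: str = "exclude",
) -> dict[tuple[str, str], StateSubset]:
    """Partition feature rows into the four (axis, state) subsets.

    Each row must carry a ``stimulus_id``; its valence/arousal ratings are
    attached as the regression target.  Ratings exactly at the neutral
    value are excluded with a warning under the default policy.
    """
    if "stimulus_id" not in features.columns:
        raise ValueError("features table needs a stimulus_id column")
    table = ratings.table.set_index("stimulus_id")
    out: dict[tuple[str, str], StateSubset] = {}
    for axis in AXES:
        vals = table.loc[features["stimulus_id"], axis].to_numpy(dtype=float)
        neutral = vals == NEUTRAL
        n_neutral = int(neutral.sum())
        if n_neutral:
            if neutral_policy != "exclude":
                raise ValueError(f"rating exactly {NEUTRAL} with policy {neutral_policy!r}")
            warnings.warn(
                f"{n_neutral} epochs at neutral {axis} rating excluded", stacklevel=2
            )
        for state in STATES:
            mask = (vals > NEUTRAL) if state == "high" else (vals < NEUTRAL)
            sub = features.loc[mask].copy()
            sub["rating"] = vals[mask]
            if sub.empty:
                warnings.warn(f"empty subset ({axis}, {state})", stacklevel=2)
            out[(axis, state)] = StateSubset(
                axis=axis, state=state, table=sub.reset_index(drop=True),
                n_excluded_neutral=n_neutral,
            )
    return out


def standardize_per_participant(
    table: pd.DataFrame,
    columns: tuple[str, ...] = BAND_NAMES + ("rating",),
) -> pd.DataFrame:
    """Z-score the named columns within each participant (denominator n).

    After the transform every (participant, column) pair has mean 0 and
    variance exactly 1; the operation is idempotent and invariant to affine
    re-scaling of the inputs.
    """
    out = table.copy()
    for pid, idx in table.groupby("participant_id").groups.items():
        block = table.loc[idx, list(columns)].to_numpy(dtype=float)
        mu = block.mean(axis=0)
        sd = block.std(axis=0)  # population convention: variance of 1 exactly
        zero = sd == 0
        if zero.any():
            bad = [c for c, z in zip(columns, zero) if z]
            raise ValueError(f"zero-variance column(s) {bad} for participant {pid}")
        out.loc[idx, list(columns)] = (block - mu) / sd
    return out


def lopo_regress(
    subset: StateSubset,
    cluster_index: int = 0,
    min_epochs_per_participant: int = 8,
    standardized: bool = False,
) -> RegressionOutcome:
    """Leave-one-participant-out OLS on a state subset.

    Every fold trains on the pooled standardized epochs of all other
    participants and never reads the held-out participant's data at fit
    time.  Folds with constant predictions or a constant target have an
    undefined correlation; they are flagged and excluded.
    """
    table = subset.table
    pids = sorted(table["participant_id"].unique())
    if len(pids) < 3:
        raise ValueError(f"need >= 3 participants, got {len(pids)}")
    counts = table.groupby("participant_id").size()
    if (counts < min_epochs_per_participant).any():
        low = counts[counts < min_epochs_per_participant]
        raise ValueError(f"too few epochs per participant: {low.to_dict()}")
    if not standardized:
        table = standardize_per_participant(table)

    bands = list(BAND_NAMES)
    fold_pids, rs, mses, coefs, icepts, undefined = [], [], [], [], [], []
    for pid in pids:
        train = table[table["participant_id"] != pid]
        test = table[table["participant_id"] == pid]
        model = BandPowerOLS().fit(train[bands].to_numpy(), train["rating"].to_numpy())
        pred = model.predict(test[bands].to_numpy())
        y = test["rating"].to_numpy(dtype=float)
        if np.std(pred) == 0 or np.std(y) == 0:
            undefined.append(pid)
            warnings.warn(f"fold {pid}: constant prediction or target", stacklevel=2)
            continue
        r, _ = stats.pearsonr(pred, y)
        fold_pids.append(pid)
        rs.append(float(r))
        mses.append(float(np.mean((pred - y) ** 2)))
        coefs.append(model.coef_)
        icepts.append(model.intercept_)
    return RegressionOutcome(
        cluster_index=cluster_index,
        axis=subset.axis,
        state=subset.state,
        fold_participants=fold_pids,
        pearson_r=np.array(rs),
        mse=np.array(mses),
        coefficients=np.array(coefs).reshape(len(fold_pids), len(bands)),
        intercepts=np.array(icepts),
        undefined_folds=undefined,
    )


def regress_cluster(
    features: pd.DataFrame,
    ratings: StimulusSet,
    cluster_index: int = 0,
    min_epochs_per_participant: int = 8,
) -> dict[tuple[str, str], RegressionOutcome]:
    """All four state-specific LOPO regressions for one cluster's features."""
    subsets = split_by_state(features, ratings)
    out = {}
    for key, subset in subsets.items():
        out[key] = lopo_regress(
            subset,
            cluster_index=cluster_index,
            min_epochs_per_participant=min_epochs_per_participant,
        )
    return out
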
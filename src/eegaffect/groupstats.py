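"""Group-level inference over LOPO fold correlations.

Fold-wise Pearson correlations are Fisher-z transformed (atanh), tested
against zero with a one-tailed one-sample t-test per cluster, and the
p-values are Holm–Bonferroni corrected across the retained clusters of each
(axis, state) family.  Because each rating axis is analysed in two states,
the family significance level defaults to 0.025 (= 0.05 / 2).  Mean
correlations are reported back-transformed (tanh of the mean z), and band
coefficients are summarized as mean (SD) over folds in the fixed order
theta, alpha, beta, gamma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bandpower import BAND_NAMES
from .regression import RegressionOutcome

DEFAULT_ALPHA = 0.025
_R_CLAMP = 1.0 - 1e-12


@dataclass
class GroupStats:
    cluster_index: int
    axis: str
    state: str
    n_folds: int
    mean_r: float            # tanh of the mean Fisher z
    mean_mse: float
    t_statistic: float
    p_raw: float
    p_holm: float
    significant: bool
    coef_mean: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    coef_sd: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))

    def as_row(self) -> dict:
        row = {
            "cluster_index": self.cluster_index,
            "axis": self.axis,
            "state": self.state,
            "n_folds": self.n_folds,
            "mean_r": self.mean_r,
            "mean_mse": self.mean_mse,
            "t": self.t_statistic,
            "p_raw": self.p_raw,
            "p_holm": self.p_holm,
            "significant": self.significant,
        }
        for i, b in enumerate(BAND_NAMES):
            row[f"coef_{b}_mean"] = float(self.coef_mean[i])
            row[f"coef_{b}_sd"] = float(self.coef_sd[i])
        return row


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clamped just inside 1 (a warning flags clamping)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("fold correlation at |r| >= 1 clamped for Fisher z", stacklevel=2)
    return np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))


def one_tailed_t(z: np.ndarray) -> tuple[float, float]:
    """One-sample t-statistic and upper-tail p for mean(z) > 0.

    Sample SD (denominator n−1); a zero-variance sample degenerates to
    p = 0 or 1 by the sign of the mean, with a warning.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n < 2:
        raise ValueError("need at least 2 folds for a t-test")
    sd = z.std(ddof=1)
    if sd == 0:
        warnings.warn("zero variance of Fisher z across folds", stacklevel=2)
        m = z.mean()
        return (np.inf if m > 0 else (-np.inf if m < 0 else 0.0)), (
            0.0 if m > 0 else (1.0 if m < 0 else 0.5)
        )
    t = z.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def holm_bonferroni(p_values, alpha: float = DEFAULT_ALPHA):
    """Step-down Holm adjustment; returns (adjusted p, reject flags).

    Sorted ascending, adjusted_(i) = max_{j<=i} (m−j)·p_(j) (0-based),
    capped at 1, then mapped back to the original order; rejections are
    adjusted p ≤ alpha.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.maximum.accumulate((m - np.arange(m)) * p[order])
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= alpha


def coefficient_summary(outcome: RegressionOutcome) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample SD of each band's coefficient across folds.

    Always in the fixed band order (theta, alpha, beta, gamma).
    """
    c = np.asarray(outcome.coefficients, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need >= 2 folds to summarize coefficients")
    return c.mean(axis=0), c.std(axis=0, ddof=1)


def group_significance(
    outcomes: list[RegressionOutcome], alpha: float = DEFAULT_ALPHA
) -> list[GroupStats]:
    """Fisher-z t-tests with Holm correction for one (axis, state) family.

    ``outcomes`` holds one RegressionOutcome per retained cluster of a
    single (axis, state); the Holm correction spans exactly these clusters.
    """
    if not outcomes:
        return []
    axes = {(o.axis, o.state) for o in outcomes}
    if len(axes) != 1:
        raise ValueError(f"outcomes mix (axis, state) families: {axes}")
    rows = []
    for o in outcomes:
        if o.n_folds < 3:
            raise ValueError(
                f"cluster {o.cluster_index}: need >= 3 folds, got {o.n_folds}"
            )
        z = fisher_z(o.pearson_r)
        t, p = one_tailed_t(z)
        coef_mean, coef_sd = coefficient_summary(o)
        rows.append(
            GroupStats(
                cluster_index=o.cluster_index,
                axis=o.axis,
                state=o.state,
                n_folds=o.n_folds,
                mean_r=float(np.tanh(z.mean())),
                mean_mse=float(np.mean(o.mse)),
                t_statistic=t,
                p_raw=p,
                p_holm=np.nan,
                significant=False,
                coef_mean=coef_mean,
                coef_sd=coef_sd,
            )
        )
    adjusted, reject = holm_bonferroni([g.p_raw for g in rows], alpha)
    for g, pa, rej in zip(rows, adjusted, reject):
        g.p_holm = float(pa)
        g.significant = bool(rej)
    return rows


def stats_table(all_stats: list[GroupStats]) -> pd.DataFrame:
    """One row per (cluster, axis, state), the pipeline's final report."""
    df = pd.DataFrame([g.as_row() for g in all_stats])
    if not df.empty:
        df = df.sort_values(["axis", "state", "cluster_index"]).reset_index(drop=True)
    return df
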
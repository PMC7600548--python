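"""Fisher-z t-tests, Holm-Bonferroni correction, coefficient summaries."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from eegaffect.groupstats import (
    coefficient_summary,
    fisher_z,
    group_significance,
    holm_bonferroni,
    one_tailed_t,
)
from eegaffect.regression import RegressionOutcome


def _outcome(rs, cluster=0, axis="valence", state="high", coefs=None):
    rs = np.asarray(rs, dtype=float)
    n = rs.size
    coefs = np.tile([0.1, -0.05, 0.02, 0.0], (n, 1)) if coefs is None else np.asarray(coefs)
    return RegressionOutcome(
        cluster_index=cluster,
        axis=axis,
        state=state,
        fold_participants=[f"P{i}" for i in range(n)],
        pearson_r=rs,
        mse=np.full(n, 0.98),
        coefficients=coefs,
        intercepts=np.zeros(n),
    )


def test_fisher_t_p_match_closed_form_recomputation():
    rs = np.array([0.1, 0.2, 0.3])
    z = fisher_z(rs)
    assert np.allclose(z, np.arctanh(rs), atol=1e-12)
    assert np.allclose(z, [0.100335, 0.202733, 0.309520], atol=1e-6)
    t, p = one_tailed_t(z)
    zm, zs = z.mean(), z.std(ddof=1)
    t_ref = zm / (zs / np.sqrt(3))
    p_ref = float(sps.t.sf(t_ref, df=2))
    assert abs(t - t_ref) < 1e-10
    assert abs(p - p_ref) < 1e-10


def test_all_zero_correlations_not_significant():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = group_significance([_outcome([0.0, 0.0, 0.0, 0.0])])
    g = stats[0]
    assert g.t_statistic == 0.0
    assert g.p_raw == 0.5
    assert not g.significant


def test_mean_r_is_tanh_of_mean_z():
    g = group_significance([_outcome([0.5, 0.5, 0.5])])[0]
    assert abs(g.mean_r - 0.5) < 1e-12
    g2 = group_significance([_outcome([0.2, 0.6, 0.4])])[0]
    expected = np.tanh(np.arctanh([0.2, 0.6, 0.4]).mean())
    assert abs(g2.mean_r - expected) < 1e-12


def test_extreme_r_clamped_with_warning():
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        z = fisher_z(np.array([1.0, 0.5, -1.0]))
    assert np.isfinite(z).all()
    assert any("clamped" in str(w.message) for w in caught)


def test_zero_variance_folds_degenerate_p():
    with warnings.catch_warnings(record=True):
        warnings.simplefilter("ignore")
        t, p = one_tailed_t(np.array([0.3, 0.3, 0.3]))
        assert p == 0.0 and t == np.inf
        t, p = one_tailed_t(np.array([-0.3, -0.3, -0.3]))
        assert p == 1.0


# ---------------------------------------------------------------------- Holm


def _holm_brute_force(p_values, alpha):
    """Independent sequential-testing implementation of the step-down rule."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    reject = [False] * m
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    adjusted = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted, reject


def test_holm_single_p_is_identity():
    adj, rej = holm_bonferroni([0.01], alpha=0.025)
    assert adj[0] == 0.01 and rej[0]


def test_holm_worked_example():
    adj, rej = holm_bonferroni([0.001, 0.02, 0.04], alpha=0.05)
    assert np.allclose(adj, [0.003, 0.04, 0.04], atol=1e-12)
    assert rej.all()


def test_holm_smallest_p_scaled_by_family_size_seven():
    p = [0.003, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
    adj, rej = holm_bonferroni(p, alpha=0.025)
    assert abs(adj[0] - 7 * 0.003) < 1e-12
    assert rej[0] and not rej[1:].any()


@pytest.mark.parametrize("m", [2, 3, 4, 5])
def test_holm_matches_brute_force_and_statsmodels(m):
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(m)
    for _ in range(25):
        p = rng.uniform(0, 1, size=m)
        alpha = rng.choice([0.01, 0.025, 0.05])
        adj, rej = holm_bonferroni(p, alpha=alpha)
        adj_bf, rej_bf = _holm_brute_force(p, alpha)
        assert np.allclose(adj, adj_bf, atol=1e-12)
        assert list(rej) == rej_bf
        sm_rej, sm_adj, *_ = multipletests(p, alpha=alpha, method="holm")
        assert np.allclose(adj, sm_adj, atol=1e-9)
        assert np.array_equal(rej, sm_rej)


def test_holm_rejects_invalid_p():
    with pytest.raises(ValueError):
        holm_bonferroni([0.5, 1.2])
    with pytest.raises(ValueError):
        holm_bonferroni([-0.1])


# ---------------------------------------------------------------- summaries


def test_identical_coefficients_have_zero_sd():
    mean, sd = coefficient_summary(_outcome([0.1, 0.2, 0.3]))
    assert np.allclose(sd, 0.0)


def test_two_fold_coefficient_arithmetic():
    coefs = np.array([[-0.10, 0.0, 0.0, 0.0], [-0.14, 0.0, 0.0, 0.0]])
    mean, sd = coefficient_summary(_outcome([0.1, 0.2], coefs=coefs))
    assert abs(mean[0] - (-0.12)) < 1e-12
    assert abs(sd[0] - 0.028284271) < 1e-8


def test_summary_row_band_order():
    g = group_significance([_outcome([0.1, 0.2, 0.3])])[0]
    row = g.as_row()
    keys = [k for k in row if k.startswith("coef_") and k.endswith("_mean")]
    assert keys == [
        "coef_theta_mean", "coef_alpha_mean", "coef_beta_mean", "coef_gamma_mean"
    ]


def test_group_significance_contract():
    outs = [_outcome([0.3, 0.35, 0.4], cluster=c) for c in range(3)]
    stats = group_significance(outs, alpha=0.025)
    for g in stats:
        assert g.p_holm >= g.p_raw - 1e-15
        assert -1 < g.mean_r < 1
    with pytest.raises(ValueError):
        group_significance([_outcome([0.1] * 3), _outcome([0.1] * 3, state="low")])
    with pytest.raises(ValueError):
        group_significance([_outcome([0.1, 0.2])])  # too few folds
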
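"""State splitting, per-participant standardization, and LOPO regression."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegaffect.bandpower import BAND_NAMES
from eegaffect.regression import (
    BandPowerOLS,
    StateSubset,
    lopo_regress,
    split_by_state,
    standardize_per_participant,
)
from eegaffect.stimuli import generate_stimulus_set

BANDS = list(BAND_NAMES)


def _feature_table(stimuli, n_participants=5, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    sids = stimuli.table["stimulus_id"].to_numpy()
    rows = []
    for p in range(n_participants):
        for sid in sids:
            row = {"participant_id": f"P{p:02d}", "stimulus_id": int(sid)}
            row.update({b: rng.standard_normal() for b in BANDS})
            rows.append(row)
    return pd.DataFrame(rows)


def test_default_design_splits_into_four_80_epoch_subsets(stimuli160):
    table = _feature_table(stimuli160, n_participants=1)
    subsets = split_by_state(table, stimuli160)
    assert set(subsets) == {
        ("valence", "high"), ("valence", "low"),
        ("arousal", "high"), ("arousal", "low"),
    }
    assert all(len(s) == 80 for s in subsets.values())


def test_quadrant_membership_consistency(stimuli160):
    table = _feature_table(stimuli160, n_participants=1)
    subsets = split_by_state(table, stimuli160)
    hvha = stimuli160.table.loc[
        stimuli160.table["quadrant"] == "HVHA", "stimulus_id"
    ]
    for sid in hvha:
        assert sid in set(subsets[("valence", "high")].table["stimulus_id"])
        assert sid in set(subsets[("arousal", "high")].table["stimulus_id"])
        assert sid not in set(subsets[("valence", "low")].table["stimulus_id"])
        assert sid not in set(subsets[("arousal", "low")].table["stimulus_id"])


def test_one_sided_toy_set_flags_empty_subset():
    stim = generate_stimulus_set(3, seed=0)
    stim.table.loc[:, "valence"] = 7.0  # all high valence
    table = _feature_table(stim, n_participants=1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        subsets = split_by_state(table, stim)
    assert len(subsets[("valence", "low")]) == 0
    assert any("empty subset" in str(w.message) for w in caught)


def test_neutral_rating_excluded_with_warning():
    stim = generate_stimulus_set(2, seed=0)
    stim.table.loc[0, "valence"] = 5.0
    table = _feature_table(stim, n_participants=1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        subsets = split_by_state(table, stim)
    n = len(subsets[("valence", "high")]) + len(subsets[("valence", "low")])
    assert n == len(stim) - 1
    assert any("neutral" in str(w.message) for w in caught)


# ----------------------------------------------------------------------


def _standardizable_table(rng, n_participants=3, n_epochs=12):
    rows = []
    for p in range(n_participants):
        for e in range(n_epochs):
            row = {"participant_id": f"P{p}", "rating": rng.uniform(1, 9)}
            row.update({b: rng.normal(5 * p, p + 1) for b in BANDS})
            rows.append(row)
    return pd.DataFrame(rows)


def test_standardization_is_exact_per_participant(rng):
    out = standardize_per_participant(_standardizable_table(rng))
    for _, g in out.groupby("participant_id"):
        block = g[BANDS + ["rating"]].to_numpy()
        assert np.abs(block.mean(axis=0)).max() < 1e-12
        assert np.abs(block.var(axis=0) - 1.0).max() < 1e-12


def test_standardization_idempotent(rng):
    t = _standardizable_table(rng)
    once = standardize_per_participant(t)
    twice = standardize_per_participant(once)
    pd.testing.assert_frame_equal(once, twice)


@settings(max_examples=15, deadline=None)
@given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
def test_standardization_affine_invariant(scale, shift):
    rng = np.random.default_rng(1)
    t = _standardizable_table(rng)
    t2 = t.copy()
    t2["theta"] = t2["theta"] * scale + shift
    a = standardize_per_participant(t)
    b = standardize_per_participant(t2)
    assert np.allclose(a["theta"].to_numpy(), b["theta"].to_numpy(), atol=1e-9)


def test_zero_variance_column_named_in_error(rng):
    t = _standardizable_table(rng)
    t.loc[t["participant_id"] == "P1", "beta"] = 3.14
    with pytest.raises(ValueError, match="beta"):
        standardize_per_participant(t)


# ----------------------------------------------------------------------


def _subset_from(table, axis="valence", state="high"):
    return StateSubset(axis=axis, state=state, table=table.reset_index(drop=True))


def _lopo_table(rng, coef=None, noise=0.0, n_participants=4, n_epochs=20):
    rows = []
    for p in range(n_participants):
        X = rng.standard_normal((n_epochs, 4))
        if coef is None:
            y = rng.standard_normal(n_epochs)
        else:
            y = X @ np.asarray(coef) + noise * rng.standard_normal(n_epochs)
        for e in range(n_epochs):
            row = {"participant_id": f"P{p}", "rating": y[e]}
            row.update({b: X[e, i] for i, b in enumerate(BANDS)})
            rows.append(row)
    return pd.DataFrame(rows)


def test_perfect_linear_target_gives_unit_correlation(rng):
    """Identical exact linear law in every participant -> every fold r = 1."""
    table = _lopo_table(rng, coef=[0.5, -0.3, 0.2, 0.1])
    out = lopo_regress(
        _subset_from(table), min_epochs_per_participant=8, standardized=True
    )
    assert out.n_folds == 4
    assert np.all(out.pearson_r > 1 - 1e-12)
    assert np.all(out.mse < 1e-20)


def test_null_features_give_near_zero_mean_r():
    rs = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        table = _lopo_table(rng, coef=None, n_participants=5, n_epochs=40)
        out = lopo_regress(_subset_from(table), min_epochs_per_participant=8)
        rs.extend(out.pearson_r)
    rs = np.asarray(rs)
    assert abs(rs.mean()) < 3.0 / np.sqrt(rs.size * 40)


def test_ols_matches_normal_equations(rng):
    X = rng.standard_normal((200, 4))
    y = rng.standard_normal(200)
    model = BandPowerOLS().fit(X, y)
    A = np.column_stack([X, np.ones(200)])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    assert np.allclose(model.coef_, beta[:4], atol=1e-8)
    assert np.allclose(model.intercept_, beta[4], atol=1e-8)


def test_intercept_negligible_on_standardized_folds(rng):
    table = standardize_per_participant(_lopo_table(rng, coef=[0.4, 0, 0, 0], noise=1.0))
    out = lopo_regress(_subset_from(table), min_epochs_per_participant=8, standardized=True)
    assert np.abs(out.intercepts).max() < 1e-10


def test_lopo_never_reads_held_out_data_at_fit_time(rng):
    table = standardize_per_participant(
        _lopo_table(rng, coef=[0.4, -0.2, 0.1, 0.0], noise=1.0)
    )
    out = lopo_regress(_subset_from(table), min_epochs_per_participant=8, standardized=True)
    corrupted = table.copy()
    mask = corrupted["participant_id"] == "P2"
    corrupted.loc[mask, BANDS] = 1e6 * rng.standard_normal((int(mask.sum()), 4))
    out2 = lopo_regress(
        _subset_from(corrupted), min_epochs_per_participant=8, standardized=True
    )
    i = out.fold_participants.index("P2")
    j = out2.fold_participants.index("P2")
    # P2's fold was fitted without P2's rows: identical coefficients
    assert np.allclose(out.coefficients[i], out2.coefficients[j], atol=1e-12)


def test_constant_fold_flagged_and_excluded(rng):
    table = _lopo_table(rng, coef=None, n_participants=4)
    mask = table["participant_id"] == "P3"
    table.loc[mask, "rating"] = 42.0
    table_std = table.copy()  # bypass standardization (would reject zero var)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        out = lopo_regress(
            _subset_from(table_std), min_epochs_per_participant=8, standardized=True
        )
    assert "P3" in out.undefined_folds
    assert "P3" not in out.fold_participants
    assert any("constant" in str(w.message) for w in caught)


def test_preconditions(rng):
    table = _lopo_table(rng, n_participants=2)
    with pytest.raises(ValueError):
        lopo_regress(_subset_from(table))
    table = _lopo_table(rng, n_participants=4, n_epochs=4)
    with pytest.raises(ValueError):
        lopo_regress(_subset_from(table), min_epochs_per_participant=8)


def test_null_model_mse_is_about_one(rng):
    """On standardized targets with weak effects, MSE sits near 1."""
    table = _lopo_table(rng, coef=[0.1, 0, 0, 0], noise=1.0, n_participants=5, n_epochs=40)
    out = lopo_regress(_subset_from(table), min_epochs_per_participant=8)
    assert 0.8 < out.mse.mean() < 1.3
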
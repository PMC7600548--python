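"""18-d IC features and cross-participant k-means with pruning/retention."""

import numpy as np
import pytest

from eegaffect.cluster import (
    ICClusterer,
    ICFeatureSet,
    ICRecord,
    build_features,
    cluster_ics,
)


def _records(rng, n=14, n_channels=24, n_epochs=6, n_samples=512):
    recs = []
    for i in range(n):
        topo = rng.standard_normal(n_channels)
        topo /= np.linalg.norm(topo)
        recs.append(
            ICRecord(
                participant_id=f"P{i % 7}",
                ic_index=i,
                topography=topo,
                dipole_location_mm=rng.uniform(-60, 60, 3),
                epoch_activations=rng.standard_normal((n_epochs, n_samples)),
            )
        )
    return recs


def test_feature_vectors_have_18_dimensions(rng):
    fs = build_features(_records(rng))
    assert fs.features.shape == (14, 18)
    assert fs.block_slices["dipole"] == slice(0, 3)
    assert fs.block_slices["topo"] == slice(3, 13)
    assert fs.block_slices["erp"] == slice(13, 18)
    # every dimension standardized across ICs
    assert np.abs(fs.features.mean(axis=0)).max() < 1e-9
    assert np.abs(fs.features.std(axis=0) - 1.0).max() < 1e-9


def test_identical_ics_get_identical_features(rng):
    recs = _records(rng, n=12)
    clone = ICRecord(
        participant_id="P9",
        ic_index=99,
        topography=recs[0].topography.copy(),
        dipole_location_mm=recs[0].dipole_location_mm.copy(),
        epoch_activations=recs[0].epoch_activations.copy(),
    )
    fs = build_features(recs + [clone])
    assert np.allclose(fs.features[0], fs.features[-1], atol=1e-10)


def test_topo_pca_variance_fraction_matches_eigendecomposition(rng):
    recs = _records(rng, n=20)
    fs = build_features(recs)
    topos = np.stack([r.topography for r in recs])
    centered = topos - topos.mean(axis=0)
    evals = np.linalg.eigvalsh(centered.T @ centered)[::-1]
    expected = evals[:10].sum() / evals.sum()
    assert abs(fs.topo_explained_fraction - expected) < 1e-8


def test_too_few_ics_rejected(rng):
    with pytest.raises(ValueError):
        build_features(_records(rng, n=9))  # need max(10, 5) + 1


def _blob_feature_set(rng, centers, sizes, spread=0.5, n_participants=None):
    feats, prov, labels = [], [], []
    pid = 0
    for ci, (c, s) in enumerate(zip(centers, sizes)):
        for _ in range(s):
            feats.append(c + spread * rng.standard_normal(len(c)))
            prov.append((f"P{pid:02d}", 0))
            labels.append(ci)
            pid += 1
    feats = np.asarray(feats)
    return (
        ICFeatureSet(
            features=feats,
            provenance=prov,
            locations_mm=feats[:, :3],
            block_slices={"dipole": slice(0, 3)},
            topo_explained_fraction=1.0,
            erp_explained_fraction=1.0,
        ),
        np.asarray(labels),
    )


def test_well_separated_blobs_recovered_exactly(rng):
    centers = [np.full(18, v) for v in (-10.0, 0.0, 10.0)]
    fs, truth = _blob_feature_set(rng, centers, [8, 8, 8])
    est = ICClusterer(k=3, random_state=0).fit(None, feature_set=fs)
    labels = est.labels_
    # identical partition up to label permutation
    for c in range(3):
        assert len(set(labels[truth == c])) == 1
    assert len(set(labels)) == 3


def test_far_outlier_pruned(rng):
    centers = [np.zeros(18), np.full(18, 8.0)]
    fs, _ = _blob_feature_set(rng, centers, [11, 10], spread=0.5)
    # plant a point ~14 clean in-cluster SDs from the first centroid, still
    # nearer to it than to the other blob
    fs.features[0] = np.zeros(18)
    fs.features[0, 0] = 30.0
    est = ICClusterer(k=2, random_state=0).fit(None, feature_set=fs)
    assert est.labels_[0] == -1
    assert est.outliers_[0]
    # no clean point was pruned
    assert est.outliers_.sum() == 1


def test_majority_participant_retention_rule(rng):
    """With a 25-participant cohort, 13 distinct members retain, 12 do not."""
    centers = [np.zeros(18), np.full(18, 10.0)]
    fs, _ = _blob_feature_set(rng, centers, [12, 13])
    clusters = cluster_ics(fs, k=2, seed=0, n_participants=25)
    by_size = {len(c.participant_ids): c for c in clusters}
    assert set(by_size) == {12, 13}
    assert by_size[13].retained is True
    assert by_size[12].retained is False


def test_clustering_invariant_to_input_order(rng):
    recs = _records(rng, n=16)
    fs1 = build_features(recs)
    order = rng.permutation(len(recs))
    fs2 = build_features([recs[i] for i in order])
    c1 = cluster_ics(fs1, k=3, seed=5)
    c2 = cluster_ics(fs2, k=3, seed=5)
    sets1 = sorted(sorted(cl.members) for cl in c1)
    sets2 = sorted(sorted(cl.members) for cl in c2)
    assert sets1 == sets2


def test_centroid_location_is_mean_of_member_dipoles(rng):
    centers = [np.zeros(18), np.full(18, 10.0)]
    fs, truth = _blob_feature_set(rng, centers, [6, 6])
    clusters = cluster_ics(fs, k=2, seed=0, n_participants=12)
    for cl in clusters:
        if cl.member_rows:
            assert np.allclose(
                cl.centroid_location_mm, fs.locations_mm[cl.member_rows].mean(axis=0)
            )


def test_invalid_k_rejected(rng):
    fs, _ = _blob_feature_set(rng, [np.zeros(18)], [6])
    with pytest.raises(ValueError):
        cluster_ics(fs, k=1)
    with pytest.raises(ValueError):
        cluster_ics(fs, k=6)
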
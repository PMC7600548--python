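"""Cross-participant grouping of brain ICs by k-means.

Each IC is summarized by an 18-dimensional vector: 3 dipole-location
coordinates, the top 10 principal components of the pooled scalp
topographies, and the top 5 principal components of the pooled 0–500 ms
ERPs.  Every block is standardized (per-dimension zero mean, unit variance
across ICs) so the three characteristics carry equal weight.  Clusters are
pruned of 3-SD outliers and reported only when they contain ICs from more
than half of the cohort's participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

ERP_RESAMPLE_LEN = 128  # fixed ERP length after resampling


@dataclass
class ICRecord:
    """One brain IC queued for clustering."""

    participant_id: str
    ic_index: int
    topography: np.ndarray              # (n_channels,), unit norm, sign fixed
    dipole_location_mm: np.ndarray      # (3,)
    epoch_activations: np.ndarray = field(repr=False)  # (n_epochs, n_samples)
    sampling_rate: float = 512.0


@dataclass
class ICFeatureSet:
    """Feature matrix with provenance; blocks in order (dipole, topo, erp)."""

    features: np.ndarray                # (n_ics, 18)
    provenance: list[tuple[str, int]]   # (participant_id, ic_index)
    locations_mm: np.ndarray            # (n_ics, 3) raw dipole locations
    block_slices: dict[str, slice]
    topo_explained_fraction: float
    erp_explained_fraction: float

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class ICCluster:
    cluster_index: int
    members: list[tuple[str, int]]      # (participant_id, ic_index)
    member_rows: list[int]              # rows into the feature set
    centroid: np.ndarray                # 18-d, feature space
    centroid_location_mm: np.ndarray    # mean of member dipole locations
    retained: bool
    n_participants_cohort: int

    @property
    def participant_ids(self) -> list[str]:
        return sorted({pid for pid, _ in self.members})


def _standardize_columns(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def build_features(
    ics: list[ICRecord],
    erp_window_s: tuple[float, float] = (0.0, 0.5),
    n_topo_pcs: int = 10,
    n_erp_pcs: int = 5,
    erp_len: int = ERP_RESAMPLE_LEN,
) -> ICFeatureSet:
    """Assemble the 18-d clustering features for a cohort's brain ICs.

    The ERP of an IC is the across-epoch mean of its activation in the
    0–500 ms window, resampled to a fixed length; topographies and ERPs are
    pooled over all cohort ICs and PCA-reduced to 10 and 5 components.
    """
    n_ics = len(ics)
    needed = max(n_topo_pcs, n_erp_pcs) + 1
    if n_ics < needed:
        raise ValueError(f"need at least {needed} ICs for PCA retention, got {n_ics}")

    topos = np.stack([np.asarray(ic.topography, dtype=float) for ic in ics])
    erps = []
    for ic in ics:
        acts = np.asarray(ic.epoch_activations, dtype=float)
        if acts.ndim != 2 or acts.shape[0] < 2:
            raise ValueError("each IC needs >= 2 epochs of activation")
        fs = ic.sampling_rate
        i0 = int(round(erp_window_s[0] * fs))
        i1 = int(round(erp_window_s[1] * fs))
        erp = acts[:, i0:i1].mean(axis=0)
        erps.append(sp_signal.resample(erp, erp_len))
    erps = np.stack(erps)
    locs = np.stack([np.asarray(ic.dipole_location_mm, dtype=float) for ic in ics])

    topo_pca = PCA(n_components=n_topo_pcs, svd_solver="full").fit(topos)
    erp_pca = PCA(n_components=n_erp_pcs, svd_solver="full").fit(erps)
    blocks = [
        _standardize_columns(locs),
        _standardize_columns(topo_pca.transform(topos)),
        _standardize_columns(erp_pca.transform(erps)),
    ]
    features = np.hstack(blocks)
    slices = {
        "dipole": slice(0, 3),
        "topo": slice(3, 3 + n_topo_pcs),
        "erp": slice(3 + n_topo_pcs, 3 + n_topo_pcs + n_erp_pcs),
    }
    return ICFeatureSet(
        features=features,
        provenance=[(ic.participant_id, ic.ic_index) for ic in ics],
        locations_mm=locs,
        block_slices=slices,
        topo_explained_fraction=float(topo_pca.explained_variance_ratio_.sum()),
        erp_explained_fraction=float(erp_pca.explained_variance_ratio_.sum()),
    )


class ICClusterer(BaseEstimator, ClusterMixin):
    """K-means over IC feature vectors with outlier pruning and retention.

    Parameters
    ----------
    k : int
        Number of clusters (chosen by the analyst; a silhouette diagnostic
        is exposed to support the choice, but no automatic selection).
    outlier_sd : float
        Members farther than ``outlier_sd`` times the in-cluster distance SD
        from their centroid are pruned, after which membership is recomputed
        once.
    n_participants : int or None
        Cohort size used for the majority-participant retention rule; a
        cluster is retained only if its members span strictly more than half
        of the cohort.

    Attributes
    ----------
    labels_ : ndarray of int, -1 for pruned outliers
    clusters_ : list of ICCluster
    silhouette_ : float
    """

    def __init__(
        self,
        k: int = 7,
        outlier_sd: float = 3.0,
        random_state: int = 0,
        n_restarts: int = 20,
        n_participants: int | None = None,
    ):
        self.k = k
        self.outlier_sd = outlier_sd
        self.random_state = random_state
        self.n_restarts = n_restarts
        self.n_participants = n_participants

    def fit(self, X, y=None, feature_set: ICFeatureSet | None = None):
        if feature_set is not None:
            X = feature_set.features
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k <= 1:
            raise ValueError(f"k must be > 1, got {self.k}")
        if self.k >= n:
            raise ValueError(f"k={self.k} must be smaller than the number of ICs ({n})")

        # canonical internal order so results do not depend on input order
        if feature_set is not None:
            order = np.array(
                sorted(range(n), key=lambda i: feature_set.provenance[i])
            )
        else:
            order = np.lexsort(np.round(X, 9).T[::-1])
        inv = np.argsort(order)
        Xs = X[order]

        km = KMeans(
            n_clusters=self.k, n_init=self.n_restarts, random_state=self.random_state
        ).fit(Xs)
        labels = km.labels_.copy()
        centroids = km.cluster_centers_.copy()

        # one round of 3-SD outlier pruning, then a single reassignment;
        # the SD of a cluster about its centroid is the RMS member distance
        dist = np.linalg.norm(Xs - centroids[labels], axis=1)
        outlier = np.zeros(n, dtype=bool)
        for c in range(self.k):
            m = labels == c
            if m.sum() >= 3:
                sd = np.sqrt(np.mean(dist[m] ** 2))
                if sd > 0:
                    outlier |= m & (dist > self.outlier_sd * sd)
        if outlier.any():
            for c in range(self.k):
                m = (labels == c) & ~outlier
                if m.any():
                    centroids[c] = Xs[m].mean(axis=0)
            d_all = np.linalg.norm(Xs[:, None, :] - centroids[None], axis=2)
            labels = np.argmin(d_all, axis=1)
        labels = np.where(outlier, -1, labels)

        self.labels_ = labels[inv]
        self.centroids_ = centroids
        self.outliers_ = outlier[inv]
        valid = labels >= 0
        if valid.sum() > self.k and len(np.unique(labels[valid])) > 1:
            self.silhouette_ = float(silhouette_score(Xs[valid], labels[valid]))
        else:
            self.silhouette_ = float("nan")

        self.clusters_ = None
        if feature_set is not None:
            n_cohort = self.n_participants or len(
                {p for p, _ in feature_set.provenance}
            )
            clusters = []
            for c in range(self.k):
                rows = [int(i) for i in np.flatnonzero(self.labels_ == c)]
                members = [feature_set.provenance[i] for i in rows]
                pids = {p for p, _ in members}
                loc = (
                    feature_set.locations_mm[rows].mean(axis=0)
                    if rows
                    else np.full(3, np.nan)
                )
                clusters.append(
                    ICCluster(
                        cluster_index=c,
                        members=members,
                        member_rows=rows,
                        centroid=centroids[c],
                        centroid_location_mm=loc,
                        retained=len(pids) > n_cohort / 2,
                        n_participants_cohort=n_cohort,
                    )
                )
            self.clusters_ = clusters
        return self

    def fit_predict(self, X, y=None, **kwargs):
        return self.fit(X, y, **kwargs).labels_


def cluster_ics(
    feature_set: ICFeatureSet,
    k: int = 7,
    outlier_sd: float = 3.0,
    seed: int = 0,
    n_restarts: int = 20,
    n_participants: int | None = None,
) -> list[ICCluster]:
    """Functional wrapper over :class:`ICClusterer`; returns the clusters."""
    est = ICClusterer(
        k=k,
        outlier_sd=outlier_sd,
        random_state=seed,
        n_restarts=n_restarts,
        n_participants=n_participants,
    )
    est.fit(None, feature_set=feature_set)
    return est.clusters_
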
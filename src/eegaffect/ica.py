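"""Linear blind source separation of rank-reduced EEG.

Any unmixing algorithm meeting the contract is acceptable — the downstream
analysis needs dipolar components, not a particular ICA flavour.  Two
algorithms are exposed: extended Infomax (natural-gradient, the default) and
the fixed-point negentropy iteration (FastICA).  Components are returned in
descending order of projected scalp variance, with a fixed polarity/scale
convention (unit-norm topography, largest-magnitude weight positive) so that
clustering features are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import IcaReady

ALGORITHMS = ("extended-infomax", "fixed-point-negentropy")


class ICATransformer(BaseEstimator, TransformerMixin):
    """Square ICA on (n_samples, n_features) data, sklearn estimator style.

    Parameters
    ----------
    algorithm : {"extended-infomax", "fixed-point-negentropy"}
    random_state : int
        Seeds the algorithm's internal randomness; identical seeds give
        identical decompositions.
    sample_step : int
        Fit on every ``sample_step``-th sample (transform always uses all
        samples); >1 trades estimation variance for speed on long records.

    Attributes
    ----------
    unmixing_ : ndarray (k, k)
        Maps input features to component activations.
    mixing_ : ndarray (k, k)
        Pseudo-inverse of ``unmixing_``; columns are component patterns in
        the input feature space.
    converged_ : bool
    """

    def __init__(
        self,
        algorithm: str = "extended-infomax",
        random_state: int = 0,
        max_iter: int = 500,
        tol: float = 1e-5,
        sample_step: int = 1,
    ):
        self.algorithm = algorithm
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol
        self.sample_step = sample_step

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (n_samples, n_features)")
        n, k = X.shape
        if n <= 20 * k:
            raise ValueError(f"need more than 20 x {k} samples, got {n}")
        var = X.var(axis=0)
        if np.any(var <= 0) or not np.isfinite(X).all():
            raise ValueError("degenerate or non-finite input data")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; use one of {ALGORITHMS}")
        Xf = X[:: max(int(self.sample_step), 1)]

        if self.algorithm == "extended-infomax":
            from mne.preprocessing import infomax

            # whiten, then natural-gradient extended Infomax on the sphered data
            mean = Xf.mean(axis=0)
            cov = np.cov(Xf.T)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            sphere = (evecs / np.sqrt(evals)) @ evecs.T  # symmetric whitener
            Xw = (Xf - mean) @ sphere
            w, n_iter = infomax(
                Xw,
                extended=True,
                max_iter=self.max_iter,
                rng=np.random.RandomState(self.random_state),
                verbose="error",
                return_n_iter=True,
            )
            self.unmixing_ = w @ sphere
            self.n_iter_ = int(n_iter)
            self.converged_ = self.n_iter_ < self.max_iter
        else:
            est = FastICA(
                whiten="unit-variance",
                whiten_solver="eigh",
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                est.fit(Xf)
            self.converged_ = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            self.n_iter_ = int(est.n_iter_)
            self.unmixing_ = est.components_

        self.mixing_ = np.linalg.pinv(self.unmixing_)
        self.n_features_in_ = k
        return self

    def transform(self, X):
        return np.asarray(X) @ self.unmixing_.T


@dataclass
class Decomposition:
    """A fitted ICA decomposition in channel space.

    ``mixing`` columns are unit-norm scalp topographies (average reference);
    ``unmixing @ mixing`` is the identity on the retained subspace and
    ``mixing @ activations`` reconstructs the rank-reduced data.
    """

    unmixing: np.ndarray        # (rank, n_channels)
    mixing: np.ndarray          # (n_channels, rank)
    activations: np.ndarray = field(repr=False)  # (rank, total_samples)
    algorithm: str = "extended-infomax"
    seed: int = 0
    converged: bool = True
    n_epochs: int = 0
    n_samples_per_epoch: int = 0

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    @property
    def topographies(self) -> np.ndarray:
        """Unit-norm scalp patterns, one column per component."""
        return self.mixing

    def epoch_activations(self, index: int) -> np.ndarray:
        """(n_epochs, n_samples) activation of one component."""
        return self.activations[index].reshape(self.n_epochs, self.n_samples_per_epoch)


def _fix_polarity_and_order(
    mixing: np.ndarray, unmixing: np.ndarray, activations: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-norm topographies, positive max weight, variance-ordered."""
    norms = np.linalg.norm(mixing, axis=0)
    norms[norms == 0] = 1.0
    mixing = mixing / norms
    unmixing = unmixing * norms[:, None]
    signs = np.sign(mixing[np.abs(mixing).argmax(axis=0), np.arange(mixing.shape[1])])
    signs[signs == 0] = 1.0
    mixing = mixing * signs
    unmixing = unmixing * signs[:, None]
    activations *= (norms * signs)[:, None]
    # mean projected variance per component: |a_j|^2 var(s_j); |a_j| = 1 here
    proj_var = activations.var(axis=1)
    order = np.argsort(proj_var)[::-1]
    return mixing[:, order], unmixing[order], activations[order]


def run_ica(
    prepared: IcaReady,
    algorithm: str = "extended-infomax",
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    sample_step: int = 1,
) -> Decomposition:
    """Decompose rank-reduced data and express the result in channel space."""
    est = ICATransformer(
        algorithm=algorithm,
        random_state=seed,
        max_iter=max_iter,
        tol=tol,
        sample_step=sample_step,
    )
    est.fit(prepared.scores.T)
    # compose with the orthonormal principal basis to reach channel space
    unmixing = est.unmixing_ @ prepared.basis.T
    mixing = prepared.basis @ est.mixing_
    activations = est.unmixing_ @ prepared.scores
    mixing, unmixing, activations = _fix_polarity_and_order(mixing, unmixing, activations)
    return Decomposition(
        unmixing=unmixing,
        mixing=mixing,
        activations=activations,
        algorithm=algorithm,
        seed=seed,
        converged=bool(est.converged_),
        n_epochs=prepared.n_epochs,
        n_samples_per_epoch=prepared.n_samples_per_epoch,
    )


def amari_index(estimated_unmixing: np.ndarray, true_mixing: np.ndarray) -> float:
    """Amari separation error of ``W @ A`` (0 = perfect up to permutation/scale)."""
    P = np.abs(np.asarray(estimated_unmixing) @ np.asarray(true_mixing))
    k = P.shape[0]
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))
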
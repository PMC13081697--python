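"""Preparation of HMM training data.

Time-delay embedding (TDE) augments each parcel with lagged copies of
itself so that the channel covariance captures autocorrelation, i.e.
spectral, structure.  The embedded data are reduced with a group-level PCA
fitted on the pooled covariance across subjects, then temporally z-scored.

Shapes follow the scikit-learn convention (samples x features) for the
transformers; the module-level :func:`tde_embed` helper additionally
accepts/returns the (channels x samples) orientation used by
:class:`~netstates.containers.ParcelTimeSeries`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ParcelTimeSeries


@dataclass
class EmbeddingConfig:
    n_lags_each_side: int = 7
    n_pca_components: int = 120
    whiten: bool = False

    def __post_init__(self) -> None:
        if self.n_lags_each_side < 0:
            raise ValueError("n_lags_each_side must be >= 0")
        if self.n_pca_components < 1:
            raise ValueError("n_pca_components must be >= 1")


class TimeDelayEmbedding(TransformerMixin, BaseEstimator):
    """Augment channels with time-lagged copies.

    ``transform`` maps (n_samples, n_parcels) to
    (n_samples - 2 L, n_parcels * (2 L + 1)); the 2 L boundary samples are
    trimmed rather than zero-padded.  Output channels are parcel-major with
    the lag running from -L to +L.
    """

    def __init__(self, n_lags_each_side: int = 7):
        self.n_lags_each_side = n_lags_each_side

    def fit(self, X=None, y=None):
        if self.n_lags_each_side < 0:
            raise ValueError("n_lags_each_side must be >= 0")
        self.n_lags_each_side_ = int(self.n_lags_each_side)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        self.fit()
        L = self.n_lags_each_side_
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x parcels)")
        T, p = X.shape
        if T <= 2 * L:
            raise ValueError(f"need more than {2 * L} samples, got {T}")
        if L == 0:
            return X.copy()
        Tp = T - 2 * L
        out = np.empty((Tp, p * (2 * L + 1)))
        for parcel in range(p):
            for j, lag in enumerate(range(-L, L + 1)):
                out[:, parcel * (2 * L + 1) + j] = X[L + lag : L + lag + Tp, parcel]
        return out

    @staticmethod
    def n_embedded_channels(n_parcels: int, n_lags_each_side: int) -> int:
        return n_parcels * (2 * n_lags_each_side + 1)

    @staticmethod
    def window_ms(n_lags_each_side: int, sampling_rate_hz: float) -> float:
        """Half-width of the embedding window in milliseconds."""
        return 1000.0 * n_lags_each_side / sampling_rate_hz


def tde_embed(ts, n_lags_each_side: int) -> np.ndarray:
    """Time-delay embed a recording, (channels x samples) orientation.

    Accepts a :class:`ParcelTimeSeries` or a (parcels x samples) array and
    returns (parcels * (2 L + 1)) x (samples - 2 L).
    """
    data = ts.data if isinstance(ts, ParcelTimeSeries) else np.asarray(ts, dtype=float)
    emb = TimeDelayEmbedding(n_lags_each_side).fit().transform(data.T)
    return emb.T


class GroupPCA(TransformerMixin, BaseEstimator):
    """PCA fitted on the pooled covariance of several subjects.

    The covariance is accumulated subject-by-subject (bounded memory) and
    is defined to equal the PCA of the time-concatenated data.  The sign of
    each component is fixed so its largest-magnitude loading is positive,
    making runs comparable.

    Attributes
    ----------
    components_ : ndarray (n_components, n_channels)
    mean_ : ndarray (n_channels,)
    explained_variance_ : ndarray (n_components,)
    explained_variance_ratio_ : ndarray (n_components,)
    """

    def __init__(self, n_components: int = 120, whiten: bool = False):
        self.n_components = n_components
        self.whiten = whiten

    def fit(self, X, y=None):
        subjects = [np.asarray(s, dtype=float) for s in _as_subject_list(X)]
        d = subjects[0].shape[1]
        if any(s.shape[1] != d for s in subjects):
            raise ValueError("all subjects must share the channel count")
        if self.n_components > d:
            raise ValueError(
                f"n_components ({self.n_components}) exceeds channels ({d})"
            )
        n_total = sum(s.shape[0] for s in subjects)
        if n_total < d:
            raise ValueError("fewer total samples than embedded channels")
        total = np.zeros(d)
        outer = np.zeros((d, d))
        for s in subjects:
            total += s.sum(axis=0)
            outer += s.T @ s
        mean = total / n_total
        cov = (outer - n_total * np.outer(mean, mean)) / (n_total - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][: self.n_components]
        evals_sorted = np.clip(evals[np.argsort(evals)[::-1]], 0.0, None)
        comps = evecs[:, order].T
        # deterministic sign: largest-|loading| element positive
        for c in comps:
            if c[np.argmax(np.abs(c))] < 0:
                c *= -1
        self.mean_ = mean
        self.components_ = comps
        self.explained_variance_ = np.clip(evals[order], 0.0, None)
        tv = evals_sorted.sum()
        self.explained_variance_ratio_ = self.explained_variance_ / tv
        self.n_samples_seen_ = n_total
        return self

    def transform(self, X):
        single = not _is_subject_list(X)
        out = []
        for s in _as_subject_list(X):
            z = (np.asarray(s, dtype=float) - self.mean_) @ self.components_.T
            if self.whiten:
                z /= np.sqrt(self.explained_variance_)
            out.append(z)
        return out[0] if single else out

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        if self.whiten:
            Z = Z * np.sqrt(self.explained_variance_)
        return Z @ self.components_ + self.mean_


def _is_subject_list(X) -> bool:
    return isinstance(X, (list, tuple))


def _as_subject_list(X) -> list:
    return list(X) if _is_subject_list(X) else [X]


def fit_group_pca(embedded_subjects, n_components: int) -> GroupPCA:
    """Fit a :class:`GroupPCA` on (samples x channels) subject arrays."""
    return GroupPCA(n_components=n_components).fit(embedded_subjects)


def standardize(X: np.ndarray, axis: int = 0) -> np.ndarray:
    """Z-score each channel over time (zero mean, unit variance).

    ``axis`` is the time axis.  Raises on constant channels, naming the
    first offender.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(np.squeeze(sd, axis=axis) == 0)[0])
        raise ValueError(f"channel {bad} is constant; cannot standardise")
    return (X - X.mean(axis=axis, keepdims=True)) / sd


def prepare_subjects(
    series: list, cfg: EmbeddingConfig | None = None
) -> tuple[list, GroupPCA]:
    """Full preparation: TDE -> group PCA -> temporal standardisation.

    Parameters
    ----------
    series : list of ParcelTimeSeries
    cfg : EmbeddingConfig

    Returns
    -------
    prepared : list of (samples' x n_pca_components) arrays
    pca : fitted GroupPCA
    """
    cfg = cfg or EmbeddingConfig()
    tde = TimeDelayEmbedding(cfg.n_lags_each_side).fit()
    embedded = [tde.transform(ts.data.T) for ts in series]
    pca = GroupPCA(cfg.n_pca_components, whiten=cfg.whiten).fit(embedded)
    return [standardize(pca.transform(e)) for e in embedded], pca
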
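"""Zero-mean Gaussian-covariance hidden Markov model.

Each hidden state k emits ``x_t ~ N(0, D_k)``; the mean is forced to zero
so the states model covariance (connectivity and, through time-delay
embedding, spectral) structure only.  Transitions follow a first-order
Markov chain with matrix ``A``.

Inference is full-batch Baum-Welch EM: scaled forward-backward posteriors
(numerically safe for sequences of 1e5+ samples; the numba-compiled
recursion works on per-row max-shifted likelihoods, equivalent to log-space
arithmetic) with maximum-likelihood M-steps and a small diagonal
regularisation on the state covariances.  Training is restarted from
several random initialisations and the run with the lowest free energy
(negative log-likelihood, lower is better) is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import linalg as sla
from sklearn.base import BaseEstimator


@dataclass
class TrainConfig:
    n_states: int = 10
    n_runs: int = 5
    max_iter: int = 100
    tol: float = 1e-6
    reg: float = 1e-5  # diagonal regularisation, relative to the mean variance
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1 or self.n_runs < 1 or self.reg < 0:
            raise ValueError("invalid training configuration")


@dataclass
class FitDiagnostics:
    """Objective traces and run-selection bookkeeping."""

    traces: list = field(default_factory=list)  # log-likelihood per iteration, per run
    final_free_energy: list = field(default_factory=list)
    selected_run: int = 0
    converged: bool = False


@njit(cache=True)
def _forward_backward(logB, A, pi0):  # pragma: no cover - compiled
    """Scaled forward-backward.

    logB : (T, K) framewise log-likelihoods.
    Returns (gamma (T, K), xi_sum (K, K), loglik).
    """
    T, K = logB.shape
    B = np.empty((T, K))
    shift = np.empty(T)
    for t in range(T):
        m = logB[t, 0]
        for k in range(1, K):
            if logB[t, k] > m:
                m = logB[t, k]
        shift[t] = m
        for k in range(K):
            B[t, k] = np.exp(logB[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi0[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            a = 0.0
            for i in range(K):
                a += alpha[t - 1, i] * A[i, j]
            a *= B[t, j]
            alpha[t, j] = a
            s += a
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            b = 0.0
            for j in range(K):
                b += A[i, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, i] = b / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(1, T):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t - 1, i] * A[i, j] * B[t, j] * beta[t, j] / c[t]
                )

    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + shift[t]
    return gamma, xi_sum, loglik


def _framewise_loglik(X: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """(T, K) log N(x_t | 0, D_k) via Cholesky factors."""
    T, d = X.shape
    K = covariances.shape[0]
    out = np.empty((T, K))
    const = -0.5 * d * np.log(2.0 * np.pi)
    for k in range(K):
        L = np.linalg.cholesky(covariances[k])
        z = sla.solve_triangular(L, X.T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = const - 0.5 * logdet - 0.5 * (z**2).sum(axis=0)
    return out


class GaussianCovarianceHMM(BaseEstimator):
    """Hidden Markov model with zero-mean Gaussian state covariances.

    Parameters
    ----------
    n_states : int
        Number of hidden states K.
    n_runs : int
        Independent training restarts; the run with the lowest free energy
        is selected (ties go to the lowest run index).
    max_iter, tol : int, float
        EM iterations and relative objective-change convergence threshold.
    reg : float
        Diagonal covariance regularisation as a fraction of the mean
        channel variance; guards against singular accumulated covariances.
    random_state : int or None
        Seeds initialisation; fixed seed gives reproducible fits.

    Attributes
    ----------
    covariances_ : ndarray (K, d, d)
    transmat_ : ndarray (K, K)
    startprob_ : ndarray (K,)
    free_energy_ : float
        Negative log-likelihood of the training data under the selected run.
    diagnostics_ : FitDiagnostics
    """

    def __init__(
        self,
        n_states: int = 10,
        n_runs: int = 5,
        max_iter: int = 100,
        tol: float = 1e-6,
        reg: float = 1e-5,
        random_state: int | None = None,
    ):
        self.n_states = n_states
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.reg = reg
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_list(X) -> list:
        if isinstance(X, (list, tuple)):
            subjects = [np.ascontiguousarray(s, dtype=float) for s in X]
        else:
            subjects = [np.ascontiguousarray(X, dtype=float)]
        d = subjects[0].shape[1]
        for s in subjects:
            if s.ndim != 2 or s.shape[1] != d:
                raise ValueError("all subjects must be (samples x channels) with equal channels")
        return subjects

    def _m_step(self, subjects, gammas, xi_sums, reg_eps):
        K = self.n_states
        d = subjects[0].shape[1]
        weights = np.zeros(K)
        scatter = np.zeros((K, d, d))
        for X, g in zip(subjects, gammas):
            weights += g.sum(axis=0)
            for k in range(K):
                scatter[k] += (X * g[:, k : k + 1]).T @ X
        covs = scatter / weights[:, None, None]
        covs += reg_eps * np.eye(d)
        xi = sum(xi_sums)
        rows = xi.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xi / np.where(rows == 0, 1.0, rows), 1.0 / K)
        pi0 = np.mean([g[0] for g in gammas], axis=0)
        pi0 /= pi0.sum()
        return covs, A, pi0

    def _e_step(self, subjects, covs, A, pi0):
        gammas, xi_sums = [], []
        loglik = 0.0
        for X in subjects:
            logB = _framewise_loglik(X, covs)
            g, xi, ll = _forward_backward(logB, A, pi0)
            gammas.append(g)
            xi_sums.append(xi)
            loglik += ll
        return gammas, xi_sums, loglik

    def _single_run(self, subjects, rng, reg_eps):
        K = self.n_states
        # random responsibilities -> M-step gives the initial covariances;
        # sticky initial transition matrix is standard for slow switching.
        gammas0 = []
        for X in subjects:
            g = rng.random((X.shape[0], K)) + 0.1
            g /= g.sum(axis=1, keepdims=True)
            gammas0.append(g)
        A = 0.8 * np.eye(K) + 0.2 / K
        A /= A.sum(axis=1, keepdims=True)
        xi0 = [A * 0 + 1.0 / K]
        covs, _, pi0 = self._m_step(subjects, gammas0, xi0, reg_eps)
        pi0 = np.full(K, 1.0 / K)

        trace = []
        prev = -np.inf
        converged = False
        gammas = gammas0
        for _ in range(self.max_iter):
            gammas, xi_sums, loglik = self._e_step(subjects, covs, A, pi0)
            trace.append(loglik)
            if prev > -np.inf and abs(loglik - prev) <= self.tol * abs(prev):
                converged = True
                break
            prev = loglik
            covs, A, pi0 = self._m_step(subjects, gammas, xi_sums, reg_eps)
        return covs, A, pi0, gammas, trace, converged

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        subjects = self._as_list(X)
        if any(s.shape[0] < self.n_states for s in subjects):
            raise ValueError("each subject needs at least K samples")
        mean_var = float(np.mean([s.var(axis=0).mean() for s in subjects]))
        reg_eps = self.reg * mean_var
        if reg_eps == 0:
            # probe for degenerate data up front
            pooled = sum(s.T @ s for s in subjects)
            if np.linalg.matrix_rank(pooled) < subjects[0].shape[1]:
                raise np.linalg.LinAlgError(
                    "singular accumulated covariance; set reg > 0"
                )
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_runs)
        diag = FitDiagnostics()
        best = None
        for r in range(self.n_runs):
            rng = np.random.default_rng(seeds[r])
            covs, A, pi0, gammas, trace, conv = self._single_run(
                subjects, rng, reg_eps
            )
            fe = -trace[-1]
            diag.traces.append(trace)
            diag.final_free_energy.append(fe)
            if best is None or fe < best[0]:
                best = (fe, r, covs, A, pi0, conv)
        fe, r, covs, A, pi0, conv = best
        diag.selected_run = r
        diag.converged = conv
        self.covariances_ = covs
        self.transmat_ = A
        self.startprob_ = pi0
        self.free_energy_ = fe
        self.diagnostics_ = diag
        self.n_channels_ = subjects[0].shape[1]
        return self

    def _check_channels(self, subjects):
        if subjects[0].shape[1] != self.n_channels_:
            raise ValueError(
                f"channel mismatch: model has {self.n_channels_}, "
                f"data has {subjects[0].shape[1]}"
            )

    def predict_proba(self, X):
        """Marginal state probabilities gamma, (T, K) per subject."""
        subjects = self._as_list(X)
        self._check_channels(subjects)
        out = []
        for s in subjects:
            logB = _framewise_loglik(s, self.covariances_)
            g, _, _ = _forward_backward(logB, self.transmat_, self.startprob_)
            out.append(g)
        return out if isinstance(X, (list, tuple)) else out[0]

    def predict(self, X):
        """Maximum a posteriori (marginal) state sequence per subject."""
        g = self.predict_proba(X)
        if isinstance(g, list):
            return [gg.argmax(axis=1) for gg in g]
        return g.argmax(axis=1)

    def score(self, X, y=None):
        """Total log-likelihood of the data."""
        subjects = self._as_list(X)
        self._check_channels(subjects)
        total = 0.0
        for s in subjects:
            logB = _framewise_loglik(s, self.covariances_)
            _, _, ll = _forward_backward(logB, self.transmat_, self.startprob_)
            total += ll
        return total

    def free_energy(self, X):
        """Negative log-likelihood; lower is a better description of the data."""
        return -self.score(X)


def free_energy(model: GaussianCovarianceHMM, X) -> float:
    return model.free_energy(X)


def select_best_run(models: list) -> GaussianCovarianceHMM:
    """Model with the lowest free energy; ties go to the lowest index."""
    if not models:
        raise ValueError("no fitted models supplied")
    fes = [m.free_energy_ for m in models]
    return models[int(np.argmin(fes))]


def fit_hmm(data, cfg: TrainConfig | None = None):
    """Train with restarts and return ``(model, posteriors, diagnostics)``."""
    cfg = cfg or TrainConfig()
    model = GaussianCovarianceHMM(
        n_states=cfg.n_states,
        n_runs=cfg.n_runs,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        reg=cfg.reg,
        random_state=cfg.seed,
    ).fit(data)
    gammas = model.predict_proba(data)
    return model, gammas, model.diagnostics_


def match_states_by_covariance(
    cov_true: np.ndarray, cov_est: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Match estimated to true states by covariance correlation.

    Solves the assignment maximising the Pearson correlation between the
    vectorised covariances.  Returns ``(perm, corrs)`` where ``perm[k]`` is
    the estimated state matched to true state ``k``.
    """
    from scipy.optimize import linear_sum_assignment

    K = cov_true.shape[0]
    corr = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            corr[i, j] = np.corrcoef(cov_true[i].ravel(), cov_est[j].ravel())[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


def match_states_by_overlap(
    seq_true: np.ndarray, seq_est: np.ndarray, n_states: int
) -> np.ndarray:
    """Match estimated to true states by time-course overlap.

    Returns ``perm`` with ``perm[k]`` the estimated label matched to true
    label ``k`` (maximum-overlap assignment).
    """
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((n_states, n_states))
    np.add.at(conf, (np.asarray(seq_true), np.asarray(seq_est)), 1)
    rows, cols = linear_sum_assignment(-conf)
    return cols
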
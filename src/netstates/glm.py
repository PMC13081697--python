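"""Group-level inference with confound-aware permutation GLMs.

A general linear model ``y = X beta + eps`` is fitted by ordinary least
squares across subjects, with the regressor of interest (age or the
PCA-reduced cognitive performance score) alongside a comprehensive set of
standardised confounds.  Significance is assessed
non-parametrically with random per-subject sign-flips under the
confound-aware Freedman-Lane scheme: per permutation the GLM is refitted
once for all features jointly and the maximum absolute statistic across
features is recorded, giving a single null distribution that controls the
family-wise error rate across all features tested together.

The regression coefficient is the default test statistic; the t-statistic
is available for feature sets with heterogeneous effect scales (the
dynamics summary statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: Confound columns used alongside an age regressor.
DEFAULT_CONFOUNDS = (
    "sex",
    "total_brain_vol",
    "gm_vol",
    "wm_vol",
    "head_size",
    "head_pos_x",
    "head_pos_y",
    "head_pos_z",
)


def reduce_scores_pca(scores) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a battery of cognitive task scores.

    Tasks are z-scored column-wise before the PCA.  The component's sign is
    fixed so the mean loading is positive: an increase in the summary score
    then means an increase across the tasks.

    Returns
    -------
    pc1 : (n_subjects,) subject scores on the first component
    loadings : (n_tasks,) loadings of each task
    variance_explained : fraction of total variance in the first component
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 subjects and 2 tasks")
    if np.any(np.isnan(X)):
        raise ValueError("scores contain missing values")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError(f"task column {int(np.flatnonzero(sd == 0)[0])} is constant")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    pc1 = Z @ loadings
    if loadings.mean() < 0:
        loadings, pc1 = -loadings, -pc1
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return pc1, loadings, var_explained


@dataclass
class DesignMatrix:
    """Standardised design matrix with named regressors."""

    X: np.ndarray
    names: list
    interest: str

    @property
    def interest_index(self) -> int:
        return self.names.index(self.interest)

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


def build_design(
    covariates: pd.DataFrame, interest: str, confounds=()
) -> DesignMatrix:
    """Design matrix: constant + interest + confounds, all z-scored.

    Non-constant columns are standardised across subjects.  Rank deficiency
    (a pair of columns with |correlation| ~ 1) raises, naming the pair.
    """
    names = [interest] + [c for c in confounds]
    for name in names:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not found")
    cols = []
    for name in names:
        v = covariates[name].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"regressor {name!r} is constant")
        cols.append((v - v.mean()) / sd)
    Z = np.column_stack(cols)
    if len(names) > 1:
        corr = np.corrcoef(Z, rowvar=False)
        iu, ju = np.triu_indices(len(names), k=1)
        bad = np.abs(corr[iu, ju]) > 1 - 1e-10
        if bad.any():
            b = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"regressors {names[iu[b]]!r} and {names[ju[b]]!r} are collinear"
            )
    X = np.column_stack([np.ones(Z.shape[0]), Z])
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than regressors")
    return DesignMatrix(X=X, names=["constant"] + names, interest=interest)


@dataclass
class GLMResult:
    beta: np.ndarray  # (n_regressors, n_features)
    residuals: np.ndarray  # (n_subjects, n_features)
    residual_variance: np.ndarray  # (n_features,)
    dof: int


def fit_glm(y: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary-least-squares fit of all features jointly."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.ndim == 2 and y.shape[0] != design.n_subjects:
        raise ValueError("y rows must match design subjects")
    if np.any(np.isnan(y)):
        raise ValueError("y contains missing values; drop subjects per feature first")
    X = design.X
    n, k = X.shape
    if n < k + 1:
        raise ValueError("fewer subjects than regressors + 1")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    resid_var = (resid**2).sum(axis=0) / dof
    return GLMResult(beta=beta, residuals=resid, residual_variance=resid_var, dof=dof)


def _interest_stat(X, pinvX, xtx_inv_ii, y, interest_idx, stat):
    """|beta| or |t| of the interest regressor, per feature."""
    beta = pinvX @ y
    b = beta[interest_idx]
    if stat == "beta":
        return np.abs(b)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    resid_var = (resid**2).sum(axis=0) / dof
    se = np.sqrt(resid_var * xtx_inv_ii)
    se = np.where(se == 0, np.inf, se)
    return np.abs(b / se)


@dataclass
class PermResult:
    observed: np.ndarray  # |stat| per feature
    beta: np.ndarray  # signed interest coefficient per feature
    null_max: np.ndarray  # (n_perm,)
    pvalues: np.ndarray
    significant: np.ndarray
    stat: str
    seed: int | None = None
    n_dropped: dict = field(default_factory=dict)


def maxstat_signflip_test(
    y: np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    stat: str = "beta",
    seed=None,
    alpha: float = 0.05,
) -> PermResult:
    """Sign-flip max-statistic permutation test on the interest regressor.

    Each of ``n_perm`` permutations draws an independent +-1 flip (50%
    chance each) per subject, refits the GLM once for all features
    jointly, and records the maximum absolute statistic across features,
    giving a single family-wise-error-controlling null distribution.
    Because confounds correlate with the regressor of interest, the flips
    are applied within the Freedman-Lane scheme of Winkler et al.: the
    data are residualised against the confounds (everything but the
    interest column), the residuals are sign-flipped, and the full model
    is refitted - this keeps the null calibrated, which naive flipping of
    the interest column itself does not.  P-values use the positively
    biased estimator ``(1 + #{null >= obs}) / (1 + n_perm)`` so they are
    valid (never zero) and the identity permutation need not be forced
    into the null.

    Features with missing values are handled per feature: subjects missing
    a feature are dropped for that feature only (features sharing a
    missingness pattern are fitted jointly), and the max statistic is still
    taken across all features within each permutation.
    """
    if stat not in ("beta", "t"):
        raise ValueError("stat must be 'beta' or 't'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if design.interest not in design.names:
        raise ValueError(f"interest regressor {design.interest!r} not in the design")
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != design.n_subjects:
        y = y.T
    if y.shape[0] != design.n_subjects:
        raise ValueError("y must have one row per subject")
    n, f = y.shape
    idx = design.interest_index
    rng = np.random.default_rng(seed)

    # group features by missingness pattern so each group is fitted jointly
    missing = np.isnan(y)
    patterns: dict[bytes, list] = {}
    for j in range(f):
        patterns.setdefault(missing[:, j].tobytes(), []).append(j)
    n_dropped = {}

    observed = np.empty(f)
    signed = np.empty(f)
    null_max = np.full(n_perm, -np.inf)
    flips = np.where(rng.random((n_perm, n)) < 0.5, -1.0, 1.0)

    for key, feats in patterns.items():
        keep = ~np.frombuffer(key, dtype=bool)
        dropped = int(n - keep.sum())
        if dropped:
            for j in feats:
                n_dropped[j] = dropped
            logger.info("dropping %d subjects for features %s", dropped, feats)
        Xk = design.X[keep]
        if Xk.shape[0] < Xk.shape[1] + 1:
            raise ValueError("too few complete subjects for a feature block")
        yk = y[np.ix_(keep, feats)]
        pinvX = np.linalg.pinv(Xk)
        xtx_inv_ii = np.linalg.inv(Xk.T @ Xk)[idx, idx]
        signed[feats] = (pinvX @ yk)[idx]
        observed[feats] = _interest_stat(Xk, pinvX, xtx_inv_ii, yk, idx, stat)
        # Freedman-Lane: residualise against confounds, flip, refit full model.
        # Residuals are rescaled by 1/sqrt(1 - h_ii) (confound-model leverage)
        # so their variance matches the error variance; without this the
        # null is narrower than the observed statistic by (n - k)/n.
        Z = np.delete(Xk, idx, axis=1)
        pinvZ = np.linalg.pinv(Z)
        ez = yk - Z @ (pinvZ @ yk)
        leverage = np.einsum("ij,ji->i", Z, pinvZ)
        ez = ez / np.sqrt(np.clip(1.0 - leverage, 1e-12, None))[:, None]
        for p in range(n_perm):
            ystar = flips[p, keep][:, None] * ez
            m = _interest_stat(Xk, pinvX, xtx_inv_ii, ystar, idx, stat).max()
            if m > null_max[p]:
                null_max[p] = m

    # tolerance makes exact ties (and roundoff dust on degenerate targets)
    # count as null >= observed
    pvals = (
        1.0 + (null_max[None, :] >= observed[:, None] - 1e-12).sum(axis=1)
    ) / (1.0 + n_perm)
    return PermResult(
        observed=observed,
        beta=signed,
        null_max=null_max,
        pvalues=pvals,
        significant=pvals < alpha,
        stat=stat,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        n_dropped=n_dropped,
    )


class SignFlipMaxStatGLM(BaseEstimator):
    """Estimator wrapper around the sign-flip max-statistic permutation GLM.

    Parameters
    ----------
    interest : str
        Name of the regressor of interest in the covariate table.
    confounds : sequence of str
        Confound columns (standardised, fitted, but never permuted).
    n_perm : int
    stat : {"beta", "t"}
    random_state : int or None

    Attributes (after ``fit(covariates, y)``)
    ----------
    design_ : DesignMatrix
    beta_ : signed interest coefficients per feature
    pvalues_, significant_, null_max_ : permutation results
    """

    def __init__(
        self,
        interest: str = "age",
        confounds=DEFAULT_CONFOUNDS,
        n_perm: int = 1000,
        stat: str = "beta",
        alpha: float = 0.05,
        random_state=None,
    ):
        self.interest = interest
        self.confounds = confounds
        self.n_perm = n_perm
        self.stat = stat
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y: np.ndarray):
        self.design_ = build_design(X, self.interest, self.confounds)
        res = maxstat_signflip_test(
            y,
            self.design_,
            n_perm=self.n_perm,
            stat=self.stat,
            seed=self.random_state,
            alpha=self.alpha,
        )
        self.result_ = res
        self.beta_ = res.beta
        self.observed_ = res.observed
        self.pvalues_ = res.pvalues
        self.significant_ = res.significant
        self.null_max_ = res.null_max
        return self
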
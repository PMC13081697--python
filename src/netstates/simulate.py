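"""Synthetic cohort generation.

Generates Markov-switching oscillatory parcel time courses together with a
covariate table (age, sex, anatomical and head-geometry confounds, cognitive
task scores) in which configurable covariate effects modulate state dynamics,
oscillatory power and inter-parcel coupling.  Every downstream stage of the
pipeline can therefore be validated against ground truth.

Oscillators are damped AR(2) resonators (pole radius fixed at 0.95) excited
by white noise; parcels in a coupling group share the driving noise source,
which induces coherence at the resonance frequency.  Covariate effects act
on the logit of transition probabilities (rows stay stochastic) and
multiplicatively on oscillator gains (gains stay nonnegative).  State labels
are 0-based integers throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import GroundTruth, ParcelTimeSeries

# Pole radius of the AR(2) resonators.  Close to 1 gives narrow spectral
# peaks; fixed rather than configurable so StateSpec stays interpretable.
_AR2_DAMPING = 0.95

_ROW_SUM_TOL = 1e-8


@dataclass
class StateSpec:
    """Observation model of one hidden state.

    Parameters
    ----------
    oscillator_freq_hz : array-like, shape (n_parcels,)
        Resonance frequency per parcel; 0 means broadband white noise.
    oscillator_gain : array-like, shape (n_parcels,)
        Amplitude (standard deviation units) of the unit-variance
        oscillatory component per parcel.  Must be nonnegative.
    coupling_groups : sequence of sequences of int
        Sets of parcel indices driven by a shared noise source.
    noise_sd : float
        Standard deviation of additive observation noise.
    """

    oscillator_freq_hz: np.ndarray
    oscillator_gain: np.ndarray
    coupling_groups: tuple = ()
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.oscillator_freq_hz = np.atleast_1d(
            np.asarray(self.oscillator_freq_hz, dtype=float)
        )
        self.oscillator_gain = np.atleast_1d(
            np.asarray(self.oscillator_gain, dtype=float)
        )
        if self.oscillator_freq_hz.shape != self.oscillator_gain.shape:
            raise ValueError("freq and gain arrays must have the same shape")
        if np.any(self.oscillator_gain < 0):
            raise ValueError("oscillator gains must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        n = self.oscillator_freq_hz.size
        self.coupling_groups = tuple(tuple(int(i) for i in g) for g in self.coupling_groups)
        for g in self.coupling_groups:
            if any(i < 0 or i >= n for i in g):
                raise ValueError(f"coupling group {g} references an unknown parcel")

    @property
    def n_parcels(self) -> int:
        return self.oscillator_freq_hz.size


@dataclass
class Effect:
    """A linear covariate effect planted in the generator.

    ``feature`` is one of ``"stay_probability"`` (acts on the logit of a
    state's self-transition probability), ``"gain"`` (multiplicative,
    ``exp(slope * z(covariate))``, on a state/parcel oscillator gain) or
    ``"coupling"`` (logit of a coupling-group mixing weight).
    """

    covariate: str
    feature: str
    slope: float
    state: int = 0
    parcel: int | None = None
    group: int | None = None

    _FEATURES = ("stay_probability", "gain", "coupling")

    def __post_init__(self) -> None:
        if self.feature not in self._FEATURES:
            raise ValueError(f"unknown feature {self.feature!r}; one of {self._FEATURES}")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort."""

    n_subjects: int
    n_parcels: int
    n_samples: int
    state_specs: list
    base_transition_matrix: np.ndarray
    sampling_rate_hz: float = 250.0
    effect_map: list = field(default_factory=list)
    n_cog_scores: int = 10
    latent_cog_age_slope: float = -0.5
    cog_noise_sd: float = 1.0
    age_range: tuple = (18.0, 88.0)
    gain_jitter_sd: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_parcels, self.n_samples) <= 0:
            raise ValueError("n_subjects, n_parcels, n_samples must be positive")
        self.base_transition_matrix = np.asarray(self.base_transition_matrix, dtype=float)
        _validate_stochastic(self.base_transition_matrix)
        if len(self.state_specs) != self.base_transition_matrix.shape[0]:
            raise ValueError("number of state specs must equal transition-matrix size")
        for spec in self.state_specs:
            if spec.n_parcels != self.n_parcels:
                raise ValueError("state spec parcel count differs from n_parcels")
        for eff in self.effect_map:
            if not 0 <= eff.state < self.n_states:
                raise ValueError(f"effect references unknown state {eff.state}")
            if eff.feature == "gain":
                if eff.parcel is None or not 0 <= eff.parcel < self.n_parcels:
                    raise ValueError(f"gain effect references unknown parcel {eff.parcel}")
            if eff.feature == "coupling":
                groups = self.state_specs[eff.state].coupling_groups
                if eff.group is None or not 0 <= eff.group < len(groups):
                    raise ValueError(f"coupling effect references unknown group {eff.group}")

    @property
    def n_states(self) -> int:
        return len(self.state_specs)


def _validate_stochastic(a: np.ndarray) -> None:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("transition probabilities must lie in [0, 1]")
    rows = a.sum(axis=1)
    if np.any(np.abs(rows - 1.0) > _ROW_SUM_TOL):
        bad = int(np.argmax(np.abs(rows - 1.0)))
        raise ValueError(f"row {bad} of the transition matrix sums to {rows[bad]}, not 1")


def stationary_distribution(a: np.ndarray) -> np.ndarray:
    """Stationary distribution pi of a stochastic matrix (pi A = pi)."""
    _validate_stochastic(a)
    vals, vecs = np.linalg.eig(a.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    return pi / pi.sum()


def simulate_state_sequence(
    a: np.ndarray,
    n_samples: int,
    initial: np.ndarray | int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Sample a Markov chain of hidden states.

    Parameters
    ----------
    a : ndarray, shape (K, K)
        Transition matrix; ``a[i, j]`` is P(state j at t | state i at t-1).
    n_samples : int
        Length of the sequence.
    initial : int, K-vector, or None
        Initial state, initial distribution, or None for the stationary
        distribution of ``a``.
    rng : Generator or int seed

    Returns
    -------
    ndarray of int, shape (n_samples,), values in 0..K-1.
    """
    _validate_stochastic(a)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(rng)
    k = a.shape[0]
    if initial is None:
        p0 = stationary_distribution(a)
    elif np.isscalar(initial):
        p0 = np.zeros(k)
        p0[int(initial)] = 1.0
    else:
        p0 = np.asarray(initial, dtype=float)
        if abs(p0.sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError("initial distribution must sum to 1")
    # Sample by inverse-CDF against pre-drawn uniforms: one pass, reproducible.
    cdf = np.cumsum(a, axis=1)
    u = rng.random(n_samples)
    states = np.empty(n_samples, dtype=np.int64)
    states[0] = np.searchsorted(np.cumsum(p0), u[0], side="right")
    for t in range(1, n_samples):
        states[t] = np.searchsorted(cdf[states[t - 1]], u[t], side="right")
    np.clip(states, 0, k - 1, out=states)
    return states


def _ar2_resonator(driver: np.ndarray, freq_hz: float, fs: float) -> np.ndarray:
    """Filter white noise through a damped AR(2) resonator, unit variance out."""
    if freq_hz <= 0:
        out = driver
    else:
        w = 2.0 * np.pi * freq_hz / fs
        a = [1.0, -2.0 * _AR2_DAMPING * np.cos(w), _AR2_DAMPING**2]
        out = signal.lfilter([1.0], a, driver)
    sd = out.std()
    return out / sd if sd > 0 else out


def _state_latent_signals(
    spec: StateSpec,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
    coupling_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-variance oscillatory component per parcel for one state.

    Parcels in a coupling group mix a shared filtered source with an
    independent one: ``w * shared + sqrt(1 - w^2) * own`` keeps unit
    variance while setting the zero-lag coupling strength to ``w``.
    """
    p = spec.n_parcels
    group_of = {}
    for gi, g in enumerate(spec.coupling_groups):
        for parcel in g:
            group_of[parcel] = gi
    shared = {
        gi: rng.standard_normal(n_samples) for gi in range(len(spec.coupling_groups))
    }
    if coupling_weights is None:
        coupling_weights = np.ones(len(spec.coupling_groups))
    out = np.empty((p, n_samples))
    for parcel in range(p):
        f = spec.oscillator_freq_hz[parcel]
        if parcel in group_of:
            gi = group_of[parcel]
            w = float(coupling_weights[gi])
            s = _ar2_resonator(shared[gi], f, fs)
            if w < 1.0:
                own = _ar2_resonator(rng.standard_normal(n_samples), f, fs)
                s = w * s + np.sqrt(1.0 - w**2) * own
        else:
            s = _ar2_resonator(rng.standard_normal(n_samples), f, fs)
        out[parcel] = spec.oscillator_gain[parcel] * s
    return out


def simulate_subject_signals(
    states: np.ndarray,
    specs: list,
    fs: float,
    rng: np.random.Generator | int | None = None,
    coupling_weights: dict | None = None,
) -> ParcelTimeSeries:
    """Generate parcel time courses for a given hidden-state sequence.

    Each state's stationary oscillatory process runs for the whole recording
    and the observed signal switches between them sample-wise (abrupt
    switching, matching the piecewise-stationary hidden Markov assumption).

    Parameters
    ----------
    states : int array, shape (n_samples,)
        Hidden state per sample, values in 0..K-1.
    specs : list of StateSpec, length K
    fs : float
        Sampling rate in Hz.
    coupling_weights : dict, optional
        ``{state: array of per-group mixing weights}`` overriding the
        default weight of 1 (fully shared source).
    """
    states = np.asarray(states)
    k = len(specs)
    if states.min() < 0 or states.max() >= k:
        raise ValueError("state index outside 0..K-1")
    rng = np.random.default_rng(rng)
    t = states.size
    p = specs[0].n_parcels
    data = np.zeros((p, t))
    noise = rng.standard_normal((p, t))
    for ki, spec in enumerate(specs):
        cw = None if coupling_weights is None else coupling_weights.get(ki)
        latent = _state_latent_signals(spec, t, fs, rng, cw)
        mask = states == ki
        data[:, mask] = latent[:, mask] + spec.noise_sd * noise[:, mask]
    return ParcelTimeSeries(data, fs)


def simulate_cognitive_scores(
    age: np.ndarray,
    n_scores: int,
    latent_slope: float,
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Cognitive task scores driven by one latent performance factor.

    ``scores = loadings (positive) x latent + noise`` with
    ``latent = latent_slope * z(age) + residual``; all pairwise score
    correlations are positive in expectation, so the first principal
    component recovers the latent factor.
    """
    if n_scores < 2:
        raise ValueError("n_scores must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(rng)
    age = np.asarray(age, dtype=float)
    z_age = (age - age.mean()) / age.std()
    latent = latent_slope * z_age + rng.standard_normal(age.size)
    loadings = rng.uniform(0.5, 1.5, size=n_scores)
    return np.outer(latent, loadings) + noise_sd * rng.standard_normal((age.size, n_scores))


# Correlation of each anatomical/geometry confound with z(age); volumes
# shrink with age, head geometry is essentially age-independent.
_CONFOUND_AGE_CORR = {
    "total_brain_vol": -0.4,
    "gm_vol": -0.35,
    "wm_vol": -0.2,
    "head_size": 0.1,
    "head_pos_x": 0.0,
    "head_pos_y": 0.0,
    "head_pos_z": 0.0,
}


def simulate_covariates(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Covariate table: age, sex, confounds correlated with age, cognition."""
    n = cfg.n_subjects
    age = rng.uniform(*cfg.age_range, size=n)
    z_age = (age - age.mean()) / age.std()
    cols = {"age": age, "sex": rng.integers(0, 2, size=n).astype(float)}
    for name, r in _CONFOUND_AGE_CORR.items():
        cols[name] = r * z_age + np.sqrt(1.0 - r**2) * rng.standard_normal(n)
    scores = simulate_cognitive_scores(
        age, cfg.n_cog_scores, cfg.latent_cog_age_slope, cfg.cog_noise_sd, rng
    )
    for j in range(cfg.n_cog_scores):
        cols[f"cog_{j + 1}"] = scores[:, j]
    return pd.DataFrame(cols)


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


def _perturb_stay_probability(a: np.ndarray, state: int, delta_logit: float) -> np.ndarray:
    """Shift a row's self-transition probability on the logit scale.

    The off-diagonal entries of the row are rescaled proportionally so the
    row remains stochastic.
    """
    a = a.copy()
    stay = a[state, state]
    new_stay = _expit(_logit(stay) + delta_logit)
    off = 1.0 - stay
    if off > 0:
        a[state, :] *= (1.0 - new_stay) / off
    else:
        a[state, :] = (1.0 - new_stay) / (a.shape[0] - 1)
    a[state, state] = new_stay
    return a


def simulate_cohort(
    cfg: CohortConfig, seed: int | None = None
) -> tuple[list, pd.DataFrame, GroundTruth]:
    """Generate a full cohort: signals, covariates and ground truth.

    Covariate effects listed in ``cfg.effect_map`` are applied per subject
    using the z-scored covariate value.  The returned :class:`GroundTruth`
    records the exact per-subject transition matrices, gains, coupling
    weights and hidden-state sequences.

    Identical ``(cfg, seed)`` reproduce bit-identical output.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    covariates = simulate_covariates(cfg, rng)
    k, p = cfg.n_states, cfg.n_parcels

    z_cov = {}
    for eff in cfg.effect_map:
        if eff.covariate not in covariates.columns:
            raise ValueError(f"effect references unknown covariate {eff.covariate!r}")
        v = covariates[eff.covariate].to_numpy(dtype=float)
        z_cov[eff.covariate] = (v - v.mean()) / v.std()

    base_gains = np.stack([s.oscillator_gain for s in cfg.state_specs])  # (K, p)
    transition_matrices = np.empty((cfg.n_subjects, k, k))
    gains = np.empty((cfg.n_subjects, k, p))
    coupling_weights: dict = {}
    sequences = []
    series = []

    for s in range(cfg.n_subjects):
        a_s = cfg.base_transition_matrix.copy()
        gain_s = base_gains * np.exp(
            cfg.gain_jitter_sd * rng.standard_normal((k, p))
        )
        cw_s = {
            ki: np.ones(len(spec.coupling_groups))
            for ki, spec in enumerate(cfg.state_specs)
            if spec.coupling_groups
        }
        for eff in cfg.effect_map:
            z = z_cov[eff.covariate][s]
            if eff.feature == "stay_probability":
                a_s = _perturb_stay_probability(a_s, eff.state, eff.slope * z)
            elif eff.feature == "gain":
                gain_s[eff.state, eff.parcel] *= np.exp(eff.slope * z)
            elif eff.feature == "coupling":
                w = cw_s[eff.state][eff.group]
                w = min(w, 1.0 - 1e-9)
                cw_s[eff.state][eff.group] = _expit(_logit(w) + eff.slope * z)

        specs_s = [
            StateSpec(
                oscillator_freq_hz=spec.oscillator_freq_hz,
                oscillator_gain=gain_s[ki],
                coupling_groups=spec.coupling_groups,
                noise_sd=spec.noise_sd,
            )
            for ki, spec in enumerate(cfg.state_specs)
        ]
        states = simulate_state_sequence(a_s, cfg.n_samples, rng=rng)
        ts = simulate_subject_signals(
            states, specs_s, cfg.sampling_rate_hz, rng, cw_s or None
        )
        transition_matrices[s] = a_s
        gains[s] = gain_s
        if cw_s:
            coupling_weights[s] = {ki: w.copy() for ki, w in cw_s.items()}
        sequences.append(states)
        series.append(ts)

    truth = GroundTruth(
        transition_matrices=transition_matrices,
        gains=gains,
        coupling_weights=coupling_weights,
        state_sequences=sequences,
    )
    return series, covariates, truth


def simulate_hmm_observations(
    covariances: np.ndarray,
    a: np.ndarray,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw directly from the zero-mean Gaussian-covariance HMM.

    Returns ``(X, states)`` with ``X`` of shape (n_samples, n_channels).
    Useful for exercising inference under its own generative model.
    """
    rng = np.random.default_rng(rng)
    covariances = np.asarray(covariances, dtype=float)
    k, d, _ = covariances.shape
    states = simulate_state_sequence(a, n_samples, rng=rng)
    chol = np.linalg.cholesky(covariances)
    z = rng.standard_normal((n_samples, d))
    x = np.einsum("tij,tj->ti", chol[states], z)
    return x, states
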
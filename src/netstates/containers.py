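"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ParcelTimeSeries:
    """A single subject's parcellated recording.

    Parameters
    ----------
    data : ndarray, shape (n_parcels, n_samples)
        Parcel time courses.
    sampling_rate_hz : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"data must be 2-D (parcels x samples), got shape {self.data.shape}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_parcels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def standardized(self) -> "ParcelTimeSeries":
        """Return a copy with each parcel z-scored over time."""
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd[:, 0] == 0)[0])
            raise ValueError(f"parcel {bad} has zero variance; cannot standardise")
        out = (self.data - self.data.mean(axis=1, keepdims=True)) / sd
        return ParcelTimeSeries(out, self.sampling_rate_hz)

    def trimmed(self, n_each_side: int) -> "ParcelTimeSeries":
        """Drop ``n_each_side`` samples from both ends (embedding alignment)."""
        if n_each_side == 0:
            return ParcelTimeSeries(self.data.copy(), self.sampling_rate_hz)
        if 2 * n_each_side >= self.n_samples:
            raise ValueError("trim longer than the recording")
        return ParcelTimeSeries(
            self.data[:, n_each_side:-n_each_side].copy(), self.sampling_rate_hz
        )


@dataclass
class SpectralEstimate:
    """Multitaper spectral estimate for one subject (or one subject-state).

    Attributes
    ----------
    freqs : ndarray, shape (n_freqs,)
        Frequency axis in Hz, ascending.
    psd : ndarray, shape (n_parcels, n_freqs)
        One-sided power spectral density; the integral over frequency
        approximates the signal variance.
    csd : ndarray, shape (n_parcels, n_parcels, n_freqs), complex
        Cross-spectral density, Hermitian in the parcel indices; the
        diagonal equals the PSD.
    """

    freqs: np.ndarray
    psd: np.ndarray
    csd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        self.csd = np.asarray(self.csd)

    @property
    def n_parcels(self) -> int:
        return self.psd.shape[0]


@dataclass
class StateSpectralEstimate:
    """Dual-estimated per-state spectra for one subject.

    States never visited (fractional occupancy 0) carry all-NaN spectra,
    never silent zeros.
    """

    freqs: np.ndarray
    psd: np.ndarray  # (n_states, n_parcels, n_freqs), FO-rescaled
    coherence: np.ndarray  # (n_states, n_parcels, n_parcels, n_freqs)
    fractional_occupancy: np.ndarray  # (n_states,)

    @property
    def n_states(self) -> int:
        return self.psd.shape[0]


@dataclass
class GroundTruth:
    """Per-subject generative parameters recorded by the cohort simulator."""

    transition_matrices: np.ndarray  # (n_subjects, K, K)
    gains: np.ndarray  # (n_subjects, K, n_parcels)
    coupling_weights: dict = field(default_factory=dict)
    state_sequences: list = field(default_factory=list)
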
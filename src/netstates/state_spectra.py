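"""Dual estimation of per-state spectra.

The spectral content of each transient state is re-estimated from the
original (pre-embedding) parcel data: the standardised parcel time courses
are multiplied by the state's binary MAP indicator, a multitaper P/CSD is
computed with the same settings as the time-averaged analysis, coherence
follows from the P/CSD, and the PSD amplitude bias introduced by masking is
removed by rescaling with one over the state's fractional occupancy.
Coherence needs no rescaling (it self-normalises).

Windows straddling state boundaries are retained (the mask inserts zeros);
the resulting leakage is accepted and documented rather than excising
segments, matching the multiply-then-window definition of the estimator.
"""

from __future__ import annotations

import numpy as np

from .containers import ParcelTimeSeries, SpectralEstimate, StateSpectralEstimate
from .spectra import (
    SpectralConfig,
    band_collapse,
    coherence_from_spectra,
    coherence_map,
    coherence_network,
    multitaper_spectra,
)

#: Default frequency range for state spectra (the HMM states carry their own
#: characteristic spectra, so the full range is integrated).
STATE_FREQ_RANGE = (1.0, 80.0)


def dual_estimate(
    ts: ParcelTimeSeries,
    states: np.ndarray,
    n_states: int,
    cfg: SpectralConfig | None = None,
    n_embedding_lags: int = 0,
) -> StateSpectralEstimate:
    """Per-state multitaper spectra for one subject.

    Parameters
    ----------
    ts : ParcelTimeSeries
        The original parcel data (pre-embedding).  Standardised internally.
    states : int array
        MAP state time course.  If it is ``2 * n_embedding_lags`` samples
        shorter than ``ts`` (the embedding trim), ``ts`` is trimmed by
        ``n_embedding_lags`` samples at each end to align.
    n_states : int
        Number of states K.
    cfg : SpectralConfig
        Defaults to the state-spectra range ``STATE_FREQ_RANGE``.

    Returns
    -------
    StateSpectralEstimate
        FO-rescaled PSDs and coherences per state; states with zero
        fractional occupancy are all-NaN.
    """
    if cfg is None:
        cfg = SpectralConfig(freq_range_hz=STATE_FREQ_RANGE)
    states = np.asarray(states)
    ts = ts.standardized()
    if states.size != ts.n_samples:
        if states.size == ts.n_samples - 2 * n_embedding_lags and n_embedding_lags > 0:
            ts = ts.trimmed(n_embedding_lags)
        else:
            raise ValueError(
                f"state course has {states.size} samples but the recording has "
                f"{ts.n_samples}; only the {2 * n_embedding_lags}-sample "
                "embedding trim is handled"
            )
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError("state label outside 0..K-1")

    fo = np.array([(states == k).mean() for k in range(n_states)])
    psd = None
    coh = None
    freqs = None
    for k in range(n_states):
        if fo[k] == 0:
            continue
        masked = ts.data * (states == k)
        est = multitaper_spectra(
            ParcelTimeSeries(masked, ts.sampling_rate_hz), cfg, standardize=False
        )
        if psd is None:
            freqs = est.freqs
            psd = np.full((n_states,) + est.psd.shape, np.nan)
            coh = np.full((n_states,) + est.csd.shape, np.nan)
        psd[k] = est.psd / fo[k]
        coh[k] = coherence_from_spectra(est)
    if psd is None:
        raise ValueError("no state was ever active")
    return StateSpectralEstimate(
        freqs=freqs, psd=psd, coherence=coh, fractional_occupancy=fo
    )


def state_band_collapse(
    sse: StateSpectralEstimate,
    freq_range: tuple[float, float] = STATE_FREQ_RANGE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Broadband collapse of dual-estimated spectra.

    Averages PSD and coherence over all bins in ``freq_range`` (no
    hand-chosen band: each state has its own characteristic spectrum).

    Returns
    -------
    power_maps : (K, parcels)
    coherence_networks : (K, parcels, parcels), zero diagonal
    coherence_maps : (K, parcels), from the unreferenced networks
    """
    band = {"broadband": freq_range}
    power = band_collapse(sse.psd, sse.freqs, band)["broadband"]
    coh = band_collapse(sse.coherence, sse.freqs, band)["broadband"]
    networks = coherence_network(coh)
    maps = np.array(
        [
            coherence_map(networks[k]) if not np.isnan(networks[k]).any() else
            np.full(networks.shape[-1], np.nan)
            for k in range(sse.n_states)
        ]
    )
    return power, networks, maps


def state_reference(maps: np.ndarray) -> np.ndarray:
    """Reference state maps for display: subtract the mean across states."""
    return maps - np.nanmean(maps, axis=0, keepdims=True)


def reconstruct_static_psd(sse: StateSpectralEstimate) -> np.ndarray:
    """FO-weighted sum of the rescaled state PSDs.

    For stationary input this reconstructs the static PSD of the same
    (trimmed) data: power is conserved across the mutually exclusive mask
    partition up to windowing edge effects.
    """
    fo = sse.fractional_occupancy
    terms = [fo[k] * sse.psd[k] for k in range(sse.n_states) if fo[k] > 0]
    return np.sum(terms, axis=0)
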
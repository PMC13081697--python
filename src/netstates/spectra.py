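"""Time-averaged spectral characterisation.

Multitaper power and cross-spectral densities (DPSS tapers), coherence,
canonical-band power maps, coherence networks/maps, and the band-referencing
and edge-thresholding used for display.

Conventions
-----------
* PSDs are one-sided densities normalised so that the integral over the
  full frequency axis approximates the signal variance (unit-variance white
  noise at rate ``fs`` has a flat level of ``2/fs``).
* Band intervals are half-open ``[low, high)`` so touching band edges are
  not double-counted.
* Statistics always run on unreferenced, unthresholded values; referencing
  and thresholding are reporting aids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss

from .containers import ParcelTimeSeries, SpectralEstimate

#: Canonical frequency bands (Hz).  The beta band stops at 24 Hz and gamma
#: starts at 30 Hz; the 24-30 Hz gap is deliberate (site artefact range).
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 24.0),
    "gamma": (30.0, 45.0),
}


@dataclass
class SpectralConfig:
    """Multitaper settings.

    ``time_half_bandwidth`` is the dimensionless NW product; with the
    default 2 s window and NW = 4 the standard ``2 NW - 1`` rule gives the
    default 7 DPSS tapers.
    """

    window_length_s: float = 2.0
    overlap_fraction: float = 0.0
    n_tapers: int = 7
    time_half_bandwidth: float = 4.0
    freq_range_hz: tuple[float, float] = (1.0, 45.0)

    def __post_init__(self) -> None:
        if self.window_length_s <= 0:
            raise ValueError("window_length_s must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must lie in [0, 1)")
        if self.n_tapers < 1:
            raise ValueError("n_tapers must be >= 1")


def default_taper_count(time_half_bandwidth: float) -> int:
    """Number of well-concentrated DPSS tapers: ``2 NW - 1``."""
    return int(2 * time_half_bandwidth - 1)


def multitaper_spectra(
    ts: ParcelTimeSeries,
    cfg: SpectralConfig | None = None,
    standardize: bool = True,
) -> SpectralEstimate:
    """Multitaper PSD and CSD of a parcellated recording.

    The recording is split into windows (trailing partial window dropped),
    each window is multiplied by ``n_tapers`` DPSS tapers, and periodogram
    estimates are averaged over windows and tapers.  Frequency resolution is
    ``1 / window_length_s``; only bins inside ``cfg.freq_range_hz`` are
    returned.

    Parameters
    ----------
    ts : ParcelTimeSeries
    cfg : SpectralConfig
    standardize : bool
        Z-score each parcel before estimation (the default, matching the
        time-averaged analysis).  Dual estimation disables this because the
        data are standardised before masking.
    """
    cfg = cfg or SpectralConfig()
    x = np.asarray(ts.data, dtype=float)
    if np.any(np.isnan(x)):
        raise ValueError("input contains NaN")
    fs = ts.sampling_rate_hz
    nper = int(round(cfg.window_length_s * fs))
    if ts.n_samples < nper:
        raise ValueError(
            f"recording ({ts.n_samples} samples) shorter than one window ({nper})"
        )
    if standardize:
        sd = x.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd[:, 0] == 0)[0])
            raise ValueError(f"parcel {bad} is constant; cannot standardise")
        x = (x - x.mean(axis=1, keepdims=True)) / sd

    step = max(1, int(round(nper * (1.0 - cfg.overlap_fraction))))
    starts = np.arange(0, ts.n_samples - nper + 1, step)

    tapers = dpss(nper, cfg.time_half_bandwidth, Kmax=cfg.n_tapers)
    tapers /= np.sqrt((tapers**2).sum(axis=1, keepdims=True))  # unit energy

    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    n_parcels = x.shape[0]
    csd = np.zeros((n_parcels, n_parcels, freqs.size), dtype=complex)
    for s0 in starts:
        seg = x[:, s0 : s0 + nper]
        # (tapers, parcels, freqs)
        tx = np.fft.rfft(tapers[:, None, :] * seg[None, :, :], axis=-1)
        csd += np.einsum("txf,tyf->xyf", tx, np.conj(tx))
    csd /= len(starts) * cfg.n_tapers * fs

    # One-sided density: double everything except DC and (even-nper) Nyquist.
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if nper % 2 == 0:
        scale[-1] = 1.0
    csd *= scale

    lo, hi = cfg.freq_range_hz
    keep = (freqs >= lo) & (freqs <= hi)
    freqs = freqs[keep]
    csd = csd[:, :, keep]
    psd = np.real(np.einsum("xxf->xf", csd)).copy()
    return SpectralEstimate(freqs=freqs, psd=psd, csd=csd)


def coherence_from_spectra(est: SpectralEstimate) -> np.ndarray:
    """Coherence ``C_xy(f) = |CSD_xy| / sqrt(PSD_x PSD_y)``.

    Returns an array of shape (parcels, parcels, freqs) with values in
    [0, 1], unit diagonal, symmetric in the parcel indices.
    """
    psd = est.psd
    if np.any(psd <= 0):
        x, f = np.unravel_index(int(np.argmin(psd)), psd.shape)
        raise ValueError(
            f"PSD is not strictly positive at parcel {x}, {est.freqs[f]:g} Hz"
        )
    denom = np.sqrt(psd[:, None, :] * psd[None, :, :])
    coh = np.abs(est.csd) / denom
    np.clip(coh, 0.0, 1.0, out=coh)
    idx = np.arange(est.n_parcels)
    coh[idx, idx, :] = 1.0
    return coh


def _band_mask(freqs: np.ndarray, low: float, high: float) -> np.ndarray:
    if low >= high:
        raise ValueError(f"band [{low}, {high}) is empty")
    mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        raise ValueError(
            f"band [{low}, {high}) contains no bins of the retained axis"
        )
    return mask


def band_collapse(
    values: np.ndarray, freqs: np.ndarray, bands: dict[str, tuple[float, float]]
) -> dict[str, np.ndarray]:
    """Average the trailing frequency axis over each band.

    Works for PSD arrays (parcels x freqs), coherence arrays
    (parcels x parcels x freqs) or any array whose last axis is frequency.
    Bands are half-open ``[low, high)``.
    """
    values = np.asarray(values)
    out = {}
    for label, (low, high) in bands.items():
        mask = _band_mask(np.asarray(freqs), low, high)
        out[label] = values[..., mask].mean(axis=-1)
    return out


def coherence_network(band_coherence: np.ndarray) -> np.ndarray:
    """Zero the diagonal of a band-collapsed coherence matrix (convention)."""
    net = np.array(band_coherence, dtype=float)
    idx = np.arange(net.shape[-1])
    net[..., idx, idx] = 0.0
    return net


def coherence_map(network: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Per-parcel mean of off-diagonal edges of a symmetric network."""
    network = np.asarray(network, dtype=float)
    if network.ndim != 2 or network.shape[0] != network.shape[1]:
        raise ValueError("network must be a square matrix")
    if np.max(np.abs(network - network.T)) > tol:
        raise ValueError("network is not symmetric")
    p = network.shape[0]
    off = network.sum(axis=1) - np.diag(network)
    return off / (p - 1)


def weighted_band_reference(
    values_per_band: dict[str, np.ndarray],
    bands: dict[str, tuple[float, float]],
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted average across bands, weights proportional to bin counts.

    If ``freqs`` is None, band widths are used (equivalent on a uniform
    axis).  With uniform weights pass equal-width bands.
    """
    labels = list(values_per_band)
    shapes = {values_per_band[la].shape for la in labels}
    if len(shapes) != 1:
        raise ValueError("per-band arrays must share a shape")
    if freqs is not None:
        weights = np.array(
            [_band_mask(np.asarray(freqs), *bands[la]).sum() for la in labels],
            dtype=float,
        )
    else:
        weights = np.array([bands[la][1] - bands[la][0] for la in labels], dtype=float)
    weights /= weights.sum()
    return sum(w * values_per_band[la] for w, la in zip(weights, labels))


def reference_and_threshold(
    networks_per_band: dict[str, np.ndarray],
    bands: dict[str, tuple[float, float]],
    freqs: np.ndarray | None = None,
    top_fraction: float = 0.03,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Subtract the edge-wise band reference, then keep the largest edges.

    For each band the weighted-average network across bands is subtracted
    per edge, and a boolean mask keeps the ``ceil(top_fraction * n_edges)``
    edges of largest absolute referenced value (irrespective of sign).
    Ties are broken deterministically by (lower parcel index, lower partner
    index).  Intended for display; statistics use unreferenced values.

    Returns ``(referenced, masks)`` dicts keyed by band; masks are
    symmetric boolean matrices.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must lie in (0, 1]")
    if len(networks_per_band) < 2:
        raise ValueError("referencing needs at least two bands")
    reference = weighted_band_reference(networks_per_band, bands, freqs)
    p = reference.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    n_keep = math.ceil(top_fraction * iu.size)
    referenced, masks = {}, {}
    for label, net in networks_per_band.items():
        ref_net = net - reference
        vals = np.abs(ref_net[iu, ju])
        order = np.lexsort((ju, iu, -vals))
        keep = order[:n_keep]
        mask = np.zeros((p, p), dtype=bool)
        mask[iu[keep], ju[keep]] = True
        mask |= mask.T
        referenced[label] = ref_net
        masks[label] = mask
    return referenced, masks
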
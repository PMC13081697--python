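"""Multitaper spectra, coherence, band collapse, referencing/thresholding."""

import numpy as np
import pytest

import netstates as ns
from netstates.containers import ParcelTimeSeries
from netstates.spectra import (
    CANONICAL_BANDS,
    band_collapse,
    coherence_map,
    default_taper_count,
    reference_and_threshold,
    weighted_band_reference,
)


class TestMultitaper:
    def test_white_noise_level_and_parseval(self, white_noise_ts):
        est = ns.multitaper_spectra(
            white_noise_ts, ns.SpectralConfig(freq_range_hz=(0.0, 125.0))
        )
        level = 2.0 / 250.0
        n_avg = (white_noise_ts.n_samples // 500) * 7
        se = level / np.sqrt(n_avg)
        # interior bins are flat at 2/fs; DC and Nyquist are not doubled
        interior = est.psd[:, 1:-1]
        assert np.abs(interior - level).max() < 6 * se  # max over ~500 bins
        df = est.freqs[1] - est.freqs[0]
        integral = est.psd.sum(axis=1) * df
        assert np.abs(integral - 1.0).max() < 0.05  # variance of z-scored input

    def test_sinusoid_peak_bin(self):
        t = np.arange(25_000) / 250.0
        ts = ParcelTimeSeries(np.sin(2 * np.pi * 10 * t)[None, :], 250.0)
        est = ns.multitaper_spectra(ts)
        assert est.freqs[est.psd[0].argmax()] == pytest.approx(10.0)

    def test_csd_diagonal_equals_psd(self, white_noise_ts):
        est = ns.multitaper_spectra(white_noise_ts)
        diag = np.real(np.einsum("xxf->xf", est.csd))
        assert np.abs(diag - est.psd).max() < 1e-10
        assert np.abs(np.imag(np.einsum("xxf->xf", est.csd))).max() < 1e-12

    def test_csd_hermitian(self, white_noise_ts):
        est = ns.multitaper_spectra(white_noise_ts)
        assert np.abs(est.csd - np.conj(est.csd.transpose(1, 0, 2))).max() < 1e-12

    def test_frequency_resolution_and_range(self, white_noise_ts):
        est = ns.multitaper_spectra(white_noise_ts)
        assert est.freqs[1] - est.freqs[0] == pytest.approx(0.5)  # 1 / 2 s
        assert est.freqs[0] >= 1.0 and est.freqs[-1] <= 45.0

    def test_short_recording_rejected(self):
        ts = ParcelTimeSeries(np.random.default_rng(0).standard_normal((1, 100)), 250.0)
        with pytest.raises(ValueError, match="shorter"):
            ns.multitaper_spectra(ts)

    def test_nan_rejected(self):
        x = np.ones((1, 1000))
        x[0, 5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ns.multitaper_spectra(ParcelTimeSeries(x, 250.0))

    def test_taper_count_rule(self):
        assert default_taper_count(4) == 7


class TestCoherence:
    def test_duplicated_parcel_coherence_one(self, rng):
        x = rng.standard_normal(20_000)
        ts = ParcelTimeSeries(np.stack([x, x]), 250.0)
        coh = ns.coherence_from_spectra(ns.multitaper_spectra(ts))
        assert np.abs(coh[0, 1] - 1.0).max() < 1e-10

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(20_000)
        ts = ParcelTimeSeries(np.stack([x, 3 * x]), 250.0)
        coh = ns.coherence_from_spectra(ns.multitaper_spectra(ts))
        assert np.abs(coh[0, 1] - 1.0).max() < 1e-10

    def test_mixing_oracle_closed_form(self):
        from netstates.experiments import coherence_mixing_errors

        errors = coherence_mixing_errors(n_draws=5, n_samples=60_000, seed=3)
        assert errors.max() < 0.02

    def test_bounds_and_symmetry_on_random_input(self, rng):
        ts = ParcelTimeSeries(rng.standard_normal((4, 10_000)), 250.0)
        coh = ns.coherence_from_spectra(ns.multitaper_spectra(ts))
        assert coh.min() >= 0 and coh.max() <= 1
        assert np.abs(coh - coh.transpose(1, 0, 2)).max() < 1e-12
        assert np.allclose(coh[np.arange(4), np.arange(4)], 1.0)

    def test_zero_psd_bin_reported(self):
        est = ns.SpectralEstimate(
            freqs=np.array([1.0, 2.0]),
            psd=np.array([[1.0, 0.0]]),
            csd=np.ones((1, 1, 2), dtype=complex),
        )
        with pytest.raises(ValueError, match="parcel 0, 2 Hz"):
            ns.coherence_from_spectra(est)


class TestBandCollapse:
    freqs = np.arange(1.0, 45.5, 0.5)

    def test_constant_psd(self):
        psd = np.full((3, self.freqs.size), 2.5)
        out = band_collapse(psd, self.freqs, CANONICAL_BANDS)
        for v in out.values():
            assert np.allclose(v, 2.5)

    def test_three_bin_mean(self):
        freqs = np.array([1.0, 2.0, 3.0])
        psd = np.array([[1.0, 2.0, 6.0]])
        out = band_collapse(psd, freqs, {"b": (1.0, 3.5)})
        assert out["b"][0] == pytest.approx(3.0)

    def test_half_open_interval_excludes_upper_edge(self):
        freqs = np.array([3.5, 4.0])
        psd = np.array([[1.0, 100.0]])
        out = band_collapse(psd, freqs, {"delta": (1.0, 4.0)})
        assert out["delta"][0] == pytest.approx(1.0)

    def test_synthetic_alpha_block_coherence(self):
        coh = np.full((2, 2, self.freqs.size), 0.1)
        alpha = (self.freqs >= 8) & (self.freqs < 13)
        coh[..., alpha] = 0.4
        out = band_collapse(coh, self.freqs, CANONICAL_BANDS)
        assert np.allclose(out["alpha"], 0.4)
        assert np.allclose(out["delta"], 0.1)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no bins"):
            band_collapse(np.ones((1, 3)), np.array([1.0, 2.0, 3.0]), {"g": (50.0, 60.0)})


class TestCoherenceMap:
    def test_constant_edges(self):
        net = np.full((4, 4), 0.3)
        np.fill_diagonal(net, 0)
        assert np.allclose(coherence_map(net), 0.3)

    def test_hand_computed_three_parcels(self):
        net = np.zeros((3, 3))
        net[0, 1] = net[1, 0] = 0.6
        net[0, 2] = net[2, 0] = 0.2
        net[1, 2] = net[2, 1] = 0.4
        assert np.allclose(coherence_map(net), [0.4, 0.5, 0.3])

    def test_zero_network(self):
        assert np.allclose(coherence_map(np.zeros((5, 5))), 0.0)

    def test_asymmetric_rejected(self):
        net = np.zeros((3, 3))
        net[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            coherence_map(net)


class TestReferenceAndThreshold:
    def test_weighted_reference_arithmetic(self):
        bands = {"a": (1.0, 4.0), "b": (4.0, 10.0)}  # widths 3 and 6
        vals = {"a": np.full((2, 2), 1.0), "b": np.full((2, 2), 4.0)}
        ref = weighted_band_reference(vals, bands)
        assert np.allclose(ref, 3.0)

    def test_equal_width_bands_simple_mean(self):
        bands = {"a": (0.0, 2.0), "b": (2.0, 4.0)}
        vals = {"a": np.full(3, 1.0), "b": np.full(3, 3.0)}
        assert np.allclose(weighted_band_reference(vals, bands), 2.0)

    def test_single_band_reference_is_identity(self):
        bands = {"a": (0.0, 2.0)}
        vals = {"a": np.arange(4.0)}
        assert np.allclose(weighted_band_reference(vals, bands), vals["a"])

    def test_top_fraction_counting(self, rng):
        # 15 parcels -> 105 unique-magnitude edges; ceil(0.03*105) = 4 kept
        p = 15
        net = np.zeros((p, p))
        iu, ju = np.triu_indices(p, k=1)
        vals = rng.permutation(iu.size) + 1.0
        net[iu, ju] = vals
        net += net.T
        bands = {"a": (0.0, 1.0), "b": (1.0, 2.0)}
        refd, masks = reference_and_threshold(
            {"a": net, "b": np.zeros_like(net)}, bands, top_fraction=0.03
        )
        assert masks["a"].sum() // 2 == int(np.ceil(0.03 * iu.size))

    def test_top_fraction_one_keeps_all(self, rng):
        net = rng.standard_normal((4, 4))
        net = net + net.T
        bands = {"a": (0.0, 1.0), "b": (1.0, 2.0)}
        _, masks = reference_and_threshold(
            {"a": net, "b": -net}, bands, top_fraction=1.0
        )
        assert masks["a"].sum() == 12  # all off-diagonal entries

    def test_identical_networks_reference_to_zero(self, rng):
        net = rng.standard_normal((4, 4))
        net = net + net.T
        bands = {"a": (0.0, 2.0), "b": (2.0, 4.0)}  # equal widths
        refd, _ = reference_and_threshold({"a": net, "b": net.copy()}, bands)
        assert np.abs(refd["a"]).max() < 1e-12
        assert np.abs(refd["b"]).max() < 1e-12

    def test_invalid_fraction_rejected(self):
        bands = {"a": (0.0, 1.0), "b": (1.0, 2.0)}
        nets = {"a": np.zeros((3, 3)), "b": np.zeros((3, 3))}
        with pytest.raises(ValueError, match="top_fraction"):
            reference_and_threshold(nets, bands, top_fraction=0.0)
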
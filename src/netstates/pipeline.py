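"""End-to-end orchestration of the two workflows.

The static workflow characterises time-averaged networks: multitaper
spectra -> canonical-band power maps and coherence networks/maps ->
permutation GLMs for age/cognition effects.

The transient workflow characterises network dynamics: time-delay
embedding -> group PCA -> standardisation -> group HMM (multi-run, best
free energy) -> MAP state time courses -> dynamics summary statistics and
subject transition matrices -> dual-estimated state spectra -> permutation
GLMs.  Statistics always run on unreferenced feature values.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import spectra as sp
from . import state_spectra as ssp
from .containers import ParcelTimeSeries
from .embedding import EmbeddingConfig, prepare_subjects
from .glm import (
    DEFAULT_CONFOUNDS,
    build_design,
    maxstat_signflip_test,
    reduce_scores_pca,
)
from .hmm import TrainConfig, fit_hmm

logger = logging.getLogger(__name__)


@dataclass
class StatsSpec:
    interest: str = "age"
    confounds: tuple = DEFAULT_CONFOUNDS
    n_perm: int = 1000
    stat: str = "beta"


@dataclass
class PipelineConfig:
    spectral: sp.SpectralConfig = field(default_factory=sp.SpectralConfig)
    bands: dict = field(default_factory=lambda: dict(sp.CANONICAL_BANDS))
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    stats: StatsSpec = field(default_factory=StatsSpec)
    seed: int | None = None


def _augment_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Add the PCA-reduced cognitive performance score if tasks are present."""
    cov = covariates.copy()
    cog_cols = [c for c in cov.columns if c.startswith("cog_")]
    if cog_cols and "cog_perf" not in cov.columns:
        pc1, _, _ = reduce_scores_pca(cov[cog_cols].to_numpy())
        cov["cog_perf"] = pc1
    return cov


def _band_features(series, cfg: PipelineConfig):
    """Per-subject band power maps and coherence networks."""
    n = len(series)
    p = series[0].n_parcels
    labels = list(cfg.bands)
    power = np.empty((n, len(labels), p))
    networks = np.empty((n, len(labels), p, p))
    for i, ts in enumerate(series):
        est = sp.multitaper_spectra(ts, cfg.spectral)
        coh = sp.coherence_from_spectra(est)
        bp = sp.band_collapse(est.psd, est.freqs, cfg.bands)
        bc = sp.band_collapse(coh, est.freqs, cfg.bands)
        for b, la in enumerate(labels):
            power[i, b] = bp[la]
            networks[i, b] = sp.coherence_network(bc[la])
    return labels, power, networks


def run_static_pipeline(
    series: list,
    covariates: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    seed=None,
) -> dict:
    """Time-averaged network analysis with group statistics.

    Returns a dict with band labels, per-subject power maps
    (subjects x bands x parcels), coherence networks
    (subjects x bands x parcels x parcels), coherence maps, and one
    permutation-GLM result per band for power and coherence edges.
    """
    cfg = cfg or PipelineConfig()
    if len(series) != len(covariates):
        raise ValueError(
            f"{len(series)} recordings but {len(covariates)} covariate rows"
        )
    seed = cfg.seed if seed is None else seed
    t0 = time.perf_counter()
    cov = _augment_covariates(covariates)
    labels, power, networks = _band_features(series, cfg)
    p = series[0].n_parcels
    coh_maps = networks.sum(axis=-1) / (p - 1)

    confounds = [c for c in cfg.stats.confounds if c in cov.columns]
    if "cog_perf" in cov.columns and cfg.stats.interest != "cog_perf":
        confounds = confounds + ["cog_perf"]
    design = build_design(cov, cfg.stats.interest, confounds)

    iu, ju = np.triu_indices(p, k=1)
    stats = {}
    rng = np.random.default_rng(seed)
    for b, la in enumerate(labels):
        s1 = int(rng.integers(2**31))
        s2 = int(rng.integers(2**31))
        stats[la] = {
            "power": maxstat_signflip_test(
                power[:, b], design, cfg.stats.n_perm, cfg.stats.stat, seed=s1
            ),
            "coherence": maxstat_signflip_test(
                networks[:, b][:, iu, ju], design, cfg.stats.n_perm,
                cfg.stats.stat, seed=s2,
            ),
        }
    logger.info("static pipeline done in %.1f s", time.perf_counter() - t0)
    return {
        "bands": labels,
        "power_maps": power,
        "coherence_networks": networks,
        "coherence_maps": coh_maps,
        "edge_index": (iu, ju),
        "design": design,
        "stats": stats,
    }


def run_transient_pipeline(
    series: list,
    covariates: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    seed=None,
    dual_estimation: bool = True,
) -> dict:
    """Transient network analysis: TDE-PCA-HMM, dynamics, state spectra, stats."""
    cfg = cfg or PipelineConfig()
    if len(series) != len(covariates):
        raise ValueError(
            f"{len(series)} recordings but {len(covariates)} covariate rows"
        )
    seed = cfg.seed if seed is None else seed
    t0 = time.perf_counter()
    cov = _augment_covariates(covariates)
    fs = series[0].sampling_rate_hz
    K = cfg.train.n_states
    L = cfg.embedding.n_lags_each_side

    prepared, pca = prepare_subjects(series, cfg.embedding)
    train_cfg = TrainConfig(**{**cfg.train.__dict__, "seed": seed})
    model, gammas, diagnostics = fit_hmm(prepared, train_cfg)
    state_courses = [dyn.map_states(g) for g in gammas]
    stats_df = dyn.cohort_summary_stats(state_courses, K, fs)
    trans = np.stack(
        [dyn.subject_transition_matrix(stc, K)[0] for stc in state_courses]
    )

    result = {
        "model": model,
        "pca": pca,
        "gammas": gammas,
        "state_courses": state_courses,
        "summary_stats": stats_df,
        "transition_matrices": trans,
        "diagnostics": diagnostics,
    }

    if dual_estimation:
        sses = [
            ssp.dual_estimate(ts, stc, K, n_embedding_lags=L)
            for ts, stc in zip(series, state_courses)
        ]
        maps = [ssp.state_band_collapse(s) for s in sses]
        result["state_spectra"] = sses
        result["state_power_maps"] = np.stack([m[0] for m in maps])
        result["state_coherence_networks"] = np.stack([m[1] for m in maps])
        result["state_coherence_maps"] = np.stack([m[2] for m in maps])

    # dynamics statistics -> wide feature matrix, t-statistic testing
    confounds = [c for c in cfg.stats.confounds if c in cov.columns]
    if "cog_perf" in cov.columns and cfg.stats.interest != "cog_perf":
        confounds = confounds + ["cog_perf"]
    design = build_design(cov, cfg.stats.interest, confounds)
    rng = np.random.default_rng(seed)
    dyn_stats = {}
    for stat_name in dyn.STAT_COLUMNS:
        wide = stats_df.pivot(index="subject", columns="state", values=stat_name)
        dyn_stats[stat_name] = maxstat_signflip_test(
            wide.to_numpy(),
            design,
            cfg.stats.n_perm,
            stat="t",
            seed=int(rng.integers(2**31)),
        )
    result["design"] = design
    result["stats"] = {"dynamics": dyn_stats}
    if dual_estimation:
        p = series[0].n_parcels
        iu, ju = np.triu_indices(p, k=1)
        power_feat = result["state_power_maps"].reshape(len(series), -1)
        coh_feat = result["state_coherence_networks"][:, :, iu, ju].reshape(
            len(series), -1
        )
        result["stats"]["state_power"] = maxstat_signflip_test(
            power_feat, design, cfg.stats.n_perm, cfg.stats.stat,
            seed=int(rng.integers(2**31)),
        )
        result["stats"]["state_coherence"] = maxstat_signflip_test(
            coh_feat, design, cfg.stats.n_perm, cfg.stats.stat,
            seed=int(rng.integers(2**31)),
        )
    logger.info("transient pipeline done in %.1f s", time.perf_counter() - t0)
    return result
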
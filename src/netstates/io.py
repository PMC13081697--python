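"""File formats: HDF5 for arrays, CSV for tables, JSON manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import GroundTruth, ParcelTimeSeries


def save_cohort_h5(path, series: list, covariates: pd.DataFrame | None = None) -> None:
    """One dataset per subject with sampling-rate / parcel-count attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, ts in enumerate(series):
            d = f.create_dataset(f"subject_{i:04d}", data=ts.data)
            d.attrs["sampling_rate_hz"] = ts.sampling_rate_hz
            d.attrs["n_parcels"] = ts.n_parcels
    if covariates is not None:
        covariates.to_csv(path.with_suffix(".covariates.csv"), index=False)


def load_cohort_h5(path) -> list:
    with h5py.File(path, "r") as f:
        keys = sorted(k for k in f if k.startswith("subject_"))
        return [
            ParcelTimeSeries(f[k][()], float(f[k].attrs["sampling_rate_hz"]))
            for k in keys
        ]


def save_ground_truth(path, truth: GroundTruth) -> None:
    payload = {
        "transition_matrices": truth.transition_matrices.tolist(),
        "gains": truth.gains.tolist(),
        "coupling_weights": {
            str(s): {str(k): w.tolist() for k, w in d.items()}
            for s, d in truth.coupling_weights.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def save_model_h5(path, model, extra: dict | None = None) -> None:
    """Persist a fitted GaussianCovarianceHMM."""
    with h5py.File(path, "w") as f:
        f.create_dataset("covariances", data=model.covariances_)
        f.create_dataset("transmat", data=model.transmat_)
        f.create_dataset("startprob", data=model.startprob_)
        f.attrs["n_states"] = model.n_states
        f.attrs["free_energy"] = model.free_energy_
        f.attrs["selected_run"] = model.diagnostics_.selected_run
        for r, trace in enumerate(model.diagnostics_.traces):
            f.create_dataset(f"trace_run_{r}", data=np.asarray(trace))
        for k, v in (extra or {}).items():
            f.attrs[k] = v


def load_model_h5(path):
    from .hmm import FitDiagnostics, GaussianCovarianceHMM

    with h5py.File(path, "r") as f:
        model = GaussianCovarianceHMM(n_states=int(f.attrs["n_states"]))
        model.covariances_ = f["covariances"][()]
        model.transmat_ = f["transmat"][()]
        model.startprob_ = f["startprob"][()]
        model.free_energy_ = float(f.attrs["free_energy"])
        model.n_channels_ = model.covariances_.shape[1]
        diag = FitDiagnostics()
        diag.selected_run = int(f.attrs["selected_run"])
        diag.traces = [
            f[k][()].tolist() for k in sorted(f) if k.startswith("trace_run_")
        ]
        model.diagnostics_ = diag
    return model


def features_long_csv(path, values: np.ndarray, feature_names: list) -> None:
    """(subjects x features) array as long-format CSV."""
    n, f = values.shape
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n), f),
            "feature": feature_names * n,
            "value": values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def edges_tsv(path, network: np.ndarray, mask: np.ndarray | None = None) -> None:
    """Edge list (parcel_i, parcel_j, value, kept_flag) of a symmetric network."""
    p = network.shape[0]
    iu, ju = np.triu_indices(p, k=1)
    df = pd.DataFrame(
        {
            "parcel_i": iu,
            "parcel_j": ju,
            "value": network[iu, ju],
            "kept": mask[iu, ju] if mask is not None else True,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, cfg: dict, seed) -> None:
    import netstates

    manifest = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "netstates_version": netstates.__version__,
        "numpy_version": np.__version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
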
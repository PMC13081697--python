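"""State-dynamics summaries derived from HMM posteriors.

From the marginal state probabilities we take the most probable state at
each sample (the MAP state time course, mutually exclusive by
construction) and summarise each subject's dynamics per state:

* fractional occupancy - fraction of total time spent in the state;
* mean lifetime (ms) - average duration of a visit (maximal run);
* mean interval (s) - average gap between successive visits;
* switching rate (Hz) - visit onsets per second (the first visit counts).

States never visited get fractional occupancy 0, switching rate 0, and
missing (NaN) lifetime/interval; missing values propagate into the GLM
stage where subjects are dropped per feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STAT_COLUMNS = (
    "fractional_occupancy",
    "mean_lifetime_ms",
    "mean_interval_s",
    "switching_rate_hz",
)


def map_states(gamma: np.ndarray) -> np.ndarray:
    """Maximum a posteriori state per sample from (T, K) probabilities.

    Ties go to the lowest state index (argmax convention).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(np.isnan(gamma)):
        raise ValueError("state probabilities contain NaN")
    return gamma.argmax(axis=1)


def _runs(states: np.ndarray):
    """Run-length encoding: (labels, run_lengths, onsets)."""
    states = np.asarray(states)
    change = np.flatnonzero(np.diff(states)) + 1
    onsets = np.concatenate(([0], change))
    ends = np.concatenate((change, [states.size]))
    return states[onsets], ends - onsets, onsets


def summary_stats(
    states: np.ndarray,
    n_states: int,
    sampling_rate_hz: float,
    interval_mode: str = "gap",
    include_censored: bool = True,
) -> pd.DataFrame:
    """Per-state dynamics statistics of one MAP state time course.

    Parameters
    ----------
    states : int array (n_samples,)
        MAP sequence, values in 0..n_states-1.
    interval_mode : {"gap", "onset"}
        "gap" measures end-of-visit to start-of-next-visit; "onset"
        measures onset-to-onset.
    include_censored : bool
        Include the (possibly truncated) first and last visits in the
        lifetime means.

    Returns
    -------
    DataFrame indexed by state with columns ``STAT_COLUMNS``.
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("empty state sequence")
    if sampling_rate_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError(
            f"state label {states.min() if states.min() < 0 else states.max()} "
            f"outside 0..{n_states - 1}"
        )
    if interval_mode not in ("gap", "onset"):
        raise ValueError("interval_mode must be 'gap' or 'onset'")

    fs = sampling_rate_hz
    T = states.size
    labels, lengths, onsets = _runs(states)
    total_s = T / fs

    rows = []
    for k in range(n_states):
        mask = labels == k
        n_visits = int(mask.sum())
        fo = lengths[mask].sum() / T
        if n_visits == 0:
            rows.append((0.0, np.nan, np.nan, 0.0))
            continue
        lens = lengths[mask]
        if not include_censored:
            keep = np.ones(n_visits, dtype=bool)
            idx = np.flatnonzero(mask)
            if idx[0] == 0:
                keep[0] = False
            if idx[-1] == labels.size - 1:
                keep[-1] = False
            lens = lens[keep]
        lifetime_ms = 1000.0 * lens.mean() / fs if lens.size else np.nan
        k_onsets = onsets[mask]
        k_ends = k_onsets + lengths[mask]
        if n_visits > 1:
            if interval_mode == "gap":
                gaps = k_onsets[1:] - k_ends[:-1]
            else:
                gaps = np.diff(k_onsets)
            interval_s = gaps.mean() / fs
        else:
            interval_s = np.nan
        rate = n_visits / total_s
        rows.append((fo, lifetime_ms, interval_s, rate))

    return pd.DataFrame(rows, columns=list(STAT_COLUMNS)).rename_axis("state")


def cohort_summary_stats(
    state_courses: list,
    n_states: int,
    sampling_rate_hz: float,
    **kwargs,
) -> pd.DataFrame:
    """Long-format summary statistics for a cohort (subject, state, stats)."""
    frames = []
    for s, stc in enumerate(state_courses):
        df = summary_stats(stc, n_states, sampling_rate_hz, **kwargs).reset_index()
        df.insert(0, "subject", s)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def subject_transition_matrix(
    states: np.ndarray, n_states: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical transition matrix of a state sequence.

    Counts include self-transitions, so the diagonal is the empirical stay
    probability.  Rows of never-visited states are set uniform and flagged.

    Returns
    -------
    a : ndarray (K, K), rows summing to 1
    empty_rows : bool ndarray (K,), True where the row had no counts
    """
    states = np.asarray(states)
    if states.size < 2:
        raise ValueError("need at least 2 samples to count transitions")
    if states.min() < 0 or states.max() >= n_states:
        raise ValueError("state label outside 0..K-1")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (states[:-1], states[1:]), 1.0)
    rows = counts.sum(axis=1)
    empty = rows == 0
    a = np.where(
        empty[:, None], 1.0 / n_states, counts / np.where(rows == 0, 1.0, rows)[:, None]
    )
    return a, empty
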
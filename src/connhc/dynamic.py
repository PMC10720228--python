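"""Sliding-window time-resolved functional connectivity and FC states.

Windowed Pearson FC (18-volume rectangular windows, 60% overlap by
default), k-means clustering of window-wise edge vectors with correlation
distance (realized by row standardization), cluster-count selection over
k = 2..10 via the Calinski-Harabasz and Davies-Bouldin indices with a
silhouette check, and per-subject state-dynamics summaries: number of
transitions (NT), mean dwell time per state (MDT, in windows), and state
frequency (FRC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .connectome import edge_indices

__all__ = [
    "WindowSpec",
    "StateModel",
    "StateDynamics",
    "make_windows",
    "windowed_fc",
    "cluster_states",
    "state_metrics",
    "compare_state_dynamics",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Sliding-window geometry: 18 volumes with 60% overlap (step
    round(18 * 0.4) = 7) at TR 2.5 s gives 45-second windows."""

    length_volumes: int = 18
    overlap_fraction: float = 0.6
    tr_seconds: float = 2.5
    step_override: int | None = None

    @property
    def step_volumes(self) -> int:
        if self.step_override is not None:
            return self.step_override
        step = int(round(self.length_volumes * (1.0 - self.overlap_fraction)))
        return max(step, 1)

    @property
    def duration_seconds(self) -> float:
        return self.length_volumes * self.tr_seconds


def make_windows(n_timepoints: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Fully contained ``[start, stop)`` ranges; trailing partials dropped."""
    if n_timepoints < spec.length_volumes:
        raise ValueError(
            f"series of {n_timepoints} volumes is shorter than one "
            f"{spec.length_volumes}-volume window"
        )
    starts = range(0, n_timepoints - spec.length_volumes + 1, spec.step_volumes)
    return [(s, s + spec.length_volumes) for s in starts]


def windowed_fc(
    timeseries: np.ndarray,
    windows: list[tuple[int, int]],
    fisher_z: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window Pearson FC vectorized in canonical edge order.

    Returns ``(W x E matrix, flags)``; a window containing a zero-variance
    parcel is flagged and filled with NaN rather than raising.  Raw r by
    default (``fisher_z=True`` applies atanh with clipping).
    """
    x = np.asarray(timeseries, dtype=float)
    rows, cols = edge_indices(x.shape[1])
    out = np.empty((len(windows), rows.size))
    flags = np.zeros(len(windows), dtype=bool)
    for w, (a, b) in enumerate(windows):
        seg = x[a:b]
        if np.any(seg.std(axis=0) == 0):
            flags[w] = True
            out[w] = np.nan
            continue
        r = np.corrcoef(seg, rowvar=False)[rows, cols]
        if fisher_z:
            r = np.arctanh(np.clip(r, -(1 - 1e-7), 1 - 1e-7))
        out[w] = r
    return out, flags


@dataclass
class StateModel:
    """Pooled k-means FC-state solution with selection diagnostics."""

    k: int
    centroids: np.ndarray
    labels: np.ndarray
    ch_index: dict[int, float]
    db_index: dict[int, float]
    silhouette: float
    ch_choice: int
    db_choice: int
    selection_conflict: bool
    inertia: float = float("nan")


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and unit-scale each row so Euclidean k-means equals
    correlation-distance clustering."""
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("a window has zero variance across edges")
    return (x - mu) / sd


def cluster_states(
    window_fc: np.ndarray,
    k_range: range = range(2, 11),
    seed: int = 0,
    n_init: int = 20,
    max_iter: int = 300,
) -> StateModel:
    """k-means over pooled windows (states estimated jointly for the whole
    sample) with correlation distance; k selected by maximizing the
    Calinski-Harabasz index, cross-checked against the Davies-Bouldin
    minimizer (disagreements are logged, CH wins)."""
    x = np.asarray(window_fc, dtype=float)
    valid = ~np.isnan(x).any(axis=1)
    xs = _standardize_rows(x[valid])
    if xs.shape[0] < max(k_range) + 1:
        raise ValueError(
            f"only {xs.shape[0]} windows for k up to {max(k_range)}"
        )
    ch: dict[int, float] = {}
    db: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        km = KMeans(
            n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed
        ).fit(xs)
        fits[k] = km
        ch[k] = calinski_harabasz_score(xs, km.labels_)
        db[k] = davies_bouldin_score(xs, km.labels_)
    ch_choice = max(ch, key=ch.get)
    db_choice = min(db, key=db.get)
    conflict = ch_choice != db_choice
    if conflict:
        logger.warning(
            "cluster-count selection conflict: CH prefers k=%d, DB prefers k=%d; "
            "keeping the CH choice", ch_choice, db_choice,
        )
    best = fits[ch_choice]
    labels = np.full(x.shape[0], -1, dtype=int)
    labels[valid] = best.labels_
    return StateModel(
        k=ch_choice,
        centroids=best.cluster_centers_,
        labels=labels,
        ch_index=ch,
        db_index=db,
        silhouette=float(silhouette_score(xs, best.labels_)),
        ch_choice=ch_choice,
        db_choice=db_choice,
        selection_conflict=conflict,
        inertia=float(best.inertia_),
    )


@dataclass
class StateDynamics:
    """Per-subject temporal summaries of an FC-state assignment sequence."""

    nt: int
    mdt: dict[int, float]  # mean dwell time per state, windows; NaN if unvisited
    frc: dict[int, float]  # fraction of windows per state
    n_windows: int = 0


def state_metrics(sequence: np.ndarray, n_states: int | None = None) -> StateDynamics:
    """NT / MDT / FRC from one assignment sequence.

    NT counts consecutive unequal pairs; MDT per state is the mean length
    of that state's maximal runs (NaN for unvisited states); FRC sums to 1.
    """
    seq = np.asarray(sequence, dtype=int).ravel()
    if seq.size == 0:
        raise ValueError("empty state sequence")
    states = range(int(seq.max()) + 1 if n_states is None else n_states)
    nt = int((seq[1:] != seq[:-1]).sum())
    # run-length encoding
    change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
    starts = np.concatenate([[0], change])
    lengths = np.diff(np.concatenate([starts, [seq.size]]))
    run_states = seq[starts]
    mdt = {}
    frc = {}
    for s in states:
        runs = lengths[run_states == s]
        mdt[s] = float(runs.mean()) if runs.size else float("nan")
        frc[s] = float((seq == s).sum() / seq.size)
    return StateDynamics(nt=nt, mdt=mdt, frc=frc, n_windows=int(seq.size))


def dynamics_table(
    per_subject: dict[str, StateDynamics], n_states: int
) -> pd.DataFrame:
    """Long-to-wide table of NT/MDT/FRC, one row per subject."""
    rows = []
    for sid, dyn in per_subject.items():
        row = {"subject_id": sid, "nt": dyn.nt}
        for s in range(n_states):
            row[f"mdt_state{s + 1}"] = dyn.mdt.get(s, float("nan"))
            row[f"frc_state{s + 1}"] = dyn.frc.get(s, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_state_dynamics(
    table: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    case_label: object = "case",
) -> pd.DataFrame:
    """Group comparison of state dynamics in the conventional layout:
    two-sided t-test for NT (mean +- sd summaries), Mann-Whitney U for each
    state's MDT and FRC (median (range) summaries).

    A metric undefined for every subject of one group (state never visited)
    is flagged instead of tested.
    """
    g = np.asarray(groups)
    case = g == case_label
    if case.all() or (~case).all():
        raise ValueError("both groups must be non-empty")

    def describe_mean(x: np.ndarray) -> str:
        return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"

    def describe_median(x: np.ndarray) -> str:
        return f"{np.median(x):.2f} ({np.min(x):.2f}-{np.max(x):.2f})"

    rows = []
    for col in [c for c in table.columns if c != "subject_id"]:
        vals = table[col].to_numpy(float)
        a, b = vals[case], vals[~case]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            rows.append(
                {"metric": col, "test": "none", "p": float("nan"),
                 "case_summary": "undefined", "control_summary": "undefined",
                 "flagged": True}
            )
            continue
        if col == "nt":
            stat, p = stats.ttest_ind(a, b)
            rows.append(
                {"metric": col, "test": "t", "p": float(p),
                 "case_summary": describe_mean(a),
                 "control_summary": describe_mean(b), "flagged": False}
            )
        else:
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                p = 1.0
            else:
                _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append(
                {"metric": col, "test": "mannwhitney", "p": float(p),
                 "case_summary": describe_median(a),
                 "control_summary": describe_median(b), "flagged": False}
            )
    return pd.DataFrame(rows)
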
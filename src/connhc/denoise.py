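"""Parcel-level confound modelling and denoising.

Implements the standard rs-fMRI nuisance pipeline at the parcel level:
framewise displacement (Power convention) and DVARS, the 24-parameter
motion + 8-parameter physiological confound expansion, motion/DVARS spike
regressors, least-squares nuisance regression, zero-phase band-pass
filtering (0.008-0.08 Hz), and subject-level motion exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import signal

__all__ = [
    "ConfoundSet",
    "ExclusionDecision",
    "framewise_displacement",
    "dvars",
    "expand_confounds",
    "spike_regressors",
    "nuisance_regression",
    "bandpass",
    "motion_exclusion",
    "denoise_subject",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
TISSUE_COLUMNS = ["wm", "csf"]


@dataclass
class ConfoundSet:
    """Per-subject confound bundle (motion in mm/radians, tissue means,
    FD in mm, standardized DVARS, one-hot spike indicators)."""

    motion: np.ndarray
    tissue_signals: np.ndarray
    fd: np.ndarray
    dvars: np.ndarray
    spike_indicators: np.ndarray


@dataclass
class ExclusionDecision:
    subject_id: str
    excluded: bool
    reasons: list[str] = field(default_factory=list)


def framewise_displacement(
    motion: np.ndarray | pd.DataFrame, head_radius: float = 50.0
) -> np.ndarray:
    """Power-style framewise displacement.

    ``fd[t] = sum |d translation| + head_radius * sum |d rotation|`` with
    backward differences; ``fd[0] = 0`` by convention.  Rotations must be
    in radians.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be a T x 6 array")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    d = np.abs(np.diff(m, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(timeseries: np.ndarray, standardize: bool = True) -> np.ndarray:
    """Root-mean-square (over parcels) of the backward temporal difference.

    With ``standardize=True`` (default) the series is divided by its own
    median so the conventional "> 3" spike threshold applies; the raw RMS
    is available with ``standardize=False``.  First frame is 0.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("timeseries must be T x P with T >= 2")
    d = np.diff(x, axis=0)
    raw = np.sqrt((d**2).mean(axis=1))
    out = np.concatenate([[0.0], raw])
    if not standardize:
        return out
    med = np.median(raw)
    if med == 0:
        raise ValueError("DVARS median is zero (constant series); cannot standardize")
    return out / med


def expand_confounds(
    motion: np.ndarray | pd.DataFrame,
    tissue_signals: np.ndarray | pd.DataFrame,
) -> pd.DataFrame:
    """24-parameter motion + 8-parameter physiological confound expansion.

    For each of the 6 motion parameters and 2 tissue signals: the parameter,
    its backward-difference derivative (first row 0), and the squares of
    both.  Column order: params, derivatives, squared params, squared
    derivatives — 24 motion-derived plus 8 tissue-derived columns.
    """
    m = np.asarray(motion, dtype=float)
    t = np.asarray(tissue_signals, dtype=float)
    if m.shape[1] != 6:
        raise ValueError("motion must have 6 columns")
    if t.shape[1] != 2:
        raise ValueError("tissue_signals must have 2 columns")

    def block(x: np.ndarray, names: list[str]) -> pd.DataFrame:
        deriv = np.vstack([np.zeros((1, x.shape[1])), np.diff(x, axis=0)])
        cols = {}
        for j, name in enumerate(names):
            cols[name] = x[:, j]
        for j, name in enumerate(names):
            cols[f"{name}_derivative1"] = deriv[:, j]
        for j, name in enumerate(names):
            cols[f"{name}_power2"] = x[:, j] ** 2
        for j, name in enumerate(names):
            cols[f"{name}_derivative1_power2"] = deriv[:, j] ** 2
        return pd.DataFrame(cols)

    out = pd.concat([block(m, MOTION_COLUMNS), block(t, TISSUE_COLUMNS)], axis=1)
    assert out.shape[1] == 32
    return out


def spike_regressors(
    fd: np.ndarray,
    dvars_series: np.ndarray,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 3.0,
) -> np.ndarray:
    """One indicator column per frame exceeding the FD or DVARS threshold
    (union semantics: a frame flagged by both still yields one column)."""
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dvars_series, dtype=float)
    if fd.shape != dv.shape:
        raise ValueError("fd and dvars must have equal length")
    flagged = np.flatnonzero((fd > fd_thresh) | (dv > dvars_thresh))
    spikes = np.zeros((fd.size, flagged.size))
    spikes[flagged, np.arange(flagged.size)] = 1.0
    return spikes


def nuisance_regression(
    timeseries: np.ndarray, confounds: np.ndarray | pd.DataFrame
) -> np.ndarray:
    """Per-parcel least-squares residual after regression on the confound
    columns plus an intercept.  Collinear confound columns are dropped with
    a warning; residuals are orthogonal to every retained column.
    """
    y = np.asarray(timeseries, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if y.shape[0] != c.shape[0]:
        raise ValueError("timeseries and confounds must have equal length")
    x = np.hstack([np.ones((y.shape[0], 1)), c])
    if y.shape[0] <= x.shape[1]:
        raise ValueError("need more timepoints than confound columns")
    # Rank-revealing QR: drop columns that add nothing beyond tolerance.
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag[0] * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        dropped = sorted(piv[rank:])
        warnings.warn(
            f"confound matrix is rank deficient; dropping columns {dropped}",
            stacklevel=2,
        )
        keep = sorted(piv[:rank])
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def bandpass(
    timeseries: np.ndarray,
    tr_seconds: float,
    low: float = 0.008,
    high: float = 0.08,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward) along time."""
    fs = 1.0 / tr_seconds
    nyq = fs / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie strictly inside (0, {nyq:.4g}) Hz"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(timeseries, dtype=float), axis=0)


def motion_exclusion(
    fd: np.ndarray,
    subject_id: str = "",
    mean_fd_thresh: float = 0.3,
    max_fd_thresh: float = 5.0,
    outlier_fraction_thresh: float = 0.2,
    fd_spike_thresh: float = 0.5,
) -> ExclusionDecision:
    """Subject-level motion exclusion: mean FD > 0.3 mm, max FD > 5 mm, or
    more than 20% of frames above the spike threshold (0.5 mm)."""
    fd = np.asarray(fd, dtype=float)
    reasons = []
    if fd.mean() > mean_fd_thresh:
        reasons.append("mean_fd")
    if fd.max() > max_fd_thresh:
        reasons.append("max_fd")
    if (fd > fd_spike_thresh).mean() > outlier_fraction_thresh:
        reasons.append("outlier_fraction")
    return ExclusionDecision(subject_id=subject_id, excluded=bool(reasons), reasons=reasons)


def denoise_subject(
    timeseries: np.ndarray,
    motion: np.ndarray | pd.DataFrame,
    tissue_signals: np.ndarray | pd.DataFrame,
    tr_seconds: float,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 3.0,
    low: float = 0.008,
    high: float = 0.08,
) -> tuple[np.ndarray, ConfoundSet]:
    """Full per-subject denoising: 24+8 confound expansion plus spike
    regression, then band-pass filtering (in that order)."""
    fd = framewise_displacement(motion)
    dv = dvars(timeseries)
    spikes = spike_regressors(fd, dv, fd_thresh, dvars_thresh)
    expanded = expand_confounds(motion, tissue_signals)
    design = np.hstack([expanded.to_numpy(), spikes])
    residuals = nuisance_regression(timeseries, design)
    filtered = bandpass(residuals, tr_seconds, low, high)
    confset = ConfoundSet(
        motion=np.asarray(motion, dtype=float),
        tissue_signals=np.asarray(tissue_signals, dtype=float),
        fd=fd,
        dvars=dv,
        spike_indicators=spikes,
    )
    return filtered, confset
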
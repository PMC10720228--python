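"""Per-edge linear models for group differences in Fisher-z connectivity.

One ordinary-least-squares model per connection:

    z_edge ~ intercept + group + sex + age_std + mean_fd

The two-sided p-value of the group coefficient feeds the Higher-Criticism
and FDR stages; the partial eta-squared effect size is t^2 / (t^2 + df).
Fits are fully vectorized across edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DesignMatrix", "EdgeStats", "build_design", "fit_edge", "fit_all_edges"]

DESIGN_COLUMNS = ["intercept", "group", "sex", "age_std", "mean_fd"]

_CONTROL_LABELS = {"control", "con", "ctrl", "hc", "0", "controls"}


@dataclass
class DesignMatrix:
    """n_subjects x 5 design with named columns and the coding record."""

    X: np.ndarray
    columns: list[str]
    coding: dict[str, str]
    group_indicator: np.ndarray  # 0 = reference (control), 1 = case

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class EdgeStats:
    edge: int
    beta_group: float
    t_group: float
    p_group: float
    partial_eta2: float
    group_mean_diff_z: float
    flagged: bool = False


def _pick_reference(levels: list, preferred: set[str]) -> object:
    for lv in levels:
        if str(lv).lower() in preferred:
            return lv
    return sorted(levels, key=str)[0]


def build_design(
    manifest: pd.DataFrame,
    reference_group: object | None = None,
    include_covariates: bool = True,
) -> DesignMatrix:
    """Design matrix from a subject manifest (subject_id, group, sex, age,
    mean_fd).

    Group and sex are dummy-coded 0/1 (reference = the control-like label
    if recognized, else the alphabetically first level); age is standardized
    to mean 0, sample (n-1) s.d. 1 over the pooled included subjects.  With
    ``include_covariates=False`` only intercept + group are kept, which
    makes the edge fit equivalent to a two-sample t-test.
    """
    for col in ("group", "sex", "age", "mean_fd"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    glv = sorted(manifest["group"].unique(), key=str)
    slv = sorted(manifest["sex"].unique(), key=str)
    if len(glv) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {glv}")
    if len(slv) != 2:
        raise ValueError(f"sex must have exactly 2 levels, got {slv}")
    g_ref = reference_group if reference_group is not None else _pick_reference(glv, _CONTROL_LABELS)
    if g_ref not in glv:
        raise ValueError(f"reference group {g_ref!r} not among levels {glv}")
    s_ref = _pick_reference(slv, {"m", "male", "0"})
    group = (manifest["group"] != g_ref).to_numpy(float)
    if group.min() == group.max():
        raise ValueError("group indicator is constant")
    age = manifest["age"].to_numpy(float)
    if age.std(ddof=1) == 0:
        raise ValueError("age has zero variance; cannot standardize")
    age_std = (age - age.mean()) / age.std(ddof=1)
    n = len(manifest)
    if include_covariates:
        sex = (manifest["sex"] != s_ref).to_numpy(float)
        X = np.column_stack(
            [np.ones(n), group, sex, age_std, manifest["mean_fd"].to_numpy(float)]
        )
        columns = list(DESIGN_COLUMNS)
    else:
        X = np.column_stack([np.ones(n), group])
        columns = ["intercept", "group"]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(
        X=X,
        columns=columns,
        coding={"group_reference": str(g_ref), "sex_reference": str(s_ref)},
        group_indicator=group,
    )


def fit_all_edges(Z: np.ndarray, design: DesignMatrix) -> pd.DataFrame:
    """OLS over all edges at once.

    Parameters
    ----------
    Z : n_subjects x n_edges array of Fisher-z values (canonical edge order).
    design : output of :func:`build_design`.

    Returns a DataFrame with one row per edge: ``beta_group, t_group,
    p_group, partial_eta2, group_mean_diff_z, flagged``.  Edges with zero
    residual variance are flagged rather than aborting the run (convention:
    p = 1 when the group coefficient is exactly 0, else p = 0).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    X = design.X
    n, k = X.shape
    if Z.shape[0] != n:
        raise ValueError(f"Z has {Z.shape[0]} rows, design has {n} subjects")
    df = n - k
    if df < 1:
        raise ValueError("residual degrees of freedom < 1")
    gidx = design.columns.index("group")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Z                      # k x E
    resid = Z - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    var_g = sigma2 * xtx_inv[gidx, gidx]
    beta_g = beta[gidx]

    scale = max(1.0, float(np.abs(Z).max(initial=1.0)))
    flagged = sigma2 <= np.finfo(float).eps * scale
    zero_beta = np.abs(beta_g) <= 1e-10 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_g / np.sqrt(var_g)
    t = np.where(flagged & zero_beta, 0.0, t)
    t = np.where(flagged & ~zero_beta, np.sign(beta_g) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore"):
        eta2 = np.where(np.isinf(t), 1.0, t**2 / (t**2 + df))

    case = design.group_indicator == 1
    diff = Z[case].mean(axis=0) - Z[~case].mean(axis=0)
    return pd.DataFrame(
        {
            "edge": np.arange(Z.shape[1]),
            "beta_group": beta_g,
            "t_group": t,
            "p_group": p,
            "partial_eta2": eta2,
            "group_mean_diff_z": diff,
            "flagged": flagged,
        }
    )


def fit_edge(z_values: np.ndarray, design: DesignMatrix) -> EdgeStats:
    """Fit a single connection; see :func:`fit_all_edges`."""
    row = fit_all_edges(np.asarray(z_values, dtype=float)[:, None], design).iloc[0]
    return EdgeStats(
        edge=0,
        beta_group=float(row.beta_group),
        t_group=float(row.t_group),
        p_group=float(row.p_group),
        partial_eta2=float(row.partial_eta2),
        group_mean_diff_z=float(row.group_mean_diff_z),
        flagged=bool(row.flagged),
    )
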
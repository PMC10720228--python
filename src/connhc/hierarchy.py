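"""Three-level hierarchical inference over a cognitive connectome.

Level 1: a global Higher-Criticism omnibus test over every parcel-pair
group p-value.  Level 2: one HC test per network (its within-network
edges) plus one HC test over the 45 between-network connections, computed
from network-mean series.  Level 3: Benjamini-Hochberg FDR on individual
connections — across all edges, across the 45 between-network edges, and
within each network separately.  Level-3 FDR runs unconditionally; no
sequential alpha-spending is imposed by the hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .connectome import (
    NetworkPartition,
    edge_indices,
    matrix_from_edges,
    network_timeseries,
    static_fc,
)
from .edge_models import DesignMatrix, fit_all_edges
from .higher_criticism import HCNull, HCResult, hc_null_distribution, hc_test

__all__ = [
    "HierarchyReport",
    "fdr_adjust",
    "run_hierarchy",
    "static_pipeline",
    "report_summary",
]


@dataclass
class HierarchyReport:
    """Complete output of the three-level analysis."""

    global_hc: HCResult
    within_hc: dict[str, HCResult]
    between_hc: HCResult
    fdr_global: pd.DataFrame
    fdr_between: pd.DataFrame
    fdr_within: dict[str, pd.DataFrame]
    parcel_edges: pd.DataFrame
    network_edges: pd.DataFrame
    q: float = 0.05
    effect_size_matrix: np.ndarray | None = None
    diff_matrix: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def fdr_adjust(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and discovery flags.

    Adjusted values are monotone and capped at 1; an edge is discovered
    iff its adjusted p-value is <= q.
    """
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


def _discovery_table(edges: pd.DataFrame, q: float) -> pd.DataFrame:
    adjusted, flags = fdr_adjust(edges["p_group"].to_numpy(), q)
    out = edges.copy()
    out["p_adjusted"] = adjusted
    out["discovered"] = flags
    return out


def run_hierarchy(
    parcel_edges: pd.DataFrame,
    network_edges: pd.DataFrame,
    partition: NetworkPartition,
    *,
    variant: str = "hc_plus",
    alpha0: float = 0.5,
    alpha: float = 0.05,
    q: float = 0.05,
    n_null: int = 10_000,
    null_seed: int = 12345,
    null_cache: dict[int, HCNull] | None = None,
) -> HierarchyReport:
    """Run the three inference levels on fitted edge tables.

    ``parcel_edges`` must carry one row per global parcel edge in canonical
    order with columns ``i, j, p_group`` (plus any effect-size columns);
    ``network_edges`` one row per between-network connection.  Monte-Carlo
    HC nulls are computed per p-value-set size and may be shared across
    calls through ``null_cache``.
    """
    n_parcels = partition.n_parcels
    rows, cols = edge_indices(n_parcels)
    if len(parcel_edges) != rows.size:
        raise ValueError(
            f"expected {rows.size} global edges for {n_parcels} parcels, "
            f"got {len(parcel_edges)}"
        )
    n_networks = len(partition.networks)
    n_between = n_networks * (n_networks - 1) // 2
    if len(network_edges) != n_between:
        raise ValueError(
            f"expected {n_between} between-network edges, got {len(network_edges)}"
        )

    cache = null_cache if null_cache is not None else {}

    def null_for(n: int) -> HCNull:
        key = n
        if key not in cache:
            cache[key] = hc_null_distribution(
                n, variant, alpha0, n_replicates=n_null, seed=null_seed + n
            )
        return cache[key]

    p_global = parcel_edges["p_group"].to_numpy()
    global_hc = hc_test(p_global, null_for(p_global.size), alpha=alpha)

    net_of = np.asarray(partition.network_of, dtype=object)
    within_hc: dict[str, HCResult] = {}
    fdr_within: dict[str, pd.DataFrame] = {}
    within_mask = net_of[parcel_edges["i"].to_numpy()] == net_of[parcel_edges["j"].to_numpy()]
    for net in partition.networks:
        mask = within_mask & (net_of[parcel_edges["i"].to_numpy()] == net)
        sub = parcel_edges[mask]
        within_hc[net] = hc_test(
            sub["p_group"].to_numpy(), null_for(len(sub)), alpha=alpha
        )
        fdr_within[net] = _discovery_table(sub, q)

    p_between = network_edges["p_group"].to_numpy()
    between_hc = hc_test(p_between, null_for(p_between.size), alpha=alpha)

    report = HierarchyReport(
        global_hc=global_hc,
        within_hc=within_hc,
        between_hc=between_hc,
        fdr_global=_discovery_table(parcel_edges, q),
        fdr_between=_discovery_table(network_edges, q),
        fdr_within=fdr_within,
        parcel_edges=parcel_edges,
        network_edges=network_edges,
        q=q,
    )
    if "partial_eta2" in parcel_edges.columns:
        report.effect_size_matrix = matrix_from_edges(
            parcel_edges["partial_eta2"].to_numpy(), n_parcels
        )
    if "group_mean_diff_z" in parcel_edges.columns:
        report.diff_matrix = matrix_from_edges(
            parcel_edges["group_mean_diff_z"].to_numpy(), n_parcels
        )
    return report


def static_pipeline(
    timeseries: dict[str, np.ndarray],
    manifest: pd.DataFrame,
    partition: NetworkPartition,
    design: DesignMatrix,
    **hierarchy_kwargs,
) -> HierarchyReport:
    """Subject series -> Fisher-z edges (parcel and network level) -> edge
    models -> three-level hierarchy.  Subject order follows the manifest."""
    ids = list(manifest["subject_id"])
    rows, cols = edge_indices(partition.n_parcels)
    n_networks = len(partition.networks)
    nrows, ncols = edge_indices(n_networks)

    Zp = np.empty((len(ids), rows.size))
    Zn = np.empty((len(ids), nrows.size))
    for s, sid in enumerate(ids):
        z = static_fc(timeseries[sid])
        Zp[s] = z[rows, cols]
        zn = static_fc(network_timeseries(timeseries[sid], partition))
        Zn[s] = zn[nrows, ncols]

    parcel_edges = fit_all_edges(Zp, design)
    parcel_edges.insert(0, "j", cols)
    parcel_edges.insert(0, "i", rows)
    network_edges = fit_all_edges(Zn, design)
    network_edges.insert(0, "j", ncols)
    network_edges.insert(0, "i", nrows)
    return run_hierarchy(parcel_edges, network_edges, partition, **hierarchy_kwargs)


def report_summary(report: HierarchyReport, partition: NetworkPartition) -> dict:
    """Machine-readable summary (JSON-serializable) of a hierarchy run."""
    return {
        "global": report.global_hc.to_dict(),
        "within_network": {
            net: hc.to_dict() for net, hc in report.within_hc.items()
        },
        "between_network": report.between_hc.to_dict(),
        "fdr": {
            "q": report.q,
            "n_discoveries_global": int(report.fdr_global["discovered"].sum()),
            "n_discoveries_between": int(report.fdr_between["discovered"].sum()),
            "n_discoveries_within": {
                net: int(tbl["discovered"].sum())
                for net, tbl in report.fdr_within.items()
            },
        },
        "networks": partition.networks,
    }
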
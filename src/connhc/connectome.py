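"""Static functional-connectivity representations.

Fisher-z Pearson correlation matrices from parcel time series, network-mean
("concatenated") series, and the deterministic edge vectorization used by
every downstream stage.  Edge order is the row-major upper triangle in atlas
order, recorded explicitly so matrices can be reconstructed losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NetworkPartition",
    "static_fc",
    "network_timeseries",
    "edge_vector",
    "edge_indices",
    "matrix_from_edges",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class NetworkPartition:
    """Parcel -> network assignment with deterministic ordering.

    Built from an atlas lookup table (``parcel_id``, ``parcel_name``,
    ``network_label``, optional ``size``).  Networks are ordered by first
    appearance in the table; parcels keep table order.
    """

    parcel_ids: list
    parcel_names: list[str]
    network_of: list[str]
    sizes: np.ndarray | None = None

    @classmethod
    def from_atlas(cls, atlas: pd.DataFrame) -> "NetworkPartition":
        required = {"parcel_id", "network_label"}
        missing = required - set(atlas.columns)
        if missing:
            raise ValueError(f"atlas lookup is missing columns: {sorted(missing)}")
        names = (
            list(atlas["parcel_name"])
            if "parcel_name" in atlas.columns
            else [str(p) for p in atlas["parcel_id"]]
        )
        sizes = atlas["size"].to_numpy(float) if "size" in atlas.columns else None
        return cls(
            parcel_ids=list(atlas["parcel_id"]),
            parcel_names=names,
            network_of=list(atlas["network_label"]),
            sizes=sizes,
        )

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.network_of:
            seen.setdefault(label, None)
        return list(seen)

    def indices(self, network: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.network_of, dtype=object) == network)
        if idx.size == 0:
            raise ValueError(f"unknown or empty network {network!r}")
        return idx


def static_fc(timeseries: np.ndarray) -> np.ndarray:
    """Fisher z-transformed Pearson correlation matrix of a T x P series.

    r is clipped to +-(1 - 1e-7) before atanh so duplicated parcels stay
    finite; the diagonal is set to 0 (undefined by convention).  A parcel
    with zero variance raises, naming the parcel.
    """
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("timeseries must be T x P with T >= 3")
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance parcel(s) at index {bad.tolist()}")
    r = np.corrcoef(x, rowvar=False)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    np.fill_diagonal(z, 0.0)
    return z


def network_timeseries(
    timeseries: np.ndarray,
    partition: NetworkPartition,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """One series per network: the (optionally size-weighted) mean of its
    parcels' series.  Returns T x n_networks in partition network order."""
    x = np.asarray(timeseries, dtype=float)
    if x.shape[1] != partition.n_parcels:
        raise ValueError(
            f"timeseries has {x.shape[1]} parcels, partition has {partition.n_parcels}"
        )
    if weights is None:
        weights = partition.sizes
    out = np.empty((x.shape[0], len(partition.networks)))
    for k, net in enumerate(partition.networks):
        idx = partition.indices(net)
        if weights is None:
            out[:, k] = x[:, idx].mean(axis=1)
        else:
            w = np.asarray(weights, dtype=float)[idx]
            out[:, k] = x[:, idx] @ (w / w.sum())
    return out


def edge_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge order: row-major upper triangle (i < j)."""
    return np.triu_indices(n, k=1)


def edge_vector(
    matrix: np.ndarray,
    partition: NetworkPartition | None = None,
    scope: str = "global",
) -> pd.DataFrame:
    """Vectorize a symmetric connectivity matrix into the deterministic
    edge order for a given scope.

    ``scope`` is ``"global"`` (all parcel pairs), ``"within:<network>"``
    (pairs inside one network), or ``"between_networks"`` (the matrix must
    be the network-level n x n matrix; 10 networks yield 45 edges).
    Returns a DataFrame with columns ``i, j, scope, value``.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if scope == "global":
        rows, cols = edge_indices(m.shape[0])
    elif scope == "between_networks":
        if partition is not None and m.shape[0] != len(partition.networks):
            raise ValueError(
                "between_networks scope expects the network-level matrix "
                f"({len(partition.networks)} x {len(partition.networks)})"
            )
        rows, cols = edge_indices(m.shape[0])
    elif scope.startswith("within:"):
        if partition is None:
            raise ValueError("within-network scope requires a partition")
        idx = partition.indices(scope.split(":", 1)[1])
        sub_r, sub_c = edge_indices(idx.size)
        rows, cols = idx[sub_r], idx[sub_c]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return pd.DataFrame(
        {"i": rows, "j": cols, "scope": scope, "value": m[rows, cols]}
    )


def matrix_from_edges(values: np.ndarray, n: int) -> np.ndarray:
    """Rebuild a symmetric matrix (zero diagonal) from canonical edge order."""
    rows, cols = edge_indices(n)
    if values.shape[0] != rows.size:
        raise ValueError(f"expected {rows.size} edge values, got {values.shape[0]}")
    m = np.zeros((n, n))
    m[rows, cols] = values
    m[cols, rows] = values
    return m
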
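"""Cohort file I/O: plain TSV/CSV tables plus a config echo sidecar.

Layout written by :func:`write_cohort` and consumed by :func:`load_cohort`:

    <dir>/manifest.csv            subject_id, group, sex, age, mean_fd
    <dir>/atlas.csv               parcel_id, parcel_name, network_label
    <dir>/timeseries/<sub>.tsv    T rows x P parcels, header = parcel names
    <dir>/confounds/<sub>.tsv     trans_x..rot_z, wm, csf
    <dir>/config.yaml             full simulation/run configuration echo
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import NetworkPartition
from .simulate import Cohort, SimulationConfig

__all__ = ["CohortPaths", "write_cohort", "load_cohort", "LoadedCohort"]

logger = logging.getLogger(__name__)


@dataclass
class CohortPaths:
    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)

    @property
    def manifest(self) -> Path:
        return self.root / "manifest.csv"

    @property
    def atlas(self) -> Path:
        return self.root / "atlas.csv"

    @property
    def timeseries_dir(self) -> Path:
        return self.root / "timeseries"

    @property
    def confounds_dir(self) -> Path:
        return self.root / "confounds"

    @property
    def config(self) -> Path:
        return self.root / "config.yaml"


@dataclass
class LoadedCohort:
    manifest: pd.DataFrame
    timeseries: dict[str, np.ndarray]
    confounds: dict[str, pd.DataFrame]
    partition: NetworkPartition
    atlas: pd.DataFrame
    config: dict | None = None


def write_cohort(cohort: Cohort, outdir: str | Path) -> CohortPaths:
    """Write a simulated cohort to plain-text tables (see module docs)."""
    paths = CohortPaths(Path(outdir))
    paths.timeseries_dir.mkdir(parents=True, exist_ok=True)
    paths.confounds_dir.mkdir(parents=True, exist_ok=True)
    cohort.manifest.to_csv(paths.manifest, index=False)
    cohort.atlas.to_csv(paths.atlas, index=False)
    parcel_names = list(cohort.atlas["parcel_name"])
    for sid, ts in cohort.timeseries.items():
        pd.DataFrame(ts, columns=parcel_names).to_csv(
            paths.timeseries_dir / f"{sid}.tsv", sep="\t", index=False
        )
    for sid, conf in cohort.confounds.items():
        conf.to_csv(paths.confounds_dir / f"{sid}.tsv", sep="\t", index=False)
    with open(paths.config, "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=False)
    return paths


def load_cohort(
    root: str | Path,
    expected_groups: tuple[str, str] | None = None,
    drop_missing: bool = False,
) -> LoadedCohort:
    """Load a cohort directory, validating headers against the atlas.

    Subjects whose time-series or confound file is absent are dropped with
    a log message when ``drop_missing`` is set, otherwise loading fails.
    """
    paths = CohortPaths(Path(root))
    for p in (paths.manifest, paths.atlas):
        if not p.exists():
            raise FileNotFoundError(p)
    manifest = pd.read_csv(paths.manifest)
    atlas = pd.read_csv(paths.atlas)
    partition = NetworkPartition.from_atlas(atlas)

    if expected_groups is not None:
        unknown = set(manifest["group"]) - set(expected_groups)
        if unknown:
            raise ValueError(
                f"manifest contains unknown group label(s) {sorted(unknown)}; "
                f"expected {list(expected_groups)}"
            )

    parcel_names = list(atlas["parcel_name"])
    timeseries: dict[str, np.ndarray] = {}
    confounds: dict[str, pd.DataFrame] = {}
    keep = []
    for sid in manifest["subject_id"]:
        ts_path = paths.timeseries_dir / f"{sid}.tsv"
        cf_path = paths.confounds_dir / f"{sid}.tsv"
        if not ts_path.exists() or not cf_path.exists():
            if drop_missing:
                logger.warning("dropping subject %s: missing files", sid)
                continue
            raise FileNotFoundError(f"missing files for subject {sid}")
        ts = pd.read_csv(ts_path, sep="\t")
        if list(ts.columns) != parcel_names:
            raise ValueError(
                f"subject {sid}: time-series header does not match the atlas "
                f"({len(ts.columns)} columns vs {len(parcel_names)} parcels)"
            )
        timeseries[sid] = ts.to_numpy(float)
        confounds[sid] = pd.read_csv(cf_path, sep="\t")
        keep.append(sid)
    manifest = manifest[manifest["subject_id"].isin(keep)].reset_index(drop=True)

    config = None
    if paths.config.exists():
        with open(paths.config) as fh:
            config = yaml.safe_load(fh)
    return LoadedCohort(
        manifest=manifest,
        timeseries=timeseries,
        confounds=confounds,
        partition=partition,
        atlas=atlas,
        config=config,
    )


def config_from_yaml(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "network_sizes" in raw and raw["network_sizes"] is not None:
        raw["network_sizes"] = list(raw["network_sizes"])
    if "age_range" in raw and raw["age_range"] is not None:
        raw["age_range"] = tuple(raw["age_range"])
    return SimulationConfig(**raw)
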
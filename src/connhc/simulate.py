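"""Synthetic resting-state cohort generator with planted rare-weak group effects.

Generates parcel-level BOLD-like time series for a two-group cohort whose
functional-connectivity structure is block-diagonal by network, with

* a sparse, weak perturbation of edge correlations in the second group
  (the "rare-weak" alternative that Higher Criticism targets),
* additive covariate effects (age, sex, mean framewise displacement) on the
  Fisher-z edge scale,
* between-subject edge-level heterogeneity, and
* an optional hidden multi-state Markov switching covariance process for
  time-resolved analyses.

Default parameters mirror a two-group resting-state study of 39 cases and
44 controls scanned for 234 volumes at TR 2.5 s, with ten cognition-related
sub-networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_nearest

__all__ = [
    "SimulationConfig",
    "Cohort",
    "build_block_covariance",
    "plant_group_effect",
    "simulate_subject_timeseries",
    "simulate_cohort",
    "default_network_labels",
]

#: Network labels emulating the ten cognition-related components of the
#: Yeo 17-network scheme (dorsal attention, salience/ventral attention,
#: fronto-parietal control, default mode sub-networks).
DEFAULT_NETWORK_LABELS = (
    "DorsAttnA",
    "DorsAttnB",
    "SalVentAttnA",
    "SalVentAttnB",
    "ContA",
    "ContB",
    "ContC",
    "DefaultA",
    "DefaultB",
    "DefaultC",
)

_Z_CLIP = 1.0 - 1e-7


def default_network_labels(n_networks: int) -> list[str]:
    """Network labels for ``n_networks`` blocks (canonical ten, or generic)."""
    if n_networks <= len(DEFAULT_NETWORK_LABELS):
        return list(DEFAULT_NETWORK_LABELS[:n_networks])
    return [f"Net{i + 1:02d}" for i in range(n_networks)]


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic cohort.

    Attributes
    ----------
    n_group1, n_group2
        Number of control and case subjects.
    n_parcels
        Total number of cortical parcels.
    network_sizes
        Parcels per network; must sum to ``n_parcels``, each >= 2.
        Default: ten equal blocks.
    n_timepoints, tr_seconds
        Length and sampling interval of each subject's series.
    within_network_corr, between_network_corr
        Block-covariance correlations (within > between).
    effect_sparsity_eps
        Fraction of global edges perturbed in group 2.
    effect_size_delta
        Per-edge perturbation magnitude, correlation units (random sign).
    covariate_effects
        Map covariate name (``age``, ``sex``, ``mean_fd``) -> slope applied
        additively to every Fisher-z edge per unit of the covariate.
    subject_sigma
        Between-subject edge heterogeneity: s.d. of a per-subject,
        per-edge Gaussian perturbation on the Fisher-z scale.
    n_states, state_transition_prob
        Hidden Markov switching covariance process; ``n_states=1`` is the
        static case.
    seed
        Master seed; identical seeds give bit-identical cohorts.
    """

    n_group1: int = 39
    n_group2: int = 44
    n_parcels: int = 60
    network_sizes: list[int] | None = None
    n_timepoints: int = 234
    tr_seconds: float = 2.5
    within_network_corr: float = 0.5
    between_network_corr: float = 0.1
    effect_sparsity_eps: float = 0.10
    effect_size_delta: float = 0.05
    covariate_effects: dict[str, float] = field(default_factory=dict)
    subject_sigma: float = 0.12
    age_range: tuple[float, float] = (18.0, 32.0)
    mean_fd_loc: float = 0.15
    mean_fd_scale: float = 0.06
    n_states: int = 1
    state_transition_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network_sizes is None:
            if self.n_parcels % 10 == 0 and self.n_parcels >= 20:
                self.network_sizes = [self.n_parcels // 10] * 10
            else:
                raise ValueError(
                    "network_sizes must be given when n_parcels is not a "
                    "multiple of 10"
                )
        self.validate()

    def validate(self) -> None:
        if self.n_group1 < 1 or self.n_group2 < 1:
            raise ValueError("both groups need at least one subject")
        if sum(self.network_sizes) != self.n_parcels:
            raise ValueError("network_sizes must sum to n_parcels")
        if any(s < 2 for s in self.network_sizes):
            raise ValueError("every network needs at least 2 parcels")
        if not (0.0 < self.within_network_corr < 1.0):
            raise ValueError("within_network_corr must lie in (0, 1)")
        if not (0.0 <= self.between_network_corr < self.within_network_corr):
            raise ValueError(
                "between_network_corr must lie in [0, within_network_corr)"
            )
        if not (0.0 <= self.effect_sparsity_eps <= 1.0):
            raise ValueError("effect_sparsity_eps must lie in [0, 1]")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_states > 1 and not (0.0 < self.state_transition_prob < 1.0):
            raise ValueError("state_transition_prob must lie in (0, 1)")

    @property
    def network_labels(self) -> list[str]:
        return default_network_labels(len(self.network_sizes))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """A simulated cohort: manifest, per-subject data, atlas, ground truth."""

    config: SimulationConfig
    manifest: pd.DataFrame
    timeseries: dict[str, np.ndarray]
    confounds: dict[str, pd.DataFrame]
    atlas: pd.DataFrame
    perturbed_edges: list[tuple[int, int]]
    state_sequences: dict[str, np.ndarray]
    state_covariances: list[np.ndarray]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.manifest["subject_id"])


def build_block_covariance(
    network_sizes: list[int],
    within_network_corr: float,
    between_network_corr: float,
) -> np.ndarray:
    """Block-structured correlation matrix: unit diagonal, ``within`` on
    same-network pairs, ``between`` elsewhere.

    Raises ``ValueError`` if the parameters are out of range or the result
    is not positive definite.
    """
    if not (0.0 <= between_network_corr <= within_network_corr < 1.0):
        raise ValueError(
            "need 0 <= between_network_corr <= within_network_corr < 1"
        )
    p = int(sum(network_sizes))
    cov = np.full((p, p), float(between_network_corr))
    start = 0
    for size in network_sizes:
        cov[start : start + size, start : start + size] = within_network_corr
        start += size
    np.fill_diagonal(cov, 1.0)
    min_eig = np.linalg.eigvalsh(cov)[0]
    if min_eig <= 0:
        raise ValueError(
            f"block covariance is not positive definite "
            f"(smallest eigenvalue {min_eig:.3g}); reduce the correlations"
        )
    return cov


def _edge_pairs(n_parcels: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index pairs in canonical row-major order."""
    return np.triu_indices(n_parcels, k=1)


def plant_group_effect(
    base_covariance: np.ndarray,
    eps: float,
    delta: float,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Perturb ``round(eps * E)`` randomly chosen edges by ``+-delta``
    (sign drawn per edge) and repair to the nearest positive-definite
    correlation matrix (Higham alternating projection).

    Returns the repaired matrix and the list of perturbed ``(i, j)`` pairs.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = base_covariance.shape[0]
    rows, cols = _edge_pairs(p)
    n_edges = rows.size
    n_hit = int(round(eps * n_edges))
    if n_hit == 0:
        return base_covariance.copy(), []
    chosen = rng.choice(n_edges, size=n_hit, replace=False)
    chosen.sort()
    signs = rng.choice([-1.0, 1.0], size=n_hit)
    cov = base_covariance.copy()
    for idx, sign in zip(chosen, signs):
        i, j = int(rows[idx]), int(cols[idx])
        new = cov[i, j] + sign * delta
        if not (-1.0 < new < 1.0):
            raise ValueError(
                f"delta={delta} pushes edge ({i},{j}) outside (-1, 1)"
            )
        cov[i, j] = cov[j, i] = new
    if delta != 0.0:
        cov = corr_nearest(cov, threshold=1e-8, n_fact=200)
        cov = np.asarray(cov)
        np.fill_diagonal(cov, 1.0)
        cov = (cov + cov.T) / 2.0
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError("positive-definite repair failed after projection")
    return cov, [(int(rows[k]), int(cols[k])) for k in chosen]


def _repair_correlation(mat: np.ndarray, min_eig: float = 1e-6) -> np.ndarray:
    """Fast eigenvalue-clipping repair to a positive-definite correlation
    matrix (used per subject, where Higham iteration would be wasteful)."""
    w, v = np.linalg.eigh((mat + mat.T) / 2.0)
    if w[0] > min_eig:
        return mat
    w = np.clip(w, min_eig, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def simulate_subject_timeseries(
    covariances: np.ndarray | list[np.ndarray],
    n_timepoints: int,
    state_transition_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean Gaussian series whose covariance at each volume is selected
    by a first-order Markov chain over states (uniform initial state; at each
    step the chain leaves its state with probability
    ``state_transition_prob``, moving uniformly to another state).

    Returns ``(timeseries T x P, state_sequence T)``.
    """
    if isinstance(covariances, np.ndarray) and covariances.ndim == 2:
        covariances = [covariances]
    covariances = [np.asarray(c, dtype=float) for c in covariances]
    n_states = len(covariances)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    chols = []
    for k, cov in enumerate(covariances):
        try:
            chols.append(np.linalg.cholesky(cov))
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"state {k} covariance is not positive definite") from exc

    p = covariances[0].shape[0]
    states = np.zeros(n_timepoints, dtype=int)
    states[0] = rng.integers(n_states)
    if n_states > 1 and state_transition_prob > 0:
        jumps = rng.random(n_timepoints - 1) < state_transition_prob
        targets = rng.integers(n_states - 1, size=n_timepoints - 1)
        for t in range(1, n_timepoints):
            s = states[t - 1]
            if jumps[t - 1]:
                nxt = targets[t - 1]
                s = nxt if nxt < s else nxt + 1
            states[t] = s
    else:
        states[:] = states[0]

    z = rng.standard_normal((n_timepoints, p))
    ts = np.empty_like(z)
    for k in range(n_states):
        mask = states == k
        if mask.any():
            ts[mask] = z[mask] @ chols[k].T
    return ts, states


def _synthetic_motion(
    target_mean_fd: float, n_timepoints: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Random-walk rigid-body motion whose expected framewise displacement
    matches ``target_mean_fd`` (Power convention, 50 mm head radius)."""
    # E|increment| = s*sqrt(2/pi) per parameter; FD sums 3 translations and
    # 3 radius-scaled rotations, so E[FD] = 6 * s * sqrt(2/pi).
    s = target_mean_fd / (6.0 * np.sqrt(2.0 / np.pi))
    d_trans = rng.normal(0.0, s, size=(n_timepoints, 3))
    d_rot = rng.normal(0.0, s / 50.0, size=(n_timepoints, 3))
    d_trans[0] = d_rot[0] = 0.0
    motion = np.cumsum(np.hstack([d_trans, d_rot]), axis=0)
    return pd.DataFrame(
        motion,
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )


def _mean_fd_of(motion: pd.DataFrame, head_radius: float = 50.0) -> float:
    d = np.abs(np.diff(motion.to_numpy(), axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return float(np.concatenate([[0.0], fd]).mean())


def build_state_covariances(
    base: np.ndarray, config: SimulationConfig
) -> list[np.ndarray]:
    """State-wise covariances for the switching process.

    State 1 is the block-structured matrix itself; additional states are
    "integration" states — compound symmetry at the mean of the within- and
    between-network correlations — in which the network dichotomy dissolves.
    With more than two states, later states interpolate between the two.
    """
    if config.n_states == 1:
        return [base]
    p = base.shape[0]
    mid = 0.5 * (config.within_network_corr + config.between_network_corr)
    integration = np.full((p, p), mid)
    np.fill_diagonal(integration, 1.0)
    covs = [base]
    for k in range(1, config.n_states):
        w = k / (config.n_states - 1)
        covs.append(_repair_correlation((1 - w) * base + w * integration))
    return covs


def _subject_covariance(
    group_cov: np.ndarray,
    z_offset: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply covariate offset + heterogeneity on the Fisher-z edge scale,
    map back to correlations and repair positive definiteness."""
    if z_offset == 0.0 and sigma == 0.0:
        return group_cov
    p = group_cov.shape[0]
    rows, cols = _edge_pairs(p)
    z = np.arctanh(np.clip(group_cov[rows, cols], -_Z_CLIP, _Z_CLIP))
    z = z + z_offset
    if sigma > 0:
        z = z + rng.normal(0.0, sigma, size=z.size)
    r = np.tanh(z)
    cov = np.eye(p)
    cov[rows, cols] = r
    cov[cols, rows] = r
    return _repair_correlation(cov)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full cohort: manifest, per-subject time series and
    confound tables, atlas lookup, and the planted ground truth.

    Group 2 subjects are drawn under the eps/delta-perturbed covariance;
    ages are uniform over ``age_range``, sex is balanced Bernoulli(0.5),
    mean FD is truncated normal (>= 0.01 mm) and realized through synthetic
    motion traces, whose actual mean FD enters the manifest and any
    configured covariate effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # Named substreams so each stage is reproducible in isolation.
    ss_structure, ss_subjects = rng.spawn(2)

    base = build_block_covariance(
        config.network_sizes,
        config.within_network_corr,
        config.between_network_corr,
    )
    perturbed, edges = plant_group_effect(
        base, config.effect_sparsity_eps, config.effect_size_delta, ss_structure
    )
    group_covs = {"control": base, "case": perturbed}

    labels = config.network_labels
    atlas = pd.DataFrame(
        {
            "parcel_id": np.arange(config.n_parcels),
            "parcel_name": [
                f"{labels[n]}_p{i + 1:03d}"
                for n, size in enumerate(config.network_sizes)
                for i in range(size)
            ],
            "network_label": np.repeat(labels, config.network_sizes),
        }
    )

    n_total = config.n_group1 + config.n_group2
    groups = ["control"] * config.n_group1 + ["case"] * config.n_group2
    rows = []
    timeseries: dict[str, np.ndarray] = {}
    confounds: dict[str, pd.DataFrame] = {}
    state_sequences: dict[str, np.ndarray] = {}
    state_covs_report = build_state_covariances(base, config)

    for idx in range(n_total):
        sub_rng = ss_subjects.spawn(1)[0]
        subject_id = f"sub-{idx + 1:03d}"
        group = groups[idx]
        age = float(sub_rng.uniform(*config.age_range))
        sex = int(sub_rng.random() < 0.5)
        target_fd = max(
            0.01, float(sub_rng.normal(config.mean_fd_loc, config.mean_fd_scale))
        )
        motion = _synthetic_motion(target_fd, config.n_timepoints, sub_rng)
        mean_fd = _mean_fd_of(motion)

        cov_values = {
            "age": age,
            "sex": float(sex),
            "mean_fd": mean_fd,
            "group": 1.0 if group == "case" else 0.0,
        }
        z_offset = sum(
            slope * cov_values[name]
            for name, slope in config.covariate_effects.items()
        )
        subj_cov = _subject_covariance(
            group_covs[group], z_offset, config.subject_sigma, sub_rng
        )
        state_covs = build_state_covariances(subj_cov, config)
        ts, states = simulate_subject_timeseries(
            state_covs,
            config.n_timepoints,
            config.state_transition_prob if config.n_states > 1 else 0.0,
            sub_rng,
        )
        tissue = pd.DataFrame(
            sub_rng.standard_normal((config.n_timepoints, 2)),
            columns=["wm", "csf"],
        )
        timeseries[subject_id] = ts
        confounds[subject_id] = pd.concat([motion, tissue], axis=1)
        state_sequences[subject_id] = states
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "sex": "F" if sex else "M",
                "age": age,
                "mean_fd": mean_fd,
            }
        )

    manifest = pd.DataFrame(rows)
    for col in ("group", "sex"):
        if manifest[col].nunique() != 2:
            warnings.warn(
                f"cohort has a single level of '{col}'; downstream design "
                "matrices will reject it",
                stacklevel=2,
            )
    return Cohort(
        config=config,
        manifest=manifest,
        timeseries=timeseries,
        confounds=confounds,
        atlas=atlas,
        perturbed_edges=edges,
        state_sequences=state_sequences,
        state_covariances=state_covs_report,
    )
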
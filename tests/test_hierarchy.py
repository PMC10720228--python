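import numpy as np
import pandas as pd
import pytest

from connhc.connectome import NetworkPartition, edge_indices
from connhc.edge_models import build_design, fit_all_edges
from connhc.hierarchy import fdr_adjust, report_summary, run_hierarchy
from oracles import bh_brute


class TestFdrAdjust:
    def test_single_pvalue(self):
        adj, disc = fdr_adjust(np.array([0.01]))
        assert adj[0] == pytest.approx(0.01)
        assert disc[0]

    def test_hand_computed_example(self):
        adj, disc = fdr_adjust(np.array([0.001, 0.01, 0.04, 0.2]))
        assert adj == pytest.approx([0.004, 0.02, 0.05333333, 0.2])
        assert disc.sum() == 2

    def test_all_ones_no_discoveries(self):
        _, disc = fdr_adjust(np.ones(10))
        assert not disc.any()

    def test_agrees_with_brute_force_small_cases(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 9))
            p = np.round(rng.random(n), 3)
            adj, disc = fdr_adjust(p)
            badj, bdisc = bh_brute(p)
            assert np.allclose(adj, badj, atol=1e-12)
            assert np.array_equal(disc, bdisc)

    def test_monotone_and_capped(self, rng):
        p = rng.random(50)
        adj, _ = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert adj.max() <= 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5]), q=1.5)


def _make_edge_tables(partition, p_parcel, p_network, eta=None, diff=None):
    rows, cols = edge_indices(partition.n_parcels)
    parcel = pd.DataFrame({"i": rows, "j": cols, "p_group": p_parcel})
    if eta is not None:
        parcel["partial_eta2"] = eta
    if diff is not None:
        parcel["group_mean_diff_z"] = diff
    n_net = len(partition.networks)
    nrows, ncols = edge_indices(n_net)
    network = pd.DataFrame({"i": nrows, "j": ncols, "p_group": p_network})
    return parcel, network


@pytest.fixture(scope="module")
def null_cache():
    return {}


class TestRunHierarchy:
    def test_structure_on_null_input(self, small_partition, null_cache, rng):
        n_edges = small_partition.n_parcels * (small_partition.n_parcels - 1) // 2
        parcel, network = _make_edge_tables(
            small_partition, rng.random(n_edges), rng.random(45),
            eta=rng.random(n_edges) * 0.1, diff=rng.normal(size=n_edges) * 0.05,
        )
        rep = run_hierarchy(parcel, network, small_partition,
                            n_null=1000, null_cache=null_cache)
        assert len(rep.within_hc) == 10
        assert rep.global_hc.n_pvalues == n_edges
        assert rep.between_hc.n_pvalues == 45
        summary = report_summary(rep, small_partition)
        assert len(summary["within_network"]) == 10
        # effect-size matrix round-trips the edge vector
        assert rep.effect_size_matrix.shape == (30, 30)
        assert np.allclose(rep.effect_size_matrix, rep.effect_size_matrix.T)
        rows, cols = edge_indices(30)
        assert np.array_equal(
            rep.effect_size_matrix[rows, cols], parcel["partial_eta2"].to_numpy()
        )

    def test_between_matrix_has_45_unique_values(self, small_partition, null_cache, rng):
        n_edges = 435
        p_network = rng.random(45)
        parcel, network = _make_edge_tables(small_partition, rng.random(n_edges), p_network)
        rep = run_hierarchy(parcel, network, small_partition,
                            n_null=1000, null_cache=null_cache)
        assert rep.fdr_between["p_group"].nunique() == 45

    def test_missing_scope_rejected(self, small_partition, rng):
        parcel, network = _make_edge_tables(
            small_partition, rng.random(435), rng.random(45)
        )
        with pytest.raises(ValueError):
            run_hierarchy(parcel.iloc[:-1], network, small_partition, n_null=1000)
        with pytest.raises(ValueError):
            run_hierarchy(parcel, network.iloc[:-1], small_partition, n_null=1000)

    def test_strong_dense_network_effect_detected(self, small_partition, null_cache):
        """A dense strong shift inside one network drives that network's
        HC to reject and yields FDR discoveries there."""
        rng = np.random.default_rng(77)
        n = 60
        manifest = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "group": ["control"] * 30 + ["case"] * 30,
                "sex": rng.choice(["M", "F"], n),
                "age": rng.uniform(18, 32, n),
                "mean_fd": rng.uniform(0.05, 0.3, n),
            }
        )
        design = build_design(manifest)
        rows, cols = edge_indices(30)
        net_of = np.asarray(small_partition.network_of, dtype=object)
        target = small_partition.networks[0]
        dense = (net_of[rows] == target) & (net_of[cols] == target)
        Z = rng.normal(0, 0.12, size=(n, rows.size))
        Z[np.ix_(design.group_indicator == 1, dense)] += 0.5
        parcel = fit_all_edges(Z, design)
        parcel.insert(0, "j", cols)
        parcel.insert(0, "i", rows)
        nrows, ncols = edge_indices(10)
        Zn = rng.normal(0, 0.12, size=(n, 45))
        network = fit_all_edges(Zn, design)
        network.insert(0, "j", ncols)
        network.insert(0, "i", nrows)
        rep = run_hierarchy(parcel, network, small_partition,
                            n_null=1000, null_cache=null_cache)
        assert rep.within_hc[target].reject
        assert rep.fdr_within[target]["discovered"].any()

    def test_removing_network_leaves_others_unchanged(self, small_partition, rng):
        """Dropping one network's parcels does not alter the other
        networks' within-network HC outcomes."""
        p_parcel = rng.random(435)
        parcel, network = _make_edge_tables(small_partition, p_parcel, rng.random(45))
        cache: dict = {}
        rep_full = run_hierarchy(parcel, network, small_partition,
                                 n_null=1000, null_cache=cache)

        drop = small_partition.networks[0]
        keep_parcels = np.asarray(
            [net != drop for net in small_partition.network_of]
        )
        keep_idx = np.flatnonzero(keep_parcels)
        remap = {old: new for new, old in enumerate(keep_idx)}
        atlas = pd.DataFrame(
            {
                "parcel_id": range(len(keep_idx)),
                "parcel_name": [small_partition.parcel_names[i] for i in keep_idx],
                "network_label": [small_partition.network_of[i] for i in keep_idx],
            }
        )
        sub_partition = NetworkPartition.from_atlas(atlas)
        mask = keep_parcels[parcel["i"]] & keep_parcels[parcel["j"]]
        sub_parcel = parcel[mask].copy()
        sub_parcel["i"] = [remap[i] for i in sub_parcel["i"]]
        sub_parcel["j"] = [remap[j] for j in sub_parcel["j"]]
        sub_parcel = sub_parcel.sort_values(["i", "j"]).reset_index(drop=True)
        nrows, ncols = edge_indices(9)
        sub_network = pd.DataFrame(
            {"i": nrows, "j": ncols, "p_group": rng.random(36)}
        )
        rep_sub = run_hierarchy(sub_parcel, sub_network, sub_partition,
                                n_null=1000, null_cache=cache)
        for net in sub_partition.networks:
            assert rep_sub.within_hc[net].hc_value == pytest.approx(
                rep_full.within_hc[net].hc_value
            )
            assert rep_sub.within_hc[net].reject == rep_full.within_hc[net].reject

    def test_null_cohort_calibration(self):
        """With no planted effect and no covariate effects, the global HC
        test rejects at roughly the nominal 5% rate over replicate
        cohorts, and FDR discovery lists are almost always empty."""
        from scipy import stats

        from connhc.connectome import static_fc
        from connhc.higher_criticism import hc_null_distribution, hc_test
        from connhc.simulate import SimulationConfig, simulate_cohort

        rows, cols = edge_indices(30)
        null = hc_null_distribution(435, n_replicates=2000, seed=4001)
        n_reps, rejects, zero_disc = 60, 0, 0
        for r in range(n_reps):
            cfg = SimulationConfig(
                n_group1=12, n_group2=12, n_parcels=30, network_sizes=[3] * 10,
                n_timepoints=120, effect_sparsity_eps=0.0, effect_size_delta=0.0,
                seed=5000 + r,
            )
            coh = simulate_cohort(cfg)
            Z = np.array(
                [static_fc(coh.timeseries[s])[rows, cols] for s in coh.subject_ids]
            )
            p = fit_all_edges(Z, build_design(coh.manifest))["p_group"].to_numpy()
            rejects += hc_test(p, null).reject
            zero_disc += int(fdr_adjust(p)[1].sum() == 0)
        lo, hi = stats.binom.interval(0.99, n_reps, 0.05)
        assert lo <= rejects <= hi, f"{rejects}/{n_reps} outside [{lo}, {hi}]"
        assert zero_disc >= 0.85 * n_reps

    def test_within_fdr_weaker_than_global(self, small_partition, null_cache, rng):
        """An edge can survive within-network FDR while failing global FDR."""
        p = rng.random(435) * 0.98 + 0.02
        rows, cols = edge_indices(30)
        net_of = np.asarray(small_partition.network_of, dtype=object)
        target = small_partition.networks[2]
        inside = np.flatnonzero((net_of[rows] == target) & (net_of[cols] == target))
        p[inside] = 0.9
        p[inside[0]] = 0.012  # strong within its 3-edge family, weak globally
        parcel, network = _make_edge_tables(small_partition, p, rng.random(45) * 0.5 + 0.4)
        rep = run_hierarchy(parcel, network, small_partition,
                            n_null=1000, null_cache=null_cache)
        assert rep.fdr_within[target]["discovered"].any()
        sel = rep.fdr_global["p_group"] == 0.012
        assert not rep.fdr_global.loc[sel, "discovered"].any()
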
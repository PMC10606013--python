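import numpy as np
import pytest

from hypernull import (
    Hypergraph,
    SIRConfig,
    build_hypergraph,
    compare_dynamics,
    dismantle_by_hyperedges,
    dismantle_by_nodes,
    run_sir,
    seed_selection,
)

from conftest import random_hypergraph


class TestNodeDismantling:
    def test_star_hub_removal_ends_it(self, star_of_dyads):
        res = dismantle_by_nodes(star_of_dyads, target_fraction=0.2)
        assert res.n_removed == 1
        assert res.removal_order == [0]  # the hub has the top hyperdegree
        assert res.gcc_curve == [0.1]
        assert res.auc == pytest.approx(0.1)

    def test_disconnected_input_may_need_no_removals(self):
        H = Hypergraph(list(range(4)), [{0, 1}, {2, 3}])
        res = dismantle_by_nodes(H, target_fraction=1.0)
        assert res.n_removed == 0 and res.gcc_curve == []

    def test_curve_non_increasing_and_final_below_target(self):
        H = random_hypergraph(seed=0, n=50, m=80)
        res = dismantle_by_nodes(H, target_fraction=0.05)
        curve = np.array(res.gcc_curve)
        assert (np.diff(curve) <= 1e-12).all()
        assert curve[-1] < 0.05
        assert res.auc == pytest.approx(curve.sum())

    def test_invalid_target_rejected(self, t1):
        with pytest.raises(ValueError):
            dismantle_by_nodes(t1, target_fraction=0.0)
        with pytest.raises(ValueError):
            dismantle_by_nodes(t1, target_fraction=1.5)


class TestHyperedgeDismantling:
    def test_single_hyperedge_one_removal(self):
        H = Hypergraph(list(range(6)), [set(range(6))])
        res = dismantle_by_hyperedges(H, target_fraction=0.5)
        assert res.n_removed == 1
        assert res.gcc_curve == [pytest.approx(1 / 6)]

    def test_t1_hand_computed_curve(self, t1):
        # remove by degree: e1 (3 nodes), then e2, then e3; GCC 3 -> 2 -> 1
        res = dismantle_by_hyperedges(t1, target_fraction=0.5)
        assert res.removal_order == [0, 1, 2]
        assert res.gcc_curve == pytest.approx([0.75, 0.5, 0.25])
        assert res.n_removed == 3
        assert res.auc == pytest.approx(1.5)

    def test_all_removed_without_reaching_target_warns(self):
        H = Hypergraph(list(range(4)), [{0, 1}, {2, 3}])
        with pytest.warns(UserWarning, match="without the GCC reaching"):
            res = dismantle_by_hyperedges(H, target_fraction=0.25)
        assert res.n_removed == 2
        assert res.gcc_curve[-1] == pytest.approx(0.25)  # isolated nodes count 1

    def test_curve_values_in_unit_interval(self):
        H = random_hypergraph(seed=1, n=40, m=60)
        res = dismantle_by_hyperedges(H, target_fraction=0.1)
        assert all(0.0 <= v <= 1.0 for v in res.gcc_curve)


class TestSeedSelection:
    def test_all_nodes_when_count_equals_n(self, t1):
        rng = np.random.default_rng(0)
        assert seed_selection(t1, "random", 4, rng) == {0, 1, 2, 3}

    def test_hyperdegree_tie_break_takes_lowest_index(self, t1):
        rng = np.random.default_rng(0)
        # hyperdegrees (2,1,2,2): first maximal index is 0 (label 1)
        assert seed_selection(t1, "hyperdegree", 1, rng) == {0}

    def test_random_reproducible_for_fixed_seed(self, t1):
        a = seed_selection(t1, "random", 2, np.random.default_rng(5))
        b = seed_selection(t1, "random", 2, np.random.default_rng(5))
        assert a == b

    def test_count_above_n_rejected(self, t1):
        with pytest.raises(ValueError):
            seed_selection(t1, "random", 5, np.random.default_rng(0))

    def test_unknown_strategy_rejected(self, t1):
        with pytest.raises(ValueError, match="strategy"):
            SIRConfig(beta=0.1, seed_strategy="bogus")


class TestSIR:
    def test_beta_zero_recovers_only_the_seeds(self):
        H = random_hypergraph(seed=2, n=50, m=80)
        config = SIRConfig(beta=0.0, seed_fraction=0.1, n_runs=20, rng_seed=0)
        res = run_sir(H, config)
        assert np.allclose(res.per_run_fractions, 5 / 50)
        assert res.recovered_fraction_sd == pytest.approx(0.0, abs=1e-12)

    def test_threshold_above_max_degree_blocks_spread(self):
        H = random_hypergraph(seed=3, n=50, m=80)
        config = SIRConfig(
            beta=5.0, theta=100, seed_fraction=0.1, n_runs=20, rng_seed=1
        )
        res = run_sir(H, config)
        assert np.allclose(res.per_run_fractions, 5 / 50)

    def test_conservation_and_monotone_recovery(self):
        H = random_hypergraph(seed=4, n=60, m=100, sizes={6: 0.5, 8: 0.5})
        config = SIRConfig(
            beta=0.3, theta=3, seed_fraction=0.2, n_runs=5, rng_seed=2,
            store_trajectories=True,
        )
        res = run_sir(H, config)
        for traj in res.trajectories:
            for s, i, r in traj:
                assert s + i + r == H.n
            recovered = [r for _, _, r in traj]
            assert recovered == sorted(recovered)
            assert traj[-1][1] == 0  # absorbing state has no infectious nodes

    def test_gamma_one_means_one_infectious_step(self):
        H = Hypergraph(list(range(10)), [set(range(10))])
        config = SIRConfig(
            beta=1.0, gamma=1.0, theta=5, seed_fraction=0.6, n_runs=3, rng_seed=3,
            store_trajectories=True,
        )
        res = run_sir(H, config)
        for traj in res.trajectories:
            # recovered gain at each step equals the previous infectious count
            for (s0, i0, r0), (s1, i1, r1) in zip(traj, traj[1:]):
                assert r1 - r0 == i0

    def test_single_hyperedge_matches_one_step_closed_form(self):
        # 10 nodes, 6 seeds > theta=5: one infectious step, then the at most
        # 4 newly infected cannot re-trip the threshold
        H = Hypergraph(list(range(10)), [set(range(10))])
        beta = 0.2
        config = SIRConfig(
            beta=beta, gamma=1.0, theta=5, seed_fraction=0.6, n_runs=2000, rng_seed=4
        )
        res = run_sir(H, config)
        p = 1 - np.exp(-6 * beta)
        expected = (6 + 4 * p) / 10
        se = np.sqrt(4 * p * (1 - p)) / 10 / np.sqrt(config.n_runs)
        assert abs(res.recovered_fraction_mean - expected) < 3 * se

    def test_recovered_fraction_non_decreasing_in_beta(self):
        H = random_hypergraph(seed=5, n=80, m=120, sizes={6: 0.5, 8: 0.5})
        means, sds = [], []
        for beta in (0.02, 0.1, 0.5):
            res = run_sir(
                H,
                SIRConfig(beta=beta, theta=3, seed_fraction=0.05, n_runs=100,
                          rng_seed=6),
            )
            means.append(res.recovered_fraction_mean)
            sds.append(res.recovered_fraction_sd / 10)
        assert means[1] >= means[0] - 2 * (sds[0] + sds[1])
        assert means[2] >= means[1] - 2 * (sds[1] + sds[2])

    def test_tiny_seed_fraction_warns_and_uses_one_seed(self):
        H = random_hypergraph(seed=6, n=20, m=30)
        with pytest.warns(UserWarning, match="single seed"):
            res = run_sir(
                H, SIRConfig(beta=0.0, seed_fraction=0.01, n_runs=2, rng_seed=0)
            )
        assert np.allclose(res.per_run_fractions, 1 / 20)


class TestCompare:
    def test_original_row_equals_direct_call(self, t1):
        config = SIRConfig(beta=0.2, theta=1, seed_fraction=0.25, n_runs=10, rng_seed=3)
        table = compare_dynamics(
            t1, ["original"], {"kind": "sir", "config": config}, rng_seed=3
        )
        direct = run_sir(t1, config)
        assert table.loc["original", "recovered_fraction_mean"] == pytest.approx(
            direct.recovered_fraction_mean
        )

    def test_dismantling_rows_repeatable(self):
        H = random_hypergraph(seed=7, n=40, m=60)
        spec = {"kind": "dismantle_nodes", "target_fraction": 0.05}
        a = compare_dynamics(H, ["original", "H1k-HD"], spec, rng_seed=1)
        b = compare_dynamics(H, ["original", "H1k-HD"], spec, rng_seed=1)
        assert a.equals(b)

    def test_h0k_spreads_at_least_as_well_as_original(self):
        # heterogeneous original vs its most random surrogate at beta = 0.1
        H = random_hypergraph(seed=8, n=100, m=200, sizes={6: 0.5, 8: 0.5}, hetero=1.0)
        config = SIRConfig(beta=0.1, theta=3, seed_fraction=0.05, n_runs=100,
                           rng_seed=2)
        table = compare_dynamics(
            H, ["original", "H0k"], {"kind": "sir", "config": config}, rng_seed=2
        )
        orig = table.loc["original", "recovered_fraction_mean"]
        null = table.loc["H0k", "recovered_fraction_mean"]
        sd = table["recovered_fraction_sd"].max() / 10
        assert null >= orig - 2 * sd

    def test_unknown_model_rejected(self, t1):
        with pytest.raises(ValueError, match="unknown models"):
            compare_dynamics(t1, ["H7k"], {"kind": "dismantle_nodes"})
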
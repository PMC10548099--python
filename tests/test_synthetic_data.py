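import json

import numpy as np
import pytest

import paleoranges as pr
from paleoranges.statespace import RangeModelParams
from paleoranges.synthetic_data import (RangeHistorySimulator, SimulationConfig,
                                        simulate_dataset, simulate_occurrences,
                                        simulate_range_history, simulate_tree)


class TestConfigValidation:
    def test_defaults_are_valid(self):
        SimulationConfig()

    @pytest.mark.parametrize("kwargs", [
        {"n_tips": 2}, {"birth_rate": 0.05, "death_rate": 0.05},
        {"death_rate": -0.1, "birth_rate": 0.1},
        {"coord_noise_concentration": 0.0}, {"root_age": -1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestTreeSimulation:
    def test_three_tips_two_internal_nodes_four_branches(self):
        cfg = SimulationConfig(n_tips=3, seed=1, psi=0.0)
        tree = simulate_tree(cfg)
        assert tree.n_tips == 3
        assert tree.n_nodes == 5
        n_branches = sum(1 for i in range(tree.n_nodes) if tree.parent[i] >= 0)
        assert n_branches == 4

    def test_same_seed_identical_newick(self):
        cfg = SimulationConfig(n_tips=12, seed=42)
        assert simulate_tree(cfg).as_newick() == simulate_tree(cfg).as_newick()

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(n_tips=12, seed=42)
        assert simulate_tree(cfg, seed=1).as_newick() != \
            simulate_tree(cfg, seed=2).as_newick()

    def test_conditioned_extant_tip_count_exact(self):
        """The simulator conditions on the extant count, so it is exact."""
        cfg = SimulationConfig(n_tips=8, seed=0, psi=0.0, root_age=50)
        counts = [simulate_tree(cfg, seed=s).n_tips for s in range(100)]
        assert np.mean(counts) == 8.0
        assert set(counts) == {8}

    def test_root_age_and_positive_branches(self):
        cfg = SimulationConfig(n_tips=20, seed=3, root_age=120.0, psi=0.0)
        tree = simulate_tree(cfg)
        assert tree.age[tree.root] == pytest.approx(120.0, rel=0.02)
        lengths = [tree.branch_length[i] for i in range(tree.n_nodes)
                   if tree.parent[i] >= 0]
        assert min(lengths) >= 0.1 - 1e-9  # minimum branch length enforced

    def test_extant_only_tree_is_ultrametric(self):
        cfg = SimulationConfig(n_tips=15, seed=4, psi=0.0)
        assert simulate_tree(cfg).is_ultrametric(tol=1e-3)

    def test_fossil_sampling_adds_non_contemporaneous_tips(self):
        cfg = SimulationConfig(n_tips=30, seed=5, psi=0.1, root_age=150)
        tree = simulate_tree(cfg)
        assert tree.n_tips > 30
        fossil_ages = [tree.age[i] for i, lb in enumerate(tree.tip_labels)
                       if lb.startswith("f")]
        assert fossil_ages and max(fossil_ages) > 1.0
        assert not tree.is_ultrametric(tol=1e-3)


class TestRangeHistory:
    def test_no_events_limit_inherits_root_range(self, small_bundle):
        _, tree, space, _, _ = small_bundle
        # full-range copy at nodes: with no anagenetic events every node
        # carries the root range unchanged
        hist = simulate_range_history(tree, space,
                                      RangeModelParams(d=0, e=0, j=0),
                                      model="BAYAREALIKE", seed=1)
        assert len(hist.events) == 0
        assert len(set(hist.node_states.tolist())) == 1
        # subdividing models still produce no anagenetic events, and every
        # daughter range is a subset of the root range
        hist_dec = simulate_range_history(tree, space,
                                          RangeModelParams(d=0, e=0, j=0),
                                          model="DEC", seed=2)
        assert len(hist_dec.events) == 0
        root_mask = int(space.state_masks[hist_dec.root_state])
        for s in hist_dec.node_states:
            assert int(space.state_masks[int(s)]) & ~root_mask == 0

    def test_j_zero_means_no_founder_events(self, small_bundle):
        _, tree, space, _, _ = small_bundle
        hist = simulate_range_history(tree, space,
                                      RangeModelParams(d=0.05, e=0.01), seed=2,
                                      condition_branches=True)
        assert hist.n_founder_events() == 0

    def test_positive_j_produces_founder_events(self, small_bundle):
        _, tree, space, _, _ = small_bundle
        hist = simulate_range_history(tree, space,
                                      RangeModelParams(d=0.01, e=0.0, j=2.0),
                                      model="DEC", seed=3, condition_branches=True)
        assert hist.n_founder_events() > 0

    def test_all_tip_ranges_non_empty(self, small_bundle):
        _, tree, space, history, _ = small_bundle
        assert np.all(history.node_states[: tree.n_tips] > 0)

    def test_gain_waiting_time_matches_rate(self):
        """First-gain waiting times on a long branch follow Exp(d * m)."""
        tree = pr.IndexedTree.from_newick("(A:400.0,B:400.0);")
        space = pr.RangeStateSpace(("X", "Y"))
        d = 0.02
        sim = RangeHistorySimulator(tree, space, RangeModelParams(d=d, e=0.0))
        waits = []
        for s in range(400):
            hist = sim.simulate(s)
            if space.size_of_state(hist.root_state) != 1:
                continue
            for child in tree.children[tree.root]:
                gains = [ev for ev in hist.events if ev.branch == child]
                if gains:
                    first = max(ev.time_ma for ev in gains)  # oldest event
                    waits.append(400.0 - first)
        waits = np.array(waits)
        # censoring is negligible: P(no gain in 400 Myr) = e^-8
        se = (1 / d) / np.sqrt(len(waits))
        assert abs(waits.mean() - 1 / d) < 3 * se

    def test_multiplier_scales_gain_rate(self):
        tree = pr.IndexedTree.from_newick("(A:400.0,B:400.0);")
        space = pr.RangeStateSpace(("X", "Y"))
        strata = [pr.TimeStratum(1000.0, 0.0)]
        mids = {"X": pr.GeoPoint(0, 0), "Y": pr.GeoPoint(0, 60)}
        areas = pr.AreaSet(("X", "Y"), {strata[0].label: mids})
        mults = pr.build_distance_matrices(areas, strata)
        half = mults[0]
        half.relative_distance = half.relative_distance * 2.0  # multiplier 0.5
        d = 0.04
        sim = RangeHistorySimulator(tree, space, RangeModelParams(d=d, e=0.0),
                                    multipliers=[half])
        waits = []
        for s in range(400):
            hist = sim.simulate(s)
            if space.size_of_state(hist.root_state) != 1:
                continue
            for child in tree.children[tree.root]:
                gains = [ev for ev in hist.events if ev.branch == child]
                if gains:
                    waits.append(400.0 - max(ev.time_ma for ev in gains))
        rate = d * 0.5
        waits = np.array(waits)
        se = (1 / rate) / np.sqrt(len(waits))
        assert abs(waits.mean() - 1 / rate) < 3 * se

    def test_forward_frequencies_match_pruning_likelihood(self, tree3, space2):
        """Exact forward model vs normalized pruning likelihood, 3 tips."""
        import itertools
        from paleoranges.range_models import tree_loglik
        params = RangeModelParams(d=0.15, e=0.08)
        sim = RangeHistorySimulator(tree3, space2, params)
        N = 8000
        counts = {}
        for s in range(N):
            h = sim.simulate(s)
            key = tuple(int(x) for x in h.node_states[:3])
            counts[key] = counts.get(key, 0) + 1
        lls = {}
        for combo in itertools.product(range(1, 4), repeat=3):
            tips = {lb: space2.labels_of_mask(int(space2.state_masks[c]))
                    for lb, c in zip(("A", "B", "C"), combo)}
            lls[combo] = np.exp(tree_loglik(tree3, tips, "DEC", params, space2))
        Z = sum(lls.values())
        for combo, l in lls.items():
            p = l / Z
            se = np.sqrt(p * (1 - p) * N)
            assert abs(counts.get(combo, 0) - p * N) <= 4 * se + 1

    def test_intolerant_clade_suppression(self, chain_connectivity):
        strata, conn = chain_connectivity
        cfg = SimulationConfig(n_tips=30, seed=9, root_age=100, psi=0.0,
                               true_params=RangeModelParams(d=0.02, e=0.0))
        tree = simulate_tree(cfg)
        space = pr.RangeStateSpace(cfg.areas)
        clade = tree.children[tree.root][0]
        free = RangeHistorySimulator(tree, space, cfg.true_params,
                                     connectivity=conn,
                                     condition_branches=True)
        locked = RangeHistorySimulator(tree, space, cfg.true_params,
                                       connectivity=conn,
                                       intolerant_node=clade,
                                       ocean_suppression=0.0,
                                       condition_branches=True)
        sub = set(tree.subtree_nodes(clade))

        def clade_transoceanic(sim):
            total = 0
            for s in range(10):
                hist = sim.simulate(s)
                total += sum(1 for ev in hist.events
                             if ev.branch in sub and ev.transoceanic)
            return total

        assert clade_transoceanic(locked) < clade_transoceanic(free)
        # with full suppression, no unreachable-target gains occur at all
        hist = locked.simulate(123)
        cm = next(iter(conn.values()))
        for ev in hist.events:
            if ev.branch in sub and not ev.founder:
                srcs = [i for i in range(4) if ev.from_mask >> i & 1]
                to_i = cm.index(ev.to_area)
                assert any(cm.connected[i, to_i] for i in srcs) or \
                    any(cm.reachable[i, to_i] for i in srcs)


class TestOccurrences:
    def test_fixed_seed_byte_identical_csv(self, tmp_path, small_bundle):
        cfg, tree, space, history, _ = small_bundle
        a = simulate_occurrences(history, cfg, seed=7)
        b = simulate_occurrences(history, cfg, seed=7)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.write_csv(pa)
        b.write_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_every_tip_has_at_least_one_occurrence(self, small_bundle):
        cfg, tree, _, history, occs = small_bundle
        assert set(occs.taxa) == set(tree.tip_labels)
        assert occs.df.groupby("taxon").size().min() >= 1

    def test_occurrences_cluster_around_true_centroids(self, small_bundle):
        cfg, tree, space, history, occs = small_bundle
        ranges = history.tip_ranges()
        cents = {a: pr.sphere_to_cartesian(pr.GeoPoint(*ll))
                 for a, ll in cfg.area_centroids.items()}
        for row in occs.df.itertuples():
            v = pr.sphere_to_cartesian(pr.GeoPoint(row.paleolat, row.paleolng))
            best = max(cents, key=lambda a: float(v @ cents[a]))
            assert best in ranges[row.taxon]

    def test_truth_json_round_trip(self, tmp_path, small_bundle):
        _, _, _, history, _ = small_bundle
        path = tmp_path / "truth.json"
        history.write_truth_json(path)
        data = json.loads(path.read_text())
        assert data["root_state"] == history.space.bitstring(history.root_state)
        assert len(data["events"]) == len(history.events)


class TestDatasetBundle:
    def test_simulate_dataset_reproducible(self):
        cfg = SimulationConfig(n_tips=8, seed=17, root_age=60, psi=0.0)
        t1, h1, o1 = simulate_dataset(cfg)
        t2, h2, o2 = simulate_dataset(cfg)
        assert t1.as_newick() == t2.as_newick()
        assert np.array_equal(h1.node_states, h2.node_states)
        assert o1.df.equals(o2.df)
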
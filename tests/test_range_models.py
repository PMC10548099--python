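import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

import paleoranges as pr
from paleoranges.range_models import (GeographicRangeModel, RangeFitResults,
                                      compare_models, parse_model_name,
                                      tree_loglik)
from paleoranges.statespace import (MODELS, RangeModelParams, RangeStateSpace,
                                    build_q_matrix, clado_table)

from conftest import brute_force_3tip, oracle_clado_2areas, oracle_q_2areas

ALL_MODELS = ["DEC", "DEC+J", "DIVALIKE", "DIVALIKE+J",
              "BAYAREALIKE", "BAYAREALIKE+J"]


class TestStateSpace:
    @pytest.mark.parametrize("n,maxsize,expected", [
        (2, None, 4), (3, None, 8), (10, None, 1024), (4, 2, 1 + 4 + 6),
    ])
    def test_state_count(self, n, maxsize, expected):
        sp = RangeStateSpace([f"A{i}" for i in range(n)], max_range_size=maxsize)
        assert sp.n_states == expected

    def test_mask_round_trip(self, space2):
        for idx in range(1, space2.n_states):
            labels = space2.labels_of_mask(int(space2.state_masks[idx]))
            assert space2.state_index(labels) == idx

    def test_null_state_is_index_zero(self, space2):
        assert space2.state_masks[0] == 0

    def test_invalid_range_rejected(self, space2):
        sp = RangeStateSpace(("A", "B", "C"), max_range_size=2)
        with pytest.raises(ValueError):
            sp.state_index(("A", "B", "C"))


class TestQMatrix:
    def test_zero_rates_give_zero_matrix(self, space2):
        Q = build_q_matrix(space2, RangeModelParams(d=0, e=0))
        assert np.allclose(Q, 0.0)

    def test_two_area_rates_match_definition(self, space2):
        m = np.array([[1.0, 0.7], [0.3, 1.0]])
        Q = build_q_matrix(space2, RangeModelParams(d=0.2, e=0.05), m)
        iA = space2.state_index(("X",))
        iAB = space2.state_index(("X", "Y"))
        assert Q[iA, iAB] == pytest.approx(0.2 * 0.7)  # gain Y from {X}
        assert Q[iA, 0] == pytest.approx(0.05)         # loss to null
        assert Q[0].sum() == 0.0                       # null absorbing

    def test_matches_hand_written_oracle(self, space2):
        Q = build_q_matrix(space2, RangeModelParams(d=0.13, e=0.07))
        assert np.allclose(Q, oracle_q_2areas(0.13, 0.07))

    def test_transition_matrix_rows_are_stochastic(self, space2):
        rng = np.random.default_rng(0)
        sp4 = RangeStateSpace(("A", "B", "C", "D"))
        for _ in range(10):
            Q = build_q_matrix(sp4, RangeModelParams(
                d=rng.uniform(0.001, 1), e=rng.uniform(0.001, 1)))
            P = expm(Q * rng.uniform(0.01, 50))
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert P.min() > -1e-12

    def test_max_range_size_caps_gains(self):
        sp = RangeStateSpace(("A", "B", "C"), max_range_size=2)
        Q = build_q_matrix(sp, RangeModelParams(d=0.5, e=0.0))
        iAB = sp.state_index(("A", "B"))
        assert np.all(Q[iAB, :] <= 0) or Q[iAB].max() == 0  # no 3-area target
        assert Q[iAB].sum() == pytest.approx(0.0)


class TestCladoTable:
    def test_single_area_dec_is_pure_sympatry(self, space2):
        ct = clado_table("DEC", 0.0, space2)
        iA = space2.state_index(("X",))
        events = ct.events_for(iA)
        assert len(events) == 1
        l, r, p, jump = events[0]
        assert (l, r, p, jump) == (iA, iA, 1.0, False)

    def test_dec_two_area_ancestor_six_equal_events(self, space2):
        ct = clado_table("DEC", 0.0, space2)
        events = ct.events_for(space2.state_index(("X", "Y")))
        assert len(events) == 6
        assert all(p == pytest.approx(1 / 6) for _, _, p, _ in events)

    @pytest.mark.parametrize("model", list(MODELS))
    @pytest.mark.parametrize("j", [0.0, 0.7, 2.9])
    def test_probabilities_normalize_and_match_oracle(self, model, j, space2):
        ct = clado_table(model, j, space2)
        oracle = oracle_clado_2areas(model, j)
        name = {1: "A", 2: "B", 3: "AB"}
        for si in range(1, space2.n_states):
            events = ct.events_for(si)
            assert sum(p for _, _, p, _ in events) == pytest.approx(1.0)
            got = sorted((name[int(l)], name[int(r)], round(float(p), 12))
                         for l, r, p, _ in events)
            want = sorted((l, r, round(p, 12)) for l, r, p in oracle[name[si]])
            assert got == want

    def test_j_zero_has_no_jump_events(self, space2):
        for model in MODELS:
            ct = clado_table(model, 0.0, space2)
            assert not ct.is_jump.any()

    def test_near_maximal_jump_weight_dominates(self, space2):
        ct = clado_table("BAYAREALIKE", 3.0 - 1e-9, space2)
        iA = space2.state_index(("X",))
        events = ct.events_for(iA)
        jump_mass = sum(p for _, _, p, jp in events if jp)
        assert jump_mass == pytest.approx(1.0, abs=1e-8)
        assert sum(p for _, _, p, _ in events) == pytest.approx(1.0)

    def test_bayarealike_copies_full_range(self, space2):
        ct = clado_table("BAYAREALIKE", 0.0, space2)
        iAB = space2.state_index(("X", "Y"))
        events = ct.events_for(iAB)
        assert events == [(iAB, iAB, 1.0, False)]


class TestTreeLoglik:
    def test_single_area_probability_one(self, tree3):
        sp = RangeStateSpace(("A",))
        tips = {"A": ("A",), "B": ("A",), "C": ("A",)}
        for model in ALL_MODELS:
            ll = tree_loglik(tree3, tips, model, RangeModelParams(d=0.1, e=0.0), sp)
            assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", ALL_MODELS)
    def test_matches_enumeration_oracle(self, model, tree3, space2):
        rng = np.random.default_rng(hash(model) % 2**31)
        for _ in range(3):
            params = RangeModelParams(
                d=rng.uniform(0.01, 0.5), e=rng.uniform(0.01, 0.3),
                j=rng.uniform(0.05, 2.5) if model.endswith("+J") else 0.0)
            probs = brute_force_3tip(tree3, space2, model, params)
            tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
            ll = tree_loglik(tree3, tips, model, params, space2)
            # oracle labels: A = first area (X), B = second (Y), AB = both
            assert ll == pytest.approx(np.log(probs[("A", "AB", "B")]), abs=1e-8)

    def test_conditioned_likelihood_sums_to_one(self, tree3, space2):
        params = RangeModelParams(d=0.05, e=0.08)
        probs = brute_force_3tip(tree3, space2, "DEC", params, conditioning="branch")
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-10)
        total = 0.0
        for (a, b, c), _ in probs.items():
            conv = {"A": ("X",), "B": ("Y",), "AB": ("X", "Y")}
            total += np.exp(tree_loglik(
                tree3, {"A": conv[a], "B": conv[b], "C": conv[c]}, "DEC",
                params, space2, conditioning="branch"))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_plus_j_at_zero_equals_base(self, tree3, space2):
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        for base in MODELS:
            p = RangeModelParams(d=0.1, e=0.05, j=0.0)
            assert tree_loglik(tree3, tips, base + "+J", p, space2) == pytest.approx(
                tree_loglik(tree3, tips, base, p, space2), abs=1e-10)

    def test_tip_order_invariance(self, space2):
        t1 = pr.IndexedTree.from_newick("((A:1.0,B:1.5):1.0,C:2.0);")
        t2 = pr.IndexedTree.from_newick("(C:2.0,(B:1.5,A:1.0):1.0);")
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        p = RangeModelParams(d=0.2, e=0.1, j=0.4)
        for model in ("DEC+J", "DIVALIKE"):
            assert tree_loglik(t1, tips, model, p, space2) == pytest.approx(
                tree_loglik(t2, tips, model, p, space2), abs=1e-10)

    def test_area_relabelling_invariance_with_permuted_multipliers(self, tree3):
        st = [pr.TimeStratum(start_ma=300.0, end_ma=0.0)]
        mids = {"P": pr.GeoPoint(0, 0), "Q": pr.GeoPoint(0, 40), "R": pr.GeoPoint(30, 90)}
        a1 = pr.AreaSet(labels=("P", "Q", "R"), midpoints={"0-300Ma": mids})
        a2 = pr.AreaSet(labels=("R", "P", "Q"), midpoints={"0-300Ma": mids})
        m1 = pr.build_distance_matrices(a1, st)
        m2 = pr.build_distance_matrices(a2, st)
        sp1 = RangeStateSpace(("P", "Q", "R"))
        sp2 = RangeStateSpace(("R", "P", "Q"))
        tips = {"A": ("P",), "B": ("Q", "R"), "C": ("Q",)}
        p = RangeModelParams(d=0.1, e=0.02)
        ll1 = tree_loglik(tree3, tips, "DEC", p, sp1, multipliers=m1)
        ll2 = tree_loglik(tree3, tips, "DEC", p, sp2, multipliers=m2)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_empty_tip_range_rejected(self, tree3, space2):
        presence = pd.DataFrame([[1, 0], [0, 0], [0, 1]], index=["A", "B", "C"],
                                columns=["X", "Y"])
        with pytest.raises(ValueError, match="empty range"):
            GeographicRangeModel(tree3, presence, model="DEC", space=space2)


class TestStratifiedLikelihood:
    def test_stratified_equals_merged_when_matrices_identical(self, tree3, space2):
        mids = {"X": pr.GeoPoint(0, 0), "Y": pr.GeoPoint(0, 50)}
        one = [pr.TimeStratum(300.0, 0.0)]
        many = [pr.TimeStratum(1.2, 0.0), pr.TimeStratum(2.1, 1.2),
                pr.TimeStratum(300.0, 2.1)]
        areas1 = pr.AreaSet(("X", "Y"), {s.label: mids for s in one})
        areas2 = pr.AreaSet(("X", "Y"), {s.label: mids for s in many})
        m1 = pr.build_distance_matrices(areas1, one)
        m2 = pr.build_distance_matrices(areas2, many)
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        p = RangeModelParams(d=0.15, e=0.05)
        assert tree_loglik(tree3, tips, "DEC", p, space2, multipliers=m1) == \
            pytest.approx(tree_loglik(tree3, tips, "DEC", p, space2,
                                      multipliers=m2), abs=1e-9)

    def test_distinct_strata_change_the_likelihood(self, tree3, space2):
        strata = [pr.TimeStratum(1.2, 0.0), pr.TimeStratum(300.0, 1.2)]
        near = {"X": pr.GeoPoint(0, 0), "Y": pr.GeoPoint(0, 20)}
        far = {"X": pr.GeoPoint(0, 0), "Y": pr.GeoPoint(0, 160)}
        mids = {strata[0].label: near, strata[1].label: far}
        areas = pr.AreaSet(("X", "Y"), mids)
        mults = pr.build_distance_matrices(areas, strata)
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        p = RangeModelParams(d=0.15, e=0.05)
        ll_strat = tree_loglik(tree3, tips, "DEC", p, space2, multipliers=mults)
        ll_plain = tree_loglik(tree3, tips, "DEC", p, space2)
        assert abs(ll_strat - ll_plain) > 1e-3


class TestFitting:
    def test_no_dispersal_signal_drives_d_to_lower_bound(self):
        tree = pr.IndexedTree.from_newick(
            "((A:10.0,B:10.0):10.0,(C:10.0,D:10.0):10.0);")
        tips = {t: ("X",) for t in "ABCD"}
        sp = RangeStateSpace(("X", "Y"))
        mdl = GeographicRangeModel(tree, tips, model="DEC", space=sp)
        fit = mdl.fit(starts=2, seed=0, e_bounds=(1e-12, 1e-11))
        # effectively zero: expected dispersals over the whole tree << 1
        assert fit.params.d * tree.branch_length.sum() < 1e-4

    def test_refit_from_optimum_is_fixed_point(self, small_bundle):
        _, tree, space, history, _ = small_bundle
        mdl = GeographicRangeModel(tree, history.presence_matrix(), model="DEC",
                                   space=space, conditioning="branch")
        fit = mdl.fit(starts=2, seed=0)
        assert mdl.loglike(fit.params) == pytest.approx(fit.llf, abs=1e-6)

    def test_nesting_plus_j_never_worse(self, small_bundle):
        _, tree, space, history, _ = small_bundle
        pres = history.presence_matrix()
        base = GeographicRangeModel(tree, pres, "DEC", space=space).fit(starts=2, seed=0)
        plus = GeographicRangeModel(tree, pres, "DEC+J", space=space).fit(starts=3, seed=0)
        assert plus.llf >= base.llf - 1e-6

    def test_aic_aicc_definitions(self, small_bundle):
        _, tree, space, history, _ = small_bundle
        mdl = GeographicRangeModel(tree, history.presence_matrix(), "DEC", space=space)
        fit = RangeFitResults(model_obj=mdl, params=RangeModelParams(0.01, 0.01),
                              llf=-123.4, converged=True)
        assert fit.aic == pytest.approx(2 * 2 - 2 * (-123.4))
        k, n = 2, tree.n_tips
        assert fit.aicc == pytest.approx(fit.aic + 2 * k * (k + 1) / (n - k - 1))


class TestCompareModels:
    def _fit(self, mdl, llf, params=None):
        return RangeFitResults(model_obj=mdl, llf=llf, converged=True,
                               params=params or RangeModelParams(0.01, 0.01))

    def test_equal_fits_share_weight(self, tree3, space2):
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        m1 = GeographicRangeModel(tree3, tips, "DEC", space=space2)
        m2 = GeographicRangeModel(tree3, tips, "DIVALIKE", space=space2)
        table = compare_models([self._fit(m1, -10.0), self._fit(m2, -10.0)])
        assert np.allclose(table["AIC_weight"], 0.5)
        assert table["AIC_weight"].sum() == pytest.approx(1.0)

    def test_lrt_statistic_and_p(self, tree3, space2):
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        base = GeographicRangeModel(tree3, tips, "DEC", space=space2)
        plus = GeographicRangeModel(tree3, tips, "DEC+J", space=space2)
        table = compare_models([
            self._fit(base, -30.0),
            self._fit(plus, -20.0, RangeModelParams(0.01, 0.01, 0.5))])
        row = table[table["model"] == "DEC+J"].iloc[0]
        assert row["LRT_p_vs_base"] == pytest.approx(chi2.sf(20.0, df=1), rel=1e-12)

    def test_weights_match_independent_softmax(self, tree3, space2):
        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        fits = []
        for model, llf in (("DEC", -31.0), ("DIVALIKE", -29.5), ("BAYAREALIKE", -33.2)):
            fits.append(self._fit(GeographicRangeModel(tree3, tips, model,
                                                       space=space2), llf))
        table = compare_models(fits).set_index("model")
        aics = {f.model: f.aic for f in fits}
        z = np.array([np.exp(-0.5 * (aics[m] - min(aics.values())))
                      for m in table.index])
        assert np.allclose(table["AIC_weight"].values, z / z.sum(), atol=1e-12)

    def test_mismatched_data_rejected(self, tree3, space2):
        f1 = self._fit(GeographicRangeModel(
            tree3, {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}, "DEC", space=space2), -10)
        f2 = self._fit(GeographicRangeModel(
            tree3, {"A": ("Y",), "B": ("X", "Y"), "C": ("Y",)}, "DEC", space=space2), -10)
        with pytest.raises(ValueError, match="hash"):
            compare_models([f1, f2])


class TestAncestralMarginals:
    def test_uniform_tips_no_movement_pin_every_node(self, tree3):
        sp = RangeStateSpace(("X", "Y"))
        tips = {"A": ("X",), "B": ("X",), "C": ("X",)}
        mdl = GeographicRangeModel(tree3, tips, "DEC", space=sp)
        fit = RangeFitResults(model_obj=mdl, params=RangeModelParams(d=0, e=0),
                              llf=mdl.loglike(RangeModelParams(d=0, e=0)),
                              converged=True)
        marg = fit.ancestral_marginals()
        iX = sp.state_index(("X",))
        assert np.allclose(marg.probs[:, iX], 1.0)

    @pytest.mark.parametrize("model", ["DEC", "DEC+J", "DIVALIKE", "BAYAREALIKE+J"])
    def test_matches_enumeration_posterior(self, model, tree3, space2):
        params = RangeModelParams(d=0.12, e=0.06,
                                  j=0.8 if model.endswith("+J") else 0.0)
        # oracle: joint enumeration, then condition on the observed tips
        from scipy.linalg import expm as _expm
        ct = oracle_clado_2areas(model.replace("+J", ""),
                                 params.j if model.endswith("+J") else 0.0)
        Q = oracle_q_2areas(params.d, params.e)
        P = lambda t: _expm(Q * t)
        PA, PB, PC, PN = P(1.0), P(1.5), P(2.0), P(1.0)
        mask_of = {"A": 1, "B": 2, "AB": 3}
        post_root = np.zeros(4)
        post_n1 = np.zeros(4)
        for sroot in ("A", "B", "AB"):
            for l0, r0, p0 in ct[sroot]:
                for sn1 in ("A", "B", "AB"):
                    for l1, r1, p1 in ct[sn1]:
                        w = (p0 * PN[mask_of[l0], mask_of[sn1]] * p1
                             * PA[mask_of[l1], 1] * PB[mask_of[r1], 3]
                             * PC[mask_of[r0], 2]) / 3.0
                        post_root[mask_of[sroot]] += w
                        post_n1[mask_of[sn1]] += w
        post_root /= post_root.sum()
        post_n1 /= post_n1.sum()

        tips = {"A": ("X",), "B": ("X", "Y"), "C": ("Y",)}
        mdl = GeographicRangeModel(tree3, tips, model, space=space2)
        fit = RangeFitResults(model_obj=mdl, params=params,
                              llf=mdl.loglike(params), converged=True)
        marg = fit.ancestral_marginals()
        for pos, node in enumerate(marg.node_ids):
            ref = post_root if node == tree3.root else post_n1
            assert np.allclose(marg.probs[pos], ref, atol=1e-8)

    def test_vectors_normalized_with_zero_null_probability(self, small_bundle):
        _, tree, space, history, _ = small_bundle
        mdl = GeographicRangeModel(tree, history.presence_matrix(), "DEC+J",
                                   space=space, conditioning="branch")
        fit = mdl.fit(starts=2, seed=0)
        marg = fit.ancestral_marginals()
        assert np.allclose(marg.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(marg.probs[:, 0], 0.0)


def test_model_name_parsing():
    assert parse_model_name("DEC") == ("DEC", False)
    assert parse_model_name("BAYAREALIKE+J") == ("BAYAREALIKE", True)
    with pytest.raises(ValueError):
        parse_model_name("DEC+X")
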
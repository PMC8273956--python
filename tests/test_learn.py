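"""Constraint-based neighbourhoods, BIC scoring, and the two searches."""

import math

import numpy as np
import pytest

from bnhybrid.core import DAG, Dataset, CategoricalVariable, Skeleton
from bnhybrid.learn import (
    FamilyScoreCache,
    TabuParams,
    bic_score,
    hill_climb,
    iamb_neighborhood,
    learn_hybrid,
    mmpc_neighborhood,
    skeleton_from_neighborhoods,
    tabu_search,
)
from bnhybrid.netgen import forward_sample

from conftest import random_binary_dataset


def true_skeleton(net):
    return Skeleton.from_dag(net.graph).adjacencies


class TestMMPC:
    def test_mutually_independent_variables_mostly_empty(self):
        nonempty_runs = empty_skeletons = 0
        for seed in range(10):
            d = random_binary_dataset(5000, 4, seed, names=list("WXYZ"))
            res = {t: mmpc_neighborhood(d, t) for t in "WXYZ"}
            nonempty_runs += any(r.members for r in res.values())
            empty_skeletons += len(skeleton_from_neighborhoods(res)) == 0
        # raw neighbourhoods admit occasional alpha-level false positives;
        # the symmetric AND-rule screens almost all of them out
        assert nonempty_runs <= 3
        assert empty_skeletons >= 8

    def test_chain_target_recovers_both_neighbours(self, chain_net):
        hits = 0
        for seed in range(10):
            d = forward_sample(chain_net, 20_000, seed)
            hits += mmpc_neighborhood(d, "Y").members == {"X", "Z"}
        assert hits >= 8

    def test_wetgrass_parents_found(self, sprinkler):
        hits = 0
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 50_000, seed)
            hits += mmpc_neighborhood(d, "WetGrass").members == {"Sprinkler", "Rain"}
        assert hits >= 8

    def test_trace_replays_to_members(self, sprinkler):
        d = forward_sample(sprinkler, 10_000, 3)
        r = mmpc_neighborhood(d, "Cloudy")
        assert r.replay() == r.members


class TestIAMB:
    def test_independent_target_gives_empty_blanket(self):
        d = random_binary_dataset(5000, 4, 12, names=list("WXYZ"))
        assert iamb_neighborhood(d, "W").members == frozenset()

    def test_markov_blanket_includes_spouse(self, sprinkler):
        # Sprinkler's blanket is {Cloudy, WetGrass, Rain}: Rain enters as
        # the co-parent (spouse) through the WetGrass collider
        hits = 0
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 50_000, seed)
            mb = iamb_neighborhood(d, "Sprinkler", variant="plain").members
            hits += mb == {"Cloudy", "Rain", "WetGrass"}
        assert hits >= 8

    def test_inter_never_strict_superset_of_plain(self, sprinkler):
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 5_000, seed)
            for target in d.names:
                inter = iamb_neighborhood(d, target, variant="inter").members
                plain = iamb_neighborhood(d, target, variant="plain").members
                assert inter <= plain

    def test_fast_variant_agrees_at_large_n(self, sprinkler):
        d = forward_sample(sprinkler, 50_000, 2)
        fast = iamb_neighborhood(d, "WetGrass", variant="fast").members
        assert fast == {"Sprinkler", "Rain"}


class TestSkeletonRule:
    def test_and_rule(self):
        from bnhybrid.learn import NeighborhoodResult

        mk = lambda t, ms: NeighborhoodResult(t, frozenset(ms))
        res = {"X": mk("X", {"Y"}), "Y": mk("Y", {"X"}), "Z": mk("Z", set())}
        skel = skeleton_from_neighborhoods(res)
        assert skel.adjacencies == {frozenset(("X", "Y"))}
        # asymmetric evidence dropped
        res = {"X": mk("X", {"Y"}), "Y": mk("Y", set()), "Z": mk("Z", set())}
        assert len(skeleton_from_neighborhoods(res)) == 0

    def test_inconsistent_universe_rejected(self):
        from bnhybrid.errors import InconsistentUniverseError
        from bnhybrid.learn import NeighborhoodResult

        res = {"X": NeighborhoodResult("X", frozenset({"Q"}))}
        with pytest.raises(InconsistentUniverseError):
            skeleton_from_neighborhoods(res)

    def test_spouse_screen_removes_collider_link(self, sprinkler):
        # Sprinkler–Rain survives the AND rule (each is in the other's
        # blanket) but is severed by conditioning on Cloudy
        severed = 0
        for seed in range(2, 12):
            d = forward_sample(sprinkler, 50_000, seed)
            res = {t: iamb_neighborhood(d, t, variant="inter") for t in d.names}
            skel = skeleton_from_neighborhoods(res, data=d, spouse_screen=True)
            severed += not skel.has("Sprinkler", "Rain")
        assert severed >= 8


class TestBIC:
    def test_single_binary_variable_hand_value(self):
        vs = [CategoricalVariable("X", ("a", "b"))]
        d = Dataset(vs, np.array([[0]] * 4 + [[1]] * 4))
        score = bic_score(d, DAG(["X"]))
        assert score == pytest.approx(8 * math.log(0.5) - 0.5 * math.log(8), abs=1e-9)

    def test_decomposability(self, sprinkler):
        d = forward_sample(sprinkler, 2_000, 5)
        cache = FamilyScoreCache(d)
        g = sprinkler.graph
        total = sum(cache.family(n, g.parents(n)) for n in g.nodes)
        assert bic_score(d, g, cache) == pytest.approx(total, abs=1e-9)

    def test_dependence_beats_empty_graph(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.integers(0, 2, 10_000)
            b = np.where(rng.random(10_000) < 0.9, a, 1 - a)
            vs = [CategoricalVariable("A", ("0", "1")), CategoricalVariable("B", ("0", "1"))]
            d = Dataset(vs, np.column_stack([a, b]))
            assert bic_score(d, DAG("AB", [("A", "B")])) > bic_score(d, DAG("AB"))


class TestSearches:
    def test_single_variable_returns_empty_graph(self):
        vs = [CategoricalVariable("X", ("a", "b"))]
        d = Dataset(vs, np.array([[0], [1], [0], [1]]))
        assert hill_climb(d).n_edges() == 0
        assert tabu_search(d).n_edges() == 0

    def test_empty_restriction_forces_empty_graph(self, sprinkler):
        d = forward_sample(sprinkler, 5_000, 1)
        empty = Skeleton(d.names)
        assert hill_climb(d, restrict=empty).n_edges() == 0
        g = tabu_search(d, restrict=empty)
        assert g.n_edges() == 0

    def test_hill_climb_terminates_at_local_optimum(self, sprinkler):
        from bnhybrid.learn import _legal_moves, _move_delta, TIE_TOL

        d = forward_sample(sprinkler, 20_000, 4)
        cache = FamilyScoreCache(d)
        g = hill_climb(d, cache=cache)
        assert all(
            _move_delta(g, cache, *mv) <= TIE_TOL for mv in _legal_moves(g, None)
        )

    def test_tabu_at_least_matches_hill_climb(self, sprinkler):
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 50_000, seed)
            cache = FamilyScoreCache(d)
            hc = hill_climb(d, cache=cache)
            tb = tabu_search(d, cache=cache)
            assert cache.total(tb) >= cache.total(hc) - 1e-6

    def test_tabu_reaches_true_equivalence_class_score(self, sprinkler):
        # the downhill-capable search escapes the local optimum that traps
        # greedy hill climbing on this network
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 50_000, seed)
            cache = FamilyScoreCache(d)
            tb = tabu_search(d, cache=cache)
            assert cache.total(tb) >= cache.total(sprinkler.graph) - 1e-6

    def test_restriction_soundness(self, sprinkler):
        d = forward_sample(sprinkler, 20_000, 9)
        res = learn_hybrid(d, "inter.iamb", "tabu")
        assert all(res.skeleton.has(u, v) for u, v in res.dag.edges)

    def test_determinism_byte_identical(self, sprinkler):
        d = forward_sample(sprinkler, 10_000, 6)
        g1 = learn_hybrid(d, "inter.iamb", "tabu").dag
        g2 = learn_hybrid(d, "inter.iamb", "tabu").dag
        assert g1.edges == g2.edges

    def test_invalid_tabu_params_rejected(self):
        with pytest.raises(ValueError):
            TabuParams(tabu_length=0)


class TestHybrid:
    def test_independent_data_yields_empty_dag(self):
        d = random_binary_dataset(5_000, 4, 42, names=list("WXYZ"))
        res = learn_hybrid(d, "inter.iamb", "tabu")
        assert res.dag.n_edges() <= 1  # at most an alpha-level fluke

    def test_skeleton_shared_across_search_methods(self, sprinkler):
        d = forward_sample(sprinkler, 20_000, 8)
        a = learn_hybrid(d, "mmpc", "hc")
        b = learn_hybrid(d, "mmpc", "tabu")
        assert a.skeleton.adjacencies == b.skeleton.adjacencies

    def test_sprinkler_skeleton_recovery_across_seeds(self, sprinkler):
        hits = 0
        for seed in range(1, 11):
            d = forward_sample(sprinkler, 50_000, seed)
            res = learn_hybrid(d, "inter.iamb", "tabu")
            hits += res.skeleton.adjacencies == true_skeleton(sprinkler)
        assert hits >= 9

    def test_unknown_methods_rejected(self, sprinkler):
        d = forward_sample(sprinkler, 100, 1)
        with pytest.raises(ValueError):
            learn_hybrid(d, "nope", "tabu")
        with pytest.raises(ValueError):
            learn_hybrid(d, "mmpc", "nope")
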
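"""Bicolor network construction, propagation (vs direct solve), GO enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from linctools.expression_analysis import spearman_coexpression
from linctools.function_annotation import (
    BicolorNetwork,
    _normalized_adjacency,
    assign_annotations,
    build_coexpression_edges,
    combine_network,
    enrich_go,
    load_go_annotations,
    load_ppi_edges,
    normalize_scores_minmax,
    propagate,
    seed_first_degree,
)


def direct_solve(W: np.ndarray, Y: np.ndarray, alpha: float) -> np.ndarray:
    """Independent closed-form oracle: F = (1-a)(I - a W')^-1 Y."""
    deg = W.sum(axis=1)
    inv = np.zeros_like(deg)
    inv[deg > 0] = 1 / np.sqrt(deg[deg > 0])
    Wn = np.outer(inv, inv) * W
    return (1 - alpha) * np.linalg.solve(np.eye(len(W)) - alpha * Wn, Y)


class TestEdgeSelection:
    def test_percentile_cut_matches_sort_and_cut_oracle(self):
        rng = np.random.default_rng(2)
        pairs = {(f"a{i}", f"b{i}"): float(r)
                 for i, r in enumerate(rng.uniform(-1, 1, 1000))}
        edges = build_coexpression_edges(pairs, percentile=0.5)
        cut = sorted((abs(r) for r in pairs.values()), reverse=True)[:5]
        assert len(edges) == 5
        assert sorted((w for _, _, w in edges), reverse=True) == pytest.approx(cut)

    def test_all_equal_rho_keeps_everything(self):
        pairs = {(f"a{i}", "b"): 0.7 for i in range(300)}
        assert len(build_coexpression_edges(pairs)) == 300

    def test_small_universe_warns_but_computes(self):
        pairs = {("a", "b"): 0.5, ("a", "c"): 0.9}
        with pytest.warns(UserWarning, match="percentile"):
            edges = build_coexpression_edges(pairs)
        assert len(edges) >= 1


class TestMinMax:
    def test_simple_and_endpoints(self):
        assert normalize_scores_minmax([2, 4, 6]) == pytest.approx([0, 0.5, 1])
        rng = np.random.default_rng(0)
        v = normalize_scores_minmax(rng.normal(size=50))
        assert v.min() == 0.0 and v.max() == 1.0

    def test_constant_vector_maps_to_zero(self):
        assert normalize_scores_minmax([3, 3, 3]) == pytest.approx([0, 0, 0])


class TestCombine:
    COLORS = {"m1": "mRNA", "m2": "mRNA", "L1": "lincRNA"}

    def test_overlap_takes_max(self):
        net = combine_network([("m1", "m2", 0.4)], [("m1", "m2", 0.9)], self.COLORS)
        i, j = net.index["m1"], net.index["m2"]
        assert net.W[i, j] == 0.9

    def test_coexpr_only_pair_kept_as_is(self):
        net = combine_network([("L1", "m1", 0.7)], [], self.COLORS)
        assert net.W[net.index["L1"], net.index["m1"]] == 0.7

    def test_ppi_edge_to_lincrna_rejected(self):
        with pytest.raises(ValueError, match="lincRNA"):
            combine_network([], [("L1", "m1", 0.5)], self.COLORS)

    def test_symmetry_and_zero_diagonal(self):
        net = combine_network([("L1", "m1", 0.7), ("m1", "m2", 0.2)],
                              [("m1", "m2", 0.8)], self.COLORS)
        assert np.allclose(net.W, net.W.T)
        assert np.all(np.diag(net.W) == 0)


class TestFirstDegree:
    def test_neighbour_union_and_isolated_empty(self):
        colors = {"L1": "lincRNA", "L2": "lincRNA", "m1": "mRNA", "m2": "mRNA"}
        net = combine_network([("L1", "m1", 0.9), ("L1", "m2", 0.8)], [], colors)
        ann = {"m1": {"GO:a", "GO:b"}, "m2": {"GO:b", "GO:c"}}
        seeds = seed_first_degree(net, ann)
        assert seeds["L1"] == {"GO:a", "GO:b", "GO:c"}
        assert seeds["L2"] == set()

    def test_matches_brute_force_neighbourhood_union(self, fixture_net):
        net, go = fixture_net
        seeds = seed_first_degree(net, go)
        for linc in net.linc_nodes:
            i = net.index[linc]
            expected = set()
            for j, w in enumerate(net.W[i]):
                if w > 0 and net.colors[net.nodes[j]] == "mRNA":
                    expected |= go.get(net.nodes[j], set())
            assert seeds[linc] == expected


class TestPropagation:
    def test_zero_prior_column_stays_zero(self):
        colors = {"a": "mRNA", "b": "lincRNA"}
        net = combine_network([("a", "b", 0.5)], [], colors)
        net.terms, net.Y = ["t"], np.zeros((2, 1))
        scores = propagate(net)
        assert np.all(scores.F.values == 0)

    def test_isolated_seed_closed_form(self):
        colors = {"a": "mRNA", "b": "mRNA", "c": "mRNA"}
        net = combine_network([("b", "c", 0.5)], [], colors)
        net.terms = ["t"]
        net.Y = np.array([[1.0], [0.0], [0.0]])  # node "a" isolated
        scores = propagate(net, alpha=0.8)
        assert scores.F.loc["a", "t"] == pytest.approx(0.2, abs=1e-6)
        assert scores.F.loc["b", "t"] == pytest.approx(0.0, abs=1e-9)

    def test_three_node_path_matches_linear_solve(self):
        colors = {"a": "mRNA", "b": "mRNA", "c": "mRNA"}
        net = combine_network([("a", "b", 1.0), ("b", "c", 1.0)], [], colors)
        net.terms = ["t"]
        net.Y = np.array([[1.0], [0.0], [0.0]])
        scores = propagate(net, alpha=0.8, tol=1e-9)
        expected = direct_solve(net.W, net.Y, 0.8)
        assert np.allclose(scores.F.values, expected, atol=1e-5)

    def test_fixture_network_equals_direct_solve_and_fixed_point(self, fixture_net):
        net, _ = fixture_net
        assert len(net.nodes) <= 200
        scores = propagate(net, alpha=0.8, tol=1e-9)
        assert scores.converged
        expected = direct_solve(net.W, net.Y, 0.8)
        assert np.allclose(scores.F.values, expected, atol=1e-5)
        # fixed-point residual below tolerance
        Wn = _normalized_adjacency(net.W)
        resid = np.abs(scores.F.values - (0.8 * Wn @ scores.F.values + 0.2 * net.Y)).sum()
        assert resid < 1e-6

    def test_random_networks_equal_direct_solve(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = int(rng.integers(5, 60))
            W = np.triu(rng.uniform(0, 1, (n, n)) * (rng.random((n, n)) < 0.2), 1)
            W = W + W.T
            Y = (rng.random((n, 3)) < 0.2).astype(float)
            colors = {f"n{i}": "mRNA" for i in range(n)}
            net = BicolorNetwork(list(colors), colors, W)
            net.terms = ["t1", "t2", "t3"]
            net.Y = Y
            scores = propagate(net, alpha=0.8, tol=1e-10)
            assert scores.converged
            assert np.allclose(scores.F.values, direct_solve(W, Y, 0.8), atol=1e-5)

    def test_adding_seed_edge_never_decreases_linc_score(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = 8
            W = np.triu((rng.random((n, n)) < 0.3) * rng.uniform(0.2, 1, (n, n)), 1)
            W = W + W.T
            W[0, :] = W[:, 0] = 0.0      # node 0: disconnected lincRNA
            colors = {f"n{i}": ("lincRNA" if i == 0 else "mRNA") for i in range(n)}
            Y = np.zeros((n, 1))
            Y[1, 0] = 1.0                # node 1 seeds the term
            net = BicolorNetwork(list(colors), colors, W.copy())
            net.terms, net.Y = ["t"], Y
            before = propagate(net, tol=1e-10).F.iloc[0, 0]
            W2 = W.copy()
            W2[0, 1] = W2[1, 0] = 0.5
            net2 = BicolorNetwork(list(colors), colors, W2)
            net2.terms, net2.Y = ["t"], Y
            after = propagate(net2, tol=1e-10).F.iloc[0, 0]
            assert after >= before - 1e-12
            assert after > 0

    def test_alpha_bounds_enforced(self, fixture_net):
        net, _ = fixture_net
        with pytest.raises(ValueError, match="alpha"):
            propagate(net, alpha=1.0)


class TestAssignment:
    def test_zero_score_never_annotated_even_in_top_ranks(self):
        colors = {"L1": "lincRNA", "L2": "lincRNA", "m": "mRNA"}
        net = combine_network([("L1", "m", 0.9)], [], colors)
        net.attach_go({"m": {"GO:x"}})
        scores = propagate(net)
        assigned = assign_annotations(scores, net, top_rank=100)
        assert assigned["L1"] == {"GO:x"}
        assert assigned["L2"] == set()   # isolated: F == 0, excluded from top list

    def test_top_rank_caps_assignments_per_term(self, fixture_net):
        net, _ = fixture_net
        scores = propagate(net)
        assigned = assign_annotations(scores, net, top_rank=1)
        for term in net.terms:
            carriers = [l for l, ts in assigned.items() if term in ts]
            assert len(carriers) <= 1

    def test_planted_modules_recovered_without_cross_assignment(
            self, fixture_net, manifest, sim_config):
        net, _ = fixture_net
        scores = propagate(net, alpha=0.8)
        n_lincs = len(net.linc_nodes)
        top_rank = min(100, math.ceil(0.05 * n_lincs))
        assigned = assign_annotations(scores, net, top_rank=top_rank)
        modules = manifest["expression"]["modules"].values()
        hit = total = 0
        for mod in modules:
            for linc in mod["lincs"]:
                total += 1
                hit += mod["term"] in assigned[linc]
                foreign = {m["term"] for m in modules if m["term"] != mod["term"]}
                assert not assigned[linc] & foreign
        assert hit / total >= 0.9


class TestEnrichment:
    def test_universal_term_p_is_one(self):
        genes = {f"g{i}" for i in range(10)}
        ann = {g: {"GO:u"} for g in genes}
        (res,) = enrich_go(genes, genes, ann)
        assert res.p_value == pytest.approx(1.0)

    def test_exact_urn_example(self):
        # all 5 study genes carry the term held by 5 of 20 population genes:
        # p = 1 / C(20,5)
        pop = {f"g{i}" for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        ann = {f"g{i}": {"GO:t"} for i in range(5)}
        (res,) = enrich_go(study, pop, ann)
        assert res.p_value == pytest.approx(1 / math.comb(20, 5), rel=1e-9)
        assert (res.k, res.n, res.K, res.N) == (5, 5, 5, 20)

    def test_empty_study_errors(self):
        with pytest.raises(ValueError, match="empty"):
            enrich_go(set(), {"g"}, {})

    def test_study_outside_population_errors(self):
        with pytest.raises(ValueError, match="subset"):
            enrich_go({"x"}, {"g"}, {})

    def test_bh_adjustment_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        pop = {f"g{i}" for i in range(100)}
        ann = {}
        for i in range(100):
            terms = {f"GO:{j}" for j in range(10) if rng.random() < 0.2}
            if terms:
                ann[f"g{i}"] = terms
        study = set(rng.choice(sorted(pop), 20, replace=False))
        results = enrich_go(study, pop, ann)
        assert all(0 < r.p_value <= 1 and r.p_value <= r.p_adjusted <= 1
                   for r in results)

    def test_null_pvalues_not_anticonservative(self):
        # p-values of a random study set must be super-uniform (no excess of
        # small p); the one-sided KS statistic tests exactly that direction,
        # which is the meaningful one for a discrete test statistic.
        rng = np.random.default_rng(6)
        N, K, n = 500, 60, 40
        pop = [f"g{i}" for i in range(N)]
        ann = {g: {"GO:t"} for g in pop[:K]}
        pvals = []
        for _ in range(1000):
            study = set(rng.choice(pop, n, replace=False))
            (res,) = enrich_go(study, set(pop), ann)
            pvals.append(res.p_value)
        ks = kstest(pvals, "uniform", alternative="greater")
        assert ks.pvalue > 0.01
        # and the p-value arithmetic agrees with the reference distribution
        k = len(set(pop[:K]) & study)
        assert pvals[-1] == pytest.approx(float(hypergeom.sf(k - 1, N, K, n)))
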
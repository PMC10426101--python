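"""Model scoring (Fisher's C, CICc), ranking, the best set, conditional
averaging, and the end-to-end exploratory search."""

import numpy as np
import pandas as pd
import pytest

import phylopathx as px
from phylopathx.pathsearch import CoefficientCache, PathConfig, _prepare_path_data
from phylopathx.synthdata import GeneratorSpec, simulate_tree, simulate_traits


class TestFisherC:
    def test_all_ones(self):
        C, p = px.fisher_c([1, 1, 1])
        assert C == 0.0 and p == 1.0

    def test_direct_evaluation(self):
        C, _ = px.fisher_c([0.05, 0.5])
        assert C == pytest.approx(-2 * (np.log(0.05) + np.log(0.5)), abs=1e-12)
        assert C == pytest.approx(7.3778, abs=1e-4)

    def test_single_p_chi_square_inverts(self):
        _, p = px.fisher_c([0.05])
        assert p == pytest.approx(0.05, abs=1e-12)

    def test_empty_is_saturated(self):
        assert px.fisher_c([]) == (0.0, 1.0)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            px.fisher_c([0.0, 0.5])


class TestCicc:
    def test_direct_evaluation(self):
        assert px.cicc(10, 5, 68) == pytest.approx(20.9677, abs=1e-4)

    def test_zero_parameters(self):
        assert px.cicc(0, 0, 10) == 0.0

    def test_asymptotic_limit(self):
        assert px.cicc(3.0, 4, 10**6) == pytest.approx(3.0 + 8.0, abs=1e-3)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="insufficient"):
            px.cicc(1.0, 5, 6)


class TestWeights:
    def test_delta_zero_two(self):
        w = px.akaike_weights([0, 2])
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    def test_equal_deltas_equal_weights(self):
        np.testing.assert_allclose(px.akaike_weights([1, 1, 1]), 1 / 3)


@pytest.fixture(scope="module")
def chain_dataset():
    dag = px.DagModel(nodes=("A", "B", "C"), edges=frozenset({("A", "B"), ("B", "C")}))
    gs = GeneratorSpec(n_taxa=200, tree_model="birth_death", dag=dag,
                       coefficients={("A", "B"): 0.8, ("B", "C"): 0.8}, seed=11)
    tree = simulate_tree(gs)
    return tree, simulate_traits(tree, gs), dag


class TestScoreModels:
    def test_sorted_and_saturated_model_has_zero_c(self, chain_dataset):
        tree, traits, _ = chain_dataset
        scores = px.score_models(px.enumerate_dags(("A", "B", "C")), traits, tree)
        assert len(scores) == 25
        ciccs = [s.CICc for s in scores]
        assert ciccs == sorted(ciccs)
        for s in scores:
            assert s.C >= 0.0
            if len(s.model.edges) == 3:  # complete DAG: empty basis
                assert s.C == 0.0
                assert s.CICc == pytest.approx(
                    2 * s.q * s.n / (s.n - 1 - s.q), abs=1e-12)

    def test_true_chain_ranks_highly(self, chain_dataset):
        tree, traits, dag = chain_dataset
        hits = 0
        for rep in range(10):
            gs = GeneratorSpec(n_taxa=200, tree_model="birth_death", dag=dag,
                               coefficients={("A", "B"): 0.8, ("B", "C"): 0.8},
                               seed=500 + rep)
            tr = simulate_tree(gs)
            tt = simulate_traits(tr, gs)
            scores = px.score_models(px.enumerate_dags(("A", "B", "C")), tt, tr)
            rank = next(i for i, s in enumerate(scores)
                        if s.model.edges == dag.edges)
            hits += rank < 5
        assert hits >= 8

    def test_cache_on_off_identical(self, chain_dataset):
        tree, traits, _ = chain_dataset
        on = px.score_models(px.enumerate_dags(("A", "B", "C")), traits, tree,
                             PathConfig(use_cache=True))
        off = px.score_models(px.enumerate_dags(("A", "B", "C")), traits, tree,
                              PathConfig(use_cache=False))
        for a, b in zip(on, off):
            assert a.model.edges == b.model.edges
            assert abs(a.CICc - b.CICc) <= 1e-12

    def test_cache_hit_counting(self, chain_dataset):
        tree, traits, _ = chain_dataset
        cache = px.ClaimCache()
        models = list(px.enumerate_dags(("A", "B", "C")))
        px.score_models(models + models[:5], traits, tree, cache=cache)
        assert cache.misses == cache.stats["size"]
        assert cache.hits > 0

    def test_q_definitions(self, chain_dataset):
        tree, traits, _ = chain_dataset
        m = [px.DagModel(nodes=("A", "B", "C"),
                         edges=frozenset({("A", "B")}))]
        s_en = px.score_models(iter(m), traits, tree,
                               PathConfig(q_definition="edges_plus_nodes"))[0]
        s_e = px.score_models(iter(m), traits, tree,
                              PathConfig(q_definition="edges"))[0]
        assert s_en.q == 4 and s_e.q == 1

    def test_mismatched_variables_rejected(self, chain_dataset):
        tree, traits, _ = chain_dataset
        bad = [px.DagModel(nodes=("A", "B", "C"), edges=frozenset()),
               px.DagModel(nodes=("A", "B"), edges=frozenset())]
        with pytest.raises(ValueError, match="same variables"):
            px.score_models(iter(bad), traits, tree)


class TestBestSet:
    def _scores(self, ciccs):
        out = []
        for i, c in enumerate(ciccs):
            m = px.DagModel(nodes=("A", "B"), edges=frozenset())
            out.append(px.ModelScore(model=m, C=c, C_pvalue=0.5, q=2, n=50, CICc=c))
        return out

    def test_threshold_and_weights(self):
        retained = px.best_set(self._scores([10.0, 12.0, 13.5]), threshold=2.0)
        assert len(retained) == 2
        assert retained[0].weight == pytest.approx(0.7311, abs=1e-4)
        assert sum(s.weight for s in retained) == pytest.approx(1.0)

    def test_single_model_weight_one(self):
        retained = px.best_set(self._scores([5.0]))
        assert retained[0].weight == 1.0

    def test_all_equal_cicc_equal_weights(self):
        retained = px.best_set(self._scores([4.0, 4.0, 4.0]))
        assert [s.weight for s in retained] == pytest.approx([1 / 3] * 3)


class TestAveraging:
    def _retained_with_weights(self, nodes, edge_sets, weights):
        out = []
        for es, w in zip(edge_sets, weights):
            s = px.ModelScore(
                model=px.DagModel(nodes=nodes, edges=frozenset(es)),
                C=0, C_pvalue=1, q=1, n=50, CICc=0, weight=w)
            out.append(s)
        return out

    def test_shared_path_equal_weights(self):
        retained = self._retained_with_weights(
            ("A", "B"), [{("A", "B")}, {("A", "B")}], [0.5, 0.5])
        fits = {0: {("A", "B"): (0.4, 0.0)}, 1: {("A", "B"): (0.6, 0.0)}}
        avg = px.average_models(retained, None, None, coefficient_fits=fits)
        assert avg.path("A", "B").coefficient == pytest.approx(0.5)

    def test_path_in_single_model(self):
        retained = self._retained_with_weights(
            ("A", "B", "C"), [{("A", "B")}, {("B", "C")}], [0.7, 0.3])
        fits = {0: {("A", "B"): (0.9, 0.1)}, 1: {("B", "C"): (0.2, 0.1)}}
        avg = px.average_models(retained, None, None, coefficient_fits=fits)
        assert avg.path("A", "B").coefficient == pytest.approx(0.9)
        assert avg.path("A", "B").total_weight == pytest.approx(0.7)

    def test_three_models_hand_computed(self):
        """Weighted conditional mean with renormalised weights and the
        between-model variance term, against direct arithmetic."""
        retained = self._retained_with_weights(
            ("A", "B"), [{("A", "B")}, {("A", "B")}, set()], [0.5, 0.3, 0.2])
        fits = {0: {("A", "B"): (0.4, 0.05)}, 1: {("A", "B"): (0.8, 0.10)}, 2: {}}
        avg = px.average_models(retained, None, None, coefficient_fits=fits)
        w = np.array([0.5, 0.3]) / 0.8
        b = np.array([0.4, 0.8])
        se = np.array([0.05, 0.10])
        b_bar = float(w @ b)
        se_bar = float(w @ np.sqrt(se**2 + (b - b_bar) ** 2))
        p = avg.path("A", "B")
        assert p.coefficient == pytest.approx(b_bar, abs=1e-12)
        assert p.se == pytest.approx(se_bar, abs=1e-12)
        assert p.ci_low == pytest.approx(b_bar - 1.96 * se_bar, abs=1e-12)

    def test_bidirectional_flagging_and_exclusion(self):
        retained = self._retained_with_weights(
            ("A", "B"), [{("A", "B")}, {("B", "A")}], [0.5, 0.5])
        fits = {0: {("A", "B"): (0.5, 0.01)}, 1: {("B", "A"): (0.01, 0.2)}}
        avg = px.average_models(retained, None, None, coefficient_fits=fits)
        assert avg.bidirectional_pairs == [("A", "B")]
        assert ("B", "A") in avg.excluded_paths  # CI crosses zero
        assert ("A", "B") not in avg.excluded_paths

    def test_full_averaging_shrinks_rare_paths(self):
        retained = self._retained_with_weights(
            ("A", "B"), [{("A", "B")}, set(), set(), set()],
            [0.25, 0.25, 0.25, 0.25])
        fits = {0: {("A", "B"): (0.8, 0.05)}, 1: {}, 2: {}, 3: {}}
        cond = px.average_models(retained, None, None, coefficient_fits=fits)
        full = px.average_models(retained, None, None,
                                 config=PathConfig(averaging="full"),
                                 coefficient_fits=fits)
        assert full.path("A", "B").coefficient < cond.path("A", "B").coefficient


class TestExplore:
    def test_three_variable_report(self, chain_dataset):
        tree, traits, dag = chain_dataset
        report = px.explore(traits, tree)
        assert report.n_models == 25
        assert report.n_taxa == 200
        assert report.n_retained >= 1
        assert report.best_cicc == report.retained[0].CICc
        assert "digraph" in report.dot
        # every averaged path exists in at least one retained model
        retained_edges = set().union(*(s.model.edges for s in report.retained))
        for p in report.averaged.paths:
            assert (p.source, p.target) in retained_edges

    def test_taxa_mismatch_fails_before_fitting(self, chain_dataset):
        tree, traits, _ = chain_dataset
        bad = traits.copy()
        bad.index = ["zz" + t for t in bad.index]
        with pytest.raises(ValueError, match="not on the tree"):
            px.explore(bad, tree)

    def test_deterministic_report(self, chain_dataset):
        import json
        tree, traits, _ = chain_dataset
        a = px.explore(traits, tree)
        b = px.explore(traits, tree)
        ja = json.dumps(a.to_json_obj(), sort_keys=True)
        jb = json.dumps(b.to_json_obj(), sort_keys=True)
        assert ja == jb

    def test_recovery_on_identifiable_benchmark(self):
        """One benchmark replicate: all six compelled true edges emerge with
        CIs excluding zero."""
        tree, traits, cons, dag = px.recovery_benchmark(seed=300)
        report = px.explore(traits, tree, cons)
        sig = report.averaged.significant_edges()
        assert dag.edges <= sig

    def test_null_c_zero_for_saturated_order_model(self, bd_tree_64):
        """Complete DAG consistent with a causal order scores C = 0 on any
        data."""
        rng = np.random.default_rng(6)
        from conftest import brownian_traits
        df = brownian_traits(bd_tree_64, rng, 3)
        nodes = tuple(df.columns)
        complete = px.DagModel(nodes=nodes, edges=frozenset(
            (nodes[i], nodes[j]) for i in range(3) for j in range(i + 1, 3)))
        s = px.score_models(iter([complete]), df, bd_tree_64)[0]
        assert s.C == 0.0


class TestCoefficientCache:
    def test_matches_direct_pgls(self, chain_dataset):
        tree, traits, dag = chain_dataset
        data = _prepare_path_data(traits, tree, dag.nodes, standardize=True)
        cc = CoefficientCache(data, tree, PathConfig())
        fits = cc.fits_for(dag)
        direct = px.pgls_fit(data, tree, px.RegressionSpec(
            response="B", predictors=["A"]))
        assert fits[("A", "B")][0] == pytest.approx(
            direct.coefficients["A"], abs=1e-10)
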
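import numpy as np
import pandas as pd
import pytest

from codemerge.data_model import ClusterPartition, ScoreMatrix
from codemerge.markers import MarkerGeneSets
from codemerge.merge import (
    MergeConfig,
    PairTestResult,
    call_significance,
    cluster_profiles,
    merge_step,
    mnn_pairs,
    run_cluster_merge,
    summarize_scores,
)
from codemerge.merge import test_pair as pair_test
from codemerge.scoring import ScoreConfig, score_matrix

from conftest import make_expr


def make_scores(values, labels, clusters=None):
    values = np.asarray(values, dtype=float)
    part = ClusterPartition(labels)
    clusters = clusters or part.clusters
    sm = ScoreMatrix(values, [f"cell{i}" for i in range(len(labels))],
                     clusters)
    return sm, part


class TestSummarize:
    @pytest.mark.parametrize("method", ["k_quantiles", "k_bins", "k_means"])
    def test_constant_vector_summarizes_to_constant(self, method):
        out = summarize_scores(np.full(40, 3.3), method, k=15)
        assert np.allclose(out, 3.3)
        assert len(out) <= 15

    def test_quantiles_of_integer_ramp(self):
        out = summarize_scores(np.arange(15.0), "k_quantiles", k=15)
        np.testing.assert_allclose(out, np.arange(15.0))

    def test_quantiles_contain_extremes(self, rng):
        v = rng.normal(size=100)
        out = summarize_scores(v, "k_quantiles", k=15)
        assert out[0] == v.min() and out[-1] == v.max()

    def test_k_bins_drops_empty_and_preserves_mean_range(self, rng):
        v = rng.normal(size=200)
        out = summarize_scores(v, "k_bins", k=15)
        assert 1 <= len(out) <= 15
        assert v.min() <= out.min() and out.max() <= v.max()

    def test_k_means_few_distinct_values_returned_as_is(self):
        v = np.array([1.0, 2.0, 1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            summarize_scores(v, "k_means", k=15), [1.0, 2.0, 3.0])

    def test_k_means_deterministic(self, rng):
        v = rng.normal(size=300)
        a = summarize_scores(v, "k_means", k=10)
        b = summarize_scores(v, "k_means", k=10)
        np.testing.assert_allclose(a, b)

    def test_none_returns_input(self, rng):
        v = rng.normal(size=37)
        np.testing.assert_array_equal(summarize_scores(v, "none"), v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_scores(np.array([]), "k_quantiles")


class TestClusterProfiles:
    def test_single_cluster(self):
        sm, part = make_scores([[1.0], [3.0]], ["a", "a"])
        prof = cluster_profiles(sm, part)
        assert prof.shape == (1, 1)
        assert prof.loc["a", "a"] == 2.0

    def test_zero_scores_zero_matrix(self):
        sm, part = make_scores(np.zeros((4, 2)), ["a", "a", "b", "b"])
        assert (cluster_profiles(sm, part).to_numpy() == 0).all()

    def test_matches_loop_oracle(self, rng):
        labels = rng.choice(["a", "b", "c"], size=30)
        sm, part = make_scores(rng.normal(size=(30, 3)), labels,
                               clusters=["a", "b", "c"])
        prof = cluster_profiles(sm, part)
        for i, ci in enumerate(["a", "b", "c"]):
            for j, cj in enumerate(["a", "b", "c"]):
                assert prof.loc[ci, cj] == pytest.approx(
                    sm.values[labels == ci, j].mean())


class TestMnnPairs:
    def test_two_clusters_always_mutual(self):
        prof = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                            columns=["a", "b"])
        assert mnn_pairs(prof, 1) == {("a", "b")}

    def test_identical_rows_always_mutual(self, rng):
        rows = rng.normal(size=(4, 4))
        rows[1] = rows[0]
        prof = pd.DataFrame(rows, index=list("abcd"), columns=list("abcd"))
        assert ("a", "b") in mnn_pairs(prof, 1)

    def test_matches_brute_force(self, rng):
        rows = rng.normal(size=(5, 5))
        names = list("abcde")
        prof = pd.DataFrame(rows, index=names, columns=names)
        k = 2
        got = mnn_pairs(prof, k)
        # brute force: compute all distances, mutual k-nearest
        expected = set()
        dist = np.array([[np.linalg.norm(rows[i] - rows[j])
                          for j in range(5)] for i in range(5)])
        np.fill_diagonal(dist, np.inf)
        near = [set(np.argsort(dist[i])[:k]) for i in range(5)]
        for i in range(5):
            for j in range(i + 1, 5):
                if j in near[i] and i in near[j]:
                    expected.add((names[i], names[j]))
        assert got == expected

    def test_neighbours_clamped_with_warning(self, rng):
        prof = pd.DataFrame(rng.normal(size=(3, 3)), index=list("abc"),
                            columns=list("abc"))
        with pytest.warns(UserWarning, match="clamped"):
            pairs = mnn_pairs(prof, 10)
        assert pairs == {("a", "b"), ("a", "c"), ("b", "c")}


class TestTestPair:
    def test_identical_distributions_p_one(self):
        vals = np.tile([[1.0, 2.0]], (40, 1))
        sm, part = make_scores(vals, ["a"] * 20 + ["b"] * 20,
                               clusters=["a", "b"])
        r = pair_test(sm, part, "a", "b")
        assert r.p_i == 1.0 and r.p_j == 1.0

    def test_separated_scores_significant(self, rng):
        vals = np.zeros((80, 2))
        vals[:40, 0] = 10 + rng.normal(0, 0.5, 40)  # cluster a on column a
        vals[40:, 1] = 10 + rng.normal(0, 0.5, 40)
        sm, part = make_scores(vals, ["a"] * 40 + ["b"] * 40,
                               clusters=["a", "b"])
        r = pair_test(sm, part, "a", "b")
        assert r.p_i < 0.01 and r.p_j < 0.01

    def test_swap_symmetry(self, rng):
        vals = rng.normal(size=(60, 2)) ** 2
        sm, part = make_scores(vals, ["a"] * 25 + ["b"] * 35,
                               clusters=["a", "b"])
        r1 = pair_test(sm, part, "a", "b")
        r2 = pair_test(sm, part, "b", "a")
        # the unordered pair has the same two p-values, direction swapped
        assert r1.p_i == pytest.approx(r2.p_j)
        assert r1.p_j == pytest.approx(r2.p_i)
        assert (r1.n_i, r1.n_j) == (r2.n_j, r2.n_i)

    def test_self_pair_rejected(self, rng):
        sm, part = make_scores(rng.random((10, 1)), ["a"] * 10)
        with pytest.raises(ValueError):
            pair_test(sm, part, "a", "a")


class TestCallSignificance:
    def test_null_pair_not_significant(self):
        res = call_significance([PairTestResult("a", "b", 1.0, 1.0, 5, 5)])
        assert res[0].significant is False

    def test_small_p_significant_at_default_cut(self):
        res = call_significance([PairTestResult("a", "b", 0.001, 0.8, 5, 5)])
        assert res[0].significant is True
        assert res[0].padj_i == pytest.approx(0.002)  # BH over 2 p-values

    def test_pooled_bh_matches_shared_routine(self, rng):
        from codemerge.markers import bh_adjust

        results = [PairTestResult(f"c{i}", f"c{i+1}", *rng.random(2), 5, 5)
                   for i in range(20)]
        out = call_significance(results)
        raw = np.array([[r.p_i, r.p_j] for r in results]).ravel()
        adj = bh_adjust(raw)
        got = np.array([[r.padj_i, r.padj_j] for r in out]).ravel()
        np.testing.assert_allclose(got, adj)

    def test_raw_thresholding_when_adjust_off(self):
        cfg = MergeConfig(adjust=False, p_cut=0.05)
        res = call_significance(
            [PairTestResult("a", "b", 0.04, 0.9, 5, 5),
             PairTestResult("a", "c", 0.9, 0.9, 5, 5)], cfg)
        assert res[0].significant is True
        assert res[1].significant is False


class TestMergeStep:
    def _results(self, sig_map):
        return [PairTestResult(a, b, 0.5, 0.5, 10, 10, 0.5, 0.5, s)
                for (a, b), s in sig_map.items()]

    def test_all_significant_partition_unchanged(self):
        part = ClusterPartition(["a", "a", "b", "c"])
        res = self._results({("a", "b"): True, ("a", "c"): True,
                             ("b", "c"): True})
        out = merge_step(part, res)
        assert list(out.labels) == ["a", "a", "b", "c"]

    def test_transitive_merge_via_components(self):
        part = ClusterPartition(["a", "a", "b", "c", "c", "c"])
        res = self._results({("a", "b"): False, ("b", "c"): False})
        out = merge_step(part, res)
        assert len(out.clusters) == 1

    def test_single_merge_among_five(self):
        labels = ["a", "b", "c", "d", "e"]
        part = ClusterPartition(labels)
        sig = {(x, y): True for i, x in enumerate(labels)
               for y in labels[i + 1:]}
        sig[("d", "e")] = False
        out = merge_step(part, self._results(sig))
        assert len(out.clusters) == 4
        # d and e now share a label
        assert out.labels[3] == out.labels[4]

    def test_new_labels_ranked_by_component_size(self):
        part = ClusterPartition(["a"] * 5 + ["b"] * 1 + ["c"] * 3)
        out = merge_step(part, self._results({("b", "c"): False}))
        # component {b,c} has 4 cells, component {a} has 5 -> labels 0 and 1
        assert out.labels[0] == "0"
        assert out.labels[5] == "1"


class TestRunClusterMerge:
    def test_separated_clusters_are_fixed_point(self, two_group_expr):
        expr, part = two_group_expr
        res = run_cluster_merge(expr, part)
        assert res.iterations == 1
        assert list(res.final_partition.labels) == list(part.labels)
        assert res.merge_map == {"A": "A", "B": "B"}

    def test_oversplit_population_merges(self, rng):
        # one homogeneous population randomly split into 3 clusters,
        # plus one genuinely distinct population
        n = 120
        vals = rng.gamma(1.0, 1.0, size=(n + 40, 10)) \
            * (rng.random((n + 40, 10)) < 0.5)
        vals[n:, 0:3] += 9.0
        expr = make_expr(vals)
        labels = list(rng.choice(["h1", "h2", "h3"], size=n)) + ["x"] * 40
        part = ClusterPartition(labels, expr.cell_ids)
        with pytest.warns(UserWarning):
            res = run_cluster_merge(expr, part)
        final = res.final_partition
        # the three homogeneous splits share one final label
        merged_labels = {res.merge_map[c] for c in ("h1", "h2", "h3")}
        assert len(merged_labels) == 1
        assert res.merge_map["x"] not in merged_labels
        assert len(final.clusters) == 2

    def test_coarsening_and_idempotence(self, rng):
        vals = rng.gamma(1.0, 1.0, size=(90, 10)) \
            * (rng.random((90, 10)) < 0.5)
        vals[:30, 0:2] += 9.0
        vals[30:60, 2:4] += 9.0
        vals[60:, 4:6] += 9.0
        expr = make_expr(vals)
        part = ClusterPartition(
            [f"{g}{i % 2}" for g in "abc" for i in range(30)
             ][:90], expr.cell_ids)
        # relabel properly: 6 subclusters, 2 per true group
        labels = np.array([f"{'abc'[i // 30]}{i % 2}" for i in range(90)])
        part = ClusterPartition(labels, expr.cell_ids)
        res = run_cluster_merge(expr, part)
        # coarsening: every input cluster maps to exactly one output label
        for c in part.clusters:
            outs = {res.merge_map[x] for x in [c]}
            assert len(outs) == 1
        frame = pd.DataFrame({"in": part.labels,
                              "out": res.final_partition.labels})
        assert (frame.groupby("in")["out"].nunique() == 1).all()
        # idempotence: re-running on the converged output changes nothing
        res2 = run_cluster_merge(expr, res.final_partition)
        assert list(res2.final_partition.labels) == \
            list(res.final_partition.labels)

    def test_determinism(self, two_group_expr):
        expr, part = two_group_expr
        r1 = run_cluster_merge(expr, part)
        r2 = run_cluster_merge(expr, part)
        assert list(r1.final_partition.labels) == \
            list(r2.final_partition.labels)
        assert r1.pair_tables[0][0].p_i == r2.pair_tables[0][0].p_i

    def test_mnn_full_neighbourhood_matches_all_pairs(self, rng):
        vals = rng.gamma(1.0, 1.0, size=(90, 10)) \
            * (rng.random((90, 10)) < 0.5)
        vals[:30, 0:2] += 9.0
        vals[30:60, 2:4] += 9.0
        vals[60:, 4:6] += 9.0
        expr = make_expr(vals)
        labels = np.array([f"{'abc'[i // 30]}{i % 2}" for i in range(90)])
        part = ClusterPartition(labels, expr.cell_ids)
        res_all = run_cluster_merge(expr, part,
                                    merge_config=MergeConfig())
        res_mnn = run_cluster_merge(
            expr, part,
            merge_config=MergeConfig(pair_selection="mnn",
                                     mnn_neighbours=len(part.clusters) - 1))
        assert list(res_all.final_partition.labels) == \
            list(res_mnn.final_partition.labels)

    def test_singleton_premerged_with_warning(self, two_group_expr):
        expr, part = two_group_expr
        labels = part.labels.copy()
        labels[0] = "solo"
        part = ClusterPartition(labels, part.cell_ids)
        with pytest.warns(UserWarning, match="singleton"):
            res = run_cluster_merge(expr, part)
        assert "solo" in res.merge_map
        assert res.merge_map["solo"] in ("A", "B")

    def test_single_cluster_input_rejected(self, random_expr):
        part = ClusterPartition(["a"] * 50, random_expr.cell_ids)
        with pytest.raises(ValueError):
            run_cluster_merge(random_expr, part)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MergeConfig(p_cut=0.0)
        with pytest.raises(ValueError):
            MergeConfig(k=1)
        with pytest.raises(ValueError):
            MergeConfig(summarization="median")
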
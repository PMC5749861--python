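import numpy as np
import pytest

from lrsslmda.core_io import AssociationMatrix, NameIndex, SimilarityMatrix
from lrsslmda.feature_extraction import (
    extract_features,
    graph_theoretical_profile,
    minmax_scale_features,
    statistical_profile,
    unweighted_graph,
)


def sim_from(values):
    values = np.asarray(values, dtype=float)
    idx = NameIndex.from_names(f"e{i}" for i in range(values.shape[0]))
    return SimilarityMatrix.fully_defined(values, idx)


def assoc_for(sim, n_other=3, pattern=None):
    n = len(sim.index)
    values = np.zeros((n, n_other)) if pattern is None else np.asarray(pattern, float)
    return AssociationMatrix(
        values, sim.index, NameIndex.from_names(f"d{j}" for j in range(values.shape[1]))
    )


class TestStatisticalProfile:
    def test_hand_computed_row_statistics(self):
        # entity 0's off-diagonal similarity row is (0.5, 0.3, 1.0)
        vals = np.eye(4)
        vals[0, 1] = vals[1, 0] = 0.5
        vals[0, 2] = vals[2, 0] = 0.3
        vals[0, 3] = vals[3, 0] = 1.0
        sim = sim_from(vals)
        fm = statistical_profile(sim, assoc_for(sim), "mirna")
        row = dict(zip(fm.feature_names, fm.values[:, 0]))
        assert row["min.sim"] == pytest.approx(0.3)
        assert row["max.sim"] == pytest.approx(1.0)
        assert row["median.sim"] == pytest.approx(0.5)
        assert row["ave.sim"] == pytest.approx(0.6)
        # linear-interpolation quartiles of (0.3, 0.5, 1.0)
        assert row["first.q.sim"] == pytest.approx(0.4)
        assert row["third.q.sim"] == pytest.approx(0.75)
        # histogram: one item each in bins 4, 6 and 10
        hist = [row[f"hist.sim.{b}"] for b in range(1, 11)]
        expected = np.zeros(10)
        expected[[3, 5, 9]] = 1 / 3
        assert hist == pytest.approx(expected.tolist())

    def test_n_obs_counts_associations(self):
        sim = sim_from(np.eye(3) * 0.0 + 0.5 + 0.5 * np.eye(3))
        pattern = [[1, 0, 1], [0, 0, 0], [1, 1, 1]]
        fm = statistical_profile(sim, assoc_for(sim, pattern=pattern), "mirna")
        assert fm.values[0].tolist() == [2.0, 0.0, 3.0]

    def test_constant_row_has_zero_sd_and_equal_quartiles(self):
        sim = sim_from(np.full((4, 4), 0.4) + 0.6 * np.eye(4))
        fm = statistical_profile(sim, assoc_for(sim), "mirna")
        row = dict(zip(fm.feature_names, fm.values[:, 0]))
        assert row["s.d.sim"] == pytest.approx(0.0, abs=1e-15)
        assert row["first.q.sim"] == row["median.sim"] == row["third.q.sim"] == 0.4

    def test_histogram_rows_sum_to_one(self, rng):
        vals = rng.random((9, 9))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        fm = statistical_profile(sim_from(vals), assoc_for(sim_from(vals)), "mirna")
        hist = fm.values[8:18]
        assert np.allclose(hist.sum(axis=0), 1.0, atol=1e-12)

    def test_single_entity_rejected(self):
        sim = sim_from([[1.0]])
        with pytest.raises(ValueError):
            statistical_profile(sim, assoc_for(sim), "mirna")


class TestUnweightedGraph:
    def test_constant_matrix_has_no_edges(self):
        adj = unweighted_graph(sim_from(np.full((4, 4), 0.5)))
        assert not adj.any()

    def test_identity_like_matrix_has_no_edges(self):
        # diag 1, off-diag 0, n=3: global mean 1/3 > 0 off-diagonal values
        adj = unweighted_graph(sim_from(np.eye(3)))
        assert not adj.any()

    def test_single_pair_above_mean(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.9
        adj = unweighted_graph(sim_from(vals))
        # brute-force threshold: mean = (3 + 1.8)/9 ≈ 0.533; only (0,1) above
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = 1.0
        assert np.array_equal(adj, expected)


class TestGraphTheoreticalProfile:
    def _profiles(self, vals, k=10):
        sim = sim_from(vals)
        stat = statistical_profile(sim, assoc_for(sim), "mirna")
        return graph_theoretical_profile(sim, stat, k=k), sim

    def test_star_graph_betweenness(self):
        # similarity graph = star with center 0: betweenness(center) = 3
        # (unnormalized pair count for the 3 leaf pairs), leaves 0
        vals = np.full((4, 4), 0.1)
        np.fill_diagonal(vals, 1.0)
        vals[0, 1:] = vals[1:, 0] = 0.8
        fm, _ = self._profiles(vals)
        row = dict(zip(fm.feature_names, fm.values[:, 0]))
        assert row["bt"] == pytest.approx(3.0)
        assert fm.values[list(fm.feature_names).index("bt"), 1:].tolist() == [0, 0, 0]

    def test_complete_component_betweenness_zero_pagerank_uniform(self):
        # entities 0..3 form a K4 above the global mean; entity 4 is far
        # from everything, dragging the mean down without joining the clique
        vals = np.full((5, 5), 0.05)
        np.fill_diagonal(vals, 1.0)
        vals[:4, :4] = 0.9
        np.fill_diagonal(vals, 1.0)
        fm, _ = self._profiles(vals)
        names = list(fm.feature_names)
        bt = fm.values[names.index("bt")]
        pr = fm.values[names.index("pr")]
        assert np.allclose(bt, 0.0)
        assert np.allclose(pr[:4], pr[0])
        assert pr[4] < pr[0]

    def test_isolated_node_features(self):
        vals = np.eye(4)
        vals[1, 2] = vals[2, 1] = 0.9
        vals[1, 3] = vals[3, 1] = 0.9
        vals[2, 3] = vals[3, 2] = 0.9
        fm, _ = self._profiles(vals)
        names = list(fm.feature_names)
        assert fm.values[names.index("num.nb"), 0] == 0.0
        assert fm.values[names.index("bt"), 0] == 0.0
        pr = fm.values[names.index("pr")]
        assert pr[0] == pytest.approx(pr.min())

    def test_k_sim_zero_padding(self):
        vals = np.eye(3)
        vals[0, 1] = vals[1, 0] = 0.6
        vals[0, 2] = vals[2, 0] = 0.2
        fm, _ = self._profiles(vals, k=10)
        names = list(fm.feature_names)
        ksim = [fm.values[names.index(f"k.sim.{j}"), 0] for j in range(1, 11)]
        assert ksim[:2] == pytest.approx([0.6, 0.2])
        assert ksim[2:] == [0.0] * 8

    def test_weighted_equals_unweighted_for_equal_similarities(self, rng):
        vals = np.full((6, 6), 0.5)
        np.fill_diagonal(vals, 1.0)
        sim = sim_from(vals)
        pattern = (rng.random((6, 4)) < 0.5).astype(float)
        stat = statistical_profile(sim, assoc_for(sim, pattern=pattern), "mirna")
        fm = graph_theoretical_profile(sim, stat, k=3)
        names = list(fm.feature_names)
        ave = fm.values[[names.index(f"k.ave.{f}") for f in stat.feature_names]]
        wave = fm.values[[names.index(f"k.w.ave.{f}") for f in stat.feature_names]]
        assert np.allclose(ave, wave, atol=1e-12)

    def test_feature_count_is_51(self, small_data):
        assoc, fs, _, _ = small_data
        from lrsslmda.pipeline import Dataset, build_integrated_similarities

        sm, _ = build_integrated_similarities(Dataset(assoc, fs))
        x1, x2 = extract_features(sm, assoc, "mirna")
        assert x1.values.shape[0] == 18
        assert x2.values.shape[0] == 51


class TestScalingAndEquivariance:
    def test_minmax_maps_to_unit_interval_and_constants_to_zero(self, rng):
        from lrsslmda.feature_extraction import FeatureMatrix

        vals = rng.random((5, 7)) * 10
        vals[2] = 3.0  # constant feature
        fm = FeatureMatrix(vals, tuple(f"f{i}" for i in range(5)), "mirna", 1)
        scaled = minmax_scale_features(fm).values
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0
        assert np.allclose(scaled[2], 0.0)
        assert scaled[0].min() == 0.0 and scaled[0].max() == 1.0

    def test_permuting_entities_permutes_feature_columns(self, rng):
        n = 7
        vals = rng.random((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        pattern = (rng.random((n, 4)) < 0.4).astype(float)
        perm = rng.permutation(n)

        sim = sim_from(vals)
        a = assoc_for(sim, pattern=pattern)
        x1, x2 = extract_features(sim, a, "mirna", k=3)

        pvals = vals[np.ix_(perm, perm)]
        idx = NameIndex.from_names(f"e{i}" for i in perm)
        psim = SimilarityMatrix.fully_defined(pvals, idx)
        pa = AssociationMatrix(pattern[perm], idx, a.diseases)
        px1, px2 = extract_features(psim, pa, "mirna", k=3)

        assert np.allclose(px1.values, x1.values[:, perm], atol=1e-12)
        assert np.allclose(px2.values, x2.values[:, perm], atol=1e-9)
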
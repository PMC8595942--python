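"""Dispersion estimation, NB Wald testing, BH adjustment and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from piezoreg.de_test import (
    NBDEModel,
    bh_adjust,
    call_deg,
    estimate_dispersion,
    zscore_cluster,
)
from piezoreg.expression_norm import NormalizedMatrix, rle_size_factors
from piezoreg.synthetic_data import SimulationConfig, generate_counts

from conftest import make_count_matrix


def unit_factors(matrix):
    return pd.Series(1.0, index=matrix.counts.columns)


class TestDispersion:
    def test_poisson_data_gives_near_zero_dispersion(self, rng):
        counts = rng.poisson(rng.uniform(100, 2000, size=2000)[:, None], size=(2000, 6))
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        est = estimate_dispersion(m, unit_factors(m))
        assert est.alpha.median() <= 0.05

    def test_nb_dispersion_recovered(self):
        cfg = SimulationConfig(seed=21, n_genes=2000, dispersion=0.1, de_fraction=0.0)
        m, _ = generate_counts(cfg, [f"g{i}" for i in range(2000)])
        est = estimate_dispersion(m, rle_size_factors(m))
        assert 0.05 <= est.alpha.median() <= 0.2

    def test_constant_gene_has_zero_genewise_estimate(self):
        counts = np.vstack([np.full(6, 50), np.full(6, 7)])
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        est = estimate_dispersion(m, unit_factors(m))
        assert (est.genewise == 0).all()
        # final estimates respect the floor
        assert (est.alpha >= 1e-8).all()

    def test_single_replicate_condition_rejected(self):
        m = make_count_matrix([[1, 2, 3]], ["a", "a", "b"])
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(m, unit_factors(m))


class TestWald:
    def test_all_zero_gene_is_null(self, rng):
        counts = rng.poisson(100, size=(20, 6))
        counts[0] = 0
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        res = NBDEModel(m, ("a", "b"), unit_factors(m)).fit()
        assert res.frame.loc["g0", "log2fc"] == 0.0
        assert res.frame.loc["g0", "p_value"] == 1.0

    def test_swapping_conditions_negates_log2fc_keeps_p(self, rng):
        counts = rng.poisson(rng.uniform(20, 500, size=(40, 1)), size=(40, 6))
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        sf = unit_factors(m)
        disp = estimate_dispersion(m, sf)
        ab = NBDEModel(m, ("a", "b"), sf, disp).fit()
        ba = NBDEModel(m, ("b", "a"), sf, disp).fit()
        assert np.allclose(ab.frame["log2fc"], -ba.frame["log2fc"])
        assert np.allclose(ab.frame["p_value"], ba.frame["p_value"])

    def test_strong_planted_signal_is_called(self, rng):
        counts = rng.poisson(200, size=(100, 6))
        counts[:5, 3:] = rng.poisson(3200, size=(5, 3))  # 16-fold up in b
        m = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        res = NBDEModel(m, ("a", "b"), unit_factors(m)).fit(alpha=0.01)
        sets = res.deg_sets()
        assert {f"g{i}" for i in range(5)} <= sets["over_in_B"]

    def test_summary_mentions_contrast_and_calls(self, count_matrix_3x3):
        res = NBDEModel(count_matrix_3x3, ("0.1MPa", "50MPa")).fit()
        text = res.summary()
        assert "0.1MPa vs 50MPa" in text
        assert "genes tested:    50" in text

    def test_missing_condition_rejected(self, count_matrix_3x3):
        with pytest.raises(ValueError, match="not present"):
            NBDEModel(count_matrix_3x3, ("0.1MPa", "nope"))


class TestBH:
    def test_textbook_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    @pytest.mark.parametrize("p,expected", [([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]), ([0.2], [0.2])])
    def test_degenerate_inputs(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_matches_direct_step_up_oracle(self, rng):
        for _ in range(10):
            p = rng.random(47)
            got = bh_adjust(p)
            # direct step-up formula: adj_(i) = min_{k>=i} p_(k) m / k
            order = np.argsort(p)
            m = len(p)
            scaled = p[order] * m / np.arange(1, m + 1)
            adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            assert np.allclose(got, expected)
            # monotone: adjustment preserves p-value order
            assert (np.diff(got[order]) >= -1e-12).all()
            assert (got >= p - 1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDeg:
    def test_empty_results(self):
        assert call_deg([]) == {"over_in_A": set(), "over_in_B": set()}

    def test_single_significant_gene(self):
        frame = pd.DataFrame(
            {"p_adj": [0.005], "log2fc": [1.2]}, index=["g"]
        )
        assert call_deg(frame)["over_in_B"] == {"g"}

    def test_matches_brute_force_filter(self, rng):
        n = 200
        frame = pd.DataFrame(
            {"p_adj": rng.random(n), "log2fc": rng.normal(0, 2, n)},
            index=[f"g{i}" for i in range(n)],
        )
        sets = call_deg(frame, alpha=0.1)
        for i in range(n):
            sig = frame["p_adj"].iloc[i] < 0.1
            lfc = frame["log2fc"].iloc[i]
            assert (f"g{i}" in sets["over_in_B"]) == (sig and lfc > 0)
            assert (f"g{i}" in sets["over_in_A"]) == (sig and lfc < 0)


def brute_force_average_linkage(points):
    """O(n^3) agglomeration returning sorted merge heights."""
    clusters = {i: [i] for i in range(len(points))}
    dist = squareform(pdist(points))
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a < b:
                    d = np.mean(
                        [dist[i, j] for i in clusters[a] for j in clusters[b]]
                    )
                    if best is None or d < best[0]:
                        best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(heights)


class TestZscoreCluster:
    @staticmethod
    def normalized(values, samples):
        return NormalizedMatrix(
            values=pd.DataFrame(
                values, index=[f"g{i}" for i in range(len(values))], columns=samples
            ),
            kind="tpm",
        )

    def test_zscores_have_mean_zero_sd_one(self, rng):
        norm = self.normalized(rng.random((30, 6)) * 100, list("abcdef"))
        clust = zscore_cluster(norm)
        z = clust.zscores.to_numpy()
        assert np.allclose(z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(z.std(axis=1), 1)

    def test_constant_genes_dropped(self, rng):
        values = rng.random((10, 4)) * 10
        values[3] = 5.0
        clust = zscore_cluster(self.normalized(values, list("abcd")))
        assert "g3" not in clust.zscores.index

    def test_identical_samples_merge_at_height_zero(self, rng):
        col = rng.random(20)
        values = np.column_stack([col, col, col * 3])
        clust = zscore_cluster(self.normalized(values, ["s1", "s2", "s3"]))
        assert clust.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_replicates_cluster_by_condition(self):
        """Three simulated conditions with distinct means: the 3-cluster cut
        must match the design exactly (adjusted Rand index 1)."""
        from scipy.cluster.hierarchy import fcluster
        from sklearn.metrics import adjusted_rand_score

        cfg = SimulationConfig(seed=31, n_genes=500, de_fraction=0.0)
        rngl = np.random.default_rng(31)
        ids = [f"g{i}" for i in range(500)]
        planted = []
        for i in range(150):  # condition-specific signatures
            cond = cfg.conditions[i % 3]
            planted.append((ids[i], cond, 2.0))
        m, _ = generate_counts(cfg, ids, planted_de=planted)
        norm = NormalizedMatrix(values=m.counts / rle_size_factors(m), kind="tpm")
        clust = zscore_cluster(norm)
        labels = fcluster(clust.linkage_matrix, t=3, criterion="maxclust")
        truth = [s.split("_")[0] for s in clust.zscores.columns]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_heights_match_brute_force_oracle(self, rng):
        values = rng.random((25, 7)) * 50
        norm = self.normalized(values, [f"s{i}" for i in range(7)])
        clust = zscore_cluster(norm)
        expected = brute_force_average_linkage(clust.zscores.to_numpy().T)
        assert np.allclose(np.sort(clust.merge_heights), np.sort(expected))

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError, match="2 samples"):
            zscore_cluster(self.normalized(rng.random((5, 1)), ["a"]))
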
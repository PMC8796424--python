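import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rnanet.coexpression import (
    CoexpressionAnalysis,
    CoexpressionParams,
    ModulePartition,
    adjacency_matrix,
    bicor,
    bicor_matrix,
    detect_modules,
    merge_similar_modules,
    module_eigengenes,
    pick_soft_threshold,
    similarity_matrix,
    tom_plot_data,
    topological_overlap,
)
from rnanet.errors import ValidationError
from rnanet.normalize import compute_cpm, filter_genes, FilterSpec
from rnanet.simulate import simulate_scale_free_similarity


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the topological-overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=1) - 1.0
    omega = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            omega[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return omega


def random_adjacency(rng, n):
    s = rng.uniform(0, 1, (n, n))
    a = ((s + s.T) / 2) ** 3
    np.fill_diagonal(a, 1.0)
    return a


class TestSimilarity:
    def test_affine_and_sign_invariance(self, rng):
        x = rng.normal(size=6)
        expr = pd.DataFrame([x, 2 * x + 1, -x], index=["g1", "g2", "g3"])
        s = similarity_matrix(expr)
        assert s.loc["g1", "g2"] == pytest.approx(1.0)
        assert s.loc["g1", "g3"] == pytest.approx(1.0)

    def test_matches_pairwise_bruteforce(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 6)))
        s = similarity_matrix(expr).to_numpy()
        for i in range(10):
            for j in range(10):
                want = abs(np.corrcoef(expr.iloc[i], expr.iloc[j])[0, 1])
                assert s[i, j] == pytest.approx(want, abs=1e-12)

    def test_zero_variance_gene_named(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 5)), index=["g1", "gflat", "g3"])
        expr.loc["gflat"] = 7.0
        with pytest.raises(ValidationError, match="gflat"):
            similarity_matrix(expr)

    def test_per_gene_rescaling_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 10)))
        scaled = expr.mul(rng.uniform(0.5, 3, 8), axis=0).add(rng.normal(size=8), axis=0)
        assert np.allclose(similarity_matrix(expr), similarity_matrix(scaled))


class TestBicor:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.normal(size=20)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_outlier_robustness(self, rng):
        x = rng.normal(size=20)
        y = x + 0.1 * rng.normal(size=20)
        y_out = y.copy()
        y_out[0] += 50.0  # gross outlier
        clean = np.corrcoef(x[1:], y[1:])[0, 1]
        pearson_with = np.corrcoef(x, y_out)[0, 1]
        assert abs(bicor(x, y_out) - clean) < abs(pearson_with - clean)

    def test_mad_zero_falls_back_to_pearson(self, rng):
        x = np.zeros(10)
        x[0] = 1.0  # median 0, MAD 0
        y = rng.normal(size=10)
        z = (x - x.mean()) / x.std(), (y - y.mean()) / y.std()
        assert bicor(x, y) == pytest.approx(float(z[0] @ z[1] / 10))

    def test_matrix_agrees_with_pairwise(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 15)))
        c = bicor_matrix(expr)
        for i in range(6):
            for j in range(6):
                assert c.iloc[i, j] == pytest.approx(bicor(expr.iloc[i], expr.iloc[j]), abs=1e-12)


class TestSoftThreshold:
    def test_planted_scale_free_reaches_cutoff(self):
        s = simulate_scale_free_similarity(n_genes=300, planted_power=6, seed=0)
        result = pick_soft_threshold(s)
        row = result.table[result.table.power == result.power].iloc[0]
        assert row.r_squared >= 0.85
        assert row.slope < 0

    def test_single_candidate_returned(self):
        s = simulate_scale_free_similarity(n_genes=100, seed=1)
        result = pick_soft_threshold(s, CoexpressionParams(candidate_powers=(5,)))
        assert result.power == 5.0
        assert len(result.table) == 1

    def test_mean_connectivity_strictly_decreasing(self, rng):
        s = rng.uniform(0.05, 0.95, (50, 50))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        result = pick_soft_threshold(pd.DataFrame(s))
        assert (np.diff(result.table.mean_connectivity) < 0).all()

    def test_all_identical_connectivity_degenerate(self):
        s = np.full((30, 30), 0.5)
        np.fill_diagonal(s, 1.0)
        with pytest.raises(ValidationError, match="degenerate"):
            pick_soft_threshold(pd.DataFrame(s))


class TestAdjacency:
    def test_power_one_is_identity(self, rng):
        s = pd.DataFrame(random_adjacency(rng, 10))
        assert np.allclose(adjacency_matrix(s, 1), s)

    def test_arithmetic(self):
        s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        assert adjacency_matrix(s, 6).iloc[0, 1] == pytest.approx(0.015625)

    def test_entries_stay_in_unit_interval(self, rng):
        s = pd.DataFrame(random_adjacency(rng, 15))
        a = adjacency_matrix(s, 8).to_numpy()
        assert (a >= 0).all() and (a <= 1).all()


class TestTopologicalOverlap:
    def test_unweighted_path(self):
        a = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]], index=list("abc"), columns=list("abc")
        )
        omega = topological_overlap(a)
        assert omega.loc["a", "c"] == pytest.approx(0.5)

    def test_isolated_nodes_zero_overlap(self):
        a = np.eye(4)
        omega = topological_overlap(pd.DataFrame(a))
        off = omega.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = random_adjacency(rng, 30)
        got = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert np.abs(got - tom_oracle(a)).max() < 1e-10

    def test_unit_interval_and_saturation(self, rng):
        a = random_adjacency(rng, 25)
        omega = topological_overlap(pd.DataFrame(a)).to_numpy()
        assert (omega >= -1e-12).all() and (omega <= 1 + 1e-12).all()
        ones = np.ones((10, 10))
        assert np.allclose(topological_overlap(pd.DataFrame(ones)), 1.0)


class TestModuleDetection:
    def _block_dissimilarity(self, sizes, within=0.0, between=1.0):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        labels = np.zeros(n, dtype=int)
        for idx, size in enumerate(sizes, start=1):
            d[start : start + size, start : start + size] = within
            labels[start : start + size] = idx
            start += size
        np.fill_diagonal(d, 0.0)
        genes = [f"g{i}" for i in range(n)]
        return pd.DataFrame(d, index=genes, columns=genes), pd.Series(labels, index=genes)

    def test_two_perfect_blocks(self):
        d, truth = self._block_dissimilarity([40, 35])
        partition = detect_modules(d, CoexpressionParams(min_module_size=30))
        assert len(partition.labels) == 2
        assert adjusted_rand_score(truth, partition.assignment) == 1.0
        # label 1 is the largest module
        assert partition.sizes.loc[1] == 40

    def test_uniform_dissimilarity_deterministic(self):
        n = 40
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        frame = pd.DataFrame(d)
        first = detect_modules(frame, CoexpressionParams(min_module_size=5))
        second = detect_modules(frame, CoexpressionParams(min_module_size=5))
        pd.testing.assert_series_equal(first.assignment, second.assignment)

    def test_small_clusters_unassigned(self):
        d, _ = self._block_dissimilarity([40, 10])
        partition = detect_modules(d, CoexpressionParams(min_module_size=30))
        assert partition.labels == [1]
        assert (partition.assignment == 0).sum() == 10

    def test_gene_order_invariance(self, rng):
        d, truth = self._block_dissimilarity([35, 30])
        perm = rng.permutation(d.index)
        shuffled = detect_modules(d.loc[perm, perm], CoexpressionParams(min_module_size=30))
        assert adjusted_rand_score(truth.loc[perm], shuffled.assignment) == 1.0


class TestEigengenes:
    def _partition(self, expr, labels):
        return ModulePartition(assignment=pd.Series(labels, index=expr.index))

    def test_identical_profiles_variance_one(self, rng):
        profile = rng.normal(size=8)
        expr = pd.DataFrame([profile] * 5, index=[f"g{i}" for i in range(5)])
        eig = module_eigengenes(expr, self._partition(expr, [1] * 5))
        assert eig.variance_explained.loc[1] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        cor = np.corrcoef(eig.eigengenes["ME1"], z)[0, 1]
        assert abs(cor) == pytest.approx(1.0)
        assert cor > 0  # sign convention: aligned with the mean profile

    def test_two_orthogonal_profiles_half_variance(self):
        expr = pd.DataFrame(
            [[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]], index=["g1", "g2"]
        )
        eig = module_eigengenes(expr, self._partition(expr, [1, 1]))
        assert eig.variance_explained.loc[1] == pytest.approx(0.5)

    def test_matches_spectral_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 10)), index=[f"g{i}" for i in range(12)])
        eig = module_eigengenes(expr, self._partition(expr, [1] * 12))
        x = expr.to_numpy()
        z = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        evals = np.linalg.eigvalsh(z @ z.T)[::-1]
        assert eig.variance_explained.loc[1] == pytest.approx(evals[0] / evals.sum(), abs=1e-8)

    def test_singleton_module_flagged(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "b", "c"])
        eig = module_eigengenes(expr, self._partition(expr, [1, 2, 2]))
        assert 1 in eig.flagged_singletons
        assert eig.variance_explained.loc[1] == 1.0


class TestModuleMerging:
    def test_identical_eigengene_modules_merge(self, rng):
        profile = rng.normal(size=10)
        noise = 0.01 * rng.normal(size=(20, 10))
        expr = pd.DataFrame(profile + noise, index=[f"g{i}" for i in range(20)])
        partition = ModulePartition(
            assignment=pd.Series([1] * 10 + [2] * 10, index=expr.index)
        )
        eig = module_eigengenes(expr, partition)
        merged, _ = merge_similar_modules(expr, partition, eig, 0.25)
        assert len(merged.labels) == 1

    def test_zero_cut_height_identity(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"g{i}" for i in range(20)])
        partition = ModulePartition(
            assignment=pd.Series([1] * 10 + [2] * 10, index=expr.index)
        )
        eig = module_eigengenes(expr, partition)
        merged, _ = merge_similar_modules(expr, partition, eig, 0.0)
        pd.testing.assert_series_equal(merged.assignment, partition.assignment)

    def test_only_correlated_pair_merges(self, rng):
        # modules 1 and 2 share a latent (cor ~0.9); module 3 independent
        base = rng.normal(size=30)
        m1 = base + 0.1 * rng.normal(size=(8, 30))
        m2 = base + 0.1 * rng.normal(size=(8, 30))
        m3 = rng.normal(size=30) + 0.1 * rng.normal(size=(8, 30))
        expr = pd.DataFrame(np.vstack([m1, m2, m3]), index=[f"g{i}" for i in range(24)])
        partition = ModulePartition(
            assignment=pd.Series([1] * 8 + [2] * 8 + [3] * 8, index=expr.index)
        )
        eig = module_eigengenes(expr, partition)
        e = eig.eigengenes
        assert 1 - abs(np.corrcoef(e["ME1"], e["ME2"])[0, 1]) < 0.25
        merged, _ = merge_similar_modules(expr, partition, eig, 0.25)
        assert len(merged.labels) == 2
        merged_label_of = merged.assignment
        assert merged_label_of.iloc[0] == merged_label_of.iloc[8]  # 1 and 2 together
        assert merged_label_of.iloc[0] != merged_label_of.iloc[16]


class TestTomPlotData:
    def test_block_structure_contiguous(self):
        helper = TestModuleDetection()
        d, truth = helper._block_dissimilarity([35, 30])
        partition = detect_modules(d, CoexpressionParams(min_module_size=30))
        ordered, order, band = tom_plot_data(d, partition)
        assert sorted(order) == sorted(d.index)
        values = band.to_numpy()
        changes = (values[1:] != values[:-1]).sum()
        assert changes == 1  # modules contiguous in leaf order
        within = ordered.iloc[:35, :35].to_numpy()
        between = ordered.iloc[:35, 35:].to_numpy()
        assert within.mean() < between.mean()

    def test_symmetry_under_permutation(self, rng):
        helper = TestModuleDetection()
        d, _ = helper._block_dissimilarity([35, 30])
        partition = detect_modules(d, CoexpressionParams(min_module_size=30))
        ordered, _, _ = tom_plot_data(d, partition)
        assert np.allclose(ordered, ordered.T)


class TestFitPipeline:
    def test_planted_modules_recovered_small(self, small_data):
        expr, _, truth = small_data
        kept, _, _ = filter_genes(expr, FilterSpec())
        log_cpm = compute_cpm(kept).log_cpm
        fit = CoexpressionAnalysis(
            log_cpm, CoexpressionParams(min_module_size=20)
        ).fit(power=6)
        planted = truth.module_labels[truth.module_labels > 0]
        common = planted.index.intersection(fit.partition.assignment.index)
        ari = adjusted_rand_score(planted.loc[common], fit.partition.assignment.loc[common])
        assert ari >= 0.9

    def test_summary_table_shape(self, small_data):
        expr, _, _ = small_data
        kept, _, _ = filter_genes(expr, FilterSpec())
        log_cpm = compute_cpm(kept).log_cpm
        fit = CoexpressionAnalysis(log_cpm, CoexpressionParams(min_module_size=20)).fit(power=6)
        summary = fit.summary()
        assert set(summary.columns) == {"module", "n_genes", "variance_explained", "mean_connectivity"}
        assert summary.attrs["power"] == 6.0
        assert (summary["variance_explained"] <= 1.0).all()
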
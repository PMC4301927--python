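import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nitronet import modules, network, simulate


def naive_complete_linkage(d: np.ndarray) -> list[float]:
    """O(n^3) agglomerative complete-linkage oracle; returns merge heights."""
    clusters = [{i} for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[i] = clusters[i] | clusters[j]
        del clusters[j]
    return heights


def block_dissimilarity(sizes, within=0.1, between=0.9):
    n = sum(sizes)
    d = np.full((n, n), between)
    pos = 0
    for s in sizes:
        d[pos : pos + s, pos : pos + s] = within
        pos += s
    np.fill_diagonal(d, 0.0)
    return d


class TestHierarchicalCluster:
    def test_identical_leaves_merge_at_zero(self):
        d = np.zeros((2, 2))
        dend = modules.hierarchical_cluster(d)
        assert dend.heights[0] == 0.0

    def test_two_block_hand_trace(self):
        d = block_dissimilarity([3, 3])
        dend = modules.hierarchical_cluster(d)
        assert dend.heights[-1] == pytest.approx(0.9)
        np.testing.assert_allclose(dend.heights[:-1], 0.1)

    def test_matches_naive_oracle(self, rng):
        for _ in range(5):
            d = np.round(rng.random((6, 6)), 3)  # rounding avoids tie ambiguity
            d = (d + d.T) / 2.0
            np.fill_diagonal(d, 0.0)
            dend = modules.hierarchical_cluster(d)
            np.testing.assert_allclose(
                sorted(dend.heights), sorted(naive_complete_linkage(d)), atol=1e-12
            )

    def test_rejects_asymmetric(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            modules.hierarchical_cluster(d)


class TestDynamicTreeCut:
    def test_planted_blocks_recovered(self):
        d = block_dissimilarity([50, 50, 50])
        dend = modules.hierarchical_cluster(d)
        labels = modules.dynamic_tree_cut(dend, min_size=30)
        truth = np.repeat([1, 2, 3], 50)
        assert len(set(labels) - {0}) == 3
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_all_identical_single_module(self):
        d = np.zeros((35, 35))
        dend = modules.hierarchical_cluster(d)
        labels = modules.dynamic_tree_cut(dend, min_size=30)
        assert set(labels) == {1}

    def test_undersized_input_unassigned(self):
        d = block_dissimilarity([20])
        dend = modules.hierarchical_cluster(d)
        with pytest.warns(UserWarning):
            labels = modules.dynamic_tree_cut(dend, min_size=30)
        assert set(labels) == {0}

    def test_min_size_above_n_warns(self):
        d = block_dissimilarity([10])
        dend = modules.hierarchical_cluster(d)
        with pytest.warns(UserWarning):
            labels = modules.dynamic_tree_cut(dend, min_size=50)
        assert set(labels) == {0}

    def test_labels_numbered_by_size(self):
        d = block_dissimilarity([60, 40])
        dend = modules.hierarchical_cluster(d)
        labels = modules.dynamic_tree_cut(dend, min_size=30)
        assert (labels[:60] == 1).all() and (labels[60:] == 2).all()


class TestStabilityCheck:
    @staticmethod
    def _detector(d, min_size=30):
        def detect(perm):
            sub = d[np.ix_(perm, perm)]
            dend = modules.hierarchical_cluster(sub)
            labels = modules.dynamic_tree_cut(dend, min_size=min_size)
            out = np.empty_like(labels)
            out[perm] = labels
            return out

        return detect

    def test_deterministic_pipeline_ari_one(self):
        d = block_dissimilarity([40, 40])
        report = modules.stability_check(self._detector(d), n_genes=80)
        assert (report["ari"] == 1.0).all()

    def test_comparison_count(self):
        d = block_dissimilarity([40, 40])
        report = modules.stability_check(self._detector(d), n_genes=80, n_repeats=5)
        assert len(report) == 10

    def test_planted_recovery_under_permutation(self, design8):
        spec = simulate.SyntheticSpec(
            n_genes=150, module_sizes=[50, 50, 50], sample_design=design8, seed=3
        )
        expr, truth = simulate.generate_expression(spec)
        adj = network.compute_adjacency(expr, beta=4)
        d = network.compute_tom(adj).dissimilarity()

        def detect(perm):
            sub = d[np.ix_(perm, perm)]
            dend = modules.hierarchical_cluster(sub)
            labels = modules.dynamic_tree_cut(dend, min_size=30)
            out = np.empty_like(labels)
            out[perm] = labels
            return out

        for seed in range(3):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(150)
            labels = detect(perm)
            assert adjusted_rand_score(truth.module_labels.values, labels) >= 0.9


class TestEigengenes:
    def test_rank_one_module(self, rng):
        profile = rng.standard_normal(8)
        expr = pd.DataFrame(
            np.tile(profile, (5, 1)) * np.array([1, 2, 3, 4, 5])[:, None],
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(8)],
        )
        es = modules.compute_eigengenes(expr, np.ones(5, dtype=int))
        e = es.eigengenes.loc[1].to_numpy()
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert es.explained_variance[1] == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_noiseless_planted_signal_recovered(self, design8):
        spec = simulate.SyntheticSpec(
            n_genes=30, module_sizes=[30], sample_design=design8,
            noise_sd=0.0, seed=4,
        )
        expr, truth = simulate.generate_expression(spec)
        es = modules.compute_eigengenes(expr, truth.module_labels.to_numpy())
        e = es.eigengenes.loc[1].to_numpy()
        r = np.corrcoef(e, truth.signals.loc[0].to_numpy())[0, 1]
        assert abs(r) >= 0.999

    def test_sign_convention(self, rng):
        for _ in range(5):
            expr = pd.DataFrame(
                rng.standard_normal((10, 8)),
                index=[f"g{i}" for i in range(10)],
                columns=[f"s{i}" for i in range(8)],
            )
            es = modules.compute_eigengenes(expr, np.ones(10, dtype=int))
            e = es.eigengenes.loc[1].to_numpy()
            cors = [np.corrcoef(row, e)[0, 1] for row in expr.to_numpy()]
            assert np.mean(cors) >= 0

    def test_single_gene_module(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 4.0, 3.0]], index=["g"], columns=list("abcd")
        )
        es = modules.compute_eigengenes(expr, np.array([1]))
        e = es.eigengenes.loc[1].to_numpy()
        std = (expr.iloc[0] - expr.iloc[0].mean()) / expr.iloc[0].std(ddof=0)
        assert abs(np.corrcoef(e, std)[0, 1]) == pytest.approx(1.0)


class TestMergeModules:
    def _two_module_expr(self, rng, cor_between):
        s1 = rng.standard_normal(10)
        s1 = (s1 - s1.mean()) / s1.std()
        e = rng.standard_normal(10)
        e -= (e @ s1) / (s1 @ s1) * s1
        e /= e.std()
        s2 = cor_between * s1 + np.sqrt(1 - cor_between**2) * e
        genes = [s1 + 0.01 * rng.standard_normal(10) for _ in range(10)]
        genes += [s2 + 0.01 * rng.standard_normal(10) for _ in range(10)]
        expr = pd.DataFrame(
            genes, index=[f"g{i}" for i in range(20)], columns=[f"s{i}" for i in range(10)]
        )
        labels = np.repeat([1, 2], 10)
        return expr, labels

    def test_same_signal_modules_merged(self, rng):
        expr, labels = self._two_module_expr(rng, cor_between=0.999)
        merged, es, _ = modules.merge_modules(expr, labels)
        assert len(set(merged) - {0}) == 1

    def test_dissimilar_modules_unchanged(self, rng):
        expr, labels = self._two_module_expr(rng, cor_between=0.3)
        merged, es, _ = modules.merge_modules(expr, labels)
        assert len(set(merged) - {0}) == 2

    def test_monotone_and_idempotent(self, rng):
        expr, labels = self._two_module_expr(rng, cor_between=0.8)
        merged, es, counts = modules.merge_modules(expr, labels)
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        again, _, _ = modules.merge_modules(expr, merged, eigengenes=es)
        assert adjusted_rand_score(merged, again) == 1.0


class TestEndToEndRecovery:
    @pytest.mark.parametrize("n_modules", [3, 6])
    def test_planted_partition_recovery(self, n_modules, design8):
        spec = simulate.SyntheticSpec(
            n_genes=50 * n_modules,
            module_sizes=[50] * n_modules,
            sample_design=design8,
            seed=n_modules,
        )
        expr, truth = simulate.generate_expression(spec)
        adj = network.compute_adjacency(expr, beta=4)
        tom = network.compute_tom(adj)
        _, merged, es = modules.detect_modules(tom.dissimilarity(), expr, min_size=30)
        ari = adjusted_rand_score(truth.module_labels.values, merged)
        assert ari >= 0.9

    def test_eigengene_signal_matching(self, design8):
        spec = simulate.SyntheticSpec(
            n_genes=150, module_sizes=[50, 50, 50], sample_design=design8,
            within_module_cor=0.9, seed=7,
        )
        expr, truth = simulate.generate_expression(spec)
        adj = network.compute_adjacency(expr, beta=4)
        tom = network.compute_tom(adj)
        _, merged, es = modules.detect_modules(tom.dissimilarity(), expr, min_size=30)
        for q in truth.signals.index:
            signal = truth.signals.loc[q].to_numpy()
            best = max(
                abs(np.corrcoef(es.eigengenes.loc[m].to_numpy(), signal)[0, 1])
                for m in es.eigengenes.index
            )
            assert best >= 0.9
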
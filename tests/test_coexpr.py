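"""FPKM normalization, signed adjacency, TOM and module detection."""

import numpy as np
import pandas as pd
import pytest

from pleionet import coexpr, synthio
from pleionet.types import (
    ConfigurationError,
    EmptyResultError,
    ExpressionMatrix,
    GeneModel,
    WeightedAdjacency,
)


def _expr(values: np.ndarray, is_fpkm=True, lengths=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                            columns=[f"s{j}" for j in range(values.shape[1])]),
        is_fpkm=is_fpkm,
        gene_lengths=None if lengths is None else pd.Series(lengths, index=genes),
    )


class TestFpkm:
    def test_formula_and_scaling(self):
        counts = _expr([[10.0], [999_990.0]], is_fpkm=False, lengths=[1000, 1000])
        fpkm = coexpr.fpkm_normalize(counts)
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)
        # doubling the library size halves FPKM
        counts2 = _expr([[10.0], [1_999_990.0]], is_fpkm=False, lengths=[1000, 1000])
        fpkm2 = coexpr.fpkm_normalize(counts2)
        assert fpkm2.values.iloc[0, 0] == pytest.approx(5.0, rel=1e-3)

    def test_zero_count_zero_fpkm(self):
        fpkm = coexpr.fpkm_normalize(
            _expr([[0.0], [100.0]], is_fpkm=False, lengths=[500, 500])
        )
        assert fpkm.values.iloc[0, 0] == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(ConfigurationError):
            coexpr.fpkm_normalize(
                _expr([[1.0], [1.0]], is_fpkm=False, lengths=[0, 100])
            )


class TestFilter:
    def test_boundary_and_planted_low_genes(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 5, size=(100, 10))
        low = rng.choice(100, size=10, replace=False)
        values[low] = 0.05
        values[0] = 0.2  # exactly at threshold: retained
        expr = _expr(values)
        out, n_removed = coexpr.filter_low_expression(expr, min_fpkm=0.2)
        removed = set(expr.values.index) - set(out.values.index)
        expected = {f"g{i}" for i in low if i != 0}
        assert removed == expected
        assert n_removed == len(expected)
        assert "g0" in out.values.index

    def test_all_removed_errors(self):
        with pytest.raises(EmptyResultError):
            coexpr.filter_low_expression(_expr(np.zeros((5, 3))))


class TestAdjacency:
    def test_signed_map_limits(self):
        t = np.linspace(0, 1, 8)
        expr = _expr(np.vstack([t, t, 1 - t, np.full(8, 0.25) + 0.01 * (-1) ** np.arange(8)]))
        adj = coexpr.signed_adjacency(expr, beta=1)
        log = np.log2(expr.values.to_numpy() + 1)
        r01 = np.corrcoef(log[0], log[1])[0, 1]
        assert r01 == pytest.approx(1.0)
        assert adj.weights.iloc[0, 1] == pytest.approx(1.0)
        r02 = np.corrcoef(log[0], log[2])[0, 1]
        assert adj.weights.iloc[0, 2] == pytest.approx((1 + r02) / 2)

    def test_uncorrelated_pair_at_high_power(self):
        rng = np.random.default_rng(1)
        expr = _expr(rng.uniform(1, 3, size=(30, 2000)))
        adj = coexpr.signed_adjacency(expr, beta=12)
        # near-zero correlation -> weight near 0.5 ** 12
        med = np.median(adj.weights.to_numpy()[~np.eye(30, dtype=bool)])
        assert med == pytest.approx(0.5**12, rel=1.5)

    def test_monotone_in_correlation_and_bounded(self):
        rng = np.random.default_rng(2)
        expr = _expr(rng.uniform(0.5, 4, size=(25, 40)))
        adj = coexpr.signed_adjacency(expr, beta=6)
        W = adj.weights.to_numpy()
        assert W.min() >= 0 and W.max() <= 1
        log = np.log2(expr.values.to_numpy() + 1)
        R = np.corrcoef(log)
        iu = np.triu_indices(25, k=1)
        order = np.argsort(R[iu])
        assert (np.diff(W[iu][order]) >= -1e-12).all()


class TestTOM:
    def test_two_node_full_edge(self):
        adj = WeightedAdjacency(
            weights=pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"],
                                 columns=["a", "b"])
        )
        tom = coexpr.compute_tom(adj)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_triangle_hand_value(self):
        W = np.full((3, 3), 0.5)
        np.fill_diagonal(W, 0)
        adj = WeightedAdjacency(weights=pd.DataFrame(W, index=list("abc"),
                                                     columns=list("abc")))
        tom = coexpr.compute_tom(adj)
        # (0.25 + 0.5) / (1 + 1 - 0.5)
        assert tom.loc["a", "b"] == pytest.approx(0.5)

    def test_symmetric_bounded(self, small_genotypes):
        rng = np.random.default_rng(3)
        W = rng.uniform(0, 1, size=(15, 15))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        ids = [f"g{i}" for i in range(15)]
        tom = coexpr.compute_tom(
            WeightedAdjacency(weights=pd.DataFrame(W, index=ids, columns=ids))
        ).to_numpy()
        np.testing.assert_allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


GENES = [GeneModel(gene_id=f"g{i}", chrom="chr1", start=i * 1000 + 1,
                   end=i * 1000 + 500) for i in range(300)]


@pytest.fixture(scope="module")
def planted_expression():
    expr, truth = synthio.simulate_expression(
        GENES, {1: 50, 2: 50, 3: 50}, n_samples=30, within_cor=0.9, seed=3
    )
    return expr, truth


class TestModules:
    def test_soft_threshold_in_grid_and_deterministic(self, planted_expression):
        expr, _ = planted_expression
        beta1, table1 = coexpr.pick_soft_threshold(expr)
        beta2, _ = coexpr.pick_soft_threshold(expr)
        assert 1 <= beta1 <= 20
        assert beta1 == beta2
        assert (table1["fit"] >= 0).all()

    def test_target_fit_zero_returns_first_power(self, planted_expression):
        expr, _ = planted_expression
        beta, _ = coexpr.pick_soft_threshold(expr, target_fit=0.0)
        assert beta == 1

    def test_planted_module_recovery(self, planted_expression):
        from sklearn.metrics import adjusted_rand_score

        expr, truth = planted_expression
        beta, _ = coexpr.pick_soft_threshold(expr)
        adj = coexpr.signed_adjacency(expr, beta)
        tom = coexpr.compute_tom(adj)
        modules, report = coexpr.detect_modules(adj, tom, expr, seed=3)
        planted = [g for g in modules.labels.index if g in truth.module_labels]
        ari = adjusted_rand_score(
            [truth.module_labels[g] for g in planted],
            modules.labels.loc[planted],
        )
        assert ari >= 0.9
        assert report.n_initial_modules == 3

    def test_reallocation_objective_non_decreasing(self, planted_expression):
        expr, _ = planted_expression
        adj = coexpr.signed_adjacency(expr, 9)
        tom = coexpr.compute_tom(adj)
        _, report = coexpr.detect_modules(adj, tom, expr, seed=3)
        for before, after in report.objective_trace:
            assert after >= before - 1e-9

    def test_zero_kmeans_iters_keeps_hierarchical_cut(self, planted_expression):
        expr, _ = planted_expression
        adj = coexpr.signed_adjacency(expr, 9)
        tom = coexpr.compute_tom(adj)
        mods0, rep0 = coexpr.detect_modules(adj, tom, expr, kmeans_iters=0, seed=3)
        assert rep0.rounds == 0
        # labels are exactly the hierarchical clusters (0 = unassigned small)
        assert set(mods0.labels.unique()) <= set(range(0, rep0.n_initial_modules + 1))

    def test_eigengene_tracks_module_mean(self, planted_expression):
        expr, truth = planted_expression
        adj = coexpr.signed_adjacency(expr, 9)
        tom = coexpr.compute_tom(adj)
        mods, _ = coexpr.detect_modules(adj, tom, expr, seed=3)
        log = np.log2(expr.values.to_numpy() + 1)
        for module in mods.modules():
            members = mods.labels.to_numpy() == module
            mean_profile = log[members].mean(axis=0)
            r = np.corrcoef(mods.eigengenes[module], mean_profile)[0, 1]
            assert r > 0.9
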
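"""Null mixture, soft-label LDA, hierarchical EM and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from pleionet import prioritize as pr
from pleionet.types import ConfigurationError, GeneScoreTable, HierarchicalFit


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestNullMixture:
    def test_uniform_grid_drives_pi_to_clamp(self):
        n = 500
        p = _series((np.arange(n) + 0.5) / n)
        fit = pr.fit_null_mixture(p)
        assert fit.pi <= 0.01
        np.testing.assert_allclose(fit.ppa, fit.pi, atol=0.01)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        n = 5000
        truth = rng.random(n) < 0.2
        p = np.clip(np.where(truth, rng.beta(0.1, 1, n), rng.random(n)), 1e-300, 1)
        fit = pr.fit_null_mixture(_series(p))
        assert abs(fit.pi - 0.2) <= 0.05
        assert abs(fit.a - 0.1) <= 0.05

    def test_weighted_beta_mle_closed_form(self):
        # w = 1, p = {e^-1, e^-1}: a = sum(w) / (-sum w ln p) = 2/2 = 1
        a = pr._beta_a_mle(np.ones(2), np.log(np.full(2, np.exp(-1))))
        assert a == pytest.approx(1.0)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(8)
        p = np.clip(np.concatenate([rng.beta(0.2, 1, 300), rng.random(700)]),
                    1e-300, 1)
        fit = pr.fit_null_mixture(_series(p))
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_out_of_domain_p_rejected(self):
        with pytest.raises(ConfigurationError):
            pr.fit_null_mixture(_series(np.linspace(0, 1, 100)))  # contains 0


class TestLDAReduce:
    def test_one_dim_embedding_identity_up_to_scale(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        labels = _series((x > 0).astype(float))
        emb = pd.DataFrame({0: x}, index=labels.index)
        feat = pr.lda_reduce(emb, labels)
        r = np.corrcoef(feat, x)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_separated_clusters_fully_split(self):
        rng = np.random.default_rng(1)
        n = 200
        z = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 2)) + np.outer(z, [8.0, 8.0])  # > 6 sigma margin
        labels = _series(z.astype(float))
        emb = pd.DataFrame(X, index=labels.index)
        feat = pr.lda_reduce(emb, labels)
        assert feat[z == 1].min() > feat[z == 0].max()

    def test_all_equal_labels_error(self):
        emb = pd.DataFrame(np.random.default_rng(2).normal(size=(50, 3)),
                           index=[f"g{i}" for i in range(50)])
        with pytest.raises(ConfigurationError):
            pr.lda_reduce(emb, _series(np.full(50, 0.5)))


class TestAssembleFeatures:
    def test_zero_fill_and_indicator(self):
        red = {"net1": pd.Series({"g0": 1.0, "g1": 3.0})}
        fm = pr.assemble_features(red, ["g0", "g1", "g2"])
        assert fm.features.loc["g2", "net1"] == 0.0
        assert fm.missing.loc["g2", "net1"]
        assert not fm.missing.loc["g0", "net1"]

    def test_columns_are_z_scores(self):
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(2, 5, size=50), index=[f"g{i}" for i in range(50)])
        fm = pr.assemble_features({"n": vals}, list(vals.index))
        assert fm.features["n"].mean() == pytest.approx(0.0, abs=1e-10)
        assert fm.features["n"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(4)
        vals = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        a = pr.assemble_features({"n": vals}, list(vals.index))
        b = pr.assemble_features({"n": vals * 10}, list(vals.index))
        pd.testing.assert_frame_equal(a.features, b.features)


class TestHierarchicalEM:
    def test_zero_features_nests_to_null_mixture(self):
        rng = np.random.default_rng(5)
        p = np.clip(np.concatenate([rng.beta(0.2, 1, 200), rng.random(1800)]),
                    1e-300, 1)
        pv = _series(p)
        fit = pr.em_hierarchical(pv, None)
        null = pr.fit_null_mixture(pv)
        assert fit.a == pytest.approx(null.a, abs=1e-3)
        assert 1 / (1 + np.exp(-fit.b0)) == pytest.approx(null.pi, abs=1e-3)

    def test_ppa_decreasing_in_p_with_constant_features(self):
        rng = np.random.default_rng(6)
        p = np.sort(np.clip(rng.random(500), 1e-12, 1))
        fit = pr.em_hierarchical(_series(p), None)
        ppa = fit.ppa.to_numpy()
        assert (np.diff(ppa) <= 1e-12).all()

    def test_loglik_monotone_and_informative_feature_helps(self):
        rng = np.random.default_rng(0)
        n = 2000
        z = rng.random(n) < 0.1
        p = np.clip(np.where(z, rng.beta(0.2, 1, n), rng.random(n)), 1e-300, 1)
        x = z.astype(float) + rng.normal(0, 1, n)
        pv = _series(p)
        fm = pr.assemble_features({"net": pd.Series(x, index=pv.index)},
                                  list(pv.index))
        fit = pr.em_hierarchical(pv, fm)
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()
        assert fit.b[0] > 0  # the informative feature gets positive weight
        null_fit = pr.em_hierarchical(pv, None)
        assert fit.loglik_trace[-1] >= null_fit.loglik_trace[-1]

    def test_ppa_calibration_monotone_by_decile(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.random(n) < 0.15
        p = np.clip(np.where(z, rng.beta(0.15, 1, n), rng.random(n)), 1e-300, 1)
        fit = pr.em_hierarchical(_series(p), None)
        df = pd.DataFrame({"ppa": fit.ppa.to_numpy(), "z": z})
        df["bin"] = pd.qcut(df["ppa"].rank(method="first"), 10, labels=False)
        rates = df.groupby("bin")["z"].mean()
        # truth fraction should broadly increase with the PPA decile
        assert rates.iloc[-1] > rates.iloc[0]
        assert (np.diff(rates.rolling(2).mean().dropna()) >= -0.05).all()


def _fit_from_ppa(ppa: pd.Series) -> HierarchicalFit:
    return HierarchicalFit(
        a=0.2, b0=-2.0, b=np.zeros(1), ppa=ppa,
        loglik_trace=np.array([-1.0]), converged=True, n_iter=1,
    )


def _scores(pvals: pd.Series) -> GeneScoreTable:
    return GeneScoreTable(
        table=pd.DataFrame({"symbol": "", "chrom": "", "n_snps": 1,
                            "T": 1.0, "p": pvals})
    )


class TestPrioritize:
    def test_top_count_ceiling(self):
        rng = np.random.default_rng(2)
        ppa = _series(rng.random(200))
        pvals = _series(rng.random(200))
        out = pr.prioritize(_fit_from_ppa(ppa), _scores(pvals), top_frac=0.01)
        assert out["prioritized"].sum() == 2

    def test_tie_break_on_gene_p_then_id(self):
        ppa = _series([0.5, 0.5, 0.5, 0.5])
        pvals = pd.Series([0.5, 0.01, 0.01, 0.2], index=ppa.index)
        out = pr.prioritize(_fit_from_ppa(ppa), _scores(pvals), top_frac=0.5)
        top = list(out.index[out["prioritized"]])
        assert top == ["g1", "g2"]  # smallest p first, then id

    def test_significance_flag_requires_alpha(self):
        ppa = _series([0.9, 0.8])
        pvals = pd.Series([0.01, 0.5], index=ppa.index)
        out = pr.prioritize(_fit_from_ppa(ppa), _scores(pvals), top_frac=1.0,
                            alpha=0.05)
        assert bool(out.loc["g0", "significant"])
        assert not bool(out.loc["g1", "significant"])


class TestSharedStats:
    def test_worked_overlap_percentage(self):
        a = {f"x{i}" for i in range(153)}
        b = {f"x{i}" for i in range(115, 264)}  # |b|=149, overlap 38
        out = pr.shared_stats(a, b)
        assert (out["n_a"], out["n_b"], out["n_shared"]) == (153, 149, 38)
        assert out["shared_pct"] == 14.4

    def test_identical_and_disjoint(self):
        s = {"a", "b"}
        assert pr.shared_stats(s, s)["shared_pct"] == 100.0
        assert pr.shared_stats(s, {"c"})["shared_pct"] == 0.0
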
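import numpy as np
import pandas as pd
import pytest

from translatome.cross_species import (
    build_ortholog_expression,
    divergence_compare,
    divergence_shuffle_control,
    fourway_divergence,
    high_loading_genes,
    pairwise_fc_correlation,
    pca_samples,
)
from translatome.ingest import OrthologMap, ValidationError

from conftest import make_counts


def fc_frame(lfc, genes, well=None):
    lfc = np.asarray(lfc, float)
    well = np.ones(len(lfc), bool) if well is None else np.asarray(well)
    return pd.DataFrame({"lfc": lfc, "well_expressed": well}, index=genes)


def four_species_tables(lfc_by_species):
    """fc tables plus a four-way map where group i links gene i of each species."""
    tables, fw = {}, {}
    for sp, lfc in lfc_by_species.items():
        genes = [f"{sp}_g{i}" for i in range(len(lfc))]
        tables[sp] = fc_frame(lfc, genes)
        fw[sp] = genes
    return tables, OrthologMap(fourway=pd.DataFrame(fw))


class TestPairwiseCorrelation:
    def pairs(self, n, a="A", b="B"):
        return pd.DataFrame(
            {"gene_a": [f"{a}_g{i}" for i in range(n)],
             "gene_b": [f"{b}_g{i}" for i in range(n)]}
        )

    def test_identical_vectors(self):
        x = [0.1, 0.5, -1.0, 2.0]
        fa = fc_frame(x, [f"A_g{i}" for i in range(4)])
        fb = fc_frame(x, [f"B_g{i}" for i in range(4)])
        res = pairwise_fc_correlation(fa, fb, self.pairs(4))
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_rank_reversal(self):
        fa = fc_frame([1, 2, 3, 4], [f"A_g{i}" for i in range(4)])
        fb = fc_frame([4, 3, 2, 1], [f"B_g{i}" for i in range(4)])
        res = pairwise_fc_correlation(fa, fb, self.pairs(4))
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula_on_toy(self):
        x = [0.3, -1.2, 2.5, 0.9, -0.4]
        y = [1.1, -0.8, 0.2, 2.0, -1.5]
        fa = fc_frame(x, [f"A_g{i}" for i in range(5)])
        fb = fc_frame(y, [f"B_g{i}" for i in range(5)])
        res = pairwise_fc_correlation(fa, fb, self.pairs(5))
        # Spearman via the classical 1 - 6*sum(d^2)/(n(n^2-1)) on hand ranks
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        d2 = ((rx - ry) ** 2).sum()
        assert res["spearman_rho"] == pytest.approx(1 - 6 * d2 / (5 * 24))

    def test_well_expressed_filter_applied(self):
        fa = fc_frame([1, 2, 3, 9], [f"A_g{i}" for i in range(4)],
                      well=[True, True, True, False])
        fb = fc_frame([1, 2, 3, -9], [f"B_g{i}" for i in range(4)])
        res = pairwise_fc_correlation(fa, fb, self.pairs(4))
        assert res["n_pairs"] == 3
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_too_few_pairs_is_error(self):
        fa = fc_frame([1, 2], ["A_g0", "A_g1"])
        fb = fc_frame([1, 2], ["B_g0", "B_g1"])
        with pytest.raises(ValidationError, match=">=3"):
            pairwise_fc_correlation(fa, fb, self.pairs(2))


class TestFourwayDivergence:
    def test_equal_zscores_give_zero_and_outlier_enumerates(self):
        # species D mirrors A/B/C except one group; verify against a
        # brute-force z-score + six-pair enumeration oracle
        rng = np.random.default_rng(21)
        base = rng.normal(0, 1, 40)
        lfc = {sp: base.copy() for sp in "ABC"}
        d = base.copy()
        d[0] += 5.0
        lfc["D"] = d
        tables, omap = four_species_tables(lfc)
        div = fourway_divergence(tables, omap)

        def z(v):
            return (v - v.mean()) / v.std(ddof=1)

        zs = np.column_stack([z(lfc[sp]) for sp in "ABCD"])
        expected = []
        for g in range(40):
            diffs = [abs(zs[g, i] - zs[g, j]) for i in range(4) for j in range(i + 1, 4)]
            expected.append(np.mean(diffs))
        assert np.allclose(div.to_numpy(), expected)

    def test_six_pair_mean_hand_case(self):
        # z-scores (0, 0, 0, 6) -> (6+6+6+0+0+0)/6 = 3
        from translatome.cross_species import _pair_mean_abs_diff

        z = np.array([[0.0, 0.0, 0.0, 6.0]])
        assert _pair_mean_abs_diff(z)[0] == pytest.approx(3.0)

    def test_per_species_shift_invariance(self):
        rng = np.random.default_rng(22)
        lfc = {sp: rng.normal(0, 1, 30) for sp in "ABCD"}
        tables, omap = four_species_tables(lfc)
        shifted = dict(lfc)
        shifted["B"] = lfc["B"] + 7.5
        tables2, _ = four_species_tables(shifted)
        assert np.allclose(
            fourway_divergence(tables, omap).to_numpy(),
            fourway_divergence(tables2, omap).to_numpy(),
        )

    def test_per_species_scale_invariance(self):
        rng = np.random.default_rng(23)
        lfc = {sp: rng.normal(0, 1, 30) for sp in "ABCD"}
        tables, omap = four_species_tables(lfc)
        scaled = dict(lfc)
        scaled["C"] = lfc["C"] * 4.0
        tables2, _ = four_species_tables(scaled)
        assert np.allclose(
            fourway_divergence(tables, omap).to_numpy(),
            fourway_divergence(tables2, omap).to_numpy(),
        )

    def test_zero_variance_is_error(self):
        lfc = {sp: np.ones(5) for sp in "ABCD"}
        tables, omap = four_species_tables(lfc)
        with pytest.raises(ValidationError, match="variance"):
            fourway_divergence(tables, omap)


class TestShuffleControl:
    def _tables(self, seed, n=400):
        rng = np.random.default_rng(seed)
        lfc_m = {sp: rng.normal(0, 1, n) for sp in "ABCD"}
        lfc_r = {sp: rng.normal(0, 1, n) for sp in "ABCD"}
        tm, omap = four_species_tables(lfc_m)
        tr, _ = four_species_tables(lfc_r)
        return tm, tr, omap

    def test_same_seed_is_deterministic(self):
        tm, tr, omap = self._tables(31)
        p1 = divergence_shuffle_control(tm, tr, omap, n_shuffles=20, seed=5)
        p2 = divergence_shuffle_control(tm, tr, omap, n_shuffles=20, seed=5)
        assert np.array_equal(p1, p2)

    def test_exchangeable_effects_give_uniform_pvalues(self):
        from scipy import stats

        tm, tr, omap = self._tables(32)
        p = divergence_shuffle_control(tm, tr, omap, n_shuffles=200, seed=9)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_permutation_mode_runs(self):
        tm, tr, omap = self._tables(33, n=100)
        p = divergence_shuffle_control(tm, tr, omap, n_shuffles=5, seed=2,
                                       replace=False)
        assert len(p) == 5 and ((p >= 0) & (p <= 1)).all()

    def test_zero_shuffles_is_error(self):
        tm, tr, omap = self._tables(34, n=50)
        with pytest.raises(ValidationError):
            divergence_shuffle_control(tm, tr, omap, n_shuffles=0, seed=1)


class TestPCA:
    def test_matches_eigen_oracle_on_toy(self):
        rng = np.random.default_rng(41)
        expr = pd.DataFrame(rng.normal(0, 1, (3, 4)),
                            index=["g0", "g1", "g2"],
                            columns=["s0", "s1", "s2", "s3"])
        res = pca_samples(expr)
        X = expr.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        k = res.scores.shape[1]
        assert np.allclose(res.variance_fraction, (evals / evals.sum())[:k], atol=1e-10)
        for i in range(k):
            got = res.scores.iloc[:, i].to_numpy()
            want = Xc @ evecs[:, i]
            assert np.allclose(got, want, atol=1e-8) or np.allclose(got, -want, atol=1e-8)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(42)
        expr = pd.DataFrame(rng.normal(size=(20, 8)))
        assert pca_samples(expr).variance_fraction.sum() == pytest.approx(1.0)

    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(43)
        expr = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        expr["w2"] = expr["w"]
        res = pca_samples(expr)
        assert np.allclose(res.scores.loc["w"], res.scores.loc["w2"], atol=1e-8)

    def test_constant_matrix_is_error(self):
        expr = pd.DataFrame(np.ones((5, 4)))
        with pytest.raises(ValidationError, match="constant"):
            pca_samples(expr)


class TestHighLoadingGenes:
    def _pca(self, loadings):
        from translatome.cross_species import PCAResult

        n = len(loadings)
        return PCAResult(
            scores=pd.DataFrame(np.zeros((2, 1)), columns=["PC1"]),
            loadings=pd.DataFrame({"PC1": loadings},
                                  index=[f"g{i}" for i in range(n)]),
            variance_fraction=np.array([1.0]),
        )

    def test_equal_loadings_give_empty_list(self):
        assert high_loading_genes(self._pca([0.5] * 10)) == []

    def test_single_outlier_found(self):
        res = high_loading_genes(self._pca([0.01] * 20 + [0.9]))
        assert res == ["g20"]

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(44)
        pca = self._pca(rng.normal(0, 1, 100))
        assert set(high_loading_genes(pca, k_sd=3)) <= set(high_loading_genes(pca, k_sd=2))

    def test_missing_component_is_error(self):
        with pytest.raises(ValidationError):
            high_loading_genes(self._pca([1.0, 2.0]), component=5)


class TestBuildOrthologExpression:
    def test_stacks_species_blocks(self):
        rng = np.random.default_rng(51)
        cms, fw = {}, {}
        for sp in ("A", "B"):
            genes = [f"{sp}_g{i}" for i in range(6)]
            cms[sp] = make_counts(rng.integers(1, 300, (6, 2)), genes=genes,
                                  samples=[f"{sp}_s0", f"{sp}_s1"])
            fw[sp] = genes[:4]
        omap = OrthologMap(fourway=pd.DataFrame(fw))
        expr = build_ortholog_expression(cms, omap)
        assert expr.shape == (4, 4)
        assert list(expr.columns) == ["A_s0", "A_s1", "B_s0", "B_s1"]
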
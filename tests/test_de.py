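import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from translatome.de import (
    DEConfig,
    bh_fdr,
    estimate_size_factors,
    fold_change_table,
    log2_fold_change,
    nb_exact_pvalue,
    nb_test,
)
from translatome.ingest import ValidationError, align_samples

from conftest import make_aligned, make_counts, make_meta


def brute_force_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios straight from the definition, gene by gene."""
    keep = [g for g in range(counts.shape[0]) if all(counts[g] > 0)]
    factors = []
    for j in range(counts.shape[1]):
        ratios = []
        for g in keep:
            geomean = np.prod([float(c) for c in counts[g]]) ** (1.0 / counts.shape[1])
            ratios.append(counts[g, j] / geomean)
        factors.append(np.median(ratios))
    factors = np.asarray(factors)
    return factors / np.prod(factors) ** (1.0 / len(factors))


class TestSizeFactors:
    def test_identical_columns_are_unity(self):
        cm = make_counts([[5, 5], [9, 9], [2, 2]])
        sf = estimate_size_factors(cm)
        assert np.allclose(sf, 1.0)

    def test_doubled_column_splits_geometrically(self):
        cm = make_counts([[4, 8], [10, 20], [7, 14]])
        sf = estimate_size_factors(cm)
        assert np.allclose(sf.to_numpy(), [2 ** -0.5, 2 ** 0.5])

    def test_matches_brute_force_on_toy(self):
        arr = np.array([[3, 10, 7], [20, 5, 9], [14, 14, 2], [1, 8, 40]])
        cm = make_counts(arr)
        sf = estimate_size_factors(cm)
        assert np.allclose(sf.to_numpy(), brute_force_size_factors(arr), rtol=1e-10)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.integers(1, 500, size=(50, 6)))
        sf = estimate_size_factors(cm)
        assert np.isclose(np.exp(np.log(sf).mean()), 1.0)

    def test_no_all_positive_gene_is_error(self):
        cm = make_counts([[0, 1], [1, 0]])
        with pytest.raises(ValidationError, match="positive"):
            estimate_size_factors(cm)


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        al = make_aligned([[10, 10, 10, 10]] * 3)
        assert np.allclose(log2_fold_change(al), 0.0)

    def test_doubling_gives_one_without_pseudocount(self):
        # flat majority keeps size factors at 1; one gene doubles
        flat = [[50, 50, 50, 50]] * 9
        al = make_aligned(flat + [[10, 10, 20, 20]])
        lfc = log2_fold_change(al, DEConfig(pseudocount=1e-9))
        assert lfc.iloc[-1] == pytest.approx(1.0, abs=1e-6)

    def test_zero_counts_give_zero_lfc_with_pseudocount(self):
        al = make_aligned([[0, 0, 0, 0], [10, 10, 10, 10]])
        lfc = log2_fold_change(al, DEConfig(pseudocount=0.5))
        assert lfc.iloc[0] == 0.0

    def test_missing_condition_is_error(self):
        cm = make_counts(np.ones((3, 4), dtype=int))
        meta = make_meta(cm.sample_ids, conditions=["diapause"] * 4)
        al = align_samples(cm, meta)
        with pytest.raises(ValidationError, match="developing"):
            log2_fold_change(al)

    def test_antisymmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        arr = rng.integers(1, 800, size=(30, 6))
        al_fwd = make_aligned(arr)
        cm = make_counts(arr)
        meta = make_meta(cm.sample_ids,
                         conditions=["developing"] * 3 + ["diapause"] * 3)
        al_rev = align_samples(cm, meta)
        assert np.allclose(log2_fold_change(al_fwd), -log2_fold_change(al_rev))


class TestNBTest:
    def test_flat_gene_has_p_one(self):
        # equal columns -> unit size factors -> identical normalized means
        arr = np.array([[7] * 6, [120] * 6, [33] * 6, [900] * 6])
        al = make_aligned(arr)
        p = nb_test(al)
        assert np.allclose(p, 1.0, atol=1e-9)

    def test_null_type_one_error_calibrated(self):
        # NB counts, equal means, dispersion 0.1, 2000 genes, 3 vs 3
        rng = np.random.default_rng(2024)
        disp, mu = 0.1, 200.0
        r = 1 / disp
        arr = rng.negative_binomial(r, r / (r + mu), size=(2000, 6))
        al = make_aligned(arr)
        p = nb_test(al)
        frac = float((p <= 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_strong_signal_detected(self):
        rng = np.random.default_rng(5)
        null = rng.negative_binomial(20, 20 / (20 + 100), size=(200, 6))
        sig = np.hstack([
            rng.negative_binomial(20, 20 / (20 + 50), size=(20, 3)),
            rng.negative_binomial(20, 20 / (20 + 400), size=(20, 3)),
        ])
        al = make_aligned(np.vstack([null, sig]))
        fc = fold_change_table(al)
        assert fc["de_flag"].iloc[200:].mean() > 0.8
        # de_flag implies well_expressed
        assert not (fc["de_flag"] & ~fc["well_expressed"]).any()

    def test_single_replicate_is_error(self):
        cm = make_counts(np.ones((3, 3), dtype=int))
        meta = make_meta(cm.sample_ids, conditions=["diapause", "diapause", "developing"])
        al = align_samples(cm, meta)
        with pytest.raises(ValidationError, match="replicates"):
            nb_test(al)

    def test_exact_pvalue_matches_enumeration(self):
        # brute-force tail sum over all splits of the conditioned total
        for tot_a, tot_b, disp in [(10, 25, 0.2), (3, 3, 0.5), (0, 12, 0.1)]:
            s_a = s_b = 3.0
            K = tot_a + tot_b
            mu0 = K / (s_a + s_b)
            r = 1 / disp
            probs = np.array([
                stats.nbinom.pmf(a, r, r / (r + mu0 * s_a))
                * stats.nbinom.pmf(K - a, r, r / (r + mu0 * s_b))
                for a in range(K + 1)
            ])
            expected = probs[probs <= probs[tot_a] * (1 + 1e-11)].sum() / probs.sum()
            got = nb_exact_pvalue(tot_a, tot_b, s_a, s_b, disp)
            assert got == pytest.approx(expected, abs=1e-6)

    def test_exact_method_runs_on_small_matrix(self):
        rng = np.random.default_rng(9)
        arr = rng.integers(1, 30, size=(10, 6))
        al = make_aligned(arr)
        p = nb_test(al, method="exact")
        assert ((p >= 0) & (p <= 1)).all()


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up definition: p(i)*m/i, cumulative minimum from the largest."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_computed_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_brute_force_step_up(self, ps):
        p = np.asarray(ps)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)


class TestDepthInvariance:
    def test_scaling_a_column_leaves_lfc_and_p_stable(self):
        rng = np.random.default_rng(11)
        arr = rng.negative_binomial(10, 10 / (10 + 300), size=(400, 6))
        arr = np.maximum(arr, 1)
        scaled = arr.copy()
        scaled[:, 0] *= 4
        cfg = DEConfig(pseudocount=1e-12)
        al_a, al_b = make_aligned(arr), make_aligned(scaled)
        # normalization absorbs the depth change exactly in the fold change
        assert np.allclose(log2_fold_change(al_a, cfg), log2_fold_change(al_b, cfg),
                           atol=1e-9)
        # the shot-noise term retains a weak depth dependence, so p-values
        # agree closely but not to machine precision
        pa, pb = nb_test(al_a, cfg), nb_test(al_b, cfg)
        assert np.allclose(np.log10(pa + 1e-30), np.log10(pb + 1e-30), atol=0.15)
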
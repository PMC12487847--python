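"""Ratio matrices, MIF, per-row OLS, variance shrinkage, moderated t, BH."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isoratio as ir
from .conftest import make_matrix

DATA = Path(__file__).parent / "data"


def two_condition_table(n_per_group, prefix="s"):
    n = 2 * n_per_group
    return pd.DataFrame({
        "sample": [f"{prefix}{i}" for i in range(n)],
        "channel": [str(126 + i) for i in range(n)],
        "condition": ["a"] * n_per_group + ["b"] * n_per_group,
    })


class TestComputeRatioMatrix:
    def test_equal_members_give_zero_row(self):
        glog = make_matrix([[5, 6, 7], [5, 6, 7]])
        pair = ir.IsoformPair("r0", "r1", "paralog")
        ratio = ir.compute_ratio_matrix(glog, [pair])
        np.testing.assert_allclose(ratio.loc["r0|r1"], 0.0)

    def test_twofold_far_above_offset(self):
        """glog(2v) − glog(v) → 1.0 (log2) when v is far above the offset."""
        c = 10.0
        v = np.array([1e5, 1e6, 1e7])
        ratio = ir.glog_transform(2 * v, c) - ir.glog_transform(v, c)
        np.testing.assert_allclose(ratio, 1.0, atol=1e-6)

    def test_missing_member_propagates(self):
        glog = make_matrix([[5, 6, 7], [5, np.nan, 7]])
        ratio = ir.compute_ratio_matrix(glog, [ir.IsoformPair("r0", "r1", "paralog")])
        assert np.isnan(ratio.iloc[0, 1]) and not np.isnan(ratio.iloc[0, 0])

    def test_absent_member_drops_pair_with_warning(self):
        glog = make_matrix([[5, 6, 7]])
        with pytest.warns(UserWarning, match="dropped"):
            ratio = ir.compute_ratio_matrix(
                glog, [ir.IsoformPair("r0", "zz", "paralog")])
        assert ratio.empty


class TestComputeMif:
    def test_equal_abundance_gives_half(self):
        raw = make_matrix([[10, 20], [10, 20]])
        assert ir.compute_mif(raw, ir.IsoformPair("r0", "r1", "paralog")) == \
            pytest.approx(0.5)

    def test_70_30_split(self):
        raw = make_matrix([[70, 140], [30, 60]])
        assert ir.compute_mif(raw, ir.IsoformPair("r0", "r1", "paralog")) == \
            pytest.approx(0.30)

    def test_absent_minor_isoform(self):
        raw = make_matrix([[0, 0], [10, 20]])
        assert ir.compute_mif(raw, ir.IsoformPair("r0", "r1", "paralog")) == \
            pytest.approx(0.0)

    def test_undefined_when_total_zero(self):
        raw = make_matrix([[0, 0], [0, 0]])
        assert np.isnan(ir.compute_mif(raw, ir.IsoformPair("r0", "r1", "paralog")))


class TestFitLinearModel:
    def test_two_group_exact(self, two_group_design):
        Y = make_matrix([[1, 1, 1, 2, 2, 2]])
        fit = ir.fit_linear_model(Y, two_group_design)
        assert fit.coefficients.iloc[0] == pytest.approx(1.0)
        assert fit.sigma2.iloc[0] == pytest.approx(0.0)
        assert fit.df_residual.iloc[0] == 4

    def test_orthogonal_block_leaves_contrast_unchanged(self):
        """Normal-equations oracle on a balanced 8-sample design."""
        rng = np.random.default_rng(8)
        table = pd.DataFrame({
            "sample": [f"s{i}" for i in range(8)],
            "channel": [str(i) for i in range(8)],
            "condition": ["a"] * 4 + ["b"] * 4,
            "block": ["b1", "b2"] * 4,
        })
        y = rng.normal(size=8)
        Y = make_matrix([y])
        d_plain = ir.build_design(table, "~ condition")
        d_block = ir.build_design(table, "~ condition + block")
        fit_plain = ir.fit_linear_model(Y, d_plain)
        fit_block = ir.fit_linear_model(Y, d_block)
        assert fit_block.coefficients.iloc[0] == \
            pytest.approx(fit_plain.coefficients.iloc[0])
        X = d_block.matrix.to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit_block.coefficients.iloc[0] == pytest.approx(beta[1])

    def test_saturated_row_flagged_untestable(self):
        table = two_condition_table(1)
        spec = ir.build_design(table, "~ condition")
        fit = ir.fit_linear_model(make_matrix([[1.0, 2.0]]), spec)
        assert fit.df_residual.iloc[0] == 0
        res = ir.moderated_t(ir.ebayes(fit, min_rows=1))
        assert np.isnan(res["p"].iloc[0])

    def test_rank_deficient_design_names_aliased_column(self):
        table = pd.DataFrame({
            "sample": list("abcdef"),
            "channel": [str(i) for i in range(6)],
            "condition": ["a"] * 3 + ["b"] * 3,
            "copy": ["a"] * 3 + ["b"] * 3,   # aliased with condition
        })
        with pytest.raises(ValueError, match="copy"):
            ir.build_design(table, "~ condition + copy")


class TestSqueezeVariances:
    def test_identical_variances_give_infinite_prior_df(self):
        from scipy.special import digamma
        s2 = np.full(100, 2.5)
        d = np.full(100, 20.0)
        d0, s0_sq, post = ir.squeeze_variances(s2, d)
        assert np.isinf(d0)
        np.testing.assert_allclose(post, s0_sq)
        # closed form: log s0² = log s² − E[log(χ²_d/d)]
        expected = 2.5 * np.exp(np.log(10.0) - digamma(10.0))
        assert s0_sq == pytest.approx(expected, rel=1e-9)

    def test_recovers_prior_from_simulated_variances(self):
        """s² ~ s0² F(d, d0) with d0 = 4, s0² = 1, 5000 rows, d = 8:
        the moment estimator recovers d0 within ±25% and s0² within ±10%."""
        rng = np.random.default_rng(123)
        d0_true, s0_true, d = 4.0, 1.0, 8.0
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        d0, s0_sq, _ = ir.squeeze_variances(s2, np.full(5000, d))
        assert abs(d0 - d0_true) / d0_true < 0.25
        assert abs(s0_sq - s0_true) / s0_true < 0.10

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(5, 200) / 5
        d = np.full(200, 5.0)
        d0, s0_sq, post = ir.squeeze_variances(s2, d)
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_too_few_rows_falls_back_unmoderated(self):
        with pytest.warns(UserWarning, match="unmoderated"):
            d0, s0_sq, post = ir.squeeze_variances(np.ones(5), np.full(5, 4.0))
        assert d0 == 0.0
        np.testing.assert_allclose(post, 1.0)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma
        for y in (0.1, 0.5, 2.0, 10.0, 100.0):
            x = float(polygamma(1, y))
            assert ir.trigamma_inverse(x) == pytest.approx(y, rel=1e-6)


class TestModeratedT:
    def test_zero_contrast_gives_p_one(self, two_group_design):
        Y = make_matrix(np.vstack([np.tile([1, 2, 3, 1, 2, 3], (30, 1))
                                   + np.random.default_rng(0).normal(
                                       0, 0.1, (30, 6))]))
        Y.iloc[0] = [1, 2, 3, 1, 2, 3]  # identical group means, variance > 0
        fit = ir.ebayes(ir.fit_linear_model(Y, two_group_design))
        res = ir.moderated_t(fit)
        assert res["t"].iloc[0] == pytest.approx(0.0)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_unmoderated_limit_equals_classical_t(self, two_group_design):
        """With d0 = 0 the pipeline reproduces the ordinary two-sample
        (pooled-variance) t-test to 1e-10."""
        rng = np.random.default_rng(10)
        Y = make_matrix(rng.normal(size=(10, 6)))
        fit = ir.fit_linear_model(Y, two_group_design)
        fit.df_prior = 0.0
        fit.s2_post = fit.sigma2.copy()
        res = ir.moderated_t(fit)
        ref = stats.ttest_ind(Y.iloc[:, 3:], Y.iloc[:, :3], axis=1,
                              equal_var=True)
        np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p"], ref.pvalue, atol=1e-10)

    def test_matches_limma_reference(self, two_group_design):
        """Frozen reference values computed with limma 3.58.1 lmFit/eBayes
        on the same matrix (synthetic, seeded) agree to 1e-10."""
        rng = np.random.default_rng(42)
        n, k = 30, 6
        true_sd = np.sqrt(0.5 / rng.chisquare(4, n) * 4)
        Y = rng.normal(0, true_sd[:, None], (n, k))
        Y[:10, 3:] += 1.0
        mat = make_matrix(Y)
        fit = ir.ebayes(ir.fit_linear_model(mat, two_group_design))
        res = ir.moderated_t(fit)
        ref = pd.read_csv(DATA / "limma_ebayes_reference.tsv", sep="\t",
                          index_col=0)
        assert fit.df_prior == pytest.approx(61.1991506603, rel=1e-9)
        assert fit.s2_prior == pytest.approx(0.504443117592, rel=1e-9)
        np.testing.assert_allclose(res["t"], ref["t"], atol=1e-10)
        np.testing.assert_allclose(res["p"], ref["p"], atol=1e-10)
        np.testing.assert_allclose(res["logFC"], ref["lfc"], atol=1e-10)


def bh_stepup_bruteforce(p):
    """Direct step-up definition: sort ascending, adj_(i) = min_{j>=i} n p_(j)/j."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(n)
    running = np.inf
    for rank in range(n, 0, -1):
        running = min(running, n * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(ir.bh_adjust(np.array([0.01, 0.02, 0.03])),
                                   [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(ir.bh_adjust(np.array([0.2])), [0.2])
        np.testing.assert_allclose(ir.bh_adjust(np.ones(5)), np.ones(5))

    def test_matches_stepup_bruteforce(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 200))
            np.testing.assert_allclose(ir.bh_adjust(p),
                                       bh_stepup_bruteforce(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ir.bh_adjust(np.array([0.5, 1.5]))


class TestClassifyPairs:
    def _results(self, adj_p, lfc, mif):
        return pd.DataFrame({"adj_p": [adj_p], "logFC": [lfc], "mif": [mif]},
                            index=["x|y"])

    @pytest.mark.parametrize("adj_p, lfc, mif, sig, reason", [
        (0.005, 0.6, 0.10, True, ""),
        (0.005, 0.6, 0.01, False, "mif"),
        (0.02, 0.6, 0.10, False, "fdr"),
        (0.005, 0.3, 0.10, False, "lfc"),
    ])
    def test_threshold_rules(self, adj_p, lfc, mif, sig, reason):
        out = ir.classify_pairs(self._results(adj_p, lfc, mif))
        assert bool(out["significant"].iloc[0]) is sig
        assert out["reason"].iloc[0] == reason


class TestPipelineInvariances:
    def _toy(self):
        rng = np.random.default_rng(12)
        n_pairs = 30
        samples = [f"s{i}" for i in range(10)]
        accs = [f"X{i:02d}{m}" for i in range(n_pairs) for m in "AB"]
        glog = pd.DataFrame(rng.normal(10, 1, (len(accs), 10)),
                            index=accs, columns=samples)
        raw = 2.0 ** glog
        pairs = [ir.IsoformPair(f"X{i:02d}A", f"X{i:02d}B", "paralog")
                 for i in range(n_pairs)]
        table = two_condition_table(5)
        table["sample"] = samples
        design = ir.build_design(table, "~ condition")
        return glog, raw, pairs, design

    def test_self_normalization(self):
        """A per-sample additive glog offset (global loading shift) leaves
        every ratio-test statistic unchanged."""
        glog, raw, pairs, design = self._toy()
        res1 = ir.ratio_test(glog, raw, pairs, design)
        offset = pd.Series(np.arange(10) * 0.37 + 1.0, index=glog.columns)
        res2 = ir.ratio_test(glog + offset, raw, pairs, design)
        for col in ("logFC", "t", "p", "adj_p", "mif"):
            np.testing.assert_allclose(res1[col], res2[col], rtol=1e-9,
                                       atol=1e-12)
        assert (res1["significant"] == res2["significant"]).all()

    def test_antisymmetry_under_orientation_flip(self):
        """Reversing pair orientation negates logFC and t, keeps p and MIF."""
        glog, raw, pairs, design = self._toy()
        res1 = ir.ratio_test(glog, raw, pairs, design)
        # rename so lexicographic order flips: member A ↔ member B
        rename = {}
        for i in range(30):
            rename[f"X{i:02d}A"] = f"X{i:02d}B"
            rename[f"X{i:02d}B"] = f"X{i:02d}A"
        res2 = ir.ratio_test(glog.rename(index=rename), raw.rename(index=rename),
                             pairs, design)
        np.testing.assert_allclose(res1["logFC"], -res2["logFC"], atol=1e-12)
        np.testing.assert_allclose(res1["t"], -res2["t"], atol=1e-10)
        np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-12)
        np.testing.assert_allclose(res1["mif"], res2["mif"], atol=1e-12)


class TestSingleProteinDe:
    def _scenario(self):
        """100 null proteins plus two engineered pairs on 5+5 samples."""
        rng = np.random.default_rng(13)
        samples = [f"s{i}" for i in range(10)]
        cond = np.array([0] * 5 + [1] * 5)
        glog = pd.DataFrame(rng.normal(12, 0.05, (100, 10)),
                            index=[f"N{i:03d}" for i in range(100)],
                            columns=samples)
        # pair 1: opposite +-0.3 shifts (below the 0.5 single-protein cutoff)
        glog.loc["PAIR1A"] = 12 + 0.3 * cond + rng.normal(0, 0.05, 10)
        glog.loc["PAIR1B"] = 12 - 0.3 * cond + rng.normal(0, 0.05, 10)
        # pair 2: both members shift +1 together (ratio cancels)
        glog.loc["PAIR2A"] = 12 + 1.0 * cond + rng.normal(0, 0.05, 10)
        glog.loc["PAIR2B"] = 12 + 1.0 * cond + rng.normal(0, 0.05, 10)
        raw = 2.0 ** glog
        table = two_condition_table(5)
        table["sample"] = samples
        spec = ir.build_design(table, "~ condition")
        pairs = [ir.IsoformPair("PAIR1A", "PAIR1B", "paralog"),
                 ir.IsoformPair("PAIR2A", "PAIR2B", "paralog")]
        return glog, raw, pairs, table, spec

    def test_constant_protein_not_de(self):
        glog, raw, pairs, table, spec = self._scenario()
        de = ir.single_protein_de(glog, spec)
        assert not de.loc["N000", "de"]

    def test_ratio_detects_subthreshold_opposite_shifts(self):
        """Opposite ±0.3 shifts: pair ratio shifts 0.6 and is significant
        while neither member passes single-protein DE."""
        glog, raw, pairs, table, spec = self._scenario()
        de = ir.single_protein_de(glog, spec)
        res = ir.ratio_test(glog, raw, pairs, spec)
        assert res.loc["PAIR1A|PAIR1B", "significant"]
        assert not de.loc["PAIR1A", "de"] and not de.loc["PAIR1B", "de"]
        xtab = ir.cross_tabulate_pair_de(res, de)
        assert xtab.loc["PAIR1A|PAIR1B", "n_members_de"] == 0

    def test_common_shift_cancels_in_ratio(self):
        glog, raw, pairs, table, spec = self._scenario()
        de = ir.single_protein_de(glog, spec)
        res = ir.ratio_test(glog, raw, pairs, spec)
        assert not res.loc["PAIR2A|PAIR2B", "significant"]
        assert de.loc["PAIR2A", "de"] and de.loc["PAIR2B", "de"]
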
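import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import toy_expression
from respmr.errors import ConfigError, DataError
from respmr.response import (ModerationPrior, ResponseMatrix, compute_response,
                             filter_detected_genes, fit_moderation_prior,
                             interindividual_variance_test,
                             pca_covariate_association)
from respmr.response import test_differential_response as diff_test
from respmr.response import test_response_all as response_test
from respmr.simulate import (SimulationConfig, simulate_expression_study,
                             simulate_reference_panel)


def make_resp(delta, groups=None):
    delta = pd.DataFrame(delta)
    delta.columns = [f"I{j}" for j in range(delta.shape[1])]
    delta.index = [f"g{i}" for i in range(delta.shape[0])]
    if groups is None:
        groups = ["A"] * delta.shape[1]
    return ResponseMatrix(delta=delta,
                          groups=pd.Series(groups, index=delta.columns))


class TestDetectionFilter:
    def test_all_detected_keeps_everything(self):
        expr = toy_expression({("a", "SG", 1): [1.0, 2.0], ("a", "HG", 1): [1, 2]},
                              detection_p=0.0)
        assert len(filter_detected_genes(expr).genes) == 2

    def test_none_detected_drops_everything(self):
        expr = toy_expression({("a", "SG", 1): [1.0, 2.0], ("a", "HG", 1): [1, 2]},
                              detection_p=1.0)
        assert len(filter_detected_genes(expr).genes) == 0

    def test_hand_counted_mixed_fixture(self):
        """10 genes, 4 samples; 3 genes detected in <50% of samples."""
        rng = np.random.default_rng(0)
        samples = {(ind, cond, 1): rng.normal(size=10)
                   for ind in ("a", "b") for cond in ("SG", "HG")}
        det = np.zeros((10, 4))
        det[7, :] = [0.5, 0.5, 0.5, 0.001]   # detected in 1/4 samples
        det[8, :] = [0.5, 0.5, 0.5, 0.001]
        det[9, :] = [0.5, 0.5, 0.5, 0.001]
        expr = toy_expression(samples, detection_p=det)
        kept = filter_detected_genes(expr, alpha=0.01, min_fraction=0.5)
        assert len(kept.genes) == 7

    def test_pass_through_without_detection(self):
        expr = toy_expression({("a", "SG", 1): [1.0], ("a", "HG", 1): [2.0]})
        assert filter_detected_genes(expr) is expr

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -1, 2])
    def test_alpha_validated(self, alpha):
        expr = toy_expression({("a", "SG", 1): [1.0], ("a", "HG", 1): [2.0]})
        with pytest.raises(ConfigError):
            filter_detected_genes(expr, alpha=alpha)


class TestComputeResponse:
    def test_identical_conditions_give_zero(self):
        expr = toy_expression({("a", "SG", 1): [3.0, 4.0], ("a", "SG", 2): [3, 4],
                               ("a", "HG", 1): [3.0, 4.0], ("a", "HG", 2): [3, 4]})
        resp = compute_response(expr)
        assert np.allclose(resp.delta.to_numpy(), 0.0)

    def test_hand_arithmetic(self):
        expr = toy_expression({("a", "SG", 1): [10.0], ("a", "SG", 2): [10.2],
                               ("a", "HG", 1): [10.6], ("a", "HG", 2): [10.8]})
        resp = compute_response(expr)
        assert resp.delta.iloc[0, 0] == pytest.approx(0.6)

    def test_replicate_order_irrelevant(self):
        a = toy_expression({("a", "SG", 1): [1.0], ("a", "SG", 2): [2.0],
                            ("a", "HG", 1): [5.0], ("a", "HG", 2): [7.0]})
        b = toy_expression({("a", "SG", 1): [2.0], ("a", "SG", 2): [1.0],
                            ("a", "HG", 1): [7.0], ("a", "HG", 2): [5.0]})
        assert compute_response(a).delta.equals(compute_response(b).delta)

    def test_individual_missing_condition_dropped(self):
        expr = toy_expression({("a", "SG", 1): [1.0], ("a", "HG", 1): [2.0],
                               ("b", "SG", 1): [9.0]})
        resp = compute_response(expr)
        assert list(resp.delta.columns) == ["a"]

    def test_no_complete_individual_is_error(self):
        expr = toy_expression({("a", "SG", 1): [1.0], ("b", "HG", 1): [2.0]})
        with pytest.raises(DataError):
            compute_response(expr)


class TestModerationPrior:
    def test_equal_variances_full_shrinkage(self):
        prior = fit_moderation_prior(np.full(50, 0.37), residual_df=10)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.37)

    def test_recovers_generating_d0(self):
        """Variances from the scaled-inverse-chi2 prior with d0=4, s0^2=1."""
        rng = np.random.default_rng(42)
        d0, df, m = 4.0, 12, 5000
        sigma2 = d0 / rng.chisquare(d0, size=m)          # s0^2 = 1
        s2 = sigma2 * rng.chisquare(df, size=m) / df
        prior = fit_moderation_prior(s2, residual_df=df)
        assert prior.d0 == pytest.approx(4.0, rel=0.2)
        assert prior.s0_sq == pytest.approx(1.0, rel=0.15)

    def test_negative_df_rejected(self):
        with pytest.raises(ConfigError):
            fit_moderation_prior(np.ones(20), residual_df=-1)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(DataError):
            fit_moderation_prior(np.zeros(20), residual_df=5)


class TestResponseAll:
    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        resp = make_resp(rng.normal(size=(10000, 8)))
        res = response_test(resp, prior=ModerationPrior(d0=1e-9, s0_sq=1.0))
        assert 0.04 < (res["pvalue"] < 0.05).mean() < 0.06

    def test_d0_zero_limit_matches_classical_t(self):
        """Oracle: scipy one-sample t-test, gene by gene."""
        rng = np.random.default_rng(2)
        delta = rng.normal(0.1, 1.0, size=(500, 9))
        resp = make_resp(delta)
        res = response_test(resp, prior=ModerationPrior(d0=1e-12, s0_sq=1.0))
        t_ref, p_ref = stats.ttest_1samp(delta, 0.0, axis=1)
        assert np.max(np.abs(res["t"].to_numpy() - t_ref)) < 1e-6
        assert np.max(np.abs(res["pvalue"].to_numpy() - p_ref)) < 1e-6

    def test_d0_inf_closed_form(self):
        rng = np.random.default_rng(3)
        delta = rng.normal(size=(100, 6))
        resp = make_resp(delta)
        res = response_test(resp, prior=ModerationPrior(d0=np.inf, s0_sq=2.0))
        expected = delta.mean(axis=1) * np.sqrt(6) / np.sqrt(2.0)
        assert np.allclose(res["t"].to_numpy(), expected)

    def test_zero_variance_gene_stays_finite(self):
        delta = np.vstack([np.full(6, 0.5), np.random.default_rng(0).normal(size=(20, 6))])
        resp = make_resp(delta)
        res = response_test(resp, prior=ModerationPrior(d0=4.0, s0_sq=0.04))
        assert np.isfinite(res["t"].iloc[0]) and res["t"].iloc[0] > 0

    def test_too_few_individuals(self):
        with pytest.raises(DataError):
            response_test(make_resp(np.zeros((5, 2))))

    def test_bh_monotone(self):
        rng = np.random.default_rng(4)
        resp = make_resp(rng.normal(size=(300, 8)))
        res = response_test(resp).sort_values("pvalue")
        q = res["qvalue"].to_numpy()
        assert (np.diff(q) >= -1e-12).all() and (q <= 1).all()


class TestDifferentialResponse:
    def groups(self):
        return ["A"] * 5 + ["B"] * 5

    def test_identical_groups_null(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(2000, 5))
        delta = np.hstack([base, base + rng.normal(0, 1e-12, size=base.shape)])
        resp = make_resp(delta, groups=self.groups())
        res = diff_test(resp, "A", "B", prior=ModerationPrior(4.0, 1.0))
        assert np.abs(res["effect_log2fc"]).max() < 1e-10

    def test_swap_groups_flips_sign_only(self):
        rng = np.random.default_rng(6)
        resp = make_resp(rng.normal(size=(200, 10)), groups=self.groups())
        ab = diff_test(resp, "A", "B")
        ba = diff_test(resp, "B", "A")
        assert np.allclose(ab["effect_log2fc"], -ba["effect_log2fc"])
        assert np.allclose(ab["pvalue"], ba["pvalue"])

    def test_permuted_labels_uniform_p(self):
        rng = np.random.default_rng(7)
        resp = make_resp(rng.normal(size=(10000, 10)),
                         groups=list(rng.permutation(self.groups())))
        res = diff_test(resp, "A", "B")
        assert stats.kstest(res["pvalue"], "uniform").pvalue > 0.01

    def test_true_diff_genes_rank_high(self):
        """Planted 0.27 genes land in the top quantile of |t| (20 sims)."""
        wins = 0
        for seed in range(20):
            config = SimulationConfig(
                n_genes=100, n_snps=100, n_response_genes=30,
                n_diff_response_genes=12, diff_response_effect=0.27,
                n_panel=60, eqtl_effect_sd=0.0, seed=seed)
            panel = simulate_reference_panel(config)
            expr, truth = simulate_expression_study(config, panel)
            res = diff_test(compute_response(expr), "PDR", "nDR")
            ranks = res["pvalue"].rank()
            true_rank = ranks.loc[truth.diff_response_genes].median()
            null_rank = ranks.drop(truth.diff_response_genes).median()
            wins += true_rank < null_rank
        assert wins >= 19

    def test_paired_mode(self):
        rng = np.random.default_rng(8)
        delta = rng.normal(size=(100, 10))
        resp = make_resp(delta, groups=self.groups())
        pairing = {f"I{j}": f"I{j + 5}" for j in range(5)}
        res = diff_test(resp, "A", "B", pairing=pairing)
        diffs = delta[:, :5] - delta[:, 5:]
        assert np.allclose(res["effect_log2fc"], diffs.mean(axis=1))

    def test_bad_pairing_rejected(self):
        resp = make_resp(np.zeros((20, 10)), groups=self.groups())
        with pytest.raises(DataError):
            diff_test(resp, "A", "B", pairing={"I0": "nope"})

    def test_unknown_label_rejected(self):
        resp = make_resp(np.zeros((20, 10)), groups=self.groups())
        with pytest.raises(DataError):
            diff_test(resp, "A", "C")


class TestInterindividualVariance:
    def _study(self, sd_ind, seed=0):
        # diff effect zero: a group-differential response breaks the
        # exchangeability of between-individual profile pairs
        config = SimulationConfig(
            n_genes=200, n_snps=100, n_response_genes=50,
            n_diff_response_genes=0, diff_response_effect=0.0,
            noise_sd_individual=sd_ind,
            noise_sd_replicate=0.1, n_panel=60, eqtl_effect_sd=0.0, seed=seed)
        panel = simulate_reference_panel(config)
        expr, _ = simulate_expression_study(config, panel)
        return expr

    def test_detects_individual_structure(self):
        hits = 0
        for seed in range(10):
            _, p = interindividual_variance_test(self._study(0.6, seed))
            hits += p < 0.01
        assert hits >= 9

    def test_exchangeable_when_no_individual_noise(self):
        calm = 0
        for seed in range(10):
            _, p = interindividual_variance_test(self._study(0.0, seed))
            calm += p > 0.05
        assert calm >= 7

    def test_single_individual_is_error(self):
        expr = toy_expression({("a", "SG", 1): [1.0, 2], ("a", "SG", 2): [1, 2],
                               ("a", "HG", 1): [2.0, 3], ("a", "HG", 2): [2, 3]})
        with pytest.raises(DataError):
            interindividual_variance_test(expr)


class TestPcaCovariates:
    def test_planted_group_structure_found(self):
        hits = 0
        for seed in range(10):
            config = SimulationConfig(
                n_genes=300, n_snps=100, n_response_genes=150,
                n_diff_response_genes=120, diff_response_effect=1.5,
                noise_sd_individual=0.05, n_panel=60, eqtl_effect_sd=0.0,
                seed=seed)
            panel = simulate_reference_panel(config)
            expr, _ = simulate_expression_study(config, panel)
            resp = compute_response(expr)
            cov = pd.DataFrame({"group": resp.groups == "PDR"},
                               index=resp.delta.columns)
            table = pca_covariate_association(resp, cov)
            p1 = table[(table["pc"] == 1)]["pvalue"].iloc[0]
            hits += p1 < 0.01
        assert hits >= 9

    def test_constant_covariate_skipped(self):
        rng = np.random.default_rng(9)
        resp = make_resp(rng.normal(size=(50, 8)))
        cov = pd.DataFrame({"const": np.ones(8)}, index=resp.delta.columns)
        table = pca_covariate_association(resp, cov)
        assert table.empty

    def test_permuted_covariate_roughly_null(self):
        rng = np.random.default_rng(10)
        rejections, pc1_pvals = 0, []
        n_reps = 150
        for _ in range(n_reps):
            resp = make_resp(rng.normal(size=(60, 12)))
            cov = pd.DataFrame({"x": rng.normal(size=12)},
                               index=resp.delta.columns)
            table = pca_covariate_association(resp, cov, n_components=5)
            pc1_pvals.append(table[table["pc"] == 1]["pvalue"].iloc[0])
            rejections += (table["pvalue"] < 0.05 / 5).any()
        # per-PC p-values are uniform; the Bonferroni familywise rate over
        # 5 (near-orthogonal) PCs stays near the nominal 5%
        assert stats.kstest(pc1_pvals, "uniform").pvalue > 0.01
        assert rejections / n_reps <= 0.12


@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=50))
@settings(max_examples=50, deadline=None)
def test_bh_qvalues_properties(pvals):
    from respmr._stats import bh_qvalues
    q = bh_qvalues(np.array(pvals))
    order = np.argsort(pvals)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert ((0 <= q) & (q <= 1)).all()
    assert (q >= np.array(pvals) - 1e-12).all()
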
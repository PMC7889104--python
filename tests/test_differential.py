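import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from methcord import (SimulationConfig, bh_fdr, call_dmps,
                      call_dmps_paired, estimate_variance_prior,
                      fit_sitewise_model, generate_dataset,
                      mean_paired_delta_beta, moderate_statistics,
                      paired_test_crosscheck)

from conftest import paired_matrix


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min over p_(j) >= p_i of m*p_(j)/rank(j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        q[i] = min(running_min, 1.0)
    return q


class TestBhFdr:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005], [0.005]),
        ([0.02, 0.5, 0.9], [0.06, 0.75, 0.9]),
    ])
    def test_hand_worked_step_up(self, p, expected):
        assert np.allclose(bh_fdr(np.array(p)), expected, atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60),
           st.integers(0, 2**31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_property(self, p, _seed):
        p = np.array(p)
        assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_matches_brute_force_thousand_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_nan_propagates_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="methcord"):
            q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])
        # non-NaN entries adjusted among themselves
        assert np.allclose(q[[0, 2]], brute_force_bh([0.01, 0.5]))


class TestSitewiseFit:
    def test_exact_two_group_fit(self, tiny_sheet):
        # constant within tissue: exact fit, effect = bone - blood, s2 = 0
        m = paired_matrix([[2.0, 2.0, 2.0]], [[1.0, 1.0, 1.0]], tiny_sheet,
                          "mvalue")
        fit = fit_sitewise_model(m, tiny_sheet, include_age=False)
        assert fit.effect[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.s2[0] == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_bone_shift(self, tiny_sheet):
        rng = np.random.default_rng(1)
        bone = rng.normal(size=(10, 3))
        blood = rng.normal(size=(10, 3))
        m1 = paired_matrix(bone, blood, tiny_sheet, "mvalue")
        m2 = paired_matrix(bone + 2.5, blood, tiny_sheet, "mvalue")
        f1 = fit_sitewise_model(m1, tiny_sheet)
        f2 = fit_sitewise_model(m2, tiny_sheet)
        assert np.allclose(f2.effect - f1.effect, 2.5, atol=1e-10)

    def test_null_labels_give_zero_mean_effect(self):
        cfg = SimulationConfig(n_sites=1000, frac_smp=0.0, frac_dmp=0.0,
                               batch_shift=0.0, seed=8)
        data = generate_dataset(cfg)
        fit = fit_sitewise_model(data.mvalues, data.sheet)
        se = cfg.noise_sd * np.sqrt(2.0 / cfg.n_subjects / cfg.n_sites)
        assert abs(fit.effect.mean()) < 4 * se

    def test_parametrization_invariance(self, planted_data):
        """Group-mean and treatment codings give the same contrast; here
        checked against per-site group-mean differences adjusted for age."""
        fit = fit_sitewise_model(planted_data.mvalues, planted_data.sheet,
                                 include_age=False)
        bone, blood = planted_data.sheet.paired_samples()
        direct = (planted_data.mvalues.values[bone].mean(axis=1)
                  - planted_data.mvalues.values[blood].mean(axis=1))
        assert np.allclose(fit.effect, direct.to_numpy(), atol=1e-10)


class TestModeration:
    def make_fit(self, s2, effect=None, df=4.0):
        from methcord import SitewiseFit
        s2 = np.asarray(s2, float)
        eff = np.ones_like(s2) if effect is None else np.asarray(effect, float)
        return SitewiseFit(eff, s2, df, 1.0, pd.Index(range(len(s2))))

    def test_infinite_prior_df_pools_variances(self):
        fit = self.make_fit([1.0, 2.0, 3.0])
        mod = moderate_statistics(fit, d0=np.inf, s02=2.0)
        assert np.allclose(mod.s2_post, 2.0)

    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(2)
        s2 = rng.chisquare(4, 50) / 4
        eff = rng.normal(size=50)
        fit = self.make_fit(s2, eff)
        mod = moderate_statistics(fit, d0=0.0, s02=1.0)
        t_ord = eff / np.sqrt(s2)
        assert np.allclose(mod.t, t_ord, atol=1e-12)
        assert np.allclose(mod.p, 2 * stats.t.sf(np.abs(t_ord), 4), atol=1e-12)

    def test_hyperparameter_recovery(self):
        """s2 ~ s0^2 chi2_d/d with s0^2=1, d=4: the moment-matched prior
        variance lands within 5% and the prior df diverges."""
        rng = np.random.default_rng(3)
        s2 = rng.chisquare(4, 50_000) / 4.0
        d0, s02 = estimate_variance_prior(s2, 4.0)
        assert 0.95 <= s02 <= 1.05
        assert d0 >= 50

    def test_finite_prior_df_recovery(self):
        """With true scaled-F variances the prior df itself is recovered."""
        rng = np.random.default_rng(4)
        d, d0_true, s02_true = 4.0, 8.0, 2.0
        true_var = s02_true * d0_true / rng.chisquare(d0_true, 40_000)
        s2 = true_var * rng.chisquare(d, 40_000) / d
        d0, s02 = estimate_variance_prior(s2, d)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s02 - s02_true) / s02_true < 0.05

    def test_equal_variances_use_infinite_prior(self):
        fit = self.make_fit(np.full(20, 1.7))
        mod = moderate_statistics(fit)
        assert np.isinf(mod.d0)
        assert np.allclose(mod.s2_post, 1.7)


class TestLimmaParity:
    """Independent oracle: Bioconductor limma's lmFit/eBayes on the same
    small matrix must reproduce the hyperparameters and moderated t."""

    R_SCRIPT = """
    suppressMessages(library(limma))
    m <- as.matrix(read.delim("{mvals}", row.names=1, check.names=FALSE))
    sheet <- read.csv("{sheet}")
    sheet <- sheet[match(colnames(m), sheet$sample_id),]
    tissue <- factor(sheet$tissue, levels=c("blood","bone"))
    age <- sheet$age - mean(sheet$age)
    design <- model.matrix(~0 + tissue + age)
    fit <- lmFit(m, design)
    cm <- makeContrasts(tissuebone - tissueblood, levels=design)
    fit2 <- eBayes(contrasts.fit(fit, cm))
    out <- data.frame(effect=fit2$coefficients[,1], t=fit2$t[,1],
                      p=fit2$p.value[,1], d0=fit2$df.prior, s02=fit2$s2.prior)
    write.csv(out, "{out}")
    """

    def test_moderated_t_matches_limma(self, tmp_path):
        cfg = SimulationConfig(n_sites=200, n_subjects=8, batch_shift=0.0,
                               seed=42, make_intensities=False)
        data = generate_dataset(cfg)
        mvals = tmp_path / "mvals.tsv"
        sheet = tmp_path / "sheet.csv"
        out = tmp_path / "r_fit.csv"
        data.mvalues.values.to_csv(mvals, sep="\t")
        data.sheet.table.to_csv(sheet, index=False)
        script = self.R_SCRIPT.format(mvals=mvals, sheet=sheet, out=out)
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        r = pd.read_csv(out, index_col=0)
        fit = fit_sitewise_model(data.mvalues, data.sheet)
        mod = moderate_statistics(fit)
        assert np.abs(fit.effect - r["effect"].to_numpy()).max() < 1e-8
        assert mod.d0 == pytest.approx(r["d0"].iloc[0], rel=1e-5)
        assert mod.s02 == pytest.approx(r["s02"].iloc[0], rel=1e-5)
        assert np.abs(mod.t - r["t"].to_numpy()).max() < 1e-8
        assert np.abs(mod.p - r["p"].to_numpy()).max() < 1e-8


class TestDeltaBetaAndCalls:
    def test_mean_paired_delta_beta_conventions(self, tiny_sheet):
        bone = [[0.8, 0.8, 0.8], [0.5, 0.1, 0.3], [0.4, 0.4, 0.4]]
        blood = [[0.5, 0.5, 0.5], [0.3, 0.3, 0.3], [0.4, 0.4, 0.4]]
        beta = paired_matrix(bone, blood, tiny_sheet, "beta")
        dbeta = mean_paired_delta_beta(beta, tiny_sheet)
        assert dbeta.iloc[0] == pytest.approx(0.3, abs=1e-12)
        # signed mean: (+0.2, -0.2, 0.0) averages to ~0, not 0.133
        assert dbeta.iloc[1] == pytest.approx(0.0, abs=1e-12)
        assert dbeta.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_call_requires_both_steps(self, planted_data, corrected_m):
        table = call_dmps(corrected_m, planted_data.beta, planted_data.sheet)
        called = table[table["is_dmp"]]
        assert (called["q"] < 0.05).all()
        assert (called["delta_beta"] > 0.2).all()
        hypo = table[table["direction"] == "hypo"]
        assert (hypo["effect"] < 0).all()

    def test_monotone_in_thresholds(self, planted_data, corrected_m):
        """Lowering the q threshold or raising the delta-beta threshold can
        only remove calls."""
        loose = call_dmps(corrected_m, planted_data.beta, planted_data.sheet,
                          q_threshold=0.05, dbeta_threshold=0.2)
        tight_q = call_dmps(corrected_m, planted_data.beta, planted_data.sheet,
                            q_threshold=0.01, dbeta_threshold=0.2)
        tight_d = call_dmps(corrected_m, planted_data.beta, planted_data.sheet,
                            q_threshold=0.05, dbeta_threshold=0.3)
        assert set(tight_q.index[tight_q["is_dmp"]]) <= set(loose.index[loose["is_dmp"]])
        assert set(tight_d.index[tight_d["is_dmp"]]) <= set(loose.index[loose["is_dmp"]])

    def test_age_covariate_does_not_change_calls_without_age_effect(
            self, planted_data, corrected_m):
        with_age = call_dmps(corrected_m, planted_data.beta, planted_data.sheet,
                             include_age=True)
        without = call_dmps(corrected_m, planted_data.beta, planted_data.sheet,
                            include_age=False)
        assert set(with_age.index[with_age["is_dmp"]]) == \
            set(without.index[without["is_dmp"]])

    def test_planted_dmp_recovery(self, planted_data, corrected_m):
        from methcord import truth_confusion
        table = call_dmps(corrected_m, planted_data.beta, planted_data.sheet)
        conf = truth_confusion(table["is_dmp"], planted_data.truth, "dmp")
        assert conf["sensitivity"] >= 0.9
        assert conf["fdr"] <= 0.1


class TestPairedCrosscheck:
    def test_constant_differences_give_infinite_t(self, tiny_sheet):
        m = paired_matrix([[2.0, 2.0, 2.0]], [[1.0, 1.0, 1.0]], tiny_sheet,
                          "mvalue")
        out = paired_test_crosscheck(m, tiny_sheet)
        assert np.isinf(out["t_paired"].iloc[0])
        assert out["p"].iloc[0] == 0.0

    def test_symmetric_differences_give_t_zero(self, tiny_sheet):
        bone = [[1.0, 2.0, 3.0]]
        blood = [[2.0, 2.0, 2.0]]  # differences (-1, 0, +1)
        m = paired_matrix(bone, blood, tiny_sheet, "mvalue")
        out = paired_test_crosscheck(m, tiny_sheet)
        assert out["t_paired"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_call_sets_identical_without_age_effects(self, planted_data,
                                                     corrected_m):
        """The paired-t route and the linear-model route call the same DMPs
        on data without age effects."""
        lm = call_dmps(corrected_m, planted_data.beta, planted_data.sheet)
        paired = call_dmps_paired(corrected_m, planted_data.beta,
                                  planted_data.sheet)
        assert set(lm.index[lm["is_dmp"]]) == set(paired.index[paired["is_dmp"]])
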
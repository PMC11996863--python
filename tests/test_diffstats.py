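import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from phosphopipe import diffstats
from phosphopipe.diffstats import (
    LinearFit,
    ModerationParams,
    bh_fdr,
    fit_linear_model,
    fit_moderation,
    moderated_f,
    moderated_t,
    paired_stimulation_ratios,
)


def _design(n, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {"intercept": np.ones(n), "x1": rng.normal(size=n), "x2": rng.normal(size=n)},
        index=[f"s{i}" for i in range(n)],
    )
    return X


class TestRatios:
    def _setup(self):
        design = pd.DataFrame(
            {
                "sample_id": ["c1_b", "c1_i", "c2_b", "c2_i", "c3_b"],
                "cell_line": ["c1", "c1", "c2", "c2", "c3"],
                "phenotype": ["CTL"] * 5,
                "sex": ["M"] * 5,
                "treatment": ["basal", "insulin"] * 2 + ["basal"],
            }
        )
        matrix = pd.DataFrame(
            [[10.0, 12.0, 7.0, 7.0, 5.0]],
            index=["site1"],
            columns=design["sample_id"],
        )
        return matrix, design

    def test_ratio_is_log2_difference(self, caplog):
        matrix, design = self._setup()
        with caplog.at_level("WARNING"):
            ratios = paired_stimulation_ratios(matrix, design)
        assert ratios.loc["site1", "c1"] == 2.0
        assert ratios.loc["site1", "c2"] == 0.0
        assert "c3" not in ratios.columns
        assert any("c3" in r.message for r in caplog.records)


class TestLinearModel:
    def test_intercept_model_gives_mean_and_variance(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"s{i}" for i in range(6)])
        X = pd.DataFrame({"intercept": np.ones(6)}, index=m.columns)
        fit = fit_linear_model(m, X)
        np.testing.assert_allclose(fit.coefficients["intercept"], m.mean(axis=1))
        np.testing.assert_allclose(fit.s2, m.var(axis=1, ddof=1))

    def test_paired_design_recovers_paired_difference(self):
        design = pd.DataFrame(
            {
                "sample_id": ["a_b", "a_i", "b_b", "b_i"],
                "cell_line": ["a", "a", "b", "b"],
                "phenotype": ["CTL"] * 4,
                "sex": ["M"] * 4,
                "treatment": ["basal", "insulin"] * 2,
            }
        )
        X = diffstats.build_design_matrix(design, ["treatment", "cell_line"])
        m = pd.DataFrame([[1.0, 3.0, 2.0, 5.0]], index=["s"], columns=design["sample_id"])
        fit = fit_linear_model(m, X)
        assert fit.coefficients.loc["s", "treatment"] == pytest.approx(2.5)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for trial in range(5):
            X = _design(6, seed=trial)
            Y = pd.DataFrame(rng.normal(size=(10, 6)), columns=X.index)
            fit = fit_linear_model(Y, X)
            Xn = X.to_numpy()
            for g in range(10):
                beta = np.linalg.solve(Xn.T @ Xn, Xn.T @ Y.iloc[g].to_numpy())
                np.testing.assert_allclose(
                    fit.coefficients.iloc[g].to_numpy(), beta, atol=1e-10
                )
                r = Y.iloc[g].to_numpy() - Xn @ beta
                np.testing.assert_allclose(fit.s2.iloc[g], r @ r / 3, atol=1e-10)

    def test_rank_deficient_design_names_collinear_columns(self):
        X = _design(6)
        X["x3"] = X["x1"] * 2
        Y = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 6)), columns=X.index)
        with pytest.raises(ValueError, match="x3"):
            fit_linear_model(Y, X)


class TestModeration:
    def test_identical_variances_give_infinite_d0(self):
        s2 = np.full(50, 0.7)
        params = fit_moderation(s2, df=5)
        assert np.isinf(params.d0)
        expected = np.exp(np.log(0.7) - special.digamma(2.5) + np.log(2.5))
        assert params.s0_2 == pytest.approx(expected)

    def test_recovers_prior_df_from_simulated_variances(self):
        rng = np.random.default_rng(10)
        d0, s0_2, d = 4.0, 0.5, 6
        n = 5000
        # s2 ~ s0^2 * inv-chi2(d0) mixing * chi2_d/d sampling
        true_var = s0_2 * d0 / rng.chisquare(d0, size=n)
        s2 = true_var * rng.chisquare(d, size=n) / d
        params = fit_moderation(s2, df=d)
        assert params.d0 == pytest.approx(d0, rel=0.25)
        assert params.s0_2 == pytest.approx(s0_2, rel=0.25)

    def test_trigamma_inversion_is_exact(self):
        rng = np.random.default_rng(11)
        s2 = rng.chisquare(5, size=200) / 5
        params = fit_moderation(s2, df=5)
        if np.isfinite(params.d0):
            e = np.log(s2) - special.digamma(2.5) + np.log(2.5)
            target = np.var(e, ddof=1) - special.polygamma(1, 2.5)
            assert special.polygamma(1, params.d0 / 2) == pytest.approx(target, abs=1e-8)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError):
            fit_moderation(np.zeros(20), df=4)

    def test_matches_limma_squeezevar(self, tmp_path):
        """Cross-check the empirical-Bayes fit against the R reference."""
        rng = np.random.default_rng(12)
        s2 = 0.4 * rng.chisquare(5, size=300) / 5 * (1 + rng.random(300))
        np.savetxt(tmp_path / "s2.txt", s2)
        script = (
            'x <- scan("%s"); sv <- limma::squeezeVar(x, df=5); '
            'cat(sv$df.prior, sv$var.prior, "\\n")' % (tmp_path / "s2.txt")
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        d0_r, s0_r = map(float, out.stdout.split())
        params = fit_moderation(s2, df=5)
        assert params.d0 == pytest.approx(d0_r, rel=0.05)
        assert params.s0_2 == pytest.approx(s0_r, rel=0.05)


class TestModeratedT:
    def _fit(self, seed=0, n=8, sites=40):
        rng = np.random.default_rng(seed)
        X = _design(n, seed=seed)
        Y = pd.DataFrame(rng.normal(size=(sites, n)), columns=X.index)
        return fit_linear_model(Y, X)

    def test_d0_zero_equals_ordinary_t(self):
        fit = self._fit()
        params = ModerationParams(d0=0.0, s0_2=1.0)
        res = moderated_t(fit, params, "x1")
        c = np.zeros(3)
        c[1] = 1.0
        u = np.sqrt(c @ fit.xtx_inv @ c)
        t_ord = fit.coefficients["x1"].to_numpy() / (u * np.sqrt(fit.s2.to_numpy()))
        np.testing.assert_allclose(res["t"].to_numpy(), t_ord, atol=1e-6)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), fit.df)
        np.testing.assert_allclose(res["p"].to_numpy(), p_ord, atol=1e-6)

    def test_d0_infinite_is_scaled_z(self):
        fit = self._fit(seed=1)
        params = ModerationParams(d0=np.inf, s0_2=2.0)
        res = moderated_t(fit, params, "x1")
        c = np.zeros(3)
        c[1] = 1.0
        u = np.sqrt(c @ fit.xtx_inv @ c)
        z = fit.coefficients["x1"].to_numpy() / (u * np.sqrt(2.0))
        np.testing.assert_allclose(res["t"].to_numpy(), z, atol=1e-6)
        np.testing.assert_allclose(
            res["p"].to_numpy(), 2 * stats.norm.sf(np.abs(z)), atol=1e-6
        )

    def test_moderated_t_interpolates_monotonically_in_d0(self):
        fit = self._fit(seed=2, sites=5)
        site = fit.s2.index[0]
        t_vals = []
        for d0 in [0.0, 1.0, 4.0, 16.0, 1e6]:
            params = ModerationParams(d0=d0, s0_2=1.0) if d0 else ModerationParams(0.0, 1.0)
            t_vals.append(moderated_t(fit, params, "x1").loc[site, "t"])
        diffs = np.diff(t_vals)
        assert (diffs >= -1e-12).all() or (diffs <= 1e-12).all()

    def test_zero_standard_error_rejected(self):
        fit = self._fit()
        with pytest.raises(ValueError):
            moderated_t(fit, ModerationParams(d0=1, s0_2=1), np.zeros(3))


class TestModeratedF:
    def test_single_contrast_is_squared_t(self):
        rng = np.random.default_rng(3)
        X = _design(10, seed=3)
        Y = pd.DataFrame(rng.normal(size=(30, 10)), columns=X.index)
        fit = fit_linear_model(Y, X)
        params = fit_moderation(fit.s2.to_numpy(), fit.df)
        c = np.array([0.0, 1.0, 0.0])
        t_res = moderated_t(fit, params, c)
        f_res = moderated_f(fit, params, c[None, :])
        np.testing.assert_allclose(f_res["F"], t_res["t"] ** 2, atol=1e-10)
        np.testing.assert_allclose(f_res["p"], t_res["p"], atol=1e-10)

    def test_f_statistic_nonnegative(self):
        rng = np.random.default_rng(4)
        X = _design(9, seed=4)
        Y = pd.DataFrame(rng.normal(size=(25, 9)), columns=X.index)
        fit = fit_linear_model(Y, X)
        params = fit_moderation(fit.s2.to_numpy(), fit.df)
        C = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        res = moderated_f(fit, params, C)
        assert (res["F"] >= 0).all()


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_ones_stay_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw_and_permutation_invariant(self, ps, rnd):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        q_perm = bh_fdr([ps[i] for i in perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


def test_run_contrasts_produces_all_canonical_contrasts(default_run):
    diff = default_run["diff"]
    assert set(diff["contrast"].unique()) == set(diffstats.CONTRASTS)
    # FDR >= p within each contrast family
    for _, grp in diff.groupby("contrast"):
        assert (grp["fdr"] >= grp["p"] - 1e-12).all()


def test_power_on_strong_planted_effects(default_run, default_sim):
    """Sites with a true |log2FC| >= 1 in CTL are detected with power > 0.8."""
    ctl = diffstats.contrast_frame(default_run["diff"], "ctl_ins_vs_bas")
    truth = default_sim.truth.sites
    strong = truth.index[truth["ctl_insulin_lfc"].abs() >= 1.0].intersection(ctl.index)
    assert (ctl.loc[strong, "p"] < 0.05).mean() > 0.8
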
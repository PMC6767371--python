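import numpy as np
import pytest

from pseudoipd.lmm_core import (DomainError, LMMParams, LMMSpec, fit_lmm,
                                loglik_from_sufficient_stats, lrt_compare,
                                m2loglik_ipd, model_grid,
                                n_residual_parameters)
from pseudoipd.pseudo_ipd import (PseudoIPD, aggregate_from_ipd,
                                  generate_pseudo_ipd)

from conftest import grid_fit
from test_pseudo_ipd import make_dataset


def random_params(spec, data, rng):
    k = n_residual_parameters(spec.residual, data.m)
    p = 2 if spec.effects == "RR" else data.m + 1
    A = rng.normal(0, 2, (2, 2))
    return LMMParams(
        beta=rng.normal(50, 20, size=p),
        residual_variances=rng.uniform(200, 2000, size=k),
        tau1_sq=rng.uniform(5, 80),
        G=A @ A.T + 10 * np.eye(2),
    )


class TestFitIron:
    def test_ff_free_reml(self, iron_grid_reml):
        fit = grid_fit(iron_grid_reml, "FF", "FREE")
        assert fit.beta1_hat == pytest.approx(-6.91, abs=0.01)
        assert fit.se_beta1 == pytest.approx(2.85, abs=0.01)

    def test_fr_free_reml(self, iron_grid_reml):
        fit = grid_fit(iron_grid_reml, "FR", "FREE")
        assert fit.beta1_hat == pytest.approx(-5.59, abs=0.01)
        assert fit.se_beta1 == pytest.approx(4.41, abs=0.01)
        assert fit.tau1_sq == pytest.approx(45.1, abs=0.1)

    def test_ff_pooled_reml(self, iron_grid_reml):
        fit = grid_fit(iron_grid_reml, "FF", "POOLED")
        assert fit.beta1_hat == pytest.approx(-5.82, abs=0.01)
        assert fit.se_beta1 == pytest.approx(3.15, abs=0.01)

    def test_parameter_counts(self, iron_grid_reml):
        counts = {(r.effects, r.residual): (r.n_fe, r.n_re)
                  for r in iron_grid_reml.itertuples()}
        assert counts[("FF", "FREE")] == (6, 10)
        assert counts[("FR", "FREE")] == (6, 11)
        assert counts[("RR", "FREE")] == (2, 13)
        assert counts[("FF", "POOLED")] == (6, 1)
        assert counts[("RR", "ARM")] == (2, 5)

    def test_aic_identities(self, iron_grid_reml):
        for r in iron_grid_reml.itertuples():
            assert r.aic_ml == pytest.approx(
                r.m2loglik_ml + 2 * (r.n_fe + r.n_re), abs=1e-9)
            assert r.aic_reml == pytest.approx(
                r.m2loglik_reml + 2 * r.n_re, abs=1e-9)

    def test_containment_df(self, iron_grid_reml):
        assert grid_fit(iron_grid_reml, "FR", "FREE").df == 4
        ff = grid_fit(iron_grid_reml, "FF", "FREE")
        assert ff.df == ff.n_obs - 6

    def test_variance_validity(self, iron_grid_reml):
        for r in iron_grid_reml.itertuples():
            fit = r.fit
            assert all(v >= 0 for v in fit.residual_variances.values())
            if fit.spec.effects == "RR":
                assert abs(fit.tau01) <= np.sqrt(
                    fit.tau0_sq * fit.tau1_sq) + 1e-8


class TestFitFolate:
    def test_fr_free_reml(self, folate_fr_free):
        fit = folate_fr_free
        assert fit.beta1_hat == pytest.approx(-3.87, abs=0.015)
        assert fit.se_beta1 == pytest.approx(0.63, abs=0.01)
        assert fit.tau1_sq == pytest.approx(9.81, abs=0.1)


class TestClosedFormOracles:
    def test_single_study_ff_pooled_is_mean_difference(self):
        data = make_dataset([("only", 10.0, 3.0, 14, 12.5, 4.0, 9)])
        pipd = generate_pseudo_ipd(data, method="two_point")
        fit = fit_lmm(pipd, LMMSpec(effects="FF", residual="POOLED",
                                    estimation="ML"), both_likelihoods=False)
        assert fit.beta1_hat == pytest.approx(12.5 - 10.0, abs=1e-10)

    def test_ff_pooled_equals_ols(self, iron_pipd):
        # brute-force least squares with study dummies as the oracle
        df = iron_pipd.to_frame()
        studies = list(dict.fromkeys(df["study_id"]))
        X = np.zeros((len(df), len(studies) + 1))
        for i, sid in enumerate(studies):
            X[(df["study_id"] == sid).to_numpy(), i] = 1.0
        X[:, -1] = df["arm"].to_numpy()
        y = df["y"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = ((y - X @ beta_ols) ** 2).sum()

        fit = fit_lmm(iron_pipd, LMMSpec(effects="FF", residual="POOLED",
                                         estimation="ML"),
                      both_likelihoods=False)
        assert fit.beta1_hat == pytest.approx(beta_ols[-1], rel=1e-10)
        sigma2 = next(iter(fit.residual_variances.values()))
        assert sigma2 == pytest.approx(rss / len(y), rel=1e-8)

    def test_pooled_ff_loglik_matches_direct_summation(self, iron,
                                                       iron_pipd):
        # closed-form Gaussian -2LL at the OLS solution, computed naively
        df = iron_pipd.to_frame()
        studies = list(dict.fromkeys(df["study_id"]))
        X = np.zeros((len(df), len(studies) + 1))
        for i, sid in enumerate(studies):
            X[(df["study_id"] == sid).to_numpy(), i] = 1.0
        X[:, -1] = df["arm"].to_numpy()
        y = df["y"].to_numpy()
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        sigma2 = (resid**2).mean()
        direct = (len(y) * np.log(2 * np.pi * sigma2)
                  + (resid**2).sum() / sigma2)

        spec = LMMSpec(effects="FF", residual="POOLED", estimation="ML")
        params = LMMParams(beta=beta_ols, residual_variances=np.array([sigma2]))
        assert m2loglik_ipd(iron_pipd, spec, params) == pytest.approx(
            direct, rel=1e-12)
        assert loglik_from_sufficient_stats(iron, spec, params) == \
            pytest.approx(direct, rel=1e-12)


class TestSufficientStatOracle:
    @pytest.mark.parametrize("effects", ["FF", "FR", "RR"])
    @pytest.mark.parametrize("residual", ["FREE", "STUDY", "ARM", "POOLED"])
    def test_matches_ipd_path(self, iron, iron_pipd, effects, residual, rng):
        for estimation in ("ML", "REML"):
            spec = LMMSpec(effects=effects, residual=residual,
                           estimation=estimation)
            for _ in range(3):
                params = random_params(spec, iron, rng)
                a = m2loglik_ipd(iron_pipd, spec, params)
                b = loglik_from_sufficient_stats(iron, spec, params)
                assert a == pytest.approx(b, rel=1e-10)

    def test_negative_variance_domain_error(self, iron):
        spec = LMMSpec(effects="FF", residual="POOLED")
        with pytest.raises(DomainError):
            loglik_from_sufficient_stats(
                iron, spec, LMMParams(beta=np.zeros(6),
                                      residual_variances=np.array([-1.0])))

    def test_optimum_agrees_with_fit(self, iron, iron_grid_reml):
        # maximised -2LL via the fit equals the sufficient-stat value at the
        # fitted parameters
        fit = grid_fit(iron_grid_reml, "FR", "FREE")
        rv = np.array([fit.residual_variances[(s.study_id, j)]
                       for s in iron for j in (0, 1)])
        params = LMMParams(beta=None, residual_variances=rv,
                           tau1_sq=fit.tau1_sq)
        spec = LMMSpec(effects="FR", residual="FREE", estimation="REML")
        val = loglik_from_sufficient_stats(iron, spec, params)
        assert val == pytest.approx(fit.m2loglik_reml, abs=1e-6)


class TestSeedInvariance:
    def test_fits_agree_across_seeds_and_methods(self, iron):
        spec = LMMSpec(effects="FR", residual="FREE", estimation="REML")
        fits = []
        for method, seed in [("two_point", None), ("rescale_normal", 1),
                             ("rescale_normal", 2)]:
            pipd = generate_pseudo_ipd(iron, method=method, seed=seed)
            fits.append(fit_lmm(pipd, spec, both_likelihoods=False))
        ref = fits[0]
        for other in fits[1:]:
            assert other.beta1_hat == pytest.approx(ref.beta1_hat, rel=1e-6)
            assert other.se_beta1 == pytest.approx(ref.se_beta1, rel=1e-6)
            assert other.tau1_sq == pytest.approx(ref.tau1_sq, rel=1e-4,
                                                  abs=1e-6)
            assert other.m2loglik_reml == pytest.approx(ref.m2loglik_reml,
                                                        rel=1e-9)


class TestLRT:
    def test_iron_free_vs_study(self, iron_grid_reml):
        full = grid_fit(iron_grid_reml, "FF", "FREE")
        reduced = grid_fit(iron_grid_reml, "FF", "STUDY")
        stat, df, p = lrt_compare(full, reduced)
        assert stat == pytest.approx(13.85, abs=0.05)
        assert df == 5
        assert p == pytest.approx(0.018, abs=0.004)

    def test_self_comparison(self, iron_grid_reml):
        fit = grid_fit(iron_grid_reml, "FF", "FREE")
        stat, df, p = lrt_compare(fit, fit)
        assert stat == 0.0
        assert p == 1.0

    def test_fr_free_vs_ff_study_allowed(self, iron_grid_reml):
        # same fixed part (study intercepts + treatment): comparable
        full = grid_fit(iron_grid_reml, "FR", "FREE")
        reduced = grid_fit(iron_grid_reml, "FF", "STUDY")
        stat, df, p = lrt_compare(full, reduced)
        assert df == 6
        assert stat >= 0

    def test_reml_across_fixed_parts_refused(self, iron_grid_reml):
        ff = grid_fit(iron_grid_reml, "FF", "FREE")
        rr = grid_fit(iron_grid_reml, "RR", "FREE")
        with pytest.raises(ValueError, match="fixed part"):
            lrt_compare(rr, ff)

    def test_mixed_estimation_refused(self, iron_pipd, iron_grid_reml):
        ml_fit = fit_lmm(iron_pipd, LMMSpec(effects="FF", residual="POOLED",
                                            estimation="ML"),
                         both_likelihoods=False)
        with pytest.raises(ValueError, match="estimation"):
            lrt_compare(grid_fit(iron_grid_reml, "FF", "FREE"), ml_fit)


class TestNestingMonotonicity:
    @pytest.mark.parametrize("effects", ["FF", "FR"])
    def test_iron_reml_deviances(self, iron_grid_reml, effects):
        dev = {r.residual: r.m2loglik_reml
               for r in iron_grid_reml.itertuples() if r.effects == effects}
        assert dev["FREE"] <= dev["STUDY"] + 1e-6
        assert dev["STUDY"] <= dev["POOLED"] + 1e-6
        assert dev["FREE"] <= dev["ARM"] + 1e-6
        assert dev["ARM"] <= dev["POOLED"] + 1e-6

    def test_synthetic_reml_deviances(self, rng):
        rows = [(f"s{i}", rng.normal(0, 5), rng.uniform(1, 4),
                 int(rng.integers(5, 30)), rng.normal(2, 5),
                 rng.uniform(1, 4), int(rng.integers(5, 30)))
                for i in range(4)]
        data = make_dataset(rows)
        pipd = generate_pseudo_ipd(data, method="two_point")
        dev = {}
        for res in ("FREE", "STUDY", "ARM", "POOLED"):
            fit = fit_lmm(pipd, LMMSpec(effects="FF", residual=res,
                                        estimation="REML"),
                          both_likelihoods=False)
            dev[res] = fit.m2loglik_reml
        assert dev["FREE"] <= dev["STUDY"] + 1e-6 <= dev["POOLED"] + 2e-6
        assert dev["FREE"] <= dev["ARM"] + 1e-6 <= dev["POOLED"] + 2e-6


class TestBoundary:
    def test_tau_zero_data(self, rng):
        # homogeneous treatment effect: FR collapses to FF at the boundary
        rows = []
        for i in range(8):
            y0 = rng.normal(10, 2, size=60)
            y1 = rng.normal(13, 2, size=60)
            rows.append((f"s{i}", y0.mean(), y0.std(ddof=1), 60,
                         y1.mean(), y1.std(ddof=1), 60))
        data = make_dataset(rows)
        pipd = generate_pseudo_ipd(data, method="two_point")
        fr = fit_lmm(pipd, LMMSpec(effects="FR", residual="POOLED",
                                   estimation="REML"), both_likelihoods=False)
        ff = fit_lmm(pipd, LMMSpec(effects="FF", residual="POOLED",
                                   estimation="REML"), both_likelihoods=False)
        assert fr.boundary
        assert fr.tau1_sq == 0.0
        assert fr.beta1_hat == pytest.approx(ff.beta1_hat, abs=1e-6)


class TestParameterRecovery:
    def test_rr_arm_large_sample(self):
        rng = np.random.default_rng(7)
        m, n = 50, 200
        theta, s0, s1 = 3.0, 1.0, 4.0
        tau0_sq, tau1_sq = 4.0, 2.0
        rows = []
        for i in range(m):
            b0 = rng.normal(0, np.sqrt(tau0_sq))
            b1 = rng.normal(0, np.sqrt(tau1_sq))
            y0 = rng.normal(b0, s0, size=n)
            y1 = rng.normal(b0 + theta + b1, s1, size=n)
            rows.append((f"s{i}", y0.mean(), y0.std(ddof=1), n,
                         y1.mean(), y1.std(ddof=1), n))
        pipd = generate_pseudo_ipd(make_dataset(rows), method="two_point")
        fit = fit_lmm(pipd, LMMSpec(effects="RR", residual="ARM",
                                    estimation="REML"), both_likelihoods=False)
        # 3 x approximate Monte-Carlo SEs: sqrt(2/m) * (tau^2 + sigma^2/n)
        se_tau0 = np.sqrt(2.0 / m) * (tau0_sq + s0**2 / n + s1**2 / n)
        se_tau1 = np.sqrt(2.0 / m) * (tau1_sq + 2 * s1**2 / n)
        assert fit.tau0_sq == pytest.approx(tau0_sq, abs=3 * se_tau0)
        assert fit.tau1_sq == pytest.approx(tau1_sq, abs=3 * se_tau1)
        resid = fit.residual_variances[("s0", 0)], \
            fit.residual_variances[("s0", 1)]
        assert resid[0] == pytest.approx(s0**2, rel=0.05)
        assert resid[1] == pytest.approx(s1**2, rel=0.05)
        assert fit.beta1_hat == pytest.approx(theta, abs=3 * np.sqrt(
            (tau1_sq + (s0**2 + s1**2) / n) / m))


class TestGridAndValidation:
    def test_empty_dataset(self):
        empty = PseudoIPD(np.array([], dtype=object), np.array([], dtype=int),
                          np.array([], dtype=float))
        with pytest.raises(ValueError):
            model_grid(empty)

    def test_bad_spec_values(self):
        with pytest.raises(ValueError):
            LMMSpec(effects="XX")
        with pytest.raises(ValueError):
            LMMSpec(residual="DIAG")
        with pytest.raises(ValueError):
            LMMSpec(estimation="MAP")

    def test_zero_sd_arm_free_structure_fails(self):
        import warnings
        data = make_dataset([("a", 1.0, 0.0, 5, 2.0, 1.0, 5),
                             ("b", 1.0, 1.0, 5, 2.0, 1.0, 5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipd = generate_pseudo_ipd(data, method="two_point")
        from pseudoipd.lmm_core import SingularModelError
        with pytest.raises(SingularModelError):
            fit_lmm(pipd, LMMSpec(effects="FF", residual="FREE"),
                    both_likelihoods=False)

    def test_grid_failures_annotated(self):
        import warnings
        data = make_dataset([("a", 1.0, 0.0, 5, 2.0, 1.0, 5),
                             ("b", 1.0, 1.0, 5, 2.0, 1.0, 5)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pipd = generate_pseudo_ipd(data, method="two_point")
            grid = model_grid(pipd)
        free = grid[(grid["effects"] == "FF") & (grid["residual"] == "FREE")]
        assert free["error"].iloc[0] != ""
        pooled = grid[(grid["effects"] == "FF")
                      & (grid["residual"] == "POOLED")]
        assert pooled["error"].iloc[0] == ""
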
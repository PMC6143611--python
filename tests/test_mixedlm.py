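"""Random-intercept REML: closed-form oracles, reference agreement, df limits."""

import numpy as np
import pandas as pd
import pytest

from rodscreen.mixedlm import LineageError, RandomInterceptModel


def make_nested(rng, n_levels=3, fish_per_level=3, rods=None, tau=0.35, sigma=1.0,
                means=None):
    """Simulate a nested rods-in-fish dataset; returns (df, control_label)."""
    rows = []
    labels = [f"G{g}" for g in range(n_levels)]
    means = means if means is not None else [5.0] * n_levels
    for g, lab in enumerate(labels):
        for f in range(fish_per_level):
            n = rods if isinstance(rods, int) else int(rng.integers(*rods))
            b = rng.normal(0.0, tau)
            y = rng.normal(means[g] + b, sigma, n)
            for r, v in enumerate(y):
                rows.append((lab, f"{lab}-F{f}", f"r{r}", v))
    df = pd.DataFrame(rows, columns=["trt", "fish", "rod", "y"])
    return df, labels[0]


def balanced_reml_closed_form(df, n_levels, fish_per_level, rods):
    """ANOVA/REML closed forms for the balanced nested one-way layout.

    For a balanced design the REML solution coincides with the ANOVA
    estimators when the between-fish component is positive; at the
    truncation boundary (tau^2 = 0) the residual variance is the pooled
    OLS residual variance around the group means.
    """
    q = n_levels * fish_per_level
    n_tot = len(df)
    fish_means = df.groupby("fish")["y"].mean()
    grp_of_fish = df.groupby("fish")["trt"].first()
    ssw = sum(
        ((grp["y"] - grp["y"].mean()) ** 2).sum() for _, grp in df.groupby("fish")
    )
    msw = ssw / (n_tot - q)
    grp_means = df.groupby("trt")["y"].mean()
    ssb = rods * sum(
        (fish_means[f] - grp_means[grp_of_fish[f]]) ** 2 for f in fish_means.index
    )
    msb = ssb / (q - n_levels)
    tau2 = (msb - msw) / rods
    if tau2 > 0:
        return tau2, msw
    return 0.0, (ssw + ssb) / (n_tot - n_levels)


class TestFitOracles:
    def test_hand_anova_toy(self, toy_controls):
        # fish means 5,6; MSB = 2*Var(5,6) = 1, MSW = 2 -> negative moment
        # estimate truncates to zero and the estimate is the pooled mean.
        res = RandomInterceptModel.from_dataframe(toy_controls).fit()
        assert res.fixed_estimates[0] == pytest.approx(5.5)
        assert res.var_fish == 0.0
        assert res.flags.get("tau_truncated")

    def test_matches_ols_when_no_fish_variance(self):
        rng = np.random.default_rng(42)
        df, _ = make_nested(rng, tau=0.0, rods=(20, 40))
        res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
        if res.var_fish == 0.0:
            ols = df.groupby("trt")["y"].mean()
            for lab, est in zip(res.treatment_levels, res.fixed_estimates):
                assert est == pytest.approx(ols[lab], abs=1e-8)

    def test_balanced_closed_form(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            df, _ = make_nested(np.random.default_rng(seed), rods=25)
            res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
            tau2, sigma2 = balanced_reml_closed_form(df, 3, 3, 25)
            assert res.var_fish == pytest.approx(tau2, abs=1e-8)
            assert res.var_resid == pytest.approx(sigma2, abs=1e-8)

    def test_reference_agreement_statsmodels(self):
        """Fixed estimates and variance components vs statsmodels MixedLM.

        Standard errors are excluded here: MixedLM reports them from the
        joint observed-information Hessian rather than the GLS form
        (X'V^-1X)^-1 used by the lme4 family; see the lme4 agreement test
        for the SE convention this package follows.
        """
        import warnings

        import statsmodels.formula.api as smf
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        worst_est = 0.0
        worst_vc = 0.0
        n_compared = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            df, _ = make_nested(
                rng,
                n_levels=int(rng.integers(2, 5)),
                rods=(8, 30),
                tau=float(rng.uniform(0.1, 0.6)),
            )
            res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
            mod = smf.mixedlm("y ~ 0 + trt", df, groups=df["fish"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                ref = mod.fit(reml=True)
            # the reference must not sit at a better restricted optimum
            theta_ref = float(ref.cov_re.iloc[0, 0]) / ref.scale
            assert (
                -2 * res.log_restricted_likelihood
                <= res.model._restricted_deviance(theta_ref) + 1e-6
            )
            if not ref.converged:
                continue  # a failed reference fit is not an oracle
            n_compared += 1
            for i, lab in enumerate(res.treatment_levels):
                est = ref.params[f"trt[{lab}]"]
                worst_est = max(worst_est, abs(res.fixed_estimates[i] - est) / abs(est))
            worst_vc = max(
                worst_vc,
                abs(res.var_fish - float(ref.cov_re.iloc[0, 0]))
                / max(res.var_fish, 1e-3),
                abs(res.var_resid - ref.scale) / res.var_resid,
            )
        assert n_compared >= 15
        assert worst_est < 1e-4
        # variance components only localize to the reference optimizer's
        # own convergence slack
        assert worst_vc < 5e-3

    def test_reference_agreement_lme4(self, tmp_path):
        """Estimates, GLS standard errors and variance components vs lme4.

        lme4/lmerTest is the reference family for this nested design; its
        vcov() uses the same (X'V^-1X)^-1 sigma^2 convention as this
        package.  Five unbalanced fixtures are exchanged through CSV and
        fitted by Rscript in one session.
        """
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")

        fixtures = []
        for seed in range(5):
            rng = np.random.default_rng(500 + seed)
            df, _ = make_nested(
                rng,
                n_levels=int(rng.integers(2, 5)),
                rods=(8, 30),
                tau=float(rng.uniform(0.15, 0.6)),
            )
            df.to_csv(tmp_path / f"fix{seed}.csv", index=False)
            fixtures.append(df)
        rcode = """
        suppressMessages(library(lme4))
        out <- NULL
        for (s in 0:4) {
          d <- read.csv(sprintf("%s/fix%d.csv", ARGS, s))
          m <- lmer(y ~ 0 + trt + (1 | fish), data = d, REML = TRUE)
          fe <- fixef(m); se <- sqrt(diag(as.matrix(vcov(m))))
          vc <- as.data.frame(VarCorr(m))
          out <- rbind(out, data.frame(fixture = s,
            level = sub("^trt", "", names(fe)), est = as.numeric(fe),
            se = as.numeric(se), tau2 = vc$vcov[1], sigma2 = vc$vcov[2]))
        }
        write.csv(out, sprintf("%s/ref.csv", ARGS), row.names = FALSE)
        """.replace("ARGS", "commandArgs(TRUE)[1]")
        script = tmp_path / "ref.R"
        script.write_text(rcode)
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(tmp_path)],
            check=True, capture_output=True, timeout=300,
        )
        ref = pd.read_csv(tmp_path / "ref.csv")
        worst = 0.0
        for s, df in enumerate(fixtures):
            res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
            sub = ref[ref["fixture"] == s].set_index("level")
            for i, lab in enumerate(res.treatment_levels):
                worst = max(
                    worst,
                    abs(res.fixed_estimates[i] - sub.at[lab, "est"])
                    / abs(sub.at[lab, "est"]),
                    abs(res.fixed_se[i] - sub.at[lab, "se"]) / sub.at[lab, "se"],
                )
            worst = max(
                worst,
                abs(res.var_fish - sub["tau2"].iloc[0]) / max(res.var_fish, 1e-3),
                abs(res.var_resid - sub["sigma2"].iloc[0]) / res.var_resid,
            )
        assert worst < 1e-4

    def test_variance_component_bias_small(self):
        # median relative bias < 10% over 200 balanced replicates
        tau2_true, sigma2_true = 0.3, 1.0
        taus, sigmas = [], []
        for seed in range(200):
            rng = np.random.default_rng(10_000 + seed)
            df, _ = make_nested(
                rng, n_levels=8, fish_per_level=3, rods=30,
                tau=np.sqrt(tau2_true), sigma=np.sqrt(sigma2_true),
            )
            res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
            taus.append(res.var_fish)
            sigmas.append(res.var_resid)
        assert abs(np.median(taus) - tau2_true) / tau2_true < 0.10
        assert abs(np.median(sigmas) - sigma2_true) / sigma2_true < 0.10


class TestFitProperties:
    def test_reml_objective_optimal(self):
        rng = np.random.default_rng(3)
        df, _ = make_nested(rng, rods=(10, 40))
        model = RandomInterceptModel(df.y, df.trt, df.fish)
        res = model.fit()
        dev_hat = model._restricted_deviance(res.theta)
        for theta in (0.0, 1e-3, 0.1, 1.0, 100.0, 1e5):
            assert dev_hat <= model._restricted_deviance(theta) + 1e-7

    def test_translation_equivariance(self):
        rng = np.random.default_rng(11)
        df, _ = make_nested(rng, rods=(10, 20))
        res0 = RandomInterceptModel(df.y, df.trt, df.fish).fit()
        res1 = RandomInterceptModel(df.y + 7.0, df.trt, df.fish).fit()
        assert np.allclose(res1.fixed_estimates - res0.fixed_estimates, 7.0, atol=1e-8)
        # variance components agree up to the optimizer's theta tolerance
        assert res1.var_fish == pytest.approx(res0.var_fish, rel=1e-6, abs=1e-7)
        assert res1.var_resid == pytest.approx(res0.var_resid, rel=1e-6)

    def test_estimate_is_weighted_fish_mean_combination(self):
        rng = np.random.default_rng(5)
        df, _ = make_nested(rng, n_levels=1, fish_per_level=4, rods=(5, 40))
        model = RandomInterceptModel(df.y, df.trt, df.fish)
        res = model.fit()
        theta = res.theta
        w = model.fish_n / (1 + theta * model.fish_n)
        expect = np.sum(w * model.fish_mean) / np.sum(w)
        assert res.fixed_estimates[0] == pytest.approx(expect, rel=1e-12)

    def test_lineage_error(self):
        df = pd.DataFrame(
            {"y": [1.0, 2.0], "trt": ["a", "b"], "fish": ["F1", "F1"]}
        )
        with pytest.raises(LineageError):
            RandomInterceptModel(df.y, df.trt, df.fish)

    def test_degenerate_constant_data_flagged(self):
        df = pd.DataFrame(
            {"y": [5.0] * 6, "trt": ["a"] * 6, "fish": ["F1"] * 3 + ["F2"] * 3}
        )
        res = RandomInterceptModel(df.y, df.trt, df.fish).fit()
        assert res.flags.get("degenerate_variance")
        assert res.var_resid > 0


class TestContrasts:
    def test_noise_free_contrast_is_mean_difference(self):
        df = pd.DataFrame(
            {
                "y": [5.0] * 6 + [6.0] * 6,
                "trt": ["ctl"] * 6 + ["cmp"] * 6,
                "fish": ["c1"] * 3 + ["c2"] * 3 + ["t1"] * 3 + ["t2"] * 3,
            }
        )
        cs = RandomInterceptModel(df.y, df.trt, df.fish, control="ctl").fit().contrast_control()
        assert cs.estimates[0] == pytest.approx(1.0)
        assert cs.se[0] >= 1e-12  # guarded, never exactly zero

    def test_balanced_offdiagonal_correlation_half(self):
        rng = np.random.default_rng(8)
        df, ctl = make_nested(rng, n_levels=4, fish_per_level=3, rods=20)
        cs = RandomInterceptModel(df.y, df.trt, df.fish, control=ctl).fit().contrast_control()
        off = cs.correlation[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5, atol=1e-10)

    def test_single_contrast_correlation(self):
        rng = np.random.default_rng(9)
        df, ctl = make_nested(rng, n_levels=2, rods=(5, 15))
        cs = RandomInterceptModel(df.y, df.trt, df.fish, control=ctl).fit().contrast_control()
        assert cs.correlation.shape == (1, 1)
        assert cs.correlation[0, 0] == 1.0

    def test_missing_control_errors(self):
        rng = np.random.default_rng(10)
        df, _ = make_nested(rng, rods=10)
        res = RandomInterceptModel(df.y, df.trt, df.fish).fit()  # no control set
        with pytest.raises(ValueError):
            res.contrast_control()


class TestSatterthwaite:
    def test_zero_fish_variance_gives_ols_df(self):
        rng = np.random.default_rng(21)
        df, ctl = make_nested(rng, n_levels=2, rods=30, tau=0.0)
        res = RandomInterceptModel(df.y, df.trt, df.fish, control=ctl).fit()
        if res.var_fish == 0.0:
            assert res.satterthwaite_df([-1, 1]) == pytest.approx(len(df) - 2)

    def test_fish_dominant_df_near_fish_level(self):
        # Huge fish variance, tiny rod noise: the contrast behaves like a
        # t-test on 6 fish means -> df near 4.
        rng = np.random.default_rng(22)
        rows = []
        for lab in ("ctl", "trt"):
            for f in range(3):
                mu = rng.normal(5.0, 1.0)
                rows += [(lab, f"{lab}{f}", mu + rng.normal(0, 0.05)) for _ in range(50)]
        df = pd.DataFrame(rows, columns=["trt", "fish", "y"])
        res = RandomInterceptModel(df.y, df.trt, df.fish, control="ctl").fit()
        assert res.satterthwaite_df([-1, 1]) == pytest.approx(4.0, abs=1.0)

    def test_df_monotone_in_variance_ratio(self):
        # identical rod noise, fish offsets scaled up -> realized variance
        # ratio grows and the effective df must not increase
        rng = np.random.default_rng(23)
        base, ctl = make_nested(rng, n_levels=2, fish_per_level=4, rods=25, tau=0.0)
        offsets = {f: o for f, o in zip(base["fish"].unique(),
                                        rng.normal(0.0, 1.0, 8))}
        dfs = []
        for scale in (0.1, 0.5, 1.5, 4.0):
            y = base["y"] + scale * base["fish"].map(offsets)
            res = RandomInterceptModel(y, base.trt, base.fish, control=ctl).fit()
            dfs.append(res.satterthwaite_df([-1, 1]))
        # tolerance covers finite-difference noise in the df computation
        assert all(a >= b - 1e-3 for a, b in zip(dfs, dfs[1:]))
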
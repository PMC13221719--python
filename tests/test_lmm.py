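"""EM-REML engine: closed-form, brute-force, and cross-package oracles."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_reml, dense_reml_loglik
from sheepmethane.lmm import (
    VAR_FLOOR,
    ModelSpec,
    RankDeficiencyError,
    _em_reml,
    estimate_repeatability,
    fit_lmm,
    marginal_means,
)


def one_way(rng, na, k, sa, se, mu=10.0):
    codes = np.repeat(np.arange(na), k)
    y = mu + rng.normal(0, np.sqrt(sa), na)[codes] + rng.normal(0, np.sqrt(se), na * k)
    return y, np.ones((na * k, 1)), codes


class TestClosedForms:
    def test_zero_within_animal_spread(self):
        # two identical records per animal: all variance is between animals
        y = np.repeat([10.0, 12.0, 14.0, 16.0], 2)
        codes = np.repeat(np.arange(4), 2)
        _, _, vc, _, _, _, ok = _em_reml(y, np.ones((8, 1)), {"animal": codes})
        assert ok
        assert vc["residual"] == pytest.approx(VAR_FLOOR)
        assert vc["animal"] == pytest.approx(np.var([10, 12, 14, 16], ddof=1), rel=1e-7)

    def test_zero_between_animal_spread(self):
        # three animals each {10, 12}: between-animal mean square is zero, so
        # the constrained optimum pins the animal variance at the floor and the
        # residual variance equals SS_total/(n-1) = 1.2 (value frozen from the
        # brute-force restricted-likelihood oracle)
        y = np.array([10.0, 12.0] * 3)
        codes = np.repeat(np.arange(3), 2)
        _, _, vc, _, ll, _, ok = _em_reml(y, np.ones((6, 1)), {"animal": codes})
        assert ok
        assert vc["animal"] == pytest.approx(VAR_FLOOR)
        assert vc["residual"] == pytest.approx(1.2, abs=1e-8)

    @pytest.mark.parametrize("na, k, sa, se", [(20, 3, 2.0, 1.0), (12, 5, 0.5, 3.0),
                                               (30, 2, 4.0, 4.0)])
    def test_balanced_one_way_equals_anova(self, rng, na, k, sa, se):
        y, X, codes = one_way(rng, na, k, sa, se)
        _, _, vc, _, _, _, ok = _em_reml(y, X, {"animal": codes})
        ybar = y.reshape(na, k).mean(axis=1)
        msb = k * np.sum((ybar - y.mean()) ** 2) / (na - 1)
        msw = np.sum((y.reshape(na, k) - ybar[:, None]) ** 2) / (na * (k - 1))
        assert ok
        assert msb > msw  # interior optimum for these draws
        assert vc["animal"] == pytest.approx((msb - msw) / k, abs=1e-8)
        assert vc["residual"] == pytest.approx(msw, abs=1e-8)


class TestBruteForceOracle:
    """On every instance of <= 30 records the EM solution must match an
    independent dense-matrix restricted-likelihood maximization."""

    def _instance(self, rng, case):
        if case == "single":
            y, X, codes = one_way(rng, 10, 3, 2.0, 1.0)
            return y, X, {"animal": codes}
        if case == "covariate":
            n = 24
            codes = np.repeat(np.arange(8), 3)
            x = rng.normal(0, 1, n)
            y = 5 + 0.7 * x + rng.normal(0, 1.2, 8)[codes] + rng.normal(0, 1.0, n)
            return y, np.column_stack([np.ones(n), x]), {"animal": codes}
        if case == "crossed":
            n = 30
            an = np.repeat(np.arange(10), 3)
            cg = rng.integers(0, 5, n)
            y = (8 + rng.normal(0, 1.5, 10)[an] + rng.normal(0, 1.0, 5)[cg]
                 + rng.normal(0, 1.0, n))
            return y, np.ones((n, 1)), {"cg": cg, "animal": an}
        raise AssertionError(case)

    @pytest.mark.parametrize("case", ["single", "covariate", "crossed"])
    @pytest.mark.parametrize("draw", [0, 1, 2])
    def test_matches_brute_force(self, case, draw):
        rng = np.random.default_rng(100 * draw + hash(case) % 97)
        y, X, terms = self._instance(rng, case)
        _, _, vc, _, _, _, ok = _em_reml(y, X, terms, rtol=1e-12, max_iter=20000)
        assert ok
        codes_list = list(terms.values())
        oracle = brute_force_reml(y, X, codes_list)
        mine = np.array([vc[t] for t in terms] + [vc["residual"]])
        ref = np.concatenate([oracle["sigmas"], [oracle["sig_e"]]])
        assert np.allclose(mine, ref, atol=1e-6)
        ll_mine = dense_reml_loglik(y, X, codes_list, mine[:-1], mine[-1])
        assert ll_mine >= oracle["loglik"] - 1e-6

    def test_loglik_dominates_grid(self):
        # boundary instance: restricted likelihood at the EM solution must not
        # fall below any grid point of the dense oracle
        y = np.array([10.0, 12.0] * 3)
        codes = np.repeat(np.arange(3), 2)
        _, _, vc, _, _, _, _ = _em_reml(y, np.ones((6, 1)), {"animal": codes})
        ll_mine = dense_reml_loglik(y, np.ones((6, 1)), [codes],
                                    [vc["animal"]], vc["residual"])
        for sa in np.linspace(VAR_FLOOR, 3.0, 40):
            for se in np.linspace(0.05, 3.0, 40):
                assert ll_mine >= dense_reml_loglik(
                    y, np.ones((6, 1)), [codes], [sa], se) - 1e-6

    def test_internal_loglik_matches_dense_formula(self, rng):
        y, X, codes = one_way(rng, 8, 3, 1.5, 1.0)
        _, _, vc, _, ll, _, _ = _em_reml(y, X, {"animal": codes})
        dense = dense_reml_loglik(y, X, [codes], [vc["animal"]], vc["residual"])
        assert ll == pytest.approx(dense, abs=1e-8)


class TestInvariances:
    def _fit(self, y, X, terms, **kw):
        beta, _, vc, blups, ll, _, ok = _em_reml(y, X, terms, **kw)
        assert ok
        return beta, vc, ll

    def test_permutation_invariance(self, rng):
        n = 60
        an = rng.integers(0, 20, n)
        cg = rng.integers(0, 6, n)
        x = rng.normal(0, 1, n)
        y = 3 + x + rng.normal(0, 1, 20)[an] + rng.normal(0, 1, 6)[cg] + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])
        b1, v1, _ = self._fit(y, X, {"cg": cg, "animal": an})
        perm = rng.permutation(n)
        b2, v2, _ = self._fit(y[perm], X[perm], {"cg": cg[perm], "animal": an[perm]})
        assert np.allclose(b1, b2, atol=1e-10)
        assert all(abs(v1[k] - v2[k]) < 1e-10 for k in v1)

    def test_constant_shift_moves_only_intercept(self, rng):
        y, X, codes = one_way(rng, 15, 3, 2.0, 1.5)
        b1, v1, _ = self._fit(y, X, {"animal": codes})
        b2, v2, _ = self._fit(y + 7.0, X, {"animal": codes})
        assert b2[0] - b1[0] == pytest.approx(7.0, abs=1e-8)
        assert all(abs(v1[k] - v2[k]) < 1e-8 for k in v1)


class TestCrossPackageOracles:
    def test_single_random_term_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n_an, k = 60, 3
        an = np.repeat(np.arange(n_an), k)
        sex = rng.integers(0, 2, n_an)[an].astype(float)
        y = 10 + 0.8 * sex + rng.normal(0, 1.4, n_an)[an] + rng.normal(0, 2.0, n_an * k)
        X = np.column_stack([np.ones(n_an * k), sex])
        beta, _, vc, _, ll, _, _ = _em_reml(y, X, {"animal": an})
        ref = sm.MixedLM(y, X, groups=an).fit(reml=True)
        assert np.allclose(beta, ref.fe_params, atol=1e-5)
        assert vc["animal"] == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-4)
        assert vc["residual"] == pytest.approx(ref.scale, abs=1e-4)
        assert ll == pytest.approx(ref.llf, abs=1e-5)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_crossed_random_terms_match_lme4(self, rng, tmp_path):
        n_an, k = 50, 3
        an = np.repeat(np.arange(n_an), k)
        cg = rng.integers(0, 12, n_an * k)
        x = rng.normal(0, 1, n_an * k)
        y = (9 + 0.5 * x + rng.normal(0, 1.2, n_an)[an]
             + rng.normal(0, 0.9, 12)[cg] + rng.normal(0, 1.5, n_an * k))
        df = pd.DataFrame({"y": y, "x": x, "an": an, "cg": cg})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1|cg) + (1|an), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(fixef(m), vc$vcov[vc$grp=="an"], vc$vcov[vc$grp=="cg"],
                vc$vcov[vc$grp=="Residual"], as.numeric(logLik(m)), sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True, timeout=120)
        b0, b1, va, vcg, ve, ll_r = map(float, out.stdout.strip().splitlines())
        X = np.column_stack([np.ones(len(y)), x])
        beta, _, vc, _, ll, _, _ = _em_reml(y, X, {"cg": cg, "an": an})
        assert np.allclose(beta, [b0, b1], atol=1e-5)
        assert vc["an"] == pytest.approx(va, abs=1e-4)
        assert vc["cg"] == pytest.approx(vcg, abs=1e-4)
        assert vc["residual"] == pytest.approx(ve, abs=1e-4)
        assert ll == pytest.approx(ll_r, abs=1e-4)


class TestModelSpecInterface:
    def _toy(self, rng, n=90):
        an = rng.integers(0, 30, n)
        return pd.DataFrame({
            "y": rng.normal(10, 2, n) + rng.normal(0, 1, 30)[an],
            "sex": rng.choice(["female", "male"], n),
            "x": rng.normal(0, 1, n),
            "animal_id": [f"A{i}" for i in an],
        })

    def test_fit_and_blup_shapes(self, rng):
        df = self._toy(rng)
        spec = ModelSpec("y", factors={"sex": "female"}, covariates=["x"],
                         random_terms=["animal_id"])
        fit = fit_lmm(spec, df)
        assert fit.converged
        assert list(fit.beta.index) == ["(Intercept)", "sex[male]", "x"]
        assert len(fit.blups["animal_id"]) == df["animal_id"].nunique()

    def test_rank_deficiency_names_aliased_columns(self, rng):
        df = self._toy(rng)
        df["x2"] = 2 * df["x"]
        spec = ModelSpec("y", covariates=["x", "x2"], random_terms=["animal_id"])
        with pytest.raises(RankDeficiencyError, match="x2?"):
            fit_lmm(spec, df)


class TestRepeatability:
    def test_formula_on_known_components(self):
        # R is a pure function of the two variances; check via a constructed
        # dataset whose REML components are known in closed form
        y = np.repeat([10.0, 12.0, 14.0, 16.0], 2)
        df = pd.DataFrame({"ch4": y, "animal_id": np.repeat(list("abcd"), 2)})
        res = estimate_repeatability(df, "ch4", contemporary_group=None,
                                     n_bootstrap=0)
        assert res["R"] == pytest.approx(1.0, abs=1e-6)

    def test_zero_animal_variance_gives_zero(self, rng):
        n_an = 150
        an = np.repeat(np.arange(n_an), 2)
        df = pd.DataFrame({"ch4": rng.normal(14, 2, 2 * n_an),
                           "animal_id": [f"A{i}" for i in an]})
        res = estimate_repeatability(df, "ch4", contemporary_group=None,
                                     n_bootstrap=0)
        assert res["R"] < 0.06

    def test_parameter_recovery_and_bootstrap_se(self, rng):
        n_an = 500
        an = np.repeat(np.arange(n_an), 2)
        sa, se = 0.3, 0.7  # repeatability 0.3
        y = 14 + rng.normal(0, np.sqrt(sa), n_an)[an] + rng.normal(0, np.sqrt(se), 2 * n_an)
        df = pd.DataFrame({"ch4": y, "animal_id": [f"A{i:04d}" for i in an]})
        res = estimate_repeatability(df, "ch4", contemporary_group=None,
                                     n_bootstrap=40, seed=5)
        assert res["R"] == pytest.approx(0.3, abs=0.08)
        assert res["SE"] is not None and 0.0 < res["SE"] < 0.12

    def test_unidentifiable_without_repeats(self):
        df = pd.DataFrame({"ch4": [10.0, 11.0, 12.0],
                           "animal_id": ["a", "b", "c"]})
        with pytest.raises(ValueError, match="unidentifiable"):
            estimate_repeatability(df, "ch4", contemporary_group=None)


class TestMarginalMeans:
    def test_balanced_two_group_equals_raw_means(self, rng):
        # 20 animals x 2 records, balanced across the sexes: generalized and
        # ordinary least squares coincide, so EMMs equal raw group means
        an = np.repeat(np.arange(20), 2)
        sex = np.where(an < 10, "female", "male")
        y = (np.where(sex == "male", 12.0, 10.0)
             + rng.normal(0, 0.8, 20)[an] + rng.normal(0, 0.5, 40))
        df = pd.DataFrame({"y": y, "sex": sex, "animal_id": an})
        fit = fit_lmm(ModelSpec("y", factors={"sex": "female"},
                                random_terms=["animal_id"]), df)
        emm = marginal_means(fit, "sex").set_index("level")
        assert emm.loc["female", "emm"] == pytest.approx(y[sex == "female"].mean(), abs=1e-6)
        assert emm.loc["male", "emm"] == pytest.approx(y[sex == "male"].mean(), abs=1e-6)

    def test_emm_is_contrast_dot_product(self, rng):
        df = pd.DataFrame({
            "y": rng.normal(0, 1, 60),
            "g": rng.choice(["a", "b", "c"], 60),
            "x": rng.normal(2.0, 1.0, 60),
            "animal_id": rng.integers(0, 20, 60),
        })
        fit = fit_lmm(ModelSpec("y", factors={"g": "a"}, covariates=["x"],
                                random_terms=["animal_id"]), df)
        emm = marginal_means(fit, "g").set_index("level")
        # hand-built contrast: intercept + g[b] dummy + covariate at its mean
        expected_b = (fit.beta["(Intercept)"] + fit.beta["g[b]"]
                      + fit.beta["x"] * df["x"].mean())
        assert emm.loc["b", "emm"] == pytest.approx(expected_b, abs=1e-10)
        pw = emm.attrs if hasattr(emm, "attrs") else {}
        assert "pairwise" not in pw or len(pw["pairwise"]) == 3

    def test_absent_factor_errors(self, rng):
        df = pd.DataFrame({"y": rng.normal(0, 1, 30),
                           "animal_id": rng.integers(0, 10, 30)})
        fit = fit_lmm(ModelSpec("y", random_terms=["animal_id"]), df)
        with pytest.raises(KeyError):
            marginal_means(fit, "sex")
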
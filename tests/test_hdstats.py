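"""Multinomial/Poisson phenotype models, LRT machinery, permutation tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dysgene import hdstats, presets, synth
from dysgene.formats import phenotypes_to_frame
from dysgene.hdstats import (
    build_design,
    bootstrap_r2_compare,
    deletable_terms,
    dsquared,
    fisher_pitman,
    fit_multinomial,
    fit_poisson,
    lrt,
    poisson_response,
    senescence_compare,
    stepwise_simplify,
    type3_terms,
)


def _ovary_frame(n0, n1, n2, **extra):
    y = [0] * n0 + [1] * n1 + [2] * n2
    df = pd.DataFrame({"ovary_count": y})
    for k, v in extra.items():
        df[k] = v
    return df


class TestDesign:
    def test_interaction_columns_are_products(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 1.0]})
        X, names, tc = build_design(df, [(), ("a",), ("b",), ("a", "b")])
        assert names == ["intercept", "a", "b", "a:b"]
        np.testing.assert_allclose(X[:, 3], df.a * df.b)

    def test_categorical_expansion_drop_first(self):
        df = pd.DataFrame({"cross": ["MxM", "MxP", "PxP", "MxP"], "age": [4.0, 9, 14, 19]})
        X, names, _ = build_design(df, [(), ("cross",), ("age", "cross")])
        assert "cross[MxP]" in names and "cross[MxM]" not in names
        assert any(n.startswith("age:cross[") for n in names)
        assert X.shape == (4, 1 + 2 + 2)


class TestMultinomial:
    def test_intercept_only_balanced_counts(self):
        fit = fit_multinomial(_ovary_frame(10, 10, 10), [()])
        # symmetric categories: both logits against "2 ovaries" are 0
        assert np.abs(fit.coefficients.to_numpy()).max() < 1e-4
        assert fit.converged and not fit.separation

    def test_all_healthy_separation_flagged(self):
        fit = fit_multinomial(_ovary_frame(0, 0, 30), [()])
        assert fit.separation
        # fitted P(2 ovaries) ~ 1: both logits strongly negative
        assert (fit.coefficients.to_numpy() < -1).all()

    def test_response_outside_categories_rejected(self):
        df = pd.DataFrame({"ovary_count": [0, 1, 3]})
        with pytest.raises(ValueError):
            fit_multinomial(df, [()])

    def test_coefficient_recovery_within_two_se(self):
        coeffs = {
            "ovary0": {("1",): -3.0, ("pe_cn",): 0.25},
            "ovary1": {("1",): -3.0, ("pe_cn",): 0.15},
            "ovarioles": {("1",): math.log(20)},
        }
        design = [
            synth.DesignCell("M", f"F{pe}", float(pe), 0.0, 29.0, 250)
            for pe in (0, 2, 4, 6, 8, 10, 12, 14)
        ]
        df = phenotypes_to_frame(synth.simulate_phenotypes(design, coeffs, seed=14))
        fit = fit_multinomial(df, [(), ("father_pe_cn",)])
        for col, true in [("logit0", 0.25), ("logit1", 0.15)]:
            est = fit.coefficients.loc["father_pe_cn", col]
            se = fit.bse.loc["father_pe_cn", col]
            assert abs(est - true) <= 2 * se


class TestPoisson:
    def test_intercept_only_constant_response(self):
        df = pd.DataFrame({"ovarioles_int": [20] * 40})
        fit = fit_poisson(df, [()])
        assert fit.coefficients.loc["intercept", "coef"] == pytest.approx(math.log(20), abs=1e-6)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson(pd.DataFrame({"ovarioles_int": []}), [()])

    def test_all_zero_response_flagged_degenerate(self):
        df = pd.DataFrame({"ovarioles_int": [0] * 30})
        assert fit_poisson(df, [()]).degenerate

    def test_slope_recovery_within_two_se(self):
        rng = np.random.default_rng(17)
        pe = np.repeat([0.0, 3, 6, 9, 12], 200)
        mu = np.exp(3.0 - 0.07 * pe)
        df = pd.DataFrame({"father_pe_cn": pe, "ovarioles_int": rng.poisson(mu)})
        fit = fit_poisson(df, [(), ("father_pe_cn",)])
        est = fit.coefficients.loc["father_pe_cn", "coef"]
        se = fit.bse.loc["father_pe_cn", "coef"]
        assert abs(est - (-0.07)) <= 2 * se

    def test_rounding_conventions(self):
        df = pd.DataFrame(
            {"mean_ovarioles": [18.5, 19.2, float("nan")], "ovary_count": [2, 2, 0]}
        )
        nearest = poisson_response(df, rounding="nearest")
        up = poisson_response(df, rounding="up")
        assert list(nearest["ovarioles_int"]) == [19, 19]
        assert list(up["ovarioles_int"]) == [19, 20]
        with pytest.raises(ValueError):
            poisson_response(df, rounding="down")


class TestLRT:
    def test_identical_models(self):
        df = pd.DataFrame({"ovarioles_int": [20, 21, 19, 20] * 5})
        fit = fit_poisson(df, [()])
        res = lrt(fit, fit)
        assert res.chi2 == 0 and res.p == 1.0

    def test_chi2_matches_per_record_log_probabilities(self):
        # independent oracle: sum Poisson log-pmfs at each model's fitted
        # means on a 20-row instance
        rng = np.random.default_rng(3)
        x = np.linspace(0, 10, 20)
        y = rng.poisson(np.exp(3.0 - 0.05 * x))
        df = pd.DataFrame({"x": x, "ovarioles_int": y})
        full = fit_poisson(df, [(), ("x",)])
        reduced = fit_poisson(df, [()])

        def loglik(fit):
            X, _, _ = build_design(df, fit.terms)
            mu = np.exp(X @ fit.coefficients["coef"].to_numpy())
            return scipy.stats.poisson.logpmf(y, mu).sum()

        expected = 2 * (loglik(full) - loglik(reduced))
        assert lrt(full, reduced).chi2 == pytest.approx(expected, abs=1e-6)

    def test_non_nested_rejected(self):
        df = pd.DataFrame({"ovarioles_int": [20] * 10, "a": 1.0, "b": 2.0})
        fa = fit_poisson(df, [(), ("a",)])
        fb = fit_poisson(df, [(), ("b",)])
        with pytest.raises(ValueError, match="nested"):
            lrt(fa, fb)

    def test_chi2_384_df1_p_approx_005(self):
        assert scipy.stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=0.001)

    def test_adding_terms_never_increases_residual_deviance(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "ovarioles_int": rng.poisson(20, 60),
                "a": rng.normal(size=60),
                "b": rng.normal(size=60),
            }
        )
        terms = [(), ("a",), ("b",), ("a", "b")]
        devs = [
            fit_poisson(df, terms[: k + 1]).residual_deviance for k in range(len(terms))
        ]
        for d1, d2 in zip(devs, devs[1:]):
            assert d2 <= d1 + 1e-8


class TestType3AndStepwise:
    def test_marginality_protects_main_effects(self):
        terms = [(), ("a",), ("b",), ("a", "b")]
        assert deletable_terms(terms) == [("a", "b")]

    def test_single_term_table_equals_plain_lrt(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"ovarioles_int": rng.poisson(20, 50), "a": rng.normal(size=50)}
        )
        table = type3_terms(df, [(), ("a",)], family="poisson")
        direct = lrt(fit_poisson(df, [(), ("a",)]), fit_poisson(df, [()]))
        assert table[("a",)].chi2 == pytest.approx(direct.chi2, abs=1e-8)

    def test_null_term_p_roughly_uniform(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(200):
            df = pd.DataFrame(
                {"ovarioles_int": rng.poisson(20, 80), "a": rng.normal(size=80)}
            )
            ps.append(type3_terms(df, [(), ("a",)], family="poisson")[("a",)].p)
        # Kolmogorov-Smirnov against uniform
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_stepwise_removes_null_interaction_keeps_real_main_effects(self):
        rng = np.random.default_rng(7)
        kept_main = removed_inter = 0
        for _ in range(20):
            n = 400
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            y = rng.poisson(np.exp(3.0 + 0.15 * a + 0.15 * b))
            df = pd.DataFrame({"ovarioles_int": y, "a": a, "b": b})
            fit = stepwise_simplify(df, [(), ("a",), ("b",), ("a", "b")], family="poisson")
            if ("a", "b") not in fit.terms:
                removed_inter += 1
            if ("a",) in fit.terms and ("b",) in fit.terms:
                kept_main += 1
        assert removed_inter >= 15
        assert kept_main >= 15

    def test_intercept_only_truth_reduces_fully(self):
        rng = np.random.default_rng(9)
        reduced_all = 0
        for _ in range(20):
            df = pd.DataFrame(
                {"ovarioles_int": rng.poisson(20, 200), "a": rng.normal(size=200)}
            )
            fit = stepwise_simplify(df, [(), ("a",)], family="poisson")
            reduced_all += fit.terms == ((),)
        assert reduced_all >= 15


def _brute_force_fp_p(x, y):
    """Exhaustive two-sided permutation p via all label assignments."""
    z = np.concatenate([x, y])
    nx = len(x)
    mu = nx * z.mean()
    obs = abs(x.sum() - mu)
    sums = [
        abs(z[list(c)].sum() - mu)
        for c in itertools.combinations(range(len(z)), nx)
    ]
    return np.mean([s >= obs - 1e-9 for s in sums])


class TestFisherPitman:
    def test_constant_samples_p_one(self):
        res = fisher_pitman([5.0] * 4, [5.0] * 4)
        assert res.p == 1.0

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.normal(0, 1, 4)
            y = rng.normal(0.8, 1, 5)
            res = fisher_pitman(x, y)
            assert res.p == pytest.approx(_brute_force_fp_p(x, y), abs=1e-12)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 4)
        y = rng.normal(1.2, 1, 4)
        exact = fisher_pitman(x, y)
        mc = fisher_pitman(x, y, n_permutations=100_000, seed=1, exact_max_n=0)
        assert abs(mc.p - exact.p) < 0.01

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1, 50)
        y = rng.normal(5, 1, 50)
        res = fisher_pitman(x, y, n_permutations=10_000, seed=2)
        assert res.p < 0.001
        assert res.statistic < -5

    def test_mc_requires_enough_permutations(self):
        with pytest.raises(ValueError):
            fisher_pitman(np.arange(20.0), np.arange(20.0) + 1, n_permutations=50)

    def test_bonferroni_constant(self):
        assert presets.BONFERRONI_ALPHA == pytest.approx(0.05 / 6)


def _senescence_frame(seed, accelerated=False, n_per_cell=40):
    # paternal P line at the population-mean copy number (~6.6)
    coeffs = presets.SENESCENCE_COEFFS if accelerated else {
        "ovary0": {("1",): -6.0},
        "ovary1": {("1",): -6.0},
        "ovarioles": {("1",): math.log(20), ("age",): -0.004},
    }
    design = []
    for mg, fl, pe in [("M", "Fm", 0.0), ("M", "Fp", 6.6), ("P", "Fm", 0.0), ("P", "Fp", 6.6)]:
        for age in (4.0, 9.0, 14.0, 19.0, 24.0, 29.0):
            design.append(
                synth.DesignCell(mg, fl, pe, 16.0, 29.0, n_per_cell, ages=(age,))
            )
    return phenotypes_to_frame(synth.simulate_phenotypes(design, coeffs, seed=seed))


class TestSenescence:
    def test_identical_slopes_truth_interaction_rarely_significant(self):
        hits = sum(
            senescence_compare(_senescence_frame(s))[2].p < 0.05 for s in range(10)
        )
        assert hits <= 3

    def test_accelerated_decline_detected(self):
        # dysgenic cross ages faster: interaction LRT should fire
        hits = sum(
            senescence_compare(_senescence_frame(s, accelerated=True, n_per_cell=80))[2].p < 0.05
            for s in range(5)
        )
        assert hits >= 4

    def test_slope_contrasts_zero_for_identical_crosses(self):
        df = _senescence_frame(3)
        half = df.copy()
        half["cross"] = np.where(np.arange(len(half)) % 2 == 0, "AxA", "BxB")
        _, _, _, contrasts = senescence_compare(half)
        assert contrasts["slope_contrast"].abs().max() < 0.01

    def test_single_age_rejected(self):
        df = _senescence_frame(1)
        with pytest.raises(ValueError, match="two ages"):
            senescence_compare(df[df.age == 4.0])


class TestDsquared:
    def test_intercept_only_zero(self):
        df = pd.DataFrame({"ovarioles_int": [18, 20, 22, 19, 21] * 4})
        assert dsquared(fit_poisson(df, [()])) == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_deviances_ten_rows(self):
        y = np.array([12, 15, 30, 28, 14, 16, 29, 31, 13, 27])
        x = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0, 1], float)
        df = pd.DataFrame({"ovarioles_int": y, "x": x})
        fit = fit_poisson(df, [(), ("x",)])

        def pois_dev(y, mu):
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return 2 * np.sum(term - (y - mu))

        mu0 = np.full_like(y, y.mean(), dtype=float)
        mu1 = np.where(x == 1, y[x == 1].mean(), y[x == 0].mean())
        expected = (pois_dev(y, mu0) - pois_dev(y, mu1)) / pois_dev(y, mu0)
        assert dsquared(fit) == pytest.approx(expected, rel=1e-6)

    def test_saturated_fit_explains_everything(self):
        y = np.array([10, 20, 30, 40])
        df = pd.DataFrame({"ovarioles_int": y, "g": ["a", "b", "c", "d"]})
        fit = fit_poisson(df, [(), ("g",)])
        assert dsquared(fit) == pytest.approx(1.0, abs=1e-8)


class TestBootstrapCompare:
    def test_identical_inputs_and_seeds_statistic_near_zero(self):
        rng = np.random.default_rng(19)
        df = pd.DataFrame(
            {"ovarioles_int": rng.poisson(20, 200), "x": rng.normal(size=200)}
        )
        res, a, b = bootstrap_r2_compare(df, [(), ("x",)], df, [(), ("x",)], n_boot=120, seed=4)
        assert res.p > 0.05

    def test_small_n_boot_rejected(self):
        df = pd.DataFrame({"ovarioles_int": [20] * 10, "x": np.arange(10.0)})
        with pytest.raises(ValueError):
            bootstrap_r2_compare(df, [()], df, [()], n_boot=50)

    def test_stronger_effect_detected(self):
        rng = np.random.default_rng(23)
        n = 300
        x = rng.normal(size=n)
        weak = pd.DataFrame({"x": x, "ovarioles_int": rng.poisson(np.exp(3 + 0.05 * x))})
        strong = pd.DataFrame({"x": x, "ovarioles_int": rng.poisson(np.exp(3 + 0.3 * x))})
        res, _, _ = bootstrap_r2_compare(
            weak, [(), ("x",)], strong, [(), ("x",)], n_boot=150, seed=5
        )
        assert res.p < 0.05
        assert res.statistic < 0  # weak dataset explains less


class TestHdSummary:
    def test_all_healthy_zero_dysgenic_fraction(self):
        recs = synth.simulate_phenotypes(
            [synth.DesignCell("P", "F", 10.0, 16.0, 23.0, 50)],
            {
                "ovary0": {("1",): -30.0},
                "ovary1": {("1",): -30.0},
                "ovarioles": {("1",): math.log(20)},
            },
            seed=1,
        )
        summary = hdstats.hd_summary(phenotypes_to_frame(recs))
        assert summary["dysgenic_fraction"].iloc[0] == 0.0

    def test_fraction_arithmetic(self):
        rows = []
        for i in range(50):
            oc = 1 if i < 10 else 2
            rows.append(
                {
                    "mother_genotype": "M",
                    "father_type": "P",
                    "temperature": 29.0,
                    "ovary_count": oc,
                    "mean_ovarioles": 20.0,
                }
            )
        df = pd.DataFrame(rows)
        summary = hdstats.hd_summary(df)
        assert summary["dysgenic_fraction"].iloc[0] == pytest.approx(0.2)
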
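"""Correlation/regression statistics, HOMA, and parent-of-origin rules."""

import numpy as np
import pandas as pd
import pytest

from lipidpoe.association import (AssociationResult, PoeContrastSet,
                                  adjusted_regression, correlate,
                                  correlation_pvalue, homa, logistic,
                                  maternal_transmission_enrichment,
                                  poe_classify, summary_group_test)


class TestCorrelate:
    @pytest.mark.parametrize("r,n,expected,tol", [
        (0.12, 475, 8.8e-3, 0.05e-3),     # published cohort-level value
        (0.257, 161, 1.0e-3, 0.05e-3),    # prints 9.7e-4 from unrounded r
        (0.167, 183, 0.0237, 5e-4),
    ])
    def test_p_from_printed_r_n(self, r, n, expected, tol):
        assert correlation_pvalue(r, n) == pytest.approx(expected, abs=tol)

    def test_orthogonal_gives_p_one(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = correlate(x, y)
        assert res.r == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_magnitude_and_sign(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        res = correlate(x, -2 * x + rng.normal(size=50))
        assert res.sign == -1 and 0 < res.r <= 1
        assert res.signed_r == -res.r

    def test_mask_propagates_to_n(self):
        x = np.array([1.0, 2, 3, np.nan, 5, 6])
        y = np.arange(6, dtype=float)
        assert correlate(x, y).n == 5

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero variance"):
            correlate(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="complete pairs"):
            correlate([1.0, 2.0], [1.0, 2.0])


class TestAdjustedRegression:
    def test_equals_correlate_without_covariates(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        a = correlate(x, y)
        b = adjusted_regression(y, x)
        assert b.p == pytest.approx(a.p, abs=1e-10)
        assert abs(b.beta_std) == pytest.approx(a.r, abs=1e-10)

    def test_noiseless_partial_relation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 2 * x + 3 * z
        res = adjusted_regression(y, x, pd.DataFrame({"z": z}))
        assert res.p < 1e-12
        assert res.beta_std == pytest.approx(2 * x.std(ddof=1) / y.std(ddof=1),
                                             rel=1e-9)

    def test_slope_recovery_simulation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=500)
        y = 0.3 * x + rng.normal(size=500)
        res = adjusted_regression(y, x)
        slope = res.beta_std * y.std(ddof=1) / x.std(ddof=1)
        se = 1 / np.sqrt(500)
        assert abs(slope - 0.3) < 3 * se

    def test_rank_deficiency(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            adjusted_regression(x, x, pd.DataFrame({"dup": x}))


class TestLogistic:
    def test_two_by_two_closed_form(self):
        # a=40, b=10, c=20, d=20 -> OR = ad/bc = 4
        x = np.repeat([1, 1, 0, 0], [40, 10, 20, 20])
        y = np.repeat([1, 0, 1, 0], [40, 10, 20, 20])
        or_, ci, p = logistic(y, x)
        assert or_ == pytest.approx(4.0, rel=1e-6)
        assert ci[0] < 4.0 < ci[1]

    def test_reparameterization(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        y = rng.binomial(1, 1 / (1 + np.exp(-x)))
        or1 = np.log(logistic(y, x)[0])
        or2 = np.log(logistic(y, 2 * x)[0])
        assert or1 == pytest.approx(2 * or2, rel=1e-6)

    def test_null_ci_coverage(self):
        rng = np.random.default_rng(6)
        cover = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=120)
            y = rng.binomial(1, 0.4, 120)
            try:
                _, (lo, hi), _ = logistic(y, x)
            except ValueError:
                continue
            cover += lo <= 1.0 <= hi
        assert abs(cover / reps - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps) + 0.01

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            logistic(np.ones(10), np.arange(10.0))


class TestHoma:
    def test_closed_form(self):
        ir, b = homa(4.3, 45.6)
        assert ir == pytest.approx(4.3 * (45.6 / 6.945) / 22.5, rel=1e-12)
        assert ir == pytest.approx(1.25, abs=0.01)
        assert b == pytest.approx(20 * (45.6 / 6.945) / 0.8, rel=1e-12)

    def test_linearity_in_insulin(self):
        ir1, _ = homa(5.0, 40.0)
        ir2, _ = homa(5.0, 80.0)
        assert ir2 == pytest.approx(2 * ir1)
        assert homa(5.0, 0.0)[0] == 0.0

    def test_monotone_in_insulin(self):
        ins = np.linspace(1, 200, 50)
        ir, _ = homa(np.full(50, 4.5), ins)
        assert (np.diff(ir) > 0).all()

    def test_low_glucose_b_undefined(self):
        _, b = homa(3.2, 50.0)
        assert np.isnan(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            homa(0.0, 50.0)


class TestSummaryGroupTest:
    def test_gestational_age_row(self):
        """Printed cohort summaries (40.1 wk vs 39.8 wk) give p ~= 0.02."""
        z, p = summary_group_test(40.1, (39.9, 40.3), 200,
                                  39.8, (39.7, 40.0), 567)
        assert p == pytest.approx(0.0187, abs=1e-3)

    def test_identical_groups(self):
        z, p = summary_group_test(5.0, (4.8, 5.2), 100, 5.0, (4.8, 5.2), 100)
        assert z == 0.0 and p == 1.0

    def test_bmi_row_nonsignificant(self):
        _, p = summary_group_test(23.9, (23.2, 24.6), 200,
                                  24.2, (23.8, 24.6), 567)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_zero_se(self):
        with pytest.raises(ValueError):
            summary_group_test(1.0, (1.0, 1.0), 5, 2.0, (2.0, 2.0), 5)


def assoc(r, p, sign=1):
    return AssociationResult("snp", "lipid", r, sign, p, 100)


class TestPoeClassify:
    def test_imprinted_maternal_pattern(self):
        """The published rs7131362/TG(44:1) pattern: strong maternal
        transmission, null paternal, weaker maternal-genome contrasts."""
        cs = PoeContrastSet("snp", "lipid",
                            maternal_transmitted=assoc(0.257, 9.7e-4),
                            paternal_transmitted=assoc(0.05, 0.57),
                            maternal_genotype=assoc(0.222, 2.9e-3),
                            maternal_untransmitted=assoc(0.119, 0.14))
        assert poe_classify(cs) == "fetal-effect-imprinted-maternal"

    def test_biallelic_pattern(self):
        cs = PoeContrastSet("snp", "lipid",
                            maternal_transmitted=assoc(0.09, 0.04),
                            paternal_transmitted=assoc(0.14, 2.3e-3))
        assert poe_classify(cs) == "fetal-biallelic"

    def test_imprinted_paternal_pattern(self):
        cs = PoeContrastSet("snp", "lipid",
                            maternal_transmitted=assoc(0.03, 0.7),
                            paternal_transmitted=assoc(0.2, 0.001),
                            maternal_genotype=assoc(0.05, 0.5),
                            maternal_untransmitted=assoc(0.02, 0.9))
        assert poe_classify(cs) == "fetal-effect-imprinted-paternal"

    def test_maternal_mediated(self):
        cs = PoeContrastSet("snp", "lipid",
                            maternal_transmitted=assoc(0.10, 0.2),
                            paternal_transmitted=assoc(0.02, 0.8),
                            maternal_genotype=assoc(0.25, 0.001),
                            maternal_untransmitted=assoc(0.20, 0.01))
        assert poe_classify(cs) == "maternal-mediated"

    def test_indeterminate(self):
        cs = PoeContrastSet("snp", "lipid",
                            maternal_transmitted=assoc(0.05, 0.5),
                            paternal_transmitted=assoc(0.04, 0.6))
        assert poe_classify(cs) == "indeterminate"
        assert cs.rationale

    def test_requires_transmitted_contrast(self):
        with pytest.raises(ValueError):
            poe_classify(PoeContrastSet("snp", "lipid"))


class TestEnrichment:
    def test_eleven_of_twelve(self):
        rows = [{"transmission": "maternal"}] * 11 + \
            [{"transmission": "paternal"}]
        res = maternal_transmission_enrichment(rows)
        assert res["p_two_sided"] == pytest.approx(2 * 13 / 4096, rel=1e-9)
        assert res["p_one_sided"] == pytest.approx(13 / 4096, rel=1e-9)

    def test_balanced(self):
        rows = [{"transmission": t} for t in ["maternal", "paternal"] * 6]
        assert maternal_transmission_enrichment(rows)["p_two_sided"] == 1.0

    def test_all_maternal(self):
        rows = [{"transmission": "maternal"}] * 12
        res = maternal_transmission_enrichment(rows)
        assert res["p_two_sided"] == pytest.approx(2 * 2 ** -12, rel=1e-9)

    def test_empty(self):
        with pytest.raises(ValueError):
            maternal_transmission_enrichment([])


def test_type_one_error_under_null():
    """Under the no-effect null, the correlate test rejects at ~5 %
    (151 SNP-like predictors x 2 transmissions x 20 replicates)."""
    rng = np.random.default_rng(17)
    reps = 151 * 2 * 20
    n = 150
    x = rng.binomial(1, 0.4, size=(reps, n)).astype(float)
    y = rng.normal(size=(reps, n))
    rejections = sum(correlate(x[i], y[i]).p < 0.05 for i in range(reps))
    rate = rejections / reps
    assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
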
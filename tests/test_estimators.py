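"""ICC estimators, variance components, population ICCs and the bias F-test."""

import numpy as np
import pytest

from iccsim import (
    AnovaTable,
    ModelParams,
    ScoreMatrix,
    analyze,
    bias_f_test,
    biased_icc1_expectation,
    compute_anova,
    expected_bias_f,
    icc1,
    icc_a1,
    icc_a1_alternative,
    icc_c1,
    population_icc,
    qualitative_band,
    variance_components,
)
from iccsim.exceptions import DegenerateInputError, InvalidInputError


def _anova_from_ms(n, k, msbs, msws, msbm, mse):
    """Assemble an AnovaTable directly from mean squares (for formula checks
    on quoted MS values).  MSWM is filled in via SSWM = SSBS + SSE."""
    ss_bs = msbs * (n - 1)
    ss_ws = msws * n * (k - 1)
    ss_bm = msbm * (k - 1)
    ss_e = mse * (n - 1) * (k - 1)
    return AnovaTable(
        n=n,
        k=k,
        ss_total=ss_bs + ss_bm + ss_e,
        ss_between_subjects=ss_bs,
        ss_within_subjects=ss_ws,
        ss_between_measurements=ss_bm,
        ss_within_measurements=ss_bs + ss_e,
        ss_error=ss_e,
    )


class TestSampleIccFormulas:
    def test_emg_values(self, emg_anova):
        """Clinical example: ICC(1)=0.706, ICC(A,1)=0.708, ICC(C,1)=0.720."""
        assert icc1(emg_anova).value == pytest.approx(0.706, abs=0.001)
        assert icc_a1(emg_anova).value == pytest.approx(0.708, abs=0.001)
        assert icc_c1(emg_anova).value == pytest.approx(0.720, abs=0.001)

    def test_quoted_ms_reference_values(self):
        """Formulas applied to the quoted mean squares alone."""
        a = _anova_from_ms(10, 3, 212.61, 25.92, 39.15, 24.45)
        assert icc1(a).value == pytest.approx(0.706, abs=0.001)

    def test_tiny_matrix_hand_arithmetic(self, tiny_anova):
        """[[1,2],[3,4]]: ICC(1)=7/9, ICC(A,1)=0.8, ICC(C,1)=1 (MSE=0)."""
        assert icc1(tiny_anova).value == pytest.approx((4 - 0.5) / (4 + 0.5))
        assert icc_a1(tiny_anova).value == pytest.approx(0.8)
        assert icc_c1(tiny_anova).value == pytest.approx(1.0)

    def test_error_free_measurements_give_unity(self):
        a = _anova_from_ms(8, 3, 5.0, 0.0, 0.0, 0.0)
        assert icc1(a).value == pytest.approx(1.0)
        assert icc_c1(a).value == pytest.approx(1.0)

    def test_consistency_reference_value(self):
        a = _anova_from_ms(5, 2, 4.0, 1.0, 1.0, 1.0)
        assert icc_c1(a).value == pytest.approx(0.6)

    def test_a1_equals_c1_when_msbm_equals_mse(self):
        a = _anova_from_ms(7, 4, 9.0, 2.0, 2.0, 2.0)
        assert icc_a1(a).value == pytest.approx(icc_c1(a).value)

    def test_constant_matrix_degenerate(self):
        a = compute_anova(np.full((5, 3), 7.0))
        for fn in (icc1, icc_a1, icc_c1):
            with pytest.raises(DegenerateInputError):
                fn(a)

    def test_negative_icc_reported_unchanged(self):
        """MSBS < MSWS yields a negative ICC(1), returned as-is."""
        a = _anova_from_ms(6, 3, 1.0, 2.0, 2.0, 2.0)
        assert icc1(a).value < 0
        assert icc1(a).value >= -1 / (a.k - 1)

    def test_alternative_a1_identity(self, emg_anova, tiny_anova, rng):
        """The MSWM-based rewriting equals the standard ICC(A,1) everywhere."""
        assert icc_a1_alternative(emg_anova) == pytest.approx(
            icc_a1(emg_anova).value, rel=1e-9
        )
        assert icc_a1_alternative(tiny_anova) == pytest.approx(0.8, rel=1e-9)
        for _ in range(20):
            a = compute_anova(rng.normal(50, 10, (20, 3)))
            assert icc_a1_alternative(a) == pytest.approx(
                icc_a1(a).value, rel=1e-9
            )

    def test_c1_vs_a1_ordering_follows_msbm_vs_mse(self, rng):
        """ICC(A,1) differs from ICC(C,1) only through the (k/n)(MSBM-MSE)
        denominator term, so with a positive numerator C >= A iff
        MSBM >= MSE (the ordering flips when MSBS < MSE)."""
        for _ in range(50):
            a = compute_anova(rng.normal(0, 5, (8, 4)))
            c, a1 = icc_c1(a).value, icc_a1(a).value
            if a.msbs >= a.mse:
                assert (c >= a1) == (a.msbm >= a.mse)
            else:
                assert (c <= a1) == (a.msbm >= a.mse)

    def test_pingouin_cross_check(self, emg_matrix):
        """Independent oracle: pingouin's ICC1/ICC2/ICC3 single-score values."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n, k = emg_matrix.n, emg_matrix.k
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), k),
                "rater": np.tile(np.arange(k), n),
                "score": emg_matrix.values.ravel(),
            }
        )
        res = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        a = compute_anova(emg_matrix)
        assert icc1(a).value == pytest.approx(res.loc["ICC(1,1)", "ICC"], abs=1e-6)
        assert icc_a1(a).value == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-6)
        assert icc_c1(a).value == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-6)


class TestVarianceComponents:
    def test_emg_oneway(self, emg_anova):
        vc = variance_components(emg_anova, model="oneway")
        assert vc.sigma_r == pytest.approx(7.89, abs=0.01)
        assert vc.sigma_v == pytest.approx(5.09, abs=0.01)
        assert vc.sigma_c is None

    def test_emg_twoway(self, emg_anova):
        vc = variance_components(emg_anova, model="twoway")
        assert vc.sigma_r == pytest.approx(7.92, abs=0.01)
        assert vc.sigma_v == pytest.approx(4.94, abs=0.01)
        assert vc.sigma_c == pytest.approx(1.21, abs=0.01)

    def test_negative_component_flagged_not_truncated(self):
        a = _anova_from_ms(6, 3, 1.0, 2.0, 2.0, 2.0)
        vc = variance_components(a, model="oneway")
        assert vc.sigma_r2 < 0
        assert vc.negative["sigma_r2"]
        assert np.isnan(vc.sigma_r)


class TestBiasFTest:
    def test_emg_f_and_p(self, emg_anova):
        t = bias_f_test(emg_anova)
        assert t.F == pytest.approx(1.601, abs=0.005)
        assert t.p_value == pytest.approx(0.229, abs=0.005)
        assert not t.reject
        assert (t.df1, t.df2) == (2, 18)

    def test_f_is_one_when_msbm_equals_mse(self):
        a = _anova_from_ms(10, 3, 5.0, 2.0, 2.0, 2.0)
        assert bias_f_test(a).F == pytest.approx(1.0)

    def test_zero_mse_degenerate(self, tiny_anova):
        with pytest.raises(DegenerateInputError):
            bias_f_test(tiny_anova)

    def test_expected_f_closed_form(self):
        """Expected F = 1 + n (sigma_c/sigma_v)^2: 21 for n=20, sigma_c=sigma_v."""
        p = ModelParams(model=2, n=20, k=3, sigma_v=5, sigma_c=5)
        assert expected_bias_f(p) == pytest.approx(21.0)


class TestPopulationIcc:
    def test_oneway_value(self):
        p = ModelParams(model=1, n=20, k=3, sigma_r=10, sigma_v=5)
        assert population_icc(p) == pytest.approx(0.8)

    def test_twoway_random_absolute(self):
        p = ModelParams(model=2, n=20, k=3, sigma_r=10, sigma_c=5, sigma_v=5)
        assert population_icc(p, "absolute") == pytest.approx(100 / 150)

    def test_fixed_bias_spread_and_icc(self):
        p = ModelParams(model=3, n=20, k=3, sigma_r=10, sigma_v=5,
                        fixed_biases=(1, 6, -1))
        assert p.theta_c2 == pytest.approx(13.0)
        assert population_icc(p, "absolute") == pytest.approx(0.725, abs=0.0005)

    def test_consistency_ignores_bias(self):
        p2 = ModelParams(model=2, n=20, k=3, sigma_r=10, sigma_c=10, sigma_v=5)
        p3 = ModelParams(model=3, n=20, k=3, sigma_r=10, sigma_v=5,
                         fixed_biases=(10, 6, -10))
        assert population_icc(p2, "consistency") == pytest.approx(0.8)
        assert population_icc(p3, "consistency") == pytest.approx(0.8)

    def test_zero_bias_reduces_to_oneway(self):
        p2 = ModelParams(model=2, n=20, k=3, sigma_r=10, sigma_c=0, sigma_v=5)
        p1 = ModelParams(model=1, n=20, k=3, sigma_r=10, sigma_v=5)
        assert population_icc(p2, "absolute") == pytest.approx(population_icc(p1))

    def test_monotone_in_noise_and_bias(self):
        vals_v = [
            population_icc(ModelParams(model=1, n=10, k=3, sigma_r=10, sigma_v=sv))
            for sv in (1, 5, 10, 20)
        ]
        assert vals_v == sorted(vals_v, reverse=True)
        vals_c = [
            population_icc(ModelParams(model=2, n=10, k=3, sigma_r=10,
                                       sigma_v=5, sigma_c=sc))
            for sc in (0, 2, 5, 10)
        ]
        assert vals_c == sorted(vals_c, reverse=True)

    def test_all_zero_variances_degenerate(self):
        p = ModelParams(model=1, n=5, k=3, sigma_r=0, sigma_v=0)
        with pytest.raises(DegenerateInputError):
            population_icc(p)

    def test_params_validation(self):
        with pytest.raises(InvalidInputError):
            ModelParams(model=3, n=5, k=3, sigma_v=5, fixed_biases=(1, 2))
        with pytest.raises(InvalidInputError):
            ModelParams(model=1, n=5, k=3, sigma_v=5, sigma_c=2)
        with pytest.raises(InvalidInputError):
            ModelParams(model=4, n=5, k=3, sigma_v=5)


class TestBiasedIcc1Expectation:
    def test_reduces_to_population_icc_without_bias(self):
        p = ModelParams(model=2, n=20, k=3, sigma_r=10, sigma_c=0, sigma_v=5)
        assert biased_icc1_expectation(p) == pytest.approx(0.8)

    def test_hand_arithmetic(self):
        p = ModelParams(model=2, n=20, k=3, sigma_r=10, sigma_c=10, sigma_v=5)
        expected = (100 - 100 / 3) / (225 - 100 / 3)
        assert biased_icc1_expectation(p) == pytest.approx(expected)
        assert expected == pytest.approx(0.3478, abs=0.0001)


class TestQualitativeBands:
    @pytest.mark.parametrize(
        "icc,band",
        [
            (-0.2, "poor"),
            (0.49, "poor"),
            (0.5, "moderate"),
            (0.75, "moderate"),
            (0.76, "good"),
            (0.9, "good"),
            (0.95, "excellent"),
        ],
    )
    def test_band_boundaries(self, icc, band):
        assert qualitative_band(icc) == band


class TestAnalyze:
    def test_emg_report(self, emg_matrix):
        r = analyze(emg_matrix)
        assert r.conclusion == "no_bias"
        assert r.ratio_c_over_a == pytest.approx(1.017, abs=0.002)
        assert not r.ratio_flags_bias
        d = r.to_dict()
        assert "icc1" in d  # reported because no bias was detected
        assert d["qualitative_bands"]["ICC_A1"] == "moderate"

    def test_icc1_suppressed_under_bias(self, rng):
        """A matrix with strong fixed column biases triggers the bias
        conclusion and drops ICC(1) from the report."""
        p = ModelParams(model=3, n=20, k=3, sigma_r=10, sigma_v=5,
                        fixed_biases=(10, 6, -10))
        from iccsim import simulate_matrix

        r = analyze(simulate_matrix(p, rng))
        assert r.conclusion == "bias_present"
        assert "icc1" not in r.to_dict()

    def test_f_test_power_against_strong_fixed_bias(self):
        """With c=(10,6,-10), n=20, the bias F-test rejects in the large
        majority of replicates."""
        from iccsim import run_simulation
        from scipy import stats

        p = ModelParams(model=3, n=20, k=3, sigma_r=10, sigma_v=5,
                        fixed_biases=(10, 6, -10))
        res = run_simulation(p, n_replicates=1000, seed=11)
        crit = stats.f.ppf(0.95, 2, 19 * 2)
        assert (res.f_values > crit).mean() > 0.9

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateInputError):
            analyze(np.full((5, 3), 7.0))

    def test_model2_and_model3_same_sample_iccs(self, rng):
        """Two-way random and two-way mixed are the same computation on any
        fixed matrix: the sample ICCs depend only on the numbers."""
        x = rng.normal(100, 10, (15, 3)) + np.array([4.0, -2.0, 1.0])
        a = compute_anova(x)
        # both model readings use the identical formulas on the same table
        assert icc_a1(a).value == icc_a1(compute_anova(x.copy())).value
        vc = variance_components(a, model="twoway")
        assert vc.sigma_c2 == pytest.approx((a.msbm - a.mse) / 15)

    def test_summary_contains_key_numbers(self, emg_matrix):
        text = analyze(emg_matrix).summary()
        assert "0.706" in text and "0.708" in text and "0.720" in text
        assert "no bias" in text
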
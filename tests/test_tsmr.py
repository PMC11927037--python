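"""Two-sample MR estimators, heterogeneity/pleiotropy diagnostics, recommendation rule."""

import numpy as np
import pytest

from conftest import make_pairs
from mrcascade.tsmr import (
    InsufficientInstrumentsError,
    TwoSampleMR,
    cochran_q,
    egger,
    egger_bootstrap,
    ivw,
    sensitivity_suite,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,beta,se",
        [(1.0, 0.5, 0.1, 0.5, 0.1), (2.0, 1.0, 0.2, 0.5, 0.1), (-1.0, 0.5, 0.1, -0.5, 0.1)],
    )
    def test_ratio_and_first_order_se(self, bx, by, sy, beta, se):
        est = wald_ratio(make_pairs([bx], [by], [sy]))
        assert est.beta == pytest.approx(beta)
        assert est.se == pytest.approx(se)

    def test_requires_exactly_one_instrument(self):
        with pytest.raises(InsufficientInstrumentsError):
            wald_ratio(make_pairs([1, 1], [0.5, 0.5], 0.1))


class TestIVW:
    def test_equal_weight_average_of_ratios(self):
        est = ivw(make_pairs([1.0, 1.0], [0.5, 1.0], 0.1), "fixed")
        assert est.beta == pytest.approx(0.75)

    def test_identical_ratios_give_zero_dispersion(self):
        pairs = make_pairs([1.0, 2.0, 0.5], [0.7, 1.4, 0.35], [0.1, 0.1, 0.1])
        fixed = ivw(pairs, "fixed")
        mre = ivw(pairs, "mre")
        q, p_q = cochran_q(pairs)
        assert fixed.beta == pytest.approx(0.7)
        assert mre.beta == pytest.approx(0.7)
        assert mre.se == pytest.approx(0.0, abs=1e-10)  # MRE scale not floored at 1
        assert q == pytest.approx(0.0, abs=1e-20)
        assert p_q == pytest.approx(1.0)

    def test_matches_weighted_least_squares_oracle(self, rng):
        """IVW equals the statsmodels WLS solution through the origin to 1e-10."""
        import statsmodels.api as sm

        for _ in range(25):
            k = 50
            bx = rng.normal(0.2, 0.05, k)
            sy = rng.uniform(0.05, 0.2, k)
            by = 1.3 * bx + rng.normal(0, sy)
            pairs = make_pairs(bx, by, sy)
            fit = sm.WLS(by, bx, weights=1 / sy**2).fit()
            est_f = ivw(pairs, "fixed")
            est_m = ivw(pairs, "mre")
            assert est_f.beta == pytest.approx(fit.params[0], abs=1e-10)
            assert est_m.beta == pytest.approx(fit.params[0], abs=1e-10)
            # statsmodels' default WLS SE is exactly the multiplicative-random-effects SE
            assert est_m.se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_fixed_equals_weighted_mean_of_ratios(self, rng):
        bx = rng.normal(0.3, 0.05, 20)
        sy = rng.uniform(0.05, 0.2, 20)
        by = 0.8 * bx + rng.normal(0, sy)
        pairs = make_pairs(bx, by, sy)
        ratio = by / bx
        w = (bx / sy) ** 2
        assert ivw(pairs, "fixed").beta == pytest.approx(np.sum(w * ratio) / np.sum(w), rel=1e-12)


class TestEgger:
    def test_recovers_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.1 + 0.5 * bx
        est = egger(make_pairs(bx, by, 0.1))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_orientation_by_exposure_sign(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        by = 0.1 * np.sign(bx) * 0 + 0.5 * bx  # no pleiotropy, mixed signs
        est = egger(make_pairs(bx, 0.5 * bx, 0.1))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_bootstrap_is_seed_deterministic(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.05 + 0.4 * bx
        pairs = make_pairs(bx, by + [0.01, -0.02, 0.005, 0.0, -0.01], 0.08)
        e1 = egger_bootstrap(pairs, n_boot=200, seed=11)
        e2 = egger_bootstrap(pairs, n_boot=200, seed=11)
        assert (e1.beta, e1.se) == (e2.beta, e2.se)
        e3 = egger_bootstrap(pairs, n_boot=1, seed=11)
        assert np.isfinite(e3.beta)

    def test_intercept_test_calibrated_under_no_pleiotropy(self, rng):
        n, k, rej = 3000, 30, 0
        for _ in range(n):
            bx = rng.uniform(0.1, 0.25, k)
            sy = np.full(k, 0.1)
            by = 0.5 * bx + rng.normal(0, sy)
            rej += egger(make_pairs(bx, by, sy)).extras["p_intercept"] < 0.05
        assert abs(rej / n - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_pairs([0.1, 0.2], [0.05, 0.1], 0.1))


class TestWeightedMedian:
    def test_interpolation_formula_on_three_ratios(self):
        # equal weights: cumulative standardized weights are (1/6, 1/2, 5/6),
        # so the 0.5 point lands exactly on the middle ratio
        est = weighted_median(make_pairs([1.0, 1.0, 1.0], [0.4, 0.5, 10.0], 0.1), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_constant_ratios_recovered(self):
        est = weighted_median(make_pairs([0.5, 1.0, 2.0], [0.35, 0.7, 1.4], [0.1, 0.2, 0.1]), n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7)

    def test_robust_to_single_outlier_where_ivw_is_not(self, rng):
        k = 20
        bx = rng.uniform(0.2, 0.4, k)
        sy = np.full(k, 0.01)
        by = 0.5 * bx + rng.normal(0, sy)
        by[0] = 5.0 * bx[0]  # one wildly pleiotropic instrument
        pairs = make_pairs(bx, by, sy)
        wm = weighted_median(pairs, n_boot=100, seed=3)
        assert abs(wm.beta - 0.5) < 0.05
        assert abs(ivw(pairs, "mre").beta - 0.5) > 0.05


class TestCochranQ:
    def test_hand_evaluated_two_instrument_case(self):
        # ratios 0 and 1 with unit ratio-SEs: Q = (0-0.5)^2 + (1-0.5)^2 = 0.5
        pairs = make_pairs([1.0, 1.0], [0.0, 1.0], 1.0)
        q, _ = cochran_q(pairs)
        assert q == pytest.approx(0.5, rel=1e-12)

    def test_null_expectation_is_degrees_of_freedom(self, rng):
        k, reps = 10, 800
        qs = []
        for _ in range(reps):
            bx = rng.uniform(0.2, 0.4, k)
            sy = np.full(k, 0.05)
            by = 0.7 * bx + rng.normal(0, sy)
            qs.append(cochran_q(make_pairs(bx, by, sy))[0])
        assert np.mean(qs) / (k - 1) == pytest.approx(1.0, abs=0.1)


class TestSensitivitySuite:
    def _simulate(self, rng, pleiotropy=0.0, het=1.0, k=30):
        bx = rng.uniform(0.1, 0.3, k)
        sy = np.full(k, 0.02)
        by = 1.8 * bx + pleiotropy + rng.normal(0, het * sy)
        return make_pairs(bx, by, sy)

    def test_clean_data_recommends_primary_ivw_mre(self, rng):
        rep = sensitivity_suite(self._simulate(rng), seed=0, n_boot=100)
        assert rep.recommended_method == "ivw_mre"

    def test_directional_pleiotropy_recommends_egger_bootstrap(self, rng):
        hits = 0
        for s in range(10):
            rep = sensitivity_suite(self._simulate(rng, pleiotropy=0.05), seed=s, n_boot=100)
            hits += rep.recommended_method == "egger_bootstrap"
        assert hits >= 8

    def test_balanced_heterogeneity_recommends_ivw_mre(self, rng):
        hits = 0
        for s in range(10):
            rep = sensitivity_suite(self._simulate(rng, het=6.0), seed=s, n_boot=100)
            hits += rep.recommended_method == "ivw_mre" and rep.p_q < 0.05
        assert hits >= 8

    def test_report_contains_all_five_methods(self, rng):
        rep = sensitivity_suite(self._simulate(rng), seed=0, n_boot=50)
        assert set(rep.estimates) == {
            "ivw_fixed", "ivw_mre", "egger", "egger_bootstrap", "weighted_median"
        }
        assert rep.recommended_method in rep.estimates


class TestEquivariance:
    @pytest.mark.parametrize("method", ["ivw_fixed", "ivw_mre", "egger", "weighted_median"])
    def test_outcome_sign_flip_negates_estimate(self, rng, method):
        bx = rng.uniform(0.1, 0.3, 12)
        sy = rng.uniform(0.02, 0.05, 12)
        by = 0.9 * bx + rng.normal(0, sy)
        model_pos = TwoSampleMR(make_pairs(bx, by, sy))
        model_neg = TwoSampleMR(make_pairs(bx, -by, sy))
        kw = {"seed": 5, "n_boot": 100} if method == "weighted_median" else {}
        e1, e2 = model_pos.fit(method, **kw), model_neg.fit(method, **kw)
        assert e1.beta == pytest.approx(-e2.beta, rel=1e-9)
        # bootstrap SEs match only up to Monte-Carlo noise
        se_tol = 0.1 if method == "weighted_median" else 1e-6
        assert e1.se == pytest.approx(e2.se, rel=se_tol)
        q1, q2 = model_pos.heterogeneity(), model_neg.heterogeneity()
        assert q1[0] == pytest.approx(q2[0], rel=1e-9)

    def test_model_single_instrument_falls_back_to_wald(self):
        model = TwoSampleMR(make_pairs([2.0], [1.0], [0.2]))
        est = model.fit("ivw_mre")
        assert est.method == "wald_ratio"
        assert est.beta == pytest.approx(0.5)
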
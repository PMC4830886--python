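"""Quantal model forms, likelihood, goodness of fit and BMC inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devtoxrank.quantal import (
    MODEL_NAMES,
    DRModelSpec,
    FitResult,
    QuantalDataset,
    binomial_loglik,
    bmc_from_fit,
    goodness_of_fit,
    model_response,
    select_bmc,
)
from devtoxrank.quantal import GofReport, _param_names


def make_fit(name, params, degree=None, max_dose=60.0, restricted=False):
    spec = DRModelSpec(name, degree=degree, restricted=restricted)
    params = np.asarray(params, float)
    return FitResult(spec, params, _param_names(spec), 0.0, True, len(params), max_dose)


class TestModelResponse:
    def test_quantal_linear_zero_dose_zero_background(self):
        assert model_response(DRModelSpec("quantal_linear"), [0.0, 0.1], 0.0) == 0.0

    def test_quantal_linear_half_life_dose(self):
        d = np.log(2) / 0.1
        assert model_response(DRModelSpec("quantal_linear"), [0.0, 0.1], d) == pytest.approx(0.5)

    def test_loglogistic_hand_evaluation(self):
        got = model_response(
            DRModelSpec("loglogistic", restricted=False), [0.1, 0.0, 1.0], 1.0
        )
        assert got == pytest.approx(0.55)

    def test_out_of_bounds_params_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            model_response(DRModelSpec("quantal_linear"), [-0.2, 0.1], 1.0)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_background_returned_at_zero_dose(self, name):
        """Every model form returns its background response at d=0."""
        params = {
            "logistic": [-2.0, 0.3],
            "probit": [-1.5, 0.2],
            "loglogistic": [0.07, -1.0, 1.5],
            "logprobit": [0.07, -1.0, 1.5],
            "weibull": [0.07, 1.2, 0.1],
            "gamma": [0.07, 2.0, 0.3],
            "quantal_linear": [0.07, 0.1],
            "multistage": [0.07, 0.05, 0.002],
        }[name]
        degree = 2 if name == "multistage" else None
        p0 = model_response(DRModelSpec(name, degree=degree), params, 0.0)
        if name == "logistic":
            expected = 1 / (1 + np.exp(2.0))
        elif name == "probit":
            from scipy.special import ndtr

            expected = ndtr(-1.5)
        else:
            expected = 0.07
        assert p0 == pytest.approx(expected)

    @given(
        name=st.sampled_from(MODEL_NAMES),
        draw=st.tuples(*[st.floats(0.0, 1.0) for _ in range(4)]),
        d=st.floats(0.0, 1e3),
    )
    @settings(max_examples=300, deadline=None)
    def test_probabilities_stay_in_unit_interval(self, name, draw, d):
        """Admissible parameters can never push the response out of [0,1]."""
        from devtoxrank.quantal import _bounds

        degree = 3 if name == "multistage" else None
        spec = DRModelSpec(name, degree=degree, restricted=False)
        bounds = _bounds(spec)
        params = [
            lo + (min(hi, 50.0) - lo) * u for (lo, hi), u in zip(bounds, draw)
        ]
        p = model_response(spec, params, d)
        assert 0.0 <= p <= 1.0


class TestBinomialLoglik:
    def test_direct_evaluation_single_group(self):
        data = QuantalDataset("x", [0.0, 1.0], [2, 2], [0, 1])
        # group p's: quantal_linear g=0 -> p(0)=0 contributes ~0; p(1)=0.5
        b = np.log(2)
        ll = binomial_loglik(DRModelSpec("quantal_linear"), [0.0, b], data)
        assert ll == pytest.approx(np.log(0.25), abs=1e-6)

    def test_clamped_never_infinite(self):
        data = QuantalDataset("x", [0.0, 1.0], [10, 10], [5, 5])
        ll = binomial_loglik(DRModelSpec("quantal_linear"), [0.0, 1e-8], data)
        assert np.isfinite(ll) and ll < -20

    def test_bounded_by_saturated_model(self, rng):
        """No parameter vector can beat the saturated likelihood p = y/n."""
        d = np.array([0.0, 1.0, 3.0, 10.0, 30.0])
        n = np.full(5, 24)
        y = np.array([1, 3, 8, 15, 22])
        data = QuantalDataset("x", d, n, y)
        phat = y / n
        sat = np.sum(
            y * np.log(np.clip(phat, 1e-12, 1))
            + (n - y) * np.log(np.clip(1 - phat, 1e-12, 1))
        )
        spec = DRModelSpec("weibull", restricted=False)
        for _ in range(50):
            params = [rng.uniform(0, 0.5), rng.uniform(0.1, 5), rng.uniform(0.01, 1)]
            assert binomial_loglik(spec, params, data) <= sat + 1e-9


class TestBMC:
    def test_quantal_linear_closed_form(self):
        fit = make_fit("quantal_linear", [0.0, 0.1])
        assert bmc_from_fit(fit, 0.5) == pytest.approx(np.log(2) / 0.1)

    def test_loglogistic_closed_form(self):
        fit = make_fit("loglogistic", [0.0, -2.0, 1.0])
        assert bmc_from_fit(fit, 0.5) == pytest.approx(np.exp(2.0))

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_bmr_monotonicity(self, name):
        """Higher benchmark response always needs a higher concentration."""
        params = {
            "logistic": [-3.0, 0.3],
            "probit": [-2.0, 0.2],
            "loglogistic": [0.05, -2.0, 1.5],
            "logprobit": [0.05, -1.5, 1.0],
            "weibull": [0.05, 1.3, 0.05],
            "gamma": [0.05, 2.0, 0.3],
            "quantal_linear": [0.05, 0.1],
            "multistage": [0.05, 0.02, 0.001],
        }[name]
        fit = make_fit(name, params, degree=2 if name == "multistage" else None)
        assert bmc_from_fit(fit, 0.5) > bmc_from_fit(fit, 0.1)

    def test_closed_form_agrees_with_root_search(self):
        fit = make_fit("loglogistic", [0.1, -2.0, 1.5])
        closed = bmc_from_fit(fit, 0.5, method="auto")
        root = bmc_from_fit(fit, 0.5, method="root", max_dose=1000.0)
        assert root == pytest.approx(closed, rel=1e-6)

    def test_bmc_beyond_range_raises(self):
        fit = make_fit("quantal_linear", [0.0, 1e-6], max_dose=10.0)
        with pytest.raises(ValueError, match="beyond tested range"):
            bmc_from_fit(fit, 0.5, method="root")


class TestGoodnessOfFit:
    def test_perfect_fit_zero_chi_square(self):
        data = QuantalDataset("x", [0.0, 5.0, 20.0, 60.0], [24] * 4, [0, 6, 12, 20])
        # a fake 1-parameter fit predicting exactly y/n
        spec = DRModelSpec("quantal_linear")
        fit = make_fit("quantal_linear", [0.0, 0.1])
        fit.predict = lambda d: np.array([0, 6, 12, 20]) / 24.0  # type: ignore
        rep = goodness_of_fit(fit, data)
        # exactly zero up to the documented probability clamp epsilon
        assert rep.chi_square == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(rep.scaled_residuals, 0.0, atol=1e-3)
        assert rep.accepted

    def test_scaled_residual_hand_formula(self):
        data = QuantalDataset("x", [0.0, 1.0, 2.0], [100, 100, 100], [50, 70, 50])
        fit = make_fit("quantal_linear", [0.0, 0.1])
        fit.predict = lambda d: np.full(np.atleast_1d(d).shape, 0.5)  # type: ignore
        rep = goodness_of_fit(fit, data)
        assert rep.scaled_residuals[1] == pytest.approx((70 - 50) / 5.0)

    def test_low_p_rejected(self):
        data = QuantalDataset("x", [0.0, 1.0, 2.0, 4.0, 8.0], [100] * 5, [50, 20, 80, 10, 90])
        fit = make_fit("quantal_linear", [0.0, 0.1])
        fit.predict = lambda d: np.full(np.atleast_1d(d).shape, 0.5)  # type: ignore
        rep = goodness_of_fit(fit, data)
        assert rep.p_value < 0.1 and not rep.accepted

    def test_df_floor_means_unidentifiable(self):
        data = QuantalDataset("x", [0.0, 1.0], [24, 24], [2, 12])
        fit = make_fit("weibull", [0.05, 1.2, 0.1])
        rep = goodness_of_fit(fit, data)
        assert not rep.accepted and rep.reason == "unidentifiable"


class TestSelectBMC:
    def _entry(self, bmc, p=0.5, accepted=True, n_params=2):
        fit = make_fit("quantal_linear", [0.0, 0.1])
        fit.n_params = n_params
        gof = GofReport(1.0, 3, p, np.zeros(5), accepted)
        return (fit, gof, bmc)

    def test_minimum_of_accepted(self):
        est = select_bmc([self._entry(4.6), self._entry(4.2), self._entry(5.0)])
        assert est.bmc_d50 == 4.2 and not est.no_accepted_model

    def test_single_accepted(self):
        est = select_bmc([self._entry(7.7)])
        assert est.bmc_d50 == 7.7

    def test_no_accepted_flagged_with_best_p_candidate(self):
        fits = [
            self._entry(4.0, p=0.01, accepted=False),
            self._entry(6.0, p=0.08, accepted=False),
        ]
        est = select_bmc(fits)
        assert est.no_accepted_model
        assert est.bmc_d50 == 6.0  # highest GOF p, not lowest BMC
        assert est.warnings
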
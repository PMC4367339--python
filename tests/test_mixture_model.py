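"""Normalization, mixture-curve fitting, tangent-intercept partials, prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_quadratic
from odorblend.core import ComponentExposure, Odorant
from odorblend.individual_response import DegenerateDesignError
from odorblend.mixture_model import (
    BinaryMixtureSample,
    ExtrapolationWarning,
    InvalidPointError,
    MissingMeasurementError,
    NormalizedPoint,
    OutOfDomainError,
    QuadraticMixtureModel,
    SubThresholdComponentError,
    evaluate_predictions,
    extended_model,
    fit_mixture_curve,
    normalize,
    partial_intensities,
    predict_oi,
    report_round_oi,
    round_half_away,
    stratify_by_level,
)

A = Odorant("A", threshold=0.02)
B = Odorant("B", threshold=0.03)


def sample_from_ln_oavs(ln_a, ln_b, oi=None):
    return BinaryMixtureSample(
        component_a=ComponentExposure.from_ln_oav(A, ln_a),
        component_b=ComponentExposure.from_ln_oav(B, ln_b),
        measured_oi=oi,
    )


def grid_points(model, xs):
    return [NormalizedPoint(x, float(model.f(x))) for x in xs]


class TestNormalize:
    def test_equal_components_split_evenly(self):
        s = sample_from_ln_oavs(1.0, 1.0, oi=3.0)
        p = normalize(s)
        assert p.x == pytest.approx(0.5)
        assert p.oi_m == pytest.approx(1.5)

    def test_per_unit_intensity_from_printed_inputs(self):
        # OI 1.7 over a total lnOAV of 2.2
        s = sample_from_ln_oavs(1.1, 1.1, oi=1.7)
        assert normalize(s).oi_m == pytest.approx(1.7 / 2.2, abs=1e-12)
        assert normalize(s).oi_m == pytest.approx(0.7727, abs=5e-5)

    def test_mixing_proportion_from_printed_inputs(self):
        s = sample_from_ln_oavs(2.18, 0.56, oi=2.3)
        assert normalize(s).x == pytest.approx(2.18 / 2.74, abs=1e-12)
        assert normalize(s).x == pytest.approx(0.7956, abs=5e-5)

    def test_missing_measurement(self):
        with pytest.raises(MissingMeasurementError):
            normalize(sample_from_ln_oavs(1.0, 1.0))

    def test_sub_threshold_component_rejected(self):
        with pytest.raises(SubThresholdComponentError):
            sample_from_ln_oavs(-0.2, 1.0, oi=2.0)


class TestFit:
    def test_noiseless_recovery_of_pooled_curve(self):
        truth = extended_model()
        model = fit_mixture_curve(grid_points(truth, np.arange(0.1, 0.95, 0.1)))
        assert model.coefficients == pytest.approx((2.20, -2.20, 1.32), abs=1e-9)
        assert model.residual_sd == pytest.approx(0.0, abs=1e-9)

    def test_rank_conditions(self):
        truth = extended_model()
        # 4 points on 3 distinct x: fits
        pts = grid_points(truth, [0.2, 0.5, 0.5, 0.8])
        assert fit_mixture_curve(pts).a2 == pytest.approx(2.20, abs=1e-9)
        with pytest.raises(DegenerateDesignError):
            fit_mixture_curve(grid_points(truth, [0.2, 0.2, 0.8, 0.8]))
        with pytest.raises(DegenerateDesignError):
            fit_mixture_curve(grid_points(truth, [0.2, 0.5, 0.8]))

    def test_points_outside_unit_interval_rejected(self):
        pts = [NormalizedPoint(x, 1.0) for x in [0.2, 0.5, 0.8, 1.2]]
        with pytest.raises(InvalidPointError):
            fit_mixture_curve(pts)

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(4, 11))
            xs = rng.uniform(0, 1, n)
            while len(np.unique(xs)) < 3:
                xs = rng.uniform(0, 1, n)
            ys = rng.normal(1.0, 0.5, n)
            model = fit_mixture_curve([NormalizedPoint(x, y) for x, y in zip(xs, ys)])
            oracle = brute_force_quadratic(xs, ys)
            assert model.coefficients == pytest.approx(tuple(oracle), abs=1e-9)

    def test_confidence_band_shrinks_with_n_and_contains_fit_center(self):
        rng = np.random.default_rng(3)
        truth = extended_model()

        def fitted(n):
            xs = rng.uniform(0.1, 0.9, n)
            ys = truth.f(xs) + rng.normal(0, 0.05, n)
            return fit_mixture_curve([NormalizedPoint(x, y) for x, y in zip(xs, ys)])

        small, large = fitted(24), fitted(240)
        for x in (0.2, 0.5, 0.8):
            lo, hi = small.confidence_band(x)
            assert lo < small.f(x) < hi
        assert np.subtract(*large.confidence_band(0.5)[::-1]) < np.subtract(
            *small.confidence_band(0.5)[::-1]
        )

    def test_literature_model_has_no_band(self):
        with pytest.raises(ValueError, match="confidence bands"):
            extended_model().confidence_band(0.5)


class TestExtendedModel:
    def test_worked_curve_values(self):
        m = extended_model()
        assert m.f(0.3) == pytest.approx(0.86, abs=5e-3)
        assert m.f(0.6) == pytest.approx(0.79, abs=5e-3)
        assert m.f(0.5) == pytest.approx(0.77, abs=5e-3)
        assert m.symmetry_axis == pytest.approx(0.5, abs=1e-12)
        assert m.provenance == "literature-fixed"


class TestPartialIntensities:
    def test_worked_tangent_at_03(self):
        p = partial_intensities(extended_model(), 0.3)
        # tangent y = −0.88x + 1.12
        assert p.oi_a_m == pytest.approx(0.24, abs=5e-3)
        assert p.oi_b_m == pytest.approx(1.12, abs=5e-3)

    def test_worked_tangent_at_06(self):
        p = partial_intensities(extended_model(), 0.6)
        assert p.oi_a_m == pytest.approx(0.97, abs=5e-3)
        assert p.oi_b_m == pytest.approx(0.53, abs=5e-3)

    def test_vertex_of_symmetric_curve_splits_equally(self):
        m = QuadraticMixtureModel(a2=1.7, a1=-1.7, a0=1.1)
        p = partial_intensities(m, 0.5)
        assert p.oi_a_m == pytest.approx(m.f(0.5), abs=1e-12)
        assert p.oi_b_m == pytest.approx(m.f(0.5), abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, 1.0, -0.1, 1.3])
    def test_domain(self, x):
        with pytest.raises(OutOfDomainError):
            partial_intensities(extended_model(), x)

    def test_design_range_warning(self):
        with pytest.warns(ExtrapolationWarning):
            partial_intensities(extended_model(), 0.05)


MODELS = st.tuples(
    st.floats(-3, 3), st.floats(-3, 3), st.floats(0.2, 3)
).map(lambda c: QuadraticMixtureModel(*c))


class TestPredictionProperties:
    @given(model=MODELS, x=st.floats(0.101, 0.899))
    @settings(max_examples=200)
    def test_tangent_euler_identity(self, model, x):
        """x·OI_a,m + (1−x)·OI_b,m equals the curve value exactly."""
        p = partial_intensities(model, x)
        assert x * p.oi_a_m + (1 - x) * p.oi_b_m == pytest.approx(model.f(x), abs=1e-9)

    @given(model=MODELS, ln_a=st.floats(0.2, 4), ln_b=st.floats(0.2, 4))
    @settings(max_examples=100)
    def test_partials_are_marginal_contributions(self, model, ln_a, ln_b):
        """Central-difference ∂OI/∂lnOAV_a equals the partial intensity."""
        import warnings

        h = 1e-6
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            rec = predict_oi(model, ln_a, ln_b)
            up = predict_oi(model, ln_a + h, ln_b).oi_pre
            dn = predict_oi(model, ln_a - h, ln_b).oi_pre
            grad_a = (up - dn) / (2 * h)
            grad_b = (
                predict_oi(model, ln_a, ln_b + h).oi_pre
                - predict_oi(model, ln_a, ln_b - h).oi_pre
            ) / (2 * h)
        assert grad_a == pytest.approx(rec.partials.oi_a_m, abs=1e-5)
        assert grad_b == pytest.approx(rec.partials.oi_b_m, abs=1e-5)

    @given(model=MODELS, ln_a=st.floats(0.2, 4), ln_b=st.floats(0.2, 4))
    @settings(max_examples=100)
    def test_component_swap_symmetry(self, model, ln_a, ln_b):
        """Relabelling components maps x → 1−x, swaps partials, keeps OI."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            rec = predict_oi(model, ln_a, ln_b)
            swapped = predict_oi(model.swapped(), ln_b, ln_a)
        assert swapped.partials.x == pytest.approx(1 - rec.partials.x, abs=1e-12)
        assert swapped.partials.oi_a_m == pytest.approx(rec.partials.oi_b_m, abs=1e-9)
        assert swapped.partials.oi_b_m == pytest.approx(rec.partials.oi_a_m, abs=1e-9)
        assert swapped.oi_pre == pytest.approx(rec.oi_pre, abs=1e-9)

    @given(x=st.floats(0.101, 0.899))
    def test_symmetric_curve_mirror_property(self, x):
        m = extended_model()
        left = partial_intensities(m, x)
        right = partial_intensities(m, 1 - x)
        assert left.oi_a_m == pytest.approx(right.oi_b_m, abs=1e-9)


class TestPredictExamples:
    @pytest.mark.parametrize(
        "ln_a, ln_b, expected",
        [(2.18, 0.56, 2.6), (2.87, 2.17, 3.9), (2.18, 2.17, 3.4)],
    )
    def test_reported_predictions(self, ln_a, ln_b, expected):
        rec = predict_oi(extended_model(), ln_a, ln_b)
        assert report_round_oi(rec.oi_pre) == pytest.approx(expected, abs=1e-12)

    def test_near_equimolar_partials(self):
        rec = predict_oi(extended_model(), 2.18, 2.17)
        assert round_half_away(rec.partials.oi_a_m, 2) == pytest.approx(0.77)
        assert round_half_away(rec.partials.oi_b_m, 2) == pytest.approx(0.77)

    def test_sub_threshold_rejected(self):
        with pytest.raises(SubThresholdComponentError):
            predict_oi(extended_model(), -0.1, 1.0)


class TestReportRounding:
    @pytest.mark.parametrize(
        "value, expected",
        [(1.5495, 1.6), (3.3495, 3.4), (2.6366, 2.6), (4.7421, 4.7), (-0.0726, -0.1)],
    )
    def test_two_stage_report_rounding(self, value, expected):
        assert report_round_oi(value) == pytest.approx(expected, abs=1e-12)

    def test_ties_away_from_zero(self):
        assert round_half_away(0.125, 2) == 0.13
        assert round_half_away(-0.125, 2) == -0.13


class TestEvaluate:
    def test_identity_predictions_give_unit_mean(self):
        model = extended_model()
        recs = []
        for ln_a, ln_b in [(2.0, 1.0), (1.5, 1.5), (0.8, 2.5)]:
            r = predict_oi(model, ln_a, ln_b)
            r.oi_mea = report_round_oi(r.oi_pre)
            recs.append(r)
        summary = evaluate_predictions(recs)
        assert summary.mean_predictive_coefficient == pytest.approx(1.0, abs=1e-12)
        assert summary.n_used == 3

    def test_missing_measurements_excluded_with_warning(self, caplog):
        model = extended_model()
        good = predict_oi(model, 2.0, 1.0, oi_mea=2.5)
        bad = predict_oi(model, 1.5, 1.5)
        with caplog.at_level("WARNING", logger="odorblend.mixture_model"):
            summary = evaluate_predictions([good, bad])
        assert summary.n_used == 1
        assert summary.n_excluded == 1
        assert any("excluded-record" in m for m in caplog.messages)

    def test_all_missing_raises(self):
        with pytest.raises(MissingMeasurementError):
            evaluate_predictions([predict_oi(extended_model(), 2.0, 1.0)])


class TestStratify:
    def test_balanced_construction(self):
        samples = []
        for oi in [1.2, 1.5, 2.0, 2.6, 3.5, 4.2, 4.6, 5.5, 6.5]:
            samples.append(sample_from_ln_oavs(1.0 + oi / 10, 1.0, oi=oi))
        groups = stratify_by_level(samples)
        assert {k: len(v) for k, v in groups.items()} == {"low": 3, "middle": 3, "high": 3}

    def test_empty_input_gives_three_empty_groups(self):
        assert stratify_by_level([]) == {"low": [], "middle": [], "high": []}

    def test_level_invariance_on_noiseless_data(self):
        """Per-band fits of noiseless curve data coincide: the interaction
        depends on the mixing ratio, not the intensity level."""
        truth = extended_model()
        samples = []
        xs = np.linspace(0.15, 0.85, 8)
        for target in (1.8, 3.5, 5.5):  # one total magnitude per band
            for x in xs:
                total = target / float(truth.f(x))
                samples.append(sample_from_ln_oavs(x * total, (1 - x) * total, oi=target))
        groups = stratify_by_level(samples)
        fits = {
            band: fit_mixture_curve([normalize(s) for s in group])
            for band, group in groups.items()
        }
        assert {k: len(v) for k, v in groups.items()} == {"low": 8, "middle": 8, "high": 8}
        for band, fit in fits.items():
            assert fit.coefficients == pytest.approx((2.20, -2.20, 1.32), abs=1e-9)
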
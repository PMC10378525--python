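import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gelprint import deposition as dep
from gelprint.synthetic import reference_inputs


@pytest.fixture(scope="module")
def ref():
    return reference_inputs()


class TestStadiumArea:
    def test_reference_value(self):
        assert dep.stadium_area(2.0, 0.5) == pytest.approx(0.75 + np.pi / 16.0, rel=1e-12)

    def test_degenerate_width_equals_circle(self):
        assert dep.stadium_area(0.5, 0.5) == pytest.approx(np.pi * 0.25**2, rel=1e-12)

    def test_strictly_increasing_in_width(self):
        areas = [dep.stadium_area(w, 0.5) for w in np.linspace(0.5, 4.0, 20)]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_width_below_layer_rejected(self):
        with pytest.raises(dep.DepositionError):
            dep.stadium_area(0.4, 0.5)


class TestTheoreticalWidth:
    @pytest.mark.parametrize(
        "vj,printed,decimals",
        [(0.0156, 1.068, 3), (0.0313, 2.034, 3), (0.0469, 2.99, 2), (0.0625, 3.955, 3)],
    )
    def test_published_widths(self, vj, printed, decimals):
        d2 = dep.theoretical_width(vj, 5.0, 14.0, 0.5)
        assert abs(round(d2, decimals) - printed) <= 10.0**-decimals + 1e-12

    def test_degenerate_balance_gives_layer_thickness(self):
        # feed exactly the circular-cap flux: d2 collapses to h
        h, vc, d1 = 0.5, 5.0, 14.0
        vj = vc * (np.pi * h**2 / 4.0) / (np.pi * d1**2 / 4.0)
        assert dep.theoretical_width(vj, vc, d1, h) == pytest.approx(h, rel=1e-12)

    def test_narrower_than_layer_warns(self):
        with pytest.warns(UserWarning, match="narrower than the layer"):
            dep.theoretical_width(1e-5, 5.0, 14.0, 0.5)

    @given(vj=st.floats(min_value=0.01, max_value=0.1),
           vc=st.floats(min_value=1.0, max_value=10.0))
    def test_volume_balance_invariant(self, vj, vc):
        d1, h = 14.0, 0.5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d2 = dep.theoretical_width(vj, vc, d1, h)
        if d2 < h:
            return  # unphysical stadium; balance only defined for d2 >= h
        extruded = vj * np.pi * d1**2 / 4.0
        deposited = vc * dep.stadium_area(d2, h)
        assert extruded == pytest.approx(deposited, rel=1e-9)


class TestSpeedRatio:
    def test_reference_value(self):
        assert dep.speed_ratio_k(14.0, 2.0, 0.5) == pytest.approx(
            np.pi * 196.0 / (4.0 - 1.0 + np.pi * 0.25), rel=1e-12)

    def test_degenerate_width(self):
        assert dep.speed_ratio_k(14.0, 0.5, 0.5) == pytest.approx((14.0 / 0.5) ** 2, rel=1e-12)

    @given(vj=st.floats(min_value=0.005, max_value=0.1),
           vc=st.floats(min_value=1.0, max_value=10.0),
           h=st.floats(min_value=0.2, max_value=1.0))
    def test_round_trip_with_theoretical_width(self, vj, vc, h):
        d1 = 14.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d2 = dep.theoretical_width(vj, vc, d1, h)
        if d2 < h:
            return  # unphysical corner of the sampled space
        assert dep.speed_ratio_k(d1, d2, h) * vj == pytest.approx(vc, rel=1e-9)


class TestWidthLaws:
    def test_published_actual_law_within_one_percent(self, ref):
        law = dep.fit_width_law(ref.measurements)
        assert law.slope == pytest.approx(35.3344, rel=0.01)
        assert law.intercept == pytest.approx(1.1415, rel=0.01)

    def test_two_points_interpolated_exactly(self):
        ms = [dep.WidthMeasurement(0.01, 1.0), dep.WidthMeasurement(0.03, 2.0)]
        law = dep.fit_width_law(ms)
        assert law(0.01) == pytest.approx(1.0, rel=1e-12)
        assert law(0.03) == pytest.approx(2.0, rel=1e-12)

    def test_exact_law_recovered_from_noiseless_points(self):
        truth = dep.LinearLaw(intercept=1.2, slope=30.0)
        ms = [dep.WidthMeasurement(v, float(truth(v))) for v in (0.01, 0.02, 0.04, 0.08)]
        law = dep.fit_width_law(ms)
        assert law.intercept == pytest.approx(1.2, rel=1e-9)
        assert law.slope == pytest.approx(30.0, rel=1e-9)

    def test_equal_velocities_rejected(self):
        ms = [dep.WidthMeasurement(0.02, 1.0), dep.WidthMeasurement(0.02, 2.0)]
        with pytest.raises(dep.DepositionError):
            dep.fit_width_law(ms)


class TestCalibration:
    def test_published_error_law_slope(self, ref):
        cal = dep.calibrate(ref.measurements, v_c=5.0, d1=14.0, h=0.5)
        assert cal.error_law.slope == pytest.approx(-26.195, rel=0.005)
        assert cal.theoretical_law.slope == pytest.approx(61.529, rel=0.005)
        # componentwise identity of the difference law
        assert cal.error_law.intercept == pytest.approx(
            cal.actual_law.intercept - cal.theoretical_law.intercept, abs=1e-9)

    def test_measurements_on_theoretical_law_give_zero_error(self):
        theo = dep.theoretical_width_law(5.0, 14.0, 0.5)
        ms = [dep.WidthMeasurement(v, float(theo(v))) for v in (0.01, 0.02, 0.04, 0.06)]
        cal = dep.calibrate(ms, v_c=5.0, d1=14.0, h=0.5)
        assert cal.error_law.intercept == pytest.approx(0.0, abs=1e-9)
        assert cal.error_law.slope == pytest.approx(0.0, abs=1e-6)

    def test_constant_offset_recovered(self):
        theo = dep.theoretical_width_law(5.0, 14.0, 0.5)
        ms = [dep.WidthMeasurement(v, float(theo(v)) + 0.3)
              for v in (0.01, 0.02, 0.04, 0.06)]
        cal = dep.calibrate(ms, v_c=5.0, d1=14.0, h=0.5)
        assert cal.error_law.intercept == pytest.approx(0.3, abs=1e-9)
        assert cal.error_law.slope == pytest.approx(0.0, abs=1e-6)


class TestCorrectedMatching:
    def test_reference_constants_match_print_speed(self):
        k1 = dep.corrected_k1(14.0, 0.5, target_width=2.0, v_j=0.0242,
                              mode="reference")
        assert k1 * 0.0242 == pytest.approx(5.0, abs=0.01)

    def test_zero_error_law_reduces_to_ideal_ratio(self):
        zero = dep.LinearLaw(0.0, 0.0)
        k1 = dep.corrected_k1(14.0, 0.5, target_width=2.0, v_j=0.03,
                              error_law=zero, mode="fitted")
        assert k1 == pytest.approx(dep.speed_ratio_k(14.0, 2.0, 0.5), rel=1e-12)

    def test_fitted_agrees_with_reference_constants(self, ref):
        cal = dep.calibrate(ref.measurements, v_c=5.0, d1=14.0, h=0.5)
        k_fit = dep.corrected_k1(14.0, 0.5, 2.0, 0.0242,
                                 error_law=cal.error_law, mode="fitted")
        k_ref = dep.corrected_k1(14.0, 0.5, 2.0, 0.0242, mode="reference")
        assert k_fit == pytest.approx(k_ref, rel=0.005)


class TestOptimalInletVelocity:
    def test_published_operating_point(self):
        vj = dep.optimal_inlet_velocity(2.0, 5.0, d1=14.0, h=0.5, mode="reference")
        assert round(vj, 4) == pytest.approx(0.0242, abs=1e-12)

    def test_inverse_identity_without_correction(self):
        zero = dep.WidthCalibration(
            actual_law=dep.theoretical_width_law(5.0, 14.0, 0.5),
            theoretical_law=dep.theoretical_width_law(5.0, 14.0, 0.5),
            error_law=dep.LinearLaw(0.0, 0.0))
        v_star = 0.035
        target = dep.theoretical_width(v_star, 5.0, 14.0, 0.5)
        vj = dep.optimal_inlet_velocity(target, 5.0, calibration=zero, d1=14.0, h=0.5)
        assert vj == pytest.approx(v_star, rel=1e-12)

    def test_monotone_in_target_width(self):
        widths = np.linspace(1.2, 4.0, 15)
        vs = [dep.optimal_inlet_velocity(w, 5.0, d1=14.0, h=0.5, mode="reference")
              for w in widths]
        assert all(b > a for a, b in zip(vs, vs[1:]))

    def test_self_consistency_with_published_actual_law(self, ref):
        vj = dep.optimal_inlet_velocity(2.0, 5.0, d1=14.0, h=0.5, mode="reference")
        predicted = ref.actual_law_published(vj)
        assert predicted == pytest.approx(2.0, abs=0.01)
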
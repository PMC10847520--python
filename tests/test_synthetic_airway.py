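"""Reduced-order duct simulator: physics limits, obstruction, determinism."""

import numpy as np
import pytest

from nasalair.errors import ValidationError
from nasalair.profile_io import DEFAULT_SCENARIOS
from nasalair.standardize import compute_theta
from nasalair.synthetic_airway import (
    DEFAULT_K,
    FlowConditions,
    Obstruction,
    generate_study,
    make_geometry,
    obstruction_at_slice,
    simulate_acclimatization,
    _theta_profile,
)


def k_for_total_exchange(geom, q_lpm, total):
    """k such that k*P*dc/Q equals ``total`` for a uniform duct."""
    q = q_lpm / 60000.0
    return total * q / ((geom.perimeter_mm[0] / 1000.0) * (geom.dc_mm / 1000.0))


class TestGeometry:
    def test_uniform_duct_stations(self):
        geom = make_geometry(n_segments=9, dc_mm=80.28)
        assert geom.n_stations == 9
        assert geom.s_mm[0] == 0.0 and geom.s_mm[-1] == 80.28
        assert np.allclose(np.diff(geom.s_mm), 80.28 / 8)

    def test_zero_blockage_is_identity(self):
        geom = make_geometry()
        obs = obstruction_at_slice(geom, 2, 0.0)
        assert np.array_equal(
            geom.with_obstruction(obs).effective_area_mm2, geom.effective_area_mm2
        )

    def test_obstruction_locality(self):
        geom = make_geometry()
        obstructed = geom.with_obstruction(obstruction_at_slice(geom, 2, 0.7))
        changed = obstructed.effective_perimeter_mm != geom.effective_perimeter_mm
        assert changed.sum() == 1 and changed[1]

    def test_obstruction_removal_restores_exactly(self):
        geom = make_geometry(area_profile="tapered")
        restored = geom.with_obstruction(
            obstruction_at_slice(geom, 3, 0.5)
        ).without_obstruction()
        assert np.array_equal(restored.effective_area_mm2, geom.effective_area_mm2)
        assert np.array_equal(restored.effective_perimeter_mm, geom.effective_perimeter_mm)

    def test_obstruction_outside_duct_rejected(self):
        geom = make_geometry(dc_mm=100.0)
        with pytest.raises(ValidationError):
            geom.with_obstruction(Obstruction(90.0, 120.0, 0.5))

    def test_velocity_rises_inside_obstruction(self):
        geom = make_geometry()
        flow = FlowConditions()
        v0 = geom.local_velocity_ms(flow)
        v1 = geom.with_obstruction(obstruction_at_slice(geom, 2, 0.7)).local_velocity_ms(flow)
        assert v1[1] > v0[1]
        assert np.allclose(np.delete(v1, 1), np.delete(v0, 1))


class TestExchangePhysics:
    def test_closed_form_exponential(self):
        """Uniform duct with total exchange number 3: theta = -exp(-3 d*)."""
        geom = make_geometry(n_segments=9, dc_mm=100.0)
        k = k_for_total_exchange(geom, 15.0, 3.0)
        theta = _theta_profile(geom, FlowConditions(k=k))
        dstar = geom.s_mm / geom.dc_mm
        assert np.allclose(theta, -np.exp(-3.0 * dstar), atol=1e-12)
        assert theta[-1] == pytest.approx(-0.0498, abs=5e-5)

    def test_limits(self):
        geom = make_geometry()
        near_zero = _theta_profile(geom, FlowConditions(k=1e-12))
        assert np.allclose(near_zero, -1.0, atol=1e-6)  # no exchange
        huge = _theta_profile(geom, FlowConditions(k=1e4))
        assert np.all(huge[1:] > -1e-8)  # instant equilibration

    def test_calibration_hits_quarter_theta_at_slice2(self):
        geom = make_geometry()
        theta = _theta_profile(geom, FlowConditions(k=DEFAULT_K))
        assert theta[1] == pytest.approx(-0.25, abs=1e-12)

    def test_monotone_approach_and_range(self):
        geom = make_geometry(area_profile="tapered")
        theta = _theta_profile(geom, FlowConditions())
        assert np.all(np.diff(theta) > 0)
        assert np.all((theta >= -1.0) & (theta <= 0.0))

    def test_simulated_profile_standardizes_to_minus_one_inlet(self):
        geom = make_geometry()
        for quantity in ("temperature", "humidity"):
            prof = simulate_acclimatization(
                geom, DEFAULT_SCENARIOS[0], FlowConditions(), quantity
            )
            wall, ext = DEFAULT_SCENARIOS[0].references(quantity)
            theta = compute_theta(prof.values[:, 0], wall, ext)
            assert theta[0] == pytest.approx(-1.0, abs=1e-12)
            assert np.all((theta >= -1 - 1e-12) & (theta <= 1e-12))


class TestGenerateStudy:
    def test_deterministic_and_restorative(self):
        b1 = generate_study(seed=0)
        b2 = generate_study(seed=0)
        for key in b1:
            assert np.array_equal(b1[key].values, b2[key].values)
        # noise-free: surgery restores the duct, profiles are bit-identical
        for quantity in ("temperature", "humidity"):
            assert np.array_equal(
                b1[("original", quantity)].values, b1[("operated", quantity)].values
            )

    def test_obstruction_delays_acclimatization(self):
        bundle = generate_study(seed=0)
        orig = bundle[("original", "temperature")]
        obst = bundle[("obstructed", "temperature")]
        assert obst.average[1] < orig.average[1] - 0.1
        assert np.all(obst.average[1:] <= orig.average[1:] + 1e-12)

    def test_noise_respects_inlet_and_range(self):
        bundle = generate_study(seed=3, flow=FlowConditions(noise_sigma=0.02))
        for prof in bundle.values():
            assert np.all(prof.values[0] == -1.0)
            assert np.all((prof.values >= -1.0) & (prof.values <= 0.0))

    def test_different_seeds_differ_with_noise(self):
        a = generate_study(seed=1, flow=FlowConditions(noise_sigma=0.005))
        b = generate_study(seed=2, flow=FlowConditions(noise_sigma=0.005))
        assert not np.array_equal(
            a[("original", "temperature")].values, b[("original", "temperature")].values
        )
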
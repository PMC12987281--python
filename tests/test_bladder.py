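"""Muscle--bladder gas model: geometry, linear maps, exact oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pneumyo.bladder import (BladderGeometry, MuscleTendonParams, RegionState,
                             SystemState, cylinder_volume, equilibrium_oracle,
                             local_pressure_change_to_area_change,
                             muscle_area_change, muscle_force_from_local,
                             muscle_force_from_total,
                             total_to_local_pressure_change)

areas = st.floats(min_value=10.0, max_value=5000.0)
pressures = st.floats(min_value=5.0, max_value=100.0)


class TestCylinderVolume:
    @pytest.mark.parametrize(
        "d, length, expected",
        [(20.0, 300.0, 94247.7796076938), (10.0, 100.0, 7853.981633974483)],
    )
    def test_matches_closed_form(self, d, length, expected):
        assert cylinder_volume(BladderGeometry(d, length)) == pytest.approx(expected)

    def test_rejects_degenerate_diameter(self):
        with pytest.raises(ValueError):
            BladderGeometry(0.0, 300.0)
        # limit D -> 0 gives volume -> 0
        assert cylinder_volume(BladderGeometry(1e-9, 300.0)) < 1e-12


class TestLocalIsothermalMap:
    def test_example_value(self):
        region = RegionState(area=100.0, pressure=20.0)
        assert local_pressure_change_to_area_change(region, 0.8) == pytest.approx(-4.0)

    def test_zero_change(self):
        assert local_pressure_change_to_area_change(RegionState(100, 20), 0.0) == 0.0

    @given(area=areas, pressure=pressures,
           dP=st.floats(min_value=1e-6, max_value=5.0))
    def test_compression_sign(self, area, pressure, dP):
        """Raising pressure always shrinks the region's cross-section."""
        assert local_pressure_change_to_area_change(RegionState(area, pressure), dP) < 0


class TestTotalToLocal:
    def test_example_value(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)
        assert total_to_local_pressure_change(state, 0.5) == pytest.approx(2.0)

    def test_single_region_reduction(self):
        """With a vanishing rest region the total and local changes coincide."""
        state = SystemState.uniform(20.0, 100.0, 1e-9)
        assert total_to_local_pressure_change(state, 0.5) == pytest.approx(0.5)

    def test_linearity(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)
        assert total_to_local_pressure_change(state, 0.0) == 0.0
        one = total_to_local_pressure_change(state, 0.3)
        assert total_to_local_pressure_change(state, 0.9) == pytest.approx(3 * one)


class TestMuscleForce:
    params = MuscleTendonParams(stiffness_k=1.0, muscle_length_x=100.0,
                                muscle_area_Am=2000.0)

    def test_local_example(self):
        region = RegionState(area=400.0, pressure=20.0)
        assert muscle_force_from_local(self.params, region, 0.5) == pytest.approx(0.5)

    def test_total_example(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)  # Ab+Au = 400
        assert muscle_force_from_total(self.params, state, 0.5) == pytest.approx(0.5)

    def test_linearity_in_pressure_change(self):
        region = RegionState(area=400.0, pressure=20.0)
        assert muscle_force_from_local(self.params, region, 0.0) == 0.0
        f = muscle_force_from_local(self.params, region, 0.4)
        assert muscle_force_from_local(self.params, region, 0.8) == pytest.approx(2 * f)

    @settings(max_examples=200, derandomize=True)
    @given(k=st.floats(0.1, 10.0), x=st.floats(10.0, 500.0),
           am=st.floats(100.0, 10000.0), ab=areas, au=areas,
           pt=pressures, dpt=st.floats(-2.0, 2.0))
    def test_total_equals_local_composition(self, k, x, am, ab, au, pt, dpt):
        """The total-pressure force law is exactly the local law composed
        with the total-to-local pressure map."""
        params = MuscleTendonParams(k, x, am)
        state = SystemState.uniform(pt, ab, au)
        direct = muscle_force_from_total(params, state, dpt)
        composed = muscle_force_from_local(
            params, state.region_contracting,
            total_to_local_pressure_change(state, dpt))
        assert direct == pytest.approx(composed, rel=1e-12, abs=1e-15)


class TestEquilibriumOracle:
    def test_mass_balance_example(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)
        assert equilibrium_oracle(state, -4.0) == pytest.approx(8000.0 / 396.0)

    def test_no_contraction_is_identity(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)
        assert equilibrium_oracle(state, 0.0) == pytest.approx(20.0)

    def test_area_collapse_rejected(self):
        state = SystemState.uniform(20.0, 100.0, 300.0)
        with pytest.raises(ValueError):
            equilibrium_oracle(state, -400.0)

    @settings(derandomize=True)
    @given(ab=areas, au=areas, pb=pressures, pu=pressures,
           frac=st.floats(-0.5, 0.5))
    def test_conserves_pressure_area_sum(self, ab, au, pb, pu, frac):
        state = SystemState(RegionState(ab, pb), RegionState(au, pu),
                            total_pressure=(pb * ab + pu * au) / (ab + au))
        dab = frac * (ab + au)
        p_new = equilibrium_oracle(state, dab)
        assert p_new * (ab + au + dab) == pytest.approx(pb * ab + pu * au, rel=1e-12)

    @given(ab=areas, au=areas, pt=pressures,
           frac=st.floats(min_value=1e-6, max_value=0.5))
    def test_contraction_raises_pressure(self, ab, au, pt, frac):
        state = SystemState.uniform(pt, ab, au)
        assert equilibrium_oracle(state, -frac * (ab + au)) > pt

    def test_small_contraction_linearization_error(self):
        """At 0.25% contraction the linearized dPt is within 0.3% of the oracle."""
        state = SystemState.uniform(20.0, 100.0, 300.0)
        dab = -1.0
        exact = equilibrium_oracle(state, dab) - 20.0
        linear = -20.0 * dab / 400.0
        assert abs(exact - linear) / linear < 0.003


def test_area_conservation_closure():
    assert muscle_area_change(-4.0) == 4.0
    assert muscle_area_change(0.0) == 0.0
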
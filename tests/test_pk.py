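"""One-compartment closed forms against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import siropk as sp
from siropk.errors import DegenerateKineticsError, InvalidParameterError


def superposition_trough(params, dose, tau, rel_change=1e-10, max_doses=50000):
    """Independent steady-state oracle: explicit Bateman superposition until
    the accumulated trough stops changing."""
    ke = params.cl / params.v
    coef = dose * params.ka / (params.v * (params.ka - ke))
    total = 0.0
    for n in range(1, max_doses + 1):
        t = n * tau  # time since the oldest dose
        total_new = total + coef * (math.exp(-ke * t) - math.exp(-params.ka * t))
        if total_new != 0 and abs(total_new - total) < rel_change * abs(total_new):
            return total_new
        total = total_new
    return total


class TestSingleDose:
    def test_zero_dose_gives_zero(self, typical_20kg):
        assert sp.conc_single_dose(typical_20kg, 0.0, 24.0) == 0.0

    def test_time_zero_gives_zero(self, typical_20kg):
        assert sp.conc_single_dose(typical_20kg, 1200.0, 0.0) == 0.0

    def test_typical_child_24h_concentration(self, typical_20kg):
        # frozen from numeric ODE integration of the depot/central system
        assert sp.conc_single_dose(typical_20kg, 1200.0, 24.0) == pytest.approx(
            4.2235, abs=2e-3
        )

    def test_matches_ode_oracle(self, typical_20kg):
        closed = sp.conc_single_dose(typical_20kg, 1200.0, 24.0)
        ode = sp.ode_oracle(typical_20kg, sp.Regimen(1200.0, 24.0, 1), [24.0])[0]
        assert closed == pytest.approx(ode, rel=1e-3)


class TestSteadyStateTrough:
    def test_typical_child_dose_006(self, typical_20kg):
        # 0.06 mg/kg/day at 20 kg = 1200 ug; frozen from the superposition oracle
        assert sp.steady_state_trough(typical_20kg, 1200.0) == pytest.approx(
            superposition_trough(typical_20kg, 1200.0, 24.0), rel=1e-6
        )
        assert sp.steady_state_trough(typical_20kg, 1200.0) == pytest.approx(9.529, abs=5e-3)

    def test_linear_in_dose(self, typical_20kg):
        one = sp.steady_state_trough(typical_20kg, 1200.0)
        two = sp.steady_state_trough(typical_20kg, 2400.0)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_posaconazole_child_low_dose(self, final_model):
        params = sp.typical_params(final_model, 20.0, pos=1)
        trough = sp.steady_state_trough(params, 400.0)  # 0.02 mg/kg/day
        assert trough == pytest.approx(superposition_trough(params, 400.0, 24.0), rel=1e-6)
        assert trough == pytest.approx(16.25, abs=0.05)

    def test_decreasing_in_clearance(self, typical_20kg):
        troughs = [
            sp.steady_state_trough(
                sp.StructuralParams(cl, typical_20kg.v, typical_20kg.ka), 1200.0
            )
            for cl in (2.0, 4.0, 8.0, 16.0)
        ]
        assert all(a > b for a, b in zip(troughs, troughs[1:]))

    def test_increasing_in_weight_at_fixed_dose_per_kg(self, final_model):
        troughs = [
            sp.steady_state_trough(
                sp.typical_params(final_model, w), 0.05 * w * 1000.0
            )
            for w in range(10, 61, 5)
        ]
        assert all(a < b for a, b in zip(troughs, troughs[1:]))


class TestOdeOracle:
    def test_steady_state_convergence(self, typical_20kg):
        n = 200
        prof = sp.ode_oracle(typical_20kg, sp.Regimen(1200.0, 24.0, n), [n * 24.0])
        assert prof[0] == pytest.approx(sp.steady_state_trough(typical_20kg, 1200.0), rel=1e-3)

    def test_zero_dose_regimen_all_zero(self, typical_20kg):
        prof = sp.ode_oracle(typical_20kg, sp.Regimen(0.0, 24.0, 3), [0.0, 12.0, 30.0, 60.0])
        assert np.allclose(prof, 0.0)

    def test_rejects_unsorted_grid(self, typical_20kg):
        with pytest.raises(InvalidParameterError):
            sp.ode_oracle(typical_20kg, sp.Regimen(100.0), [5.0, 1.0])


class TestValidation:
    @pytest.mark.parametrize("cl,v,ka", [(-1, 100, 0.5), (4, 0, 0.5), (4, 100, -0.1)])
    def test_nonpositive_parameters_rejected(self, cl, v, ka):
        with pytest.raises(InvalidParameterError):
            sp.StructuralParams(cl, v, ka)

    def test_flipflop_degenerate_rejected(self):
        with pytest.raises(DegenerateKineticsError):
            sp.StructuralParams(cl=50.0, v=100.0, ka=0.5)  # ke == ka

    def test_negative_dose_rejected(self, typical_20kg):
        with pytest.raises(InvalidParameterError):
            sp.steady_state_trough(typical_20kg, -1.0)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    cl=st.floats(0.5, 20.0),
    v=st.floats(50.0, 600.0),
    ka=st.floats(0.1, 2.0),
    dose=st.floats(100.0, 5000.0),
)
def test_steady_state_matches_superposition_oracle(cl, v, ka, dose):
    """Closed-form accumulation equals the explicit sum over past doses."""
    ke = cl / v
    if abs(ka - ke) < 1e-3 * ka or ke * 24.0 < 0.02:
        return  # outside the validated (non-degenerate, converging) domain
    params = sp.StructuralParams(cl, v, ka)
    closed = sp.steady_state_trough(params, dose, 24.0)
    oracle = superposition_trough(params, dose, 24.0)
    assert closed == pytest.approx(oracle, rel=1e-6)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(cl=st.floats(1.0, 15.0), v=st.floats(80.0, 600.0), t=st.floats(0.5, 72.0))
def test_single_dose_homogeneous_and_positive(cl, v, t):
    params = sp.StructuralParams(cl, v, 0.485)
    c1 = sp.conc_single_dose(params, 1000.0, t)
    c3 = sp.conc_single_dose(params, 3000.0, t)
    assert c1 > 0
    assert c3 == pytest.approx(3 * c1, rel=1e-12)
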
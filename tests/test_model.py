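"""Unit and property tests for the compartment model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrdyn import (
    IntegrationError,
    ModelError,
    ModelParameters,
    PopulationState,
    final_phage_ratio,
    rhs,
    simulate,
)
from acrdyn.model import Trajectory


class TestParameters:
    @pytest.mark.parametrize("field,value", [
        ("A", -0.1), ("A", 1.5), ("rho", 2.0), ("phi", -1e-9),
        ("a", -1.0), ("B", -5.0), ("gamma", -0.1), ("r", -1.0),
        ("k", -1e-6), ("m", -0.1), ("phi", float("nan")),
        ("B", float("inf")),
    ])
    def test_invalid_rejected_naming_field(self, field, value):
        with pytest.raises(ModelError, match=field):
            ModelParameters(**{field: value})

    def test_no_reversion_flagged(self, caplog):
        """gamma = 0 with phi < 1 and rho < 1 is allowed but logged:
        immunosuppressed cells would accumulate forever."""
        import logging

        with caplog.at_level(logging.WARNING, logger="acrdyn.model"):
            ModelParameters(gamma=0.0, phi=0.5, rho=0.5)
        assert any("without reversion" in r.message for r in caplog.records)

    def test_negative_density_rejected(self):
        with pytest.raises(ModelError, match="V1"):
            PopulationState(W=10.0, V1=-1.0)

    def test_totals_are_derived(self):
        s = PopulationState(W=1.0, R=2.0, S=3.0, V1=4.0, V2=5.0)
        assert s.N == 6.0
        assert s.V == 9.0


class TestRHS:
    def test_logistic_growth_only(self):
        """Pure host growth: dW/dt = r W (1 - kN) - m W, everything else
        zero."""
        p = ModelParameters(r=1.0, k=0.001, m=0.1)
        d = rhs(PopulationState(W=100.0), p)
        assert d == pytest.approx((80.0, 0.0, 0.0, 0.0, 0.0))

    def test_cell_free_system_is_stationary(self, reference_params):
        """No cells means no adsorption and the model has no free-phage
        decay term, so all derivatives vanish."""
        d = rhs(PopulationState(V1=10.0, V2=5.0), reference_params)
        assert d == pytest.approx((0.0,) * 5, abs=0.0)

    def test_term_by_term_hand_evaluation(self):
        """Every term evaluated by hand at W=1000, R=500, S=0,
        V1=V2=200 with the reference constants:

        dW  = 1000*(1 - 0.0015) - (0.2 + 0.2 + 0.1)*1000  = 498.5
        dR  = 0.0002*400*1000 + 499.25 - 0.2*500 + 0      = 479.25
        dS  = 0.001*0.5*0.7*200*500 - 0                   = 35
        dV1 = 0.00075*200*500 + 0.005*200*800 - 300       = 575
        dV2 = 0.005*200*800 - 300                         = 500
        """
        p = ModelParameters(a=0.001, A=0.2, B=5.0, rho=0.5, phi=0.3,
                            gamma=1.0, r=1.0, k=1e-6, m=0.1)
        state = PopulationState(W=1000.0, R=500.0, S=0.0, V1=200.0, V2=200.0)
        d = rhs(state, p)
        assert d == pytest.approx((498.5, 479.25, 35.0, 575.0, 500.0))

    @given(
        w=st.floats(0, 1e6), r_=st.floats(0, 1e6), s=st.floats(0, 1e6),
        v1=st.floats(0, 1e8), v2=st.floats(0, 1e8),
    )
    def test_finite_inputs_give_finite_outputs(self, w, r_, s, v1, v2):
        d = rhs(PopulationState(W=w, R=r_, S=s, V1=v1, V2=v2),
                ModelParameters())
        assert all(math.isfinite(x) for x in d)


class TestSimulate:
    def test_no_phage_logistic_fixed_point(self, reference_params):
        """Without phage, W grows logistically to the density where
        r(1 - kN) = m, i.e. N* = (1 - m/r)/k; other compartments stay
        identically zero."""
        p = reference_params
        traj = simulate(PopulationState(W=1e3), p, 100.0,
                        np.linspace(0.0, 100.0, 51))
        n_star = (1.0 - p.m / p.r) / p.k
        assert traj.final_state.W == pytest.approx(n_star, rel=1e-3)
        assert np.all(traj.densities[:, 1:] == 0.0)

    def test_initial_state_is_first_sample(self, reference_params,
                                           mixed_initial):
        traj = simulate(mixed_initial, reference_params, 5.0,
                        np.linspace(0.0, 5.0, 11))
        assert traj.densities[0] == pytest.approx(mixed_initial.as_array())
        assert len(traj) == 11
        assert np.all(np.diff(traj.times) > 0)

    def test_mixed_infection_both_phages_persist(self, reference_params,
                                                 mixed_initial):
        """Equal 100:100 inoculum on sensitive hosts: neither phage type
        crosses the extinction threshold, resistance rises and is partly
        converted to immunosuppressed cells."""
        traj = simulate(mixed_initial, reference_params, 30.0)
        assert traj.densities[-1, 3] > traj.extinction_threshold
        assert traj.densities[-1, 4] > traj.extinction_threshold
        assert traj.column("R").max() > 1.0
        assert traj.column("S").max() > 1.0

    def test_full_symmetry_when_acr_always_cleaved(self, mixed_initial):
        """rho = 1 removes every Acr-specific term, so with equal
        inocula the two phage trajectories coincide."""
        p = ModelParameters(rho=1.0)
        traj = simulate(mixed_initial, p, 30.0)
        v1, v2 = traj.column("V1"), traj.column("V2")
        rel = np.abs(v1 - v2) / np.maximum(v1, 1e-12)
        assert rel.max() < 1e-6

    def test_phage_conservation_without_cells(self, reference_params):
        """N = 0 throughout implies V1, V2 constant (no decay term)."""
        traj = simulate(PopulationState(V1=10.0, V2=5.0), reference_params,
                        10.0)
        assert np.allclose(traj.column("V1"), 10.0, rtol=1e-9)
        assert np.allclose(traj.column("V2"), 5.0, rtol=1e-9)

    def test_transfer_dilutes_all_compartments(self, reference_params):
        traj = simulate(PopulationState(W=1e3), reference_params, 2.0,
                        np.array([0.0, 0.999, 1.001, 2.0]),
                        transfers=[(1.0, 0.01)])
        kinds = [e.kind for e in traj.events]
        assert "transfer" in kinds
        w_before = traj.densities[1, 0]
        w_after = traj.densities[2, 0]
        assert w_after == pytest.approx(0.01 * w_before, rel=1e-2)

    def test_extinction_event_recorded_once(self, reference_params):
        traj = simulate(PopulationState(W=1e3, V2=100.0), reference_params,
                        30.0)
        ext = [e for e in traj.events if e.kind == "extinction"
               and e.detail == "V2"]
        assert len(ext) == 1
        i = int(np.argmax(traj.times >= ext[0].time))
        assert traj.densities[i, 4] < traj.extinction_threshold

    @pytest.mark.parametrize("bad", [
        [(0.5, 0.0)], [(0.5, 1.5)], [(-1.0, 0.5)], [(40.0, 0.5)],
    ])
    def test_invalid_transfer_schedule_rejected(self, bad,
                                                reference_params):
        with pytest.raises(ModelError):
            simulate(PopulationState(W=1e3), reference_params, 30.0,
                     transfers=bad)

    def test_non_monotone_sample_times_rejected(self, reference_params):
        with pytest.raises(ModelError, match="increasing"):
            simulate(PopulationState(W=1e3), reference_params, 10.0,
                     np.array([0.0, 5.0, 3.0]))

    @settings(max_examples=10)
    @given(
        phi=st.floats(0.0, 1.0), rho=st.floats(0.0, 1.0),
        A=st.floats(0.0, 1.0),
        gamma=st.floats(0.05, 20.0),
    )
    def test_densities_never_negative(self, phi, rho, A, gamma):
        p = ModelParameters(phi=phi, rho=rho, A=A, gamma=gamma)
        initial = PopulationState(W=1e3, V1=100.0, V2=100.0)
        traj = simulate(initial, p, 10.0, np.linspace(0.0, 10.0, 21))
        assert np.all(traj.densities >= 0.0)


class TestAnalyticLimits:
    def test_no_acquisition_means_no_resistance(self, mixed_initial):
        """A = 0: resistance is never acquired, so R and S stay zero and
        the two phage equations coincide."""
        traj = simulate(mixed_initial, ModelParameters(A=0.0), 30.0)
        # Zero is an exact fixed point of both equations; anything the
        # adaptive solver leaves behind is pure round-off.
        assert np.abs(traj.column("R")).max() < 1e-8
        assert np.abs(traj.column("S")).max() < 1e-8
        np.testing.assert_allclose(traj.column("V1"), traj.column("V2"),
                                   rtol=1e-9)

    def test_perfect_lysis_means_no_immunosuppression(self, mixed_initial):
        """phi = 1: the only production term for S carries (1 - phi)."""
        traj = simulate(mixed_initial, ModelParameters(phi=1.0), 30.0)
        assert np.abs(traj.column("S")).max() < 1e-8


class TestFinalPhageRatio:
    def test_symmetric_case_is_unity(self, mixed_initial):
        # Sample while both phage types are still above the extinction
        # threshold (with rho = 1 both behave as Acr-negative and are
        # eventually lost to resistance).
        traj = simulate(mixed_initial, ModelParameters(rho=1.0), 3.0)
        ratio = final_phage_ratio(traj)
        assert ratio.status == "ok"
        assert ratio.value == pytest.approx(1.0, rel=1e-6)

    def test_reference_mixed_infection_favours_acr_phage(
            self, reference_params, mixed_initial):
        traj = simulate(mixed_initial, reference_params, 30.0)
        ratio = final_phage_ratio(traj)
        assert ratio.status == "ok"
        assert ratio.value > 1.0

    def test_v2_extinct_gives_infinite_advantage_sentinel(self):
        traj = Trajectory(times=np.array([0.0, 1.0]),
                          densities=np.array([[1e3, 0, 0, 10.0, 1e-6],
                                              [1e3, 0, 0, 10.0, 1e-6]]),
                          parameters=ModelParameters())
        ratio = final_phage_ratio(traj)
        assert ratio.status == "v2_extinct"
        assert math.isinf(ratio.value)

    def test_both_extinct_is_undefined_not_an_exception(self):
        traj = Trajectory(times=np.array([0.0]),
                          densities=np.array([[1e3, 0, 0, 1e-9, 1e-9]]),
                          parameters=ModelParameters())
        ratio = final_phage_ratio(traj)
        assert ratio.status == "both_extinct"
        assert math.isnan(ratio.value)


def test_blowup_aborts_with_last_valid_state():
    """A genuinely negative post-step density (not round-off) aborts."""
    from acrdyn.model import _clip_roundoff

    with pytest.raises(IntegrationError) as err:
        _clip_roundoff(1.0, np.array([-1e-3, 0, 0, 0, 0]), 1e-9)
    assert err.value.t_last == 1.0
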
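"""Unit and property tests of the three-box N-P-O2 isotope model."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from nbox import (
    ModelParams,
    ModelState,
    NitrogenBoxModel,
    compute_tendencies,
    delta15N_from_ratio,
    fixation_flux,
    solve_steady_state,
)
from nbox.boxmodel import compute_fluxes, ratio_from_delta15N
from nbox.constants import R_AIR


class TestDelta15N:
    def test_reference_ratio_gives_zero(self):
        assert delta15N_from_ratio(R_AIR, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_linear_definition(self):
        assert delta15N_from_ratio(1.005 * R_AIR, 1.0) == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("delta", [-40.0, -5.0, 0.0, 3.2, 25.0, 120.0])
    def test_roundtrip_to_twelve_digits(self, delta):
        r = ratio_from_delta15N(delta)
        back = delta15N_from_ratio(r, 1.0)
        assert back == pytest.approx(delta, abs=1e-12 * max(1.0, abs(delta)))

    def test_zero_N14_is_undefined(self):
        assert np.isnan(delta15N_from_ratio(1e-9, 0.0))


class TestFixationFlux:
    def _state(self, P_surf, N_surf, params):
        s = ModelState.default_initial(params)
        s.P[0] = P_surf
        r = R_AIR
        s.N14[0] = N_surf / (1 + r)
        s.N15[0] = N_surf - s.N14[0]
        return s

    def test_no_deficit_no_fixation(self, closed_params):
        s = self._state(1.0e-3, 16.0e-3, closed_params)
        assert fixation_flux(s, closed_params) == 0.0

    def test_excess_N_clamped_at_zero(self, closed_params):
        s = self._state(1.0e-3, 20.0e-3, closed_params)
        assert fixation_flux(s, closed_params) == 0.0

    def test_hand_arithmetic_of_deficit_closure(self):
        # P=1, N=8, rNP=16, k_fix=1, V=1  ->  flux = 16*1 - 8 = 8
        p = ModelParams(k_fix=1.0, V_surf=1.0, rNP_uptake=16.0)
        s = self._state(1.0, 8.0, p)
        assert fixation_flux(s, p) == pytest.approx(8.0)


class TestTendencies:
    def test_no_transport_no_reaction_gives_zero(self):
        p = ModelParams(U=0.0, k_uptake=0.0, k_fix=0.0, k_O2_relax=0.0, W=0.0)
        s = ModelState.default_initial(p)
        s.O2[:] = p.O2_surf  # uniform tracers
        t = compute_tendencies(s, p)
        assert np.allclose(t.to_vector(), 0.0)

    def test_advective_flux_hand_arithmetic(self):
        # U = 0.1 Sv, rest-box P = 2 mmol/m3 -> P flux into OMZ = 200 mol/s
        p = ModelParams(U=0.1, k_uptake=0.0, k_fix=0.0, k_O2_relax=0.0)
        s = ModelState.default_initial(p)
        s.P[:] = [0.0, 0.0, 2.0e-3]
        t = compute_tendencies(s, p)
        assert t.P[1] * p.V_omz == pytest.approx(200.0)

    def test_denitrification_off_above_threshold(self, closed_params):
        s = ModelState.default_initial(closed_params)
        s.O2[1] = 10 * closed_params.O2_thresh  # well-oxygenated OMZ
        f = compute_fluxes(s, closed_params)
        assert f.denit_NO3 == pytest.approx(0.0, abs=1e-6 * max(f.export_N, 1.0))

    def test_negative_concentrations_rejected(self, closed_params):
        s = ModelState.default_initial(closed_params)
        s.P[0] = -1e-6
        with pytest.raises(ValueError, match="negative"):
            compute_tendencies(s, closed_params)

    def test_nan_parameter_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            ModelParams(eps_wc=np.nan)

    def test_hard_switch_variant_is_binary(self):
        p = ModelParams(o2_switch="hard")
        s = ModelState.default_initial(p)
        s.O2[1] = p.O2_thresh * 0.99
        low = compute_fluxes(s, p)
        s.O2[1] = p.O2_thresh * 1.01
        high = compute_fluxes(s, p)
        assert low.remin_P_omz_aerobic == 0.0
        assert high.remin_P_omz_aerobic == pytest.approx(
            p.remin_frac_omz * high.export_P
        )


class TestBookkeeping:
    """Flux bookkeeping closes identically at the tendency level."""

    @pytest.mark.parametrize("closed", [True, False])
    def test_total_N_tendency_equals_source_minus_sinks(self, closed):
        p = ModelParams(closed_P=closed)
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = ModelState(
                P=rng.uniform(0, 4e-3, 3),
                N14=rng.uniform(0, 40e-3, 3),
                N15=rng.uniform(0, 40e-3, 3) * R_AIR,
                O2=rng.uniform(0, 0.3, 3),
            )
            t = compute_tendencies(s, p)
            f = compute_fluxes(s, p)
            V = np.array([p.V_surf, p.V_omz, p.V_rest])
            dN = float(np.dot(t.N14 + t.N15, V))
            expected = f.fix_N - (f.denit_NO3 + f.denit_NO3_rest) - f.burial_N
            assert dN == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_closed_P_tendency_sums_to_zero(self, closed_params):
        rng = np.random.default_rng(5)
        V = np.array([closed_params.V_surf, closed_params.V_omz, closed_params.V_rest])
        for _ in range(20):
            s = ModelState(
                P=rng.uniform(0, 4e-3, 3),
                N14=rng.uniform(0, 40e-3, 3),
                N15=rng.uniform(0, 40e-3, 3) * R_AIR,
                O2=rng.uniform(0, 0.3, 3),
            )
            t = compute_tendencies(s, closed_params)
            f = compute_fluxes(s, closed_params)
            scale = max(f.export_P, closed_params.U_m3s * 4e-3, 1.0)
            assert float(np.dot(t.P, V)) == pytest.approx(0.0, abs=1e-12 * scale)

    def test_open_P_tendency_is_input_minus_burial(self, open_params):
        s = ModelState.default_initial(open_params)
        t = compute_tendencies(s, open_params)
        f = compute_fluxes(s, open_params)
        V = np.array([open_params.V_surf, open_params.V_omz, open_params.V_rest])
        assert float(np.dot(t.P, V)) == pytest.approx(
            open_params.W - f.burial_P, rel=1e-12, abs=1e-9
        )


class TestSteadyState:
    def test_closed_baseline_converges_and_conserves_P(self, closed_steady, closed_params):
        r = closed_steady
        assert r.converged
        assert r.f_burial_P == 0.0
        total = r.state.total_P_mol(closed_params)
        assert total == pytest.approx(closed_params.P_inventory_mol, rel=1e-8)

    def test_open_baseline_burial_balances_weathering(self, open_steady, open_params):
        r = open_steady
        assert r.converged
        assert r.f_burial_P == pytest.approx(open_params.W, rel=1e-6)

    def test_open_without_input_has_no_export(self):
        p = ModelParams(closed_P=False, W=0.0)
        r = solve_steady_state(p)
        assert r.converged
        assert r.export_P == pytest.approx(0.0, abs=1e-6)
        assert r.f_burial_P == pytest.approx(0.0, abs=1e-9)

    def test_surface_minus_export_equals_assimilation_eps(self, closed_steady, open_steady):
        for r in (closed_steady, open_steady):
            assert r.d15N_surface - r.d15N_export == pytest.approx(5.0, abs=1e-9)

    def test_isotope_flux_balance_at_steady_state(self, closed_steady, open_steady):
        """Source and sink isotopologue fluxes balance at convergence.

        Exact in 15N flux terms; the delta-weighted form of the same balance
        (source flux x delta = sum of sink flux x delta) holds to first order
        in the isotope ratio.
        """
        for steady in (closed_steady, open_steady):
            f = compute_fluxes(steady.state, steady.params)
            r_bur = f.r_export
            burial_15 = f.burial_N * r_bur / (1.0 + r_bur)
            sink_15 = f.denit_NO3_15 + f.denit_NO3_rest_15 + burial_15
            assert f.fix_N15 == pytest.approx(sink_15, rel=1e-6)
            # delta-weighted form, first order in r
            d_fix = delta15N_from_ratio(f.fix_N15, f.fix_N14)
            lhs = f.fix_N * d_fix
            rhs = (
                f.denit_NO3 * delta15N_from_ratio(f.denit_NO3_15, f.denit_NO3_14)
                + (f.denit_NO3_rest
                   * delta15N_from_ratio(f.denit_NO3_rest_15, f.denit_NO3_rest_14)
                   if f.denit_NO3_rest > 0 else 0.0)
                + f.burial_N * (r_bur / R_AIR - 1.0) * 1000.0
            )
            assert lhs == pytest.approx(rhs, abs=1e-3 * max(abs(lhs), abs(rhs), f.fix_N))

    def test_nonconvergence_is_flagged_not_raised(self):
        p = ModelParams(closed_P=False, U=0.0)  # no transport, constant P input
        r = solve_steady_state(p, t_max=1e10)
        assert isinstance(r.converged, (bool, np.bool_))

    def test_trajectory_conserves_closed_P(self, closed_params):
        """Total P drift along an integrated trajectory stays below 1e-8."""
        y0 = ModelState.default_initial(closed_params).to_vector()

        def rhs(t, y):
            return compute_tendencies(
                ModelState.from_vector(y), closed_params, validate=False
            ).to_vector()

        sol = solve_ivp(rhs, (0.0, 1e12), y0, method="LSODA", rtol=1e-10, atol=1e-14)
        V = np.array([closed_params.V_surf, closed_params.V_omz, closed_params.V_rest])
        totals = V @ sol.y[0:3]
        drift = np.max(np.abs(totals - totals[0])) / totals[0]
        assert drift < 1e-8

    def test_model_object_summary_mentions_setup(self, closed_steady):
        text = closed_steady.summary()
        assert "closed-P" in text and "converged: True" in text

    def test_model_class_wraps_solver(self, closed_params, closed_steady):
        m = NitrogenBoxModel(closed_params)
        r = m.steady_state()
        assert r.export_P == pytest.approx(closed_steady.export_P, rel=1e-6)
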
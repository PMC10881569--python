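"""CSTR mass balance: washout, conservation, relaxation, convergence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ernoed import (EnzymeLoading, FlowProfile, ReactorConfig, cstr_rhs,
                    fraction_times, observe, simulate)
from ernoed.network import OBSERVABLES


def dilution_steady_state(model, reactor, flows):
    stock = reactor.stock_matrix(model.species)
    return np.asarray(flows) @ stock / np.sum(flows)


class TestFlowProfile:
    def test_segments_must_be_contiguous(self):
        with pytest.raises(ValueError, match="contiguous"):
            FlowProfile(t_start=[0.0, 40.0], duration=[30.0, 30.0],
                        rates=np.ones((2, 6)))

    def test_total_flow_must_be_positive(self):
        with pytest.raises(ValueError, match="total flow"):
            FlowProfile.from_segments([(30.0, [0.0] * 6)])

    def test_level_validation(self, reactor):
        good = FlowProfile.constant([0.5, 1.0, 2.0, 0.0, 0.5, 1.0], 60.0)
        good.validate_levels(reactor)
        bad = FlowProfile.constant([0.7, 1.0, 2.0, 0.0, 0.5, 1.0], 60.0)
        with pytest.raises(ValueError, match="allowed levels"):
            bad.validate_levels(reactor)

    def test_segment_lookup_and_horizon(self, three_segment_profile):
        p = three_segment_profile
        assert p.horizon == 90.0
        assert p.segment_index(0.0) == 0
        assert p.segment_index(30.0) == 1
        assert p.segment_index(89.9) == 2
        with pytest.raises(ValueError):
            p.segment_index(91.0)


class TestWashout:
    def test_no_enzyme_steady_state_matches_dilution_closed_form(
            self, salvage_model, reactor, nominal):
        flows = np.array([0.5, 1.0, 2.0, 0.5, 1.0, 0.5])
        tau = reactor.volume_ul / flows.sum()
        profile = FlowProfile.constant(flows, 12 * tau)
        loading = EnzymeLoading({e: 0.0 for e in salvage_model.enzymes})
        traj = simulate(salvage_model, nominal, profile, reactor,
                        [12 * tau], loading=loading)
        expected = dilution_steady_state(salvage_model, reactor, flows)
        mask = expected > 0
        np.testing.assert_allclose(traj.states[-1][mask], expected[mask],
                                   rtol=1e-3)

    def test_step_change_relaxes_with_residence_time_constant(
            self, salvage_model, reactor, nominal):
        # no reactions: after a total-flow step the approach to the new
        # dilution steady state is exponential with tau = V / q_tot
        flows1 = np.array([2.0] * 6)
        flows2 = np.array([0.5] * 6)
        loading = EnzymeLoading({e: 0.0 for e in salvage_model.enzymes})
        profile = FlowProfile.from_segments([(200.0, flows1),
                                             (200.0, flows2)])
        tau2 = reactor.volume_ul / flows2.sum()
        t_probe = 200.0 + np.array([0.25, 0.5, 1.0, 2.0]) * tau2
        traj = simulate(salvage_model, nominal, profile, reactor,
                        np.concatenate([[200.0], t_probe]),
                        loading=loading, rtol=1e-10, atol=1e-12)
        c0 = traj.states[0]
        cinf = dilution_steady_state(salvage_model, reactor, flows2)
        idx = salvage_model.species.index("uracil")
        expected = cinf[idx] + (c0[idx] - cinf[idx]) * np.exp(
            -(t_probe - 200.0) / tau2)
        np.testing.assert_allclose(traj.states[1:, idx], expected,
                                   rtol=1e-2)


class TestBatchConservation:
    def test_base_moieties_conserved_without_flow(self, salvage_model,
                                                  nominal, reactor, rng):
        y0 = rng.uniform(0.05, 1.0, salvage_model.n_species)
        times = np.array([10.0, 60.0, 240.0])
        traj = simulate(salvage_model, nominal, None, reactor, times,
                        y0=y0, rtol=1e-10, atol=1e-12)
        from ernoed.network import MOIETIES
        for weights in MOIETIES.values():
            idx = [salvage_model.species.index(s) for s in weights]
            w = np.array([weights[s] for s in weights])
            totals = traj.states[:, idx] @ w
            ref = y0[idx] @ w
            np.testing.assert_allclose(totals, ref, rtol=1e-6)

    def test_no_negative_concentrations(self, salvage_model, nominal,
                                        reactor, three_segment_profile):
        times = fraction_times(reactor, three_segment_profile.horizon)
        traj = simulate(salvage_model, nominal, three_segment_profile,
                        reactor, times)
        assert traj.states.min() > -1e-9


class TestIntegrationAccuracy:
    def test_single_reaction_toy_matches_independent_integration(
            self, toy_model, reactor):
        """Brute-force oracle: re-integrate the same mass balance with an
        independently written RHS (no shared kinetics code)."""
        theta = toy_model.nominal_parameters()
        td = theta.as_dict()
        flows = np.array([1.0, 0.5, 0.5, 0.5, 0.5, 2.0])
        profile = FlowProfile.constant(flows, 120.0)
        times = np.array([20.0, 60.0, 120.0])
        traj = simulate(toy_model, theta, profile, reactor, times,
                        rtol=1e-10, atol=1e-12)

        sp = list(toy_model.species)
        stock = reactor.stock_matrix(sp)
        feed = flows @ stock / reactor.volume_ul
        dil = flows.sum() / reactor.volume_ul
        iu, ip, im, ippi = (sp.index(s) for s in
                            ("uracil", "PRPP", "UMP", "PPi"))

        def rhs(t, c):
            occ_u = c[iu] / td["UPRT.Km_uracil"]
            occ_p = c[ip] / td["UPRT.Km_PRPP"]
            den = ((1 + occ_u + c[im] / td["UPRT.Km_UMP"])
                   * (1 + occ_p + c[ippi] / td["UPRT.Km_PPi"]))
            v = td["UPRT.Vf"] * occ_u * occ_p / den
            dc = feed - dil * c
            dc[iu] -= v
            dc[ip] -= v
            dc[im] += v
            dc[ippi] += v
            return dc

        sol = solve_ivp(rhs, (0, 120.0), np.zeros(len(sp)), t_eval=times,
                        method="LSODA", rtol=1e-12, atol=1e-14)
        np.testing.assert_allclose(traj.states, sol.y.T, rtol=1e-6,
                                   atol=1e-12)

    def test_halving_tolerances_changes_little(self, salvage_model, nominal,
                                               reactor,
                                               three_segment_profile):
        times = fraction_times(reactor, three_segment_profile.horizon)
        a = simulate(salvage_model, nominal, three_segment_profile, reactor,
                     times, rtol=1e-8, atol=1e-10)
        b = simulate(salvage_model, nominal, three_segment_profile, reactor,
                     times, rtol=5e-9, atol=5e-11)
        scale = np.abs(a.states).max()
        assert np.abs(a.states - b.states).max() / scale < 1e-5


class TestObservation:
    def test_observation_projects_exactly_eight_species(
            self, salvage_model, nominal, reactor, three_segment_profile):
        times = fraction_times(reactor, three_segment_profile.horizon)
        traj = simulate(salvage_model, nominal, three_segment_profile,
                        reactor, times)
        table = observe(traj)
        assert set(table["species"]) == set(OBSERVABLES)
        assert len(set(table["species"])) == 8
        # observables are a subset of the state
        for s in OBSERVABLES:
            idx = salvage_model.species.index(s)
            sub = table[table["species"] == s]
            np.testing.assert_array_equal(
                sub["concentration_mM"].to_numpy(), traj.states[:, idx])

    def test_fraction_times_spacing(self):
        r = ReactorConfig(fraction_interval_min=30.0)
        times = fraction_times(r, 300.0)
        assert len(times) == 10
        np.testing.assert_allclose(times, 30.0 * np.arange(1, 11))

    def test_cstr_rhs_rejects_time_outside_horizon(
            self, salvage_model, nominal, reactor, three_segment_profile):
        state = np.zeros(salvage_model.n_species)
        with pytest.raises(ValueError):
            cstr_rhs(salvage_model, nominal, state, three_segment_profile,
                     1e4, reactor)
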
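"""Forward sensitivities, Fisher information, D-criterion, correlations."""

import numpy as np
import pytest

from ernoed import (EnzymeLoading, FisherInformation, d_score,
                    fisher_information, forward_sensitivities,
                    fraction_times, sensitivity_correlations, simulate)
from ernoed.sensitivity import SensitivityTrajectory


@pytest.fixture(scope="module")
def sens(salvage_model, nominal, reactor, three_segment_profile):
    times = fraction_times(reactor, three_segment_profile.horizon)
    return forward_sensitivities(salvage_model, nominal,
                                 three_segment_profile, reactor, times)


class TestForwardSensitivities:
    def test_initial_sensitivities_are_exactly_zero(
            self, salvage_model, nominal, reactor, three_segment_profile):
        s = forward_sensitivities(salvage_model, nominal,
                                  three_segment_profile, reactor,
                                  [0.0, 30.0])
        assert np.all(s.S[0] == 0.0)
        assert np.any(s.S[1] != 0.0)

    def test_matches_central_finite_differences(
            self, sens, salvage_model, nominal, reactor,
            three_segment_profile, rng):
        """Independent oracle: central differences of plain simulations."""
        times = sens.times
        obs_idx = [salvage_model.species.index(s) for s in sens.observables]
        theta = nominal.values
        scale = np.abs(sens.S).max()
        for p in rng.choice(salvage_model.n_parameters, 8, replace=False):
            h = 1e-4 * theta[p]
            up, dn = theta.copy(), theta.copy()
            up[p] += h
            dn[p] -= h
            f_up = simulate(salvage_model, up, three_segment_profile,
                            reactor, times, rtol=1e-10, atol=1e-12)
            f_dn = simulate(salvage_model, dn, three_segment_profile,
                            reactor, times, rtol=1e-10, atol=1e-12)
            fd = (f_up.states[:, obs_idx] - f_dn.states[:, obs_idx]) / (2 * h)
            assert np.abs(sens.S[:, :, p] - fd).max() / scale < 1e-3

    def test_staggered_propagation_agrees_with_exact(
            self, salvage_model, nominal, reactor, three_segment_profile,
            sens):
        fast = forward_sensitivities(
            salvage_model, nominal, three_segment_profile, reactor,
            sens.times, method="staggered", rtol=1e-6, atol=1e-8)
        scale = np.abs(sens.S).max()
        assert np.abs(fast.S - sens.S).max() / scale < 2e-3
        np.testing.assert_allclose(fast.states, sens.states, rtol=1e-4,
                                   atol=1e-8)

    def test_unloaded_enzyme_parameters_have_zero_sensitivity(
            self, salvage_model, nominal, reactor, three_segment_profile):
        loading = EnzymeLoading({"UPRT": 0.0})
        s = forward_sensitivities(salvage_model, nominal,
                                  three_segment_profile, reactor,
                                  [30.0, 60.0], loading=loading)
        for name in salvage_model.parameter_names:
            p = salvage_model.parameter_index(name)
            if name.startswith("UPRT."):
                assert np.abs(s.S[:, :, p]).max() == pytest.approx(0.0,
                                                                   abs=1e-12)


class TestFisherInformation:
    def test_single_parameter_matches_hand_sum(self):
        S = np.array([[[0.5], [1.0]], [[2.0], [0.0]]])  # (2 times, 2 obs, 1)
        sens = SensitivityTrajectory(
            times=np.array([1.0, 2.0]), S=S, states=np.zeros((2, 15)),
            observables=("a", "b"), parameter_names=("p",))
        F = fisher_information(sens, sigma=2.0, theta=np.array([3.0]))
        expected = sum((s * 3.0 / 2.0) ** 2 for s in (0.5, 1.0, 2.0, 0.0))
        assert F.matrix[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_duplicating_timepoints_doubles_information(self, sens, nominal):
        F1 = fisher_information(sens, 0.05, nominal.values).matrix
        doubled = SensitivityTrajectory(
            times=np.concatenate([sens.times, sens.times + 100.0]),
            S=np.concatenate([sens.S, sens.S]),
            states=np.concatenate([sens.states, sens.states]),
            observables=sens.observables,
            parameter_names=sens.parameter_names)
        F2 = fisher_information(doubled, 0.05, nominal.values).matrix
        np.testing.assert_allclose(F2, 2 * F1, rtol=1e-12)

    def test_matches_bruteforce_outer_product_accumulation(self, sens,
                                                           nominal):
        """Oracle: explicit per-point outer products in a separate loop."""
        theta = nominal.values
        sigma = 0.05
        F = fisher_information(sens, sigma, theta).matrix
        nt, no, p = sens.S.shape
        brute = np.zeros((p, p))
        for k in range(nt):
            for o in range(no):
                v = sens.S[k, o, :] * theta / sigma
                brute += np.outer(v, v)
        assert np.abs(F - brute).max() <= 1e-10 * max(1.0, np.abs(brute).max())

    def test_dimension_mismatch_rejected(self, sens):
        with pytest.raises(ValueError):
            fisher_information(sens, 0.05, np.ones(3))

    def test_psd_validation(self):
        with pytest.raises(ValueError):
            FisherInformation(np.array([[1.0, 0.0], [0.0, -1.0]]),
                              sigma=np.array(1.0))


class TestDScore:
    def test_doubling_law(self, sens, nominal):
        F = fisher_information(sens, 0.05, nominal.values)
        p = F.n_parameters
        s1 = d_score(F, ridge=1e-300)
        s2 = d_score(FisherInformation(2 * F.matrix, F.sigma), ridge=1e-300)
        assert s2 - s1 == pytest.approx(p * np.log(2.0), abs=1e-9)

    def test_three_by_three_matches_direct_determinant(self):
        A = np.array([[4.0, 1.0, 0.5], [1.0, 3.0, 0.2], [0.5, 0.2, 2.0]])
        F = FisherInformation(A, sigma=np.array(1.0))
        assert d_score(F, ridge=0.0) == pytest.approx(
            np.log(np.linalg.det(A)), abs=1e-12)

    def test_rank_deficient_needs_ridge(self):
        A = np.outer([1.0, 2.0], [1.0, 2.0])  # rank 1
        F = FisherInformation(A, sigma=np.array(1.0))
        with pytest.raises(np.linalg.LinAlgError):
            d_score(F, ridge=0.0)
        assert np.isfinite(d_score(F, ridge=1e-6))

    def test_default_ridge_recorded(self, sens, nominal):
        F = fisher_information(sens, 0.05, nominal.values)
        d_score(F)
        assert F.ridge is not None and F.ridge > 0

    def test_adding_timepoints_never_decreases_score(
            self, salvage_model, nominal, reactor, three_segment_profile):
        # information is a sum of PSD contributions
        all_times = fraction_times(reactor, three_segment_profile.horizon)
        s_all = forward_sensitivities(salvage_model, nominal,
                                      three_segment_profile, reactor,
                                      all_times)
        theta = nominal.values
        F_all = fisher_information(s_all, 0.05, theta)
        ridge = 1e-8 * np.trace(F_all.matrix) / F_all.n_parameters
        prev = -np.inf
        for n in (2, 4, len(all_times)):
            sub = SensitivityTrajectory(
                times=s_all.times[:n], S=s_all.S[:n],
                states=s_all.states[:n], observables=s_all.observables,
                parameter_names=s_all.parameter_names)
            score = d_score(fisher_information(sub, 0.05, theta),
                            ridge=ridge)
            assert score >= prev - 1e-9
            prev = score


class TestCorrelations:
    def test_diagonal_is_one_and_duplicates_correlate_fully(self):
        base = np.random.default_rng(0).normal(size=(5, 2, 1))
        S = np.concatenate([base, base, -base], axis=2)
        sens = SensitivityTrajectory(
            times=np.arange(5.0), S=S, states=np.zeros((5, 15)),
            observables=("a", "b"), parameter_names=("p", "q", "r"))
        corr, flags = sensitivity_correlations(sens)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert corr[0, 1] == pytest.approx(1.0)
        assert corr[0, 2] == pytest.approx(-1.0)  # opposing effect
        assert not flags.any()

    def test_zero_variance_parameter_flagged_and_zeroed(self):
        S = np.zeros((4, 1, 2))
        S[:, 0, 0] = [1.0, 2.0, 3.0, 4.0]
        sens = SensitivityTrajectory(
            times=np.arange(4.0), S=S, states=np.zeros((4, 15)),
            observables=("a",), parameter_names=("p", "dead"))
        corr, flags = sensitivity_correlations(sens)
        assert flags[1] and not flags[0]
        assert corr[0, 1] == 0.0 and corr[1, 1] == 1.0

    def test_requires_two_timepoints(self, sens):
        one = SensitivityTrajectory(
            times=sens.times[:1], S=sens.S[:1], states=sens.states[:1],
            observables=sens.observables,
            parameter_names=sens.parameter_names)
        with pytest.raises(ValueError):
            sensitivity_correlations(one)

    def test_salvage_correlation_matrix_is_valid(self, sens, nominal):
        corr, flags = sensitivity_correlations(sens, nominal.values)
        assert corr.shape == (41, 41)
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        assert np.abs(corr).max() <= 1.0 + 1e-12
        # strong couplings exist (the unidentifiability signal)
        off = corr[~np.eye(41, dtype=bool)]
        assert np.abs(off).max() > 0.9


class TestIdentifiabilitySignal:
    def test_unfed_substrate_silences_its_enzyme_parameters(
            self, salvage_model, nominal, reactor):
        # never feed uracil: UPRT never carries flux, so its parameters
        # produce (near-)zero FIM rows/columns
        from ernoed import FlowProfile
        profile = FlowProfile.constant([0.0, 1.0, 1.0, 1.0, 1.0, 1.0],
                                       90.0)
        times = fraction_times(reactor, profile.horizon)
        s = forward_sensitivities(salvage_model, nominal, profile, reactor,
                                  times)
        F = fisher_information(s, 0.05, nominal.values).matrix
        uprt = [salvage_model.parameter_index(n)
                for n in salvage_model.parameter_names
                if n.startswith("UPRT.")]
        scale = np.abs(np.diag(F)).max()
        assert np.abs(F[uprt, :]).max() <= 1e-10 * scale
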
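"""Fit objective, multistart optimisation, ensembles and predictions."""

import numpy as np
import pandas as pd
import pytest

from ernoed import (EnzymeLoading, ExperimentRound, FlowProfile,
                    ParameterEnsemble, TimeCourseDataset, fraction_times,
                    multistart_fit, objective, observe, prediction_error,
                    predict_with_ensemble, select_ensemble, simulate)
from ernoed.estimation import FitPoint, FitResult


def noiseless_round(model, theta, profile, reactor, sigma=0.02,
                    round_id="round0"):
    from ernoed.network import OBSERVABLES
    times = fraction_times(reactor, profile.horizon)
    traj = simulate(model, theta, profile, reactor, times)
    table = observe(traj, observables=[s for s in OBSERVABLES
                                       if s in model.species])
    table["sigma_mM"] = sigma
    return ExperimentRound(round_id=round_id, profile=profile,
                           loading=EnzymeLoading(), table=table)


@pytest.fixture(scope="module")
def toy_round(toy_model, reactor):
    theta = toy_model.nominal_parameters()
    profile = FlowProfile.from_segments([
        (30.0, [1.0, 0.5, 0.5, 0.5, 0.5, 2.0]),
        (30.0, [0.5, 0.5, 0.5, 0.5, 0.5, 0.5]),
        (30.0, [2.0, 0.5, 0.5, 0.5, 0.5, 1.0]),
    ])
    return noiseless_round(toy_model, theta, profile, reactor)


class TestObjective:
    def test_zero_at_generating_parameters(self, toy_model, reactor,
                                           toy_round):
        ds = TimeCourseDataset([toy_round])
        score = objective(toy_model.nominal_parameters(), ds, toy_model,
                          reactor)
        assert score < 1e-8

    def test_doubling_sigma_quarters_score(self, toy_model, reactor,
                                           toy_round, rng):
        theta = toy_model.nominal_parameters()
        off = theta.replace_values(theta.values * 1.3)
        ds1 = TimeCourseDataset([toy_round])
        table2 = toy_round.table.assign(
            sigma_mM=2 * toy_round.table["sigma_mM"])
        ds2 = TimeCourseDataset([ExperimentRound(
            "round0", toy_round.profile, toy_round.loading, table2)])
        s1 = objective(off, ds1, toy_model, reactor)
        s2 = objective(off, ds2, toy_model, reactor)
        assert s1 > 0
        assert s2 == pytest.approx(s1 / 4.0, rel=1e-12)

    def test_matches_hand_computed_chi_square(self, salvage_model, reactor,
                                              nominal,
                                              three_segment_profile):
        times = np.array([30.0, 60.0, 90.0])
        traj = simulate(salvage_model, nominal, three_segment_profile,
                        reactor, times, rtol=1e-10, atol=1e-12)
        i_atp = salvage_model.species.index("ATP")
        sim = traj.states[:, i_atp]
        obs = sim + np.array([0.01, -0.02, 0.005])
        sig = np.array([0.01, 0.02, 0.05])
        table = pd.DataFrame({
            "time_min": times, "species": ["ATP"] * 3,
            "concentration_mM": obs, "sigma_mM": sig})
        ds = TimeCourseDataset([ExperimentRound(
            "round0", three_segment_profile, EnzymeLoading(), table)])
        expected = float(np.sum(((sim - obs) / sig) ** 2))
        assert objective(nominal, ds, salvage_model, reactor) \
            == pytest.approx(expected, rel=1e-5)

    def test_round_validation(self, three_segment_profile):
        table = pd.DataFrame({
            "time_min": [30.0], "species": ["ATP"],
            "concentration_mM": [1.0], "sigma_mM": [0.0]})
        with pytest.raises(ValueError, match="sigma"):
            ExperimentRound("r", three_segment_profile, EnzymeLoading(),
                            table)
        table2 = pd.DataFrame({
            "time_min": [30.0], "species": ["PRPP"],  # not observable
            "concentration_mM": [1.0], "sigma_mM": [0.1]})
        with pytest.raises(ValueError, match="non-observable"):
            ExperimentRound("r", three_segment_profile, EnzymeLoading(),
                            table2)


class TestMultistartFit:
    def test_start_at_truth_is_a_fixed_point(self, toy_model, reactor,
                                             toy_round):
        ds = TimeCourseDataset([toy_round])
        theta = toy_model.nominal_parameters()
        fit = multistart_fit(ds, toy_model, reactor, n_starts=1, rng=0,
                             x0=[theta.values], include_nominal=False,
                             max_nfev=20)
        best = fit.best
        assert best.score < 1e-6
        np.testing.assert_allclose(best.theta.values, theta.values,
                                   rtol=1e-2)

    def test_deterministic_given_seed(self, toy_model, reactor, toy_round):
        ds = TimeCourseDataset([toy_round])
        f1 = multistart_fit(ds, toy_model, reactor, n_starts=2, rng=42,
                            max_nfev=10)
        f2 = multistart_fit(ds, toy_model, reactor, n_starts=2, rng=42,
                            max_nfev=10)
        for a, b in zip(f1.points, f2.points):
            assert a.score == b.score
            np.testing.assert_array_equal(a.theta.values, b.theta.values)

    def test_beats_coarse_grid_on_two_parameter_slice(self, toy_model,
                                                      reactor, toy_round):
        """Grid oracle: the optimiser over all parameters must do at least
        as well as a 50x50 brute-force scan of a 2-parameter slice."""
        ds = TimeCourseDataset([toy_round])
        theta = toy_model.nominal_parameters()
        iv = toy_model.parameter_index("UPRT.Vf")
        ik = toy_model.parameter_index("UPRT.Km_uracil")
        grid_best = np.inf
        for v in np.geomspace(theta.lower[iv], theta.upper[iv], 50):
            for k in np.geomspace(theta.lower[ik], theta.upper[ik], 50):
                vals = theta.values.copy()
                vals[iv], vals[ik] = v, k
                grid_best = min(grid_best,
                                objective(vals, ds, toy_model, reactor))
        fit = multistart_fit(ds, toy_model, reactor, n_starts=4, rng=1,
                             max_nfev=25)
        assert fit.best.score <= grid_best + 1e-9


class TestEnsembleSelection:
    def _result(self, scores):
        rng = np.random.default_rng(0)
        points = []
        for s in scores:
            vals = rng.uniform(0.5, 1.5, 3)
            theta = type("T", (), {})()
            from ernoed import KineticParameters
            theta = KineticParameters(("a", "b", "c"), vals,
                                      np.full(3, 0.01), np.full(3, 10.0))
            points.append(FitPoint(theta=theta, score=float(s),
                                   success=True))
        return FitResult(points)

    def test_fifteen_percent_rule(self):
        ens = select_ensemble(self._result([100.0, 110.0, 116.0]),
                              tolerance=0.15)
        assert ens.scores == [100.0, 110.0]
        assert ens.best_score == 100.0

    def test_zero_tolerance_keeps_only_ties(self):
        ens = select_ensemble(self._result([50.0, 50.0, 51.0]),
                              tolerance=0.0)
        assert all(s == 50.0 for s in ens.scores)

    def test_duplicates_are_removed(self):
        from ernoed import KineticParameters
        vals = np.array([1.0, 2.0, 3.0])
        mk = lambda v, s: FitPoint(
            KineticParameters(("a", "b", "c"), v, np.full(3, 0.01),
                              np.full(3, 10.0)), s, True)
        fit = FitResult([mk(vals, 10.0), mk(vals * (1 + 1e-5), 10.1),
                         mk(vals * 2, 10.2)])
        ens = select_ensemble(fit, tolerance=0.15)
        assert len(ens) == 2

    def test_cap_at_max_members(self):
        ens = select_ensemble(self._result(list(100.0 + 0.1 * np.arange(30))),
                              tolerance=0.15, max_members=20)
        assert len(ens) == 20

    def test_member_outside_tolerance_rejected_by_invariant(self):
        from ernoed import KineticParameters
        theta = KineticParameters(("a",), np.array([1.0]),
                                  np.array([0.1]), np.array([10.0]))
        with pytest.raises(ValueError):
            ParameterEnsemble(members=[theta, theta], scores=[100.0, 130.0],
                              best_score=100.0, tolerance=0.15)


class TestEnsemblePrediction:
    def _ensemble(self, model, factors):
        nominal = model.nominal_parameters()
        members = [nominal.replace_values(nominal.values * f)
                   for f in factors]
        return ParameterEnsemble(members=members,
                                 scores=[1.0] * len(members),
                                 best_score=1.0, tolerance=0.15)

    def test_identical_members_have_zero_sd(self, toy_model, reactor,
                                            toy_round):
        ens = self._ensemble(toy_model, [1.0, 1.0, 1.0])
        pred = predict_with_ensemble(ens, toy_model, toy_round.profile,
                                     reactor, toy_round.times)
        assert (pred["sd_mM"] == 0.0).all()

    def test_two_member_sd_is_half_the_gap(self, toy_model, reactor,
                                           toy_round):
        ens = self._ensemble(toy_model, [0.8, 1.2])
        times = toy_round.times
        pred = predict_with_ensemble(ens, toy_model, toy_round.profile,
                                     reactor, times)
        t1 = simulate(toy_model, ens.members[0], toy_round.profile,
                      reactor, times)
        t2 = simulate(toy_model, ens.members[1], toy_round.profile,
                      reactor, times)
        i_ump = toy_model.species.index("UMP")
        gap = np.abs(t1.states[:, i_ump] - t2.states[:, i_ump])
        sub = pred[pred["species"] == "UMP"]
        np.testing.assert_allclose(sub["sd_mM"].to_numpy(), gap / 2,
                                   rtol=1e-9, atol=1e-15)


class TestPredictionError:
    def _frames(self, sims, obs, species=("UTP", "GTP", "ATP")):
        pred = pd.DataFrame({
            "time_min": [10.0] * len(species), "species": list(species),
            "mean_mM": sims, "sd_mM": 0.0})
        observed = pd.DataFrame({
            "time_min": [10.0] * len(species), "species": list(species),
            "concentration_mM": obs})
        return pred, observed

    def test_perfect_prediction_is_zero(self):
        pred, obs = self._frames([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert prediction_error(pred, obs) == 0.0

    def test_hand_computed_example(self):
        pred, obs = self._frames([1.1, 0.9, 1.0], [1.0, 1.0, 1.0])
        assert prediction_error(pred, obs) == pytest.approx(20.0 / 3.0,
                                                            rel=1e-12)

    def test_scale_invariance(self):
        p1, o1 = self._frames([1.1, 0.9, 1.2], [1.0, 1.0, 1.0])
        p2, o2 = self._frames([11.0, 9.0, 12.0], [10.0, 10.0, 10.0])
        assert prediction_error(p1, o1) == pytest.approx(
            prediction_error(p2, o2), rel=1e-12)

    def test_zero_observations_are_excluded_with_warning(self):
        pred, obs = self._frames([1.1, 0.9, 1.0], [1.0, 0.0, 1.0])
        with pytest.warns(UserWarning, match="zero observations"):
            value, per_species = prediction_error(pred, obs,
                                                  return_per_species=True)
        assert "GTP" not in per_species
        assert value == pytest.approx((10.0 + 0.0) / 2.0, rel=1e-12)
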
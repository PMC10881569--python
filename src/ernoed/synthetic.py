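"""Virtual experimenter: seeded ground truth plus an HPLC-like noise model.

This module stands in for the wet lab so the full active-learning pipeline
(design -> experiment -> fit -> control) can be exercised end to end.  A
ground-truth parameter vector is drawn once per seed, simulated under any
flow profile, projected onto the eight HPLC-observable species at
fraction-collection times, and corrupted with concentration-dependent
Gaussian noise sigma(C) = max(sigma0, CV * C) truncated at zero.  Records
below the quantification limit are reported at the limit with inflated
uncertainty, emulating the loss of signal-to-noise at low concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import EnzymeLoading, KineticParameters, NetworkModel
from .reactor import (FlowProfile, ReactorConfig, fraction_times, observe,
                      simulate)

__all__ = [
    "NoiseModel",
    "GroundTruth",
    "make_ground_truth",
    "run_virtual_experiment",
    "calibration_profile",
    "VirtualExperimenter",
]


@dataclass(frozen=True)
class NoiseModel:
    """Concentration-dependent measurement noise.

    ``sigma(C) = max(sigma0, cv * C)``: proportional above the additive
    floor, flat below it.  Values below ``quant_limit`` are censored to the
    limit with sigma inflated to at least the limit itself.
    """

    cv: float = 0.05
    sigma0_mM: float = 0.01
    quant_limit_mM: float = 0.005

    def __post_init__(self) -> None:
        if self.cv < 0 or self.sigma0_mM <= 0:
            raise ValueError("require cv >= 0 and sigma0 > 0")

    def sigma(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return np.maximum(self.sigma0_mM, self.cv * np.abs(conc))

    def apply(self, conc, rng: np.random.Generator):
        """Return (noisy value, reported sigma) for true concentrations."""
        conc = np.asarray(conc, dtype=float)
        sig = self.sigma(conc)
        noisy = np.maximum(0.0, conc + rng.normal(0.0, sig))
        censored = noisy < self.quant_limit_mM
        noisy = np.where(censored, self.quant_limit_mM, noisy)
        rep_sig = np.where(censored, np.maximum(sig, self.quant_limit_mM), sig)
        return noisy, rep_sig


@dataclass
class GroundTruth:
    """The hidden true system a virtual experiment samples from."""

    theta: KineticParameters
    reactor: ReactorConfig
    seed: int
    loading: EnzymeLoading = field(default_factory=EnzymeLoading)
    resamples: int = 0

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "resamples": self.resamples,
            "loading": dict(self.loading.loading),
            "theta": self.theta.as_dict(),
        }


def _log_uniform_central(rng: np.random.Generator, lo: np.ndarray,
                         hi: np.ndarray, central: float = 0.5) -> np.ndarray:
    """Draw log-uniformly from the central fraction of [lo, hi] (log scale)."""
    llo, lhi = np.log(lo), np.log(hi)
    pad = (1.0 - central) / 2.0 * (lhi - llo)
    return np.exp(rng.uniform(llo + pad, lhi - pad))


def _draw_theta(rng: np.random.Generator, model: NetworkModel,
                nominal) -> np.ndarray:
    """One candidate truth vector.

    Michaelis/inhibition constants are log-uniform within the central half
    (log scale) of their bounds, so the truth never sits on a bound.
    Forward catalytic rates are log-uniform over 0.32-3.2 mM/min: the
    study balanced per-enzyme bead loading from activity assays, so
    effective activities are workable and of order 1 mM/min rather than
    scattered over the full fitting range.  Pyruvate-kinase reverse rates
    are drawn 1-2 decades below their forward rates because PEP
    phosphotransfer is strongly exergonic; the reaction stays mechanically
    reversible but thermodynamically forward-biased.
    """
    values = _log_uniform_central(rng, nominal.lower, nominal.upper)
    names = model.parameter_names
    for i, name in enumerate(names):
        if name.endswith(".Vf"):
            values[i] = np.clip(10.0 ** rng.uniform(-0.5, 0.5),
                                nominal.lower[i], nominal.upper[i])
    for rxn in model.reactions:
        if rxn.enzyme == "PK" and rxn.reversible:
            i_f = names.index(f"{rxn.id}.Vf")
            i_r = names.index(f"{rxn.id}.Vr")
            values[i_r] = np.clip(
                values[i_f] * 10.0 ** rng.uniform(-2.0, -1.0),
                nominal.lower[i_r], nominal.upper[i_r])
    return values


def make_ground_truth(seed: int, model: NetworkModel,
                      reactor: ReactorConfig | None = None,
                      max_resamples: int = 100, *,
                      probe_conditions: int = 256,
                      eff_target_pct: float = 60.0,
                      eff_quota: float = 0.01) -> GroundTruth:
    """Draw a viable true parameter vector (see :func:`_draw_theta`);
    deterministic per seed.

    Viability screen (non-viable draws are resampled, count recorded):

    * the calibration profile produces each triphosphate above the
      quantification limit at some timepoint, and
    * the network is controllable in the sense the study demonstrates — at
      least ``eff_quota`` of a fixed probe of random constant-inflow
      conditions reaches ``eff_target_pct`` conversion efficiency at
      steady state.
    """
    from .control import conversion_efficiency, sample_conditions, steady_state

    reactor = reactor or ReactorConfig()
    rng = np.random.default_rng(seed)
    nominal = model.nominal_parameters()
    profile = calibration_profile(reactor)
    times = fraction_times(reactor, profile.horizon)
    ntp_idx = [model.species.index(s) for s in ("UTP", "GTP", "ATP")]
    lo = np.array([0.0] * 6)
    hi = np.array([max(reactor.flow_levels)] * 6)
    probe = sample_conditions(probe_conditions, tuple(zip(lo, hi)),
                              rng=np.random.default_rng(seed + 2 ** 20))
    for attempt in range(max_resamples):
        theta = nominal.replace_values(_draw_theta(rng, model, nominal))
        try:
            traj = simulate(model, theta, profile, reactor, times)
        except Exception:
            continue
        if not np.all(traj.states[:, ntp_idx].max(axis=0) > 0.01):
            continue
        hits = 0
        for flows in probe:
            state, converged = steady_state(model, theta, flows, reactor)
            if not converged:
                continue
            feed = reactor.feed_concentrations(flows)
            outflow = dict(zip(("UTP", "GTP", "ATP"), state[ntp_idx]))
            if conversion_efficiency(outflow, feed) >= eff_target_pct:
                hits += 1
            if hits >= eff_quota * probe_conditions:
                return GroundTruth(theta=theta, reactor=reactor, seed=seed,
                                   resamples=attempt)
    raise RuntimeError(f"no viable ground truth within {max_resamples} draws")


def calibration_profile(reactor: ReactorConfig,
                        segment_min: float | None = None) -> FlowProfile:
    """Manually designed staircase used for the initial calibration round.

    Every inlet is cycled through its three positive pump levels: an
    all-inlets-low baseline segment is followed, per inlet, by one segment
    at the mid and one at the high level (the low level is covered by the
    baselines), then a closing baseline.  The first model fit therefore
    sees every inlet at every operating level.
    """
    low, mid, high = reactor.positive_levels[:3]
    dt = segment_min if segment_min is not None else reactor.fraction_interval_min
    n = len(reactor.inlets)
    baseline = [low] * n
    segments: list[tuple[float, list[float]]] = [(dt, baseline)]
    for i in range(n):
        for level in (mid, high):
            rates = list(baseline)
            rates[i] = level
            segments.append((dt, rates))
        segments.append((dt, baseline))
    return FlowProfile.from_segments(segments)


def run_virtual_experiment(truth: GroundTruth, profile: FlowProfile,
                           reactor: ReactorConfig, noise: NoiseModel,
                           rng: np.random.Generator, *,
                           loading: EnzymeLoading | None = None,
                           round_id: str = "round",
                           times=None):
    """Simulate the hidden truth and return a noisy observation round.

    Returns an :class:`ernoed.estimation.ExperimentRound` whose table holds
    one record per fraction time and observable species with the reported
    measurement sigma attached.
    """
    from .estimation import ExperimentRound
    from .network import assemble_salvage_network

    model = getattr(truth, "_model", None)
    if model is None:
        model = assemble_salvage_network(reactor)
        truth._model = model
    loading = loading or truth.loading
    if times is None:
        times = fraction_times(reactor, profile.horizon)
    traj = simulate(model, truth.theta, profile, reactor, times,
                    loading=loading)
    table = observe(traj)
    noisy, sig = noise.apply(table["concentration_mM"].to_numpy(), rng)
    table = table.assign(concentration_mM=noisy, sigma_mM=sig)
    return ExperimentRound(round_id=round_id, profile=profile,
                           loading=loading, table=table)


class VirtualExperimenter:
    """Callable wet-lab stand-in used by the active-learning loop.

    Each call runs one virtual experiment under the hidden ground truth
    with a child RNG spawned deterministically from the base seed and the
    round id, so whole-loop reruns are bit-identical.
    """

    def __init__(self, truth: GroundTruth, reactor: ReactorConfig,
                 noise: NoiseModel, seed: int) -> None:
        self.truth = truth
        self.reactor = reactor
        self.noise = noise
        self.seed = int(seed)

    def _rng(self, round_id: str) -> np.random.Generator:
        ident = int.from_bytes(round_id.encode(), "big") % (2 ** 31)
        return np.random.default_rng([self.seed, ident])

    def __call__(self, profile: FlowProfile, loading: EnzymeLoading | None,
                 round_id: str):
        return run_virtual_experiment(
            self.truth, profile, self.reactor, self.noise,
            self._rng(round_id), loading=loading, round_id=round_id)
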
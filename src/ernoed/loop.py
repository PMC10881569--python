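"""Active-learning loop: design, experiment, test, refit, stop-or-continue.

Each iteration (after a manually designed calibration round that seeds the
first fit) performs four steps:

1. evolve a maximally informative flow profile against the current
   parameter ensemble (robust D-optimal design);
2. run the experiment (here: the virtual experimenter) under that profile;
3. use the *previous* ensemble to predict the fresh round, treating it as
   held-out test data, and record the predictive-power report;
4. refit the model on the accumulated dataset and reselect the ensemble.

The loop stops when the mean prediction error drops below a threshold,
when it no longer improves by a stall fraction, or after a maximum number
of iterations (default 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import DesignSpace, OEDConfig, evolve_design
from .estimation import (ExperimentRound, ParameterEnsemble, TimeCourseDataset,
                         multistart_fit, prediction_error,
                         predict_with_ensemble, select_ensemble)
from .network import EnzymeLoading, NetworkModel
from .reactor import ReactorConfig
from .synthetic import NoiseModel, calibration_profile

__all__ = [
    "FitConfig",
    "LoopConfig",
    "LoopState",
    "evaluate_predictive_power",
    "should_stop",
    "initialize_loop",
    "run_iteration",
    "run_loop",
]


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 64
    max_nfev: int | None = None
    ensemble_tolerance: float = 0.15
    ensemble_max: int = 20
    #: how many previous-ensemble members to reuse as warm starts
    warm_starts_max: int = 4


@dataclass(frozen=True)
class LoopConfig:
    max_iterations: int = 3
    error_threshold_pct: float = 10.0
    stall_fraction: float = 0.1
    design_space: DesignSpace = field(default_factory=DesignSpace)
    oed: OEDConfig = field(default_factory=OEDConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    #: enzyme loading per round id; rounds not listed use reference loading
    loadings: dict = field(default_factory=dict)


@dataclass
class LoopState:
    """Everything accumulated by the loop; a pure function of the seeds."""

    iteration: int
    dataset: TimeCourseDataset
    ensemble: ParameterEnsemble
    reports: list[dict] = field(default_factory=list)
    designs: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    #: ensemble after every fit (index 0 = calibration-only fit)
    ensemble_history: list[ParameterEnsemble] = field(default_factory=list)


def evaluate_predictive_power(prev_ensemble: ParameterEnsemble,
                              new_round: ExperimentRound,
                              model: NetworkModel, reactor: ReactorConfig
                              ) -> dict:
    """Score how well an ensemble predicts a fresh, unseen round.

    Returns the mean percent error over the triphosphates, per-species
    percent errors over all observables, the fraction of points inside the
    two-sigma band (ensemble SD combined with measurement sigma), and the
    mean band width.
    """
    times = new_round.times
    pred = predict_with_ensemble(prev_ensemble, model, new_round.profile,
                                 reactor, times, loading=new_round.loading)
    mean_err, per_species = prediction_error(
        pred, new_round.table, return_per_species=True)
    _, all_species_err = prediction_error(
        pred, new_round.table,
        species=sorted(set(new_round.table["species"])),
        return_per_species=True)
    merged = pred.merge(new_round.table, on=["time_min", "species"])
    band = np.maximum(merged["sd_mM"].to_numpy(),
                      merged["sigma_mM"].to_numpy())
    inside = np.abs(merged["mean_mM"].to_numpy()
                    - merged["concentration_mM"].to_numpy()) <= 2.0 * band
    return {
        "round_id": new_round.round_id,
        "mean_error_pct": float(mean_err),
        "ntp_errors_pct": per_species,
        "species_errors_pct": all_species_err,
        "coverage_2sd": float(inside.mean()),
        "mean_band_width_mM": float(merged["sd_mM"].mean()),
    }


def should_stop(history, *, threshold_pct: float = 10.0,
                stall_fraction: float = 0.1, max_iterations: int = 3
                ) -> tuple[bool, str]:
    """Decide whether the optimisation cycle should terminate.

    ``history`` is the sequence of mean prediction errors (%), one entry
    per completed iteration.
    """
    history = list(history)
    if not history:
        raise ValueError("need at least one predictive-power report")
    if history[-1] <= threshold_pct:
        return True, (f"prediction error {history[-1]:.2f}% <= "
                      f"threshold {threshold_pct}%")
    if len(history) >= max_iterations:
        return True, f"reached max_iterations={max_iterations}"
    if len(history) >= 2 and history[-2] > 0:
        improvement = (history[-2] - history[-1]) / history[-2]
        if improvement < stall_fraction:
            return True, (f"improvement {100 * improvement:.1f}% < "
                          f"stall fraction {100 * stall_fraction:.0f}%")
    return False, "continue"


def _fit_and_select(dataset, model, reactor, cfg: LoopConfig, seed: int,
                    warm: ParameterEnsemble | None):
    x0 = [m.values for m in warm.members[:cfg.fit.warm_starts_max]] \
        if (warm and cfg.fit.warm_starts_max > 0) else None
    fit = multistart_fit(dataset, model, reactor, n_starts=cfg.fit.n_starts,
                         rng=np.random.default_rng(seed),
                         max_nfev=cfg.fit.max_nfev, x0=x0)
    return select_ensemble(fit, tolerance=cfg.fit.ensemble_tolerance,
                           max_members=cfg.fit.ensemble_max)


def initialize_loop(model: NetworkModel, reactor: ReactorConfig,
                    experimenter, cfg: LoopConfig, seed: int) -> LoopState:
    """Run the calibration round (staircase profile) and the first fit."""
    profile = calibration_profile(reactor)
    loading = cfg.loadings.get("round0", EnzymeLoading())
    rnd = experimenter(profile, loading, "round0")
    dataset = TimeCourseDataset()
    dataset.add_round(rnd)
    ensemble = _fit_and_select(dataset, model, reactor, cfg,
                               seed=_stage_seed(seed, "fit0"), warm=None)
    return LoopState(iteration=0, dataset=dataset, ensemble=ensemble,
                     seeds={"master": seed}, ensemble_history=[ensemble])


def _stage_seed(master: int, stage: str) -> int:
    import hashlib
    digest = hashlib.sha256(f"{master}/{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_iteration(state: LoopState, model: NetworkModel,
                  reactor: ReactorConfig, experimenter, cfg: LoopConfig
                  ) -> LoopState:
    """One full design/experiment/test/refit cycle; returns the new state."""
    it = state.iteration + 1
    master = state.seeds["master"]
    rid = f"round{it}"

    design_seed = _stage_seed(master, f"design{it}")
    result = evolve_design(cfg.design_space, model, state.ensemble, reactor,
                           cfg.oed, rng=np.random.default_rng(design_seed))
    profile = result.best.decode()

    loading = cfg.loadings.get(rid, EnzymeLoading())
    new_round = experimenter(profile, loading, rid)

    report = evaluate_predictive_power(state.ensemble, new_round, model,
                                       reactor)
    report["iteration"] = it
    report["design_fitness"] = result.best_fitness

    dataset = TimeCourseDataset(list(state.dataset.rounds))
    dataset.add_round(new_round)
    ensemble = _fit_and_select(dataset, model, reactor, cfg,
                               seed=_stage_seed(master, f"fit{it}"),
                               warm=state.ensemble)
    seeds = dict(state.seeds)
    seeds[f"design{it}"] = design_seed
    seeds[f"fit{it}"] = _stage_seed(master, f"fit{it}")
    return LoopState(iteration=it, dataset=dataset, ensemble=ensemble,
                     reports=state.reports + [report],
                     designs=state.designs + [result], seeds=seeds,
                     ensemble_history=state.ensemble_history + [ensemble])


def run_loop(model: NetworkModel, reactor: ReactorConfig, experimenter,
             cfg: LoopConfig, seed: int) -> LoopState:
    """Calibrate, then iterate until :func:`should_stop` fires."""
    state = initialize_loop(model, reactor, experimenter, cfg, seed)
    while True:
        state = run_iteration(state, model, reactor, experimenter, cfg)
        errors = [r["mean_error_pct"] for r in state.reports]
        stop, reason = should_stop(
            errors, threshold_pct=cfg.error_threshold_pct,
            stall_fraction=cfg.stall_fraction,
            max_iterations=cfg.max_iterations)
        state.seeds["stop_reason"] = reason
        if stop:
            return state
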
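"""Parameter estimation: multistart fitting, ensemble selection, prediction.

The fit criterion is the heteroscedastic weighted sum of squares

    chi^2(theta) = sum_rounds sum_points ((y_sim - y_obs) / sigma)^2 ,

each experimental round simulated under its own flow profile and enzyme
loading.  Optimisation runs in log-parameter space (positivity plus the
decade-spanning scale spread of rates and Km values) with bound-constrained
least squares and an exact Jacobian from forward sensitivities.

Uncertainty is carried by an *ensemble of fits*: every multistart terminal
point whose score lies within a tolerance (default 15%) of the best score
is kept, deduplicated, and capped at the top 20 members; predictions are
reported as the mean and standard deviation across member simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .network import (EnzymeLoading, KineticParameters, NetworkModel,
                      OBSERVABLES)
from .reactor import FlowProfile, ReactorConfig, SimulationError, simulate
from .sensitivity import forward_sensitivities

__all__ = [
    "ExperimentRound",
    "TimeCourseDataset",
    "FitPoint",
    "FitResult",
    "ParameterEnsemble",
    "objective",
    "multistart_fit",
    "acceptance_region_widths",
    "select_ensemble",
    "predict_with_ensemble",
    "prediction_error",
]

#: Penalty score assigned when a candidate parameter vector cannot be
#: simulated (stiff blow-up etc.); large but finite so optimisers recover.
FAILURE_PENALTY = 1e12

NTP_SPECIES = ("UTP", "GTP", "ATP")


@dataclass
class ExperimentRound:
    """One experimental round: profile, enzyme loading and observations.

    ``table`` is a long-format DataFrame with columns ``time_min``,
    ``species``, ``concentration_mM``, ``sigma_mM``.
    """

    round_id: str
    profile: FlowProfile
    loading: EnzymeLoading
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"time_min", "species", "concentration_mM", "sigma_mM"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"round table missing columns {sorted(missing)}")
        if (self.table["sigma_mM"] <= 0).any():
            raise ValueError("all sigma_mM must be positive")
        bad = set(self.table["species"]) - set(OBSERVABLES)
        if bad:
            raise ValueError(f"non-observable species in round: {sorted(bad)}")
        if (self.table["time_min"] > self.profile.horizon + 1e-9).any():
            raise ValueError("observation times outside the round's horizon")

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.table["time_min"].to_numpy())

    @property
    def n_points(self) -> int:
        return len(self.table)


@dataclass
class TimeCourseDataset:
    """Accumulated observation rounds used as fit training data."""

    rounds: list[ExperimentRound] = field(default_factory=list)

    def add_round(self, rnd: ExperimentRound) -> None:
        if any(r.round_id == rnd.round_id for r in self.rounds):
            raise ValueError(f"duplicate round id {rnd.round_id!r}")
        self.rounds.append(rnd)

    def __len__(self) -> int:
        return len(self.rounds)

    def __iter__(self):
        return iter(self.rounds)

    @property
    def n_points(self) -> int:
        return sum(r.n_points for r in self.rounds)

    def subset(self, round_ids: Sequence[str]) -> "TimeCourseDataset":
        keep = [r for r in self.rounds if r.round_id in set(round_ids)]
        return TimeCourseDataset(keep)

    def to_frame(self) -> pd.DataFrame:
        frames = [r.table.assign(round_id=r.round_id) for r in self.rounds]
        cols = ["round_id", "time_min", "species", "concentration_mM", "sigma_mM"]
        return pd.concat(frames, ignore_index=True)[cols]


def _round_layout(rnd: ExperimentRound, model: NetworkModel):
    """Precompute index arrays mapping a simulated trajectory onto the
    round's observation records."""
    times = rnd.times
    t_pos = np.searchsorted(times, rnd.table["time_min"].to_numpy())
    s_pos = np.array([model.species.index(s) for s in rnd.table["species"]])
    o_pos = np.array([OBSERVABLES.index(s) for s in rnd.table["species"]])
    y = rnd.table["concentration_mM"].to_numpy(dtype=float)
    sig = rnd.table["sigma_mM"].to_numpy(dtype=float)
    return times, t_pos, s_pos, o_pos, y, sig


def residuals(theta, dataset: TimeCourseDataset, model: NetworkModel,
              reactor: ReactorConfig) -> np.ndarray:
    """Stacked weighted residuals (y_sim - y_obs)/sigma over all rounds."""
    theta = model.coerce_theta(theta)
    out = []
    for rnd in dataset:
        times, t_pos, s_pos, _, y, sig = _round_layout(rnd, model)
        try:
            traj = simulate(model, theta, rnd.profile, reactor, times,
                            loading=rnd.loading, rtol=1e-7, atol=1e-9)
        except SimulationError as exc:
            warnings.warn(f"round {rnd.round_id}: simulation failed during "
                          f"objective evaluation, penalty applied ({exc})")
            out.append(np.full(rnd.n_points,
                               np.sqrt(FAILURE_PENALTY / max(rnd.n_points, 1))))
            continue
        sim = traj.states[t_pos, s_pos]
        out.append((sim - y) / sig)
    return np.concatenate(out) if out else np.zeros(0)


def objective(theta, dataset: TimeCourseDataset, model: NetworkModel,
              reactor: ReactorConfig) -> float:
    """Weighted sum-of-squares fit score (lower is better)."""
    r = residuals(theta, dataset, model, reactor)
    return float(r @ r)


@dataclass
class FitPoint:
    theta: KineticParameters
    score: float
    success: bool
    nfev: int = 0


@dataclass
class FitResult:
    points: list[FitPoint]

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.score)

    @property
    def best(self) -> FitPoint:
        return self.points[0]

    def __len__(self) -> int:
        return len(self.points)


def _residual_jacobian(theta_values, dataset, model, reactor):
    """d residual / d log(theta), from forward sensitivities (chain rule)."""
    blocks = []
    for rnd in dataset:
        times, t_pos, _, _, _, sig = _round_layout(rnd, model)
        # Staggered propagation at loose tolerance: a ~1e-4-accurate
        # Jacobian is ample for trust-region steps and an order of
        # magnitude cheaper than the reporting-grade exact setting.
        sens = forward_sensitivities(model, theta_values, rnd.profile,
                                     reactor, times, loading=rnd.loading,
                                     method="staggered", rtol=1e-6, atol=1e-8)
        o_pos = np.array([sens.observables.index(s)
                          for s in rnd.table["species"]])
        S = sens.S[t_pos, o_pos, :]                       # (n_points, p)
        blocks.append(S * theta_values[None, :] / sig[:, None])
    # runaway sensitivities carry no useful direction information; clip so
    # the trust-region solver stays finite
    return np.clip(np.vstack(blocks), -1e8, 1e8)


def multistart_fit(
    dataset: TimeCourseDataset, model: NetworkModel, reactor: ReactorConfig,
    n_starts: int = 64, rng: np.random.Generator | int | None = None, *,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    max_nfev: int | None = None, use_sensitivity_jacobian: bool = True,
    include_nominal: bool = True,
    x0: Sequence[np.ndarray] | None = None,
) -> FitResult:
    """Bound-constrained least-squares fits from log-uniform random starts.

    Every start's terminal point and score is returned (sorted by score);
    the caller selects the ensemble.  ``x0`` may inject additional warm
    starts (e.g. the previous iteration's ensemble members).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(rng)
    nominal = model.nominal_parameters()
    lo, hi = nominal.lower.copy(), nominal.upper.copy()
    if bounds:
        for name, (a, b) in bounds.items():
            i = model.parameter_index(name)
            lo[i], hi[i] = a, b
    log_lo, log_hi = np.log(lo), np.log(hi)

    starts = []
    if x0 is not None:
        starts.extend(np.clip(np.log(np.asarray(v, dtype=float)),
                              log_lo, log_hi) for v in x0)
    if include_nominal:
        starts.append(np.clip(np.log(nominal.values), log_lo, log_hi))
    while len(starts) < n_starts + (len(x0) if x0 else 0):
        starts.append(rng.uniform(log_lo, log_hi))

    def fun(x):
        return residuals(np.exp(x), dataset, model, reactor)

    def jac(x):
        th = np.exp(x)
        try:
            return _residual_jacobian(th, dataset, model, reactor)
        except SimulationError:
            return np.zeros((dataset.n_points, len(th)))

    points: list[FitPoint] = []
    errors: list[str] = []
    for x_init in starts:
        try:
            res = least_squares(
                fun, x_init, jac=jac if use_sensitivity_jacobian else "2-point",
                bounds=(log_lo, log_hi), method="trf",
                x_scale="jac", max_nfev=max_nfev)
        except Exception as exc:  # pragma: no cover - diagnostic path
            errors.append(str(exc))
            continue
        theta = nominal.replace_values(np.exp(res.x))
        theta.lower, theta.upper = lo, hi
        points.append(FitPoint(theta=theta, score=float(2 * res.cost),
                               success=bool(res.success), nfev=res.nfev))
    if not points:
        raise RuntimeError("all fit starts failed: " + "; ".join(errors[:5]))
    return FitResult(points)


@dataclass
class ParameterEnsemble:
    """Accepted parameter vectors within tolerance of the best fit score."""

    members: list[KineticParameters]
    scores: list[float]
    best_score: float
    tolerance: float = 0.15

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must contain at least one member")
        limit = (1.0 + self.tolerance) * self.best_score + 1e-12
        if any(s > limit for s in self.scores):
            raise ValueError("ensemble member outside score tolerance")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def best(self) -> KineticParameters:
        return self.members[int(np.argmin(self.scores))]

    def value_matrix(self) -> np.ndarray:
        return np.array([m.values for m in self.members])

    def interval_widths(self, lo_q: float = 5.0, hi_q: float = 95.0
                        ) -> np.ndarray:
        """Per-parameter width of the [lo_q, hi_q]% interval in log10 units."""
        V = np.log10(self.value_matrix())
        return np.percentile(V, hi_q, axis=0) - np.percentile(V, lo_q, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.value_matrix(),
                          columns=list(self.members[0].names))
        df.insert(0, "score", self.scores)
        return df


def acceptance_region_widths(
    best: KineticParameters, dataset: TimeCourseDataset,
    model: NetworkModel, reactor: ReactorConfig, *,
    tolerance: float = 0.15) -> np.ndarray:
    """Per-parameter width (log10 decades) of the fit-acceptance region.

    The acceptance region is the set of parameter vectors scoring within
    ``(1 + tolerance)`` of the best fit.  Its marginal extent along each
    parameter is estimated asymptotically from the Gauss-Newton
    information matrix ``H = J^T J`` (J in log-parameter space): the
    half-width along parameter p solves ``delta_chi2 = tol * chi2_best``
    for the profiled quadratic model, i.e. ``sqrt(delta_chi2 * (H^-1)_pp)``.
    Directions the data do not constrain are capped by the declared
    parameter bounds, which enter as a diagonal regulariser chosen so the
    zero-information width equals the bounds width.
    """
    theta0 = model.coerce_theta(best)
    r = residuals(theta0, dataset, model, reactor)
    chi0 = float(r @ r)
    delta = max(tolerance * chi0, 1e-12)
    J = _residual_jacobian(theta0, dataset, model, reactor)
    H = J.T @ J
    nominal = best if isinstance(best, KineticParameters) \
        else model.nominal_parameters()
    W = np.log(nominal.upper) - np.log(nominal.lower)  # ln units
    prior = 4.0 * delta / W ** 2
    Hreg = H + np.diag(prior)
    cov = np.linalg.inv(Hreg)
    half = np.sqrt(delta * np.clip(np.diag(cov), 0.0, None))
    return 2.0 * half / np.log(10.0)


def select_ensemble(fit: FitResult, tolerance: float = 0.15,
                    max_members: int = 20, dedup_rtol: float = 1e-3
                    ) -> ParameterEnsemble:
    """Keep fits scoring within ``(1 + tolerance) * best``, deduplicated by
    relative parameter distance, capped at ``max_members`` best."""
    if not fit.points:
        raise ValueError("empty fit result")
    best = fit.best.score
    members: list[KineticParameters] = []
    scores: list[float] = []
    for point in fit.points:  # already sorted by score
        if point.score > (1.0 + tolerance) * best + 1e-12:
            break
        dup = any(
            np.max(np.abs(np.log(point.theta.values) - np.log(m.values)))
            < dedup_rtol
            for m in members)
        if dup:
            continue
        members.append(point.theta)
        scores.append(point.score)
        if len(members) >= max_members:
            break
    return ParameterEnsemble(members=members, scores=scores,
                             best_score=best, tolerance=tolerance)


def predict_with_ensemble(ensemble: ParameterEnsemble, model: NetworkModel,
                          profile: FlowProfile, reactor: ReactorConfig,
                          times, loading: EnzymeLoading | None = None,
                          observables: Sequence[str] = OBSERVABLES
                          ) -> pd.DataFrame:
    """Mean and SD (population, ddof=0) across member simulations.

    Members whose simulation fails are dropped with a warning; returns a
    long-format frame with columns time_min, species, mean_mM, sd_mM.
    """
    times = np.asarray(times, dtype=float)
    observables = [s for s in observables if s in model.species]
    sims = []
    for i, member in enumerate(ensemble.members):
        try:
            traj = simulate(model, member, profile, reactor, times,
                            loading=loading)
        except SimulationError as exc:
            warnings.warn(f"ensemble member {i} dropped: {exc}")
            continue
        idx = [model.species.index(s) for s in observables]
        sims.append(traj.states[:, idx])
    if not sims:
        raise SimulationError("every ensemble member failed to simulate")
    stack = np.stack(sims)                      # (members, nt, n_obs)
    mean, sd = stack.mean(axis=0), stack.std(axis=0, ddof=0)
    return pd.DataFrame({
        "time_min": np.repeat(times, len(observables)),
        "species": np.tile(list(observables), len(times)),
        "mean_mM": mean.ravel(),
        "sd_mM": sd.ravel(),
    })


def prediction_error(predicted: pd.DataFrame, observed: pd.DataFrame,
                     species: Sequence[str] = NTP_SPECIES,
                     return_per_species: bool = False):
    """Percent prediction error, averaged over the triphosphates.

    Per species: the mean over matched timepoints of
    ``100 * |mean_sim - obs| / obs``; the reported error is the mean over
    the requested species.  Observations of exactly zero are excluded (the
    relative error is undefined there) and flagged via a warning.
    """
    merged = predicted.merge(
        observed[["time_min", "species", "concentration_mM"]],
        on=["time_min", "species"], how="inner")
    per_species: dict[str, float] = {}
    for s in species:
        sub = merged[merged["species"] == s]
        if sub.empty:
            continue
        obs = sub["concentration_mM"].to_numpy()
        sim = sub["mean_mM"].to_numpy()
        ok = obs > 0
        if not ok.all():
            warnings.warn(f"{(~ok).sum()} zero observations of {s} excluded "
                          "from prediction error")
        if ok.any():
            per_species[s] = float(
                np.mean(100.0 * np.abs(sim[ok] - obs[ok]) / obs[ok]))
    if not per_species:
        raise ValueError("no usable observations for prediction error")
    value = float(np.mean(list(per_species.values())))
    return (value, per_species) if return_per_species else value
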
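"""MIMO control of the salvage network: screening input conditions for
target ATP/UTP/GTP blends under a conversion-efficiency constraint.

The trained ensemble is used as a forward map from constant inlet flows to
steady-state triphosphate outputs.  A large random sample of inlet
conditions is pushed through every ensemble member to steady state; each
condition gets a predicted NTP mean and standard deviation, an
ATP:UTP:GTP ratio (normalised to sum 1) and a conversion efficiency

    eff = 100 * (UTP + GTP + (ATP_out - ATP_feed))
              / (uracil_feed + GMP_feed + adenine_feed),

with all feeds expressed as dilution-weighted inflow concentrations
``q_i * Cstock_i / q_tot``.  Conditions meeting a minimum efficiency
(default 60%) are then thinned to a small, maximally ratio-diverse panel
of test conditions by greedy farthest-point selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import root

from .network import EnzymeLoading, NetworkModel
from .reactor import FlowProfile, ReactorConfig, SimulationError, simulate

__all__ = [
    "InputCondition",
    "ControlOutcome",
    "sample_conditions",
    "steady_state",
    "predict_outcome",
    "screen_conditions",
    "conversion_efficiency",
    "select_conditions",
]

NTPS = ("UTP", "GTP", "ATP")
NUCLEOBASE_FEEDS = ("uracil", "GMP", "adenine")

DEFAULT_FLOW_BOUNDS = ((0.0, 2.0),) * 6  # ul/min per inlet (pump range)


@dataclass(frozen=True)
class InputCondition:
    """Constant per-inlet flow rates (ul/min) driving the reactor."""

    flows: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.flows) != 6:
            raise ValueError("expected 6 inlet flows")
        if any(f < 0 for f in self.flows):
            raise ValueError("flows must be non-negative")
        if sum(self.flows) <= 0:
            raise ValueError("total flow must be positive")

    @property
    def total_flow(self) -> float:
        return float(sum(self.flows))

    def feed_concentrations(self, reactor: ReactorConfig) -> dict[str, float]:
        return reactor.feed_concentrations(np.asarray(self.flows))


@dataclass
class ControlOutcome:
    """Ensemble prediction for one input condition."""

    condition: InputCondition
    ntp_mean: dict[str, float]
    ntp_sd: dict[str, float]
    ratio: np.ndarray            # (ATP, UTP, GTP), sums to 1
    efficiency_pct: float
    total_feed_mM: float         # summed dilution-weighted feed of all inlets
    flagged: bool = False

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        if not self.flagged:
            if np.any(self.ratio < -1e-12):
                raise ValueError("ratio components must be non-negative")
            if abs(self.ratio.sum() - 1.0) > 1e-9:
                raise ValueError("ratio must sum to 1")


def sample_conditions(n: int, bounds=DEFAULT_FLOW_BOUNDS,
                      rng: np.random.Generator | int | None = None
                      ) -> np.ndarray:
    """Draw ``n`` input conditions, each inlet flow uniform in its bounds.

    Returns an (n, 6) array of flows (ul/min); rows with zero total flow
    (possible only when a bound includes 0 on every inlet) are redrawn.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    flows = rng.uniform(lo, hi, size=(n, 6))
    bad = flows.sum(axis=1) <= 0
    while bad.any():
        flows[bad] = rng.uniform(lo, hi, size=(int(bad.sum()), 6))
        bad = flows.sum(axis=1) <= 0
    return flows


def steady_state(model: NetworkModel, theta, flows, reactor: ReactorConfig,
                 loading=None, *, tol: float = 1e-9,
                 residence_times: float = 10.0,
                 x0: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Steady state of the CSTR under constant flows.

    First tries a Newton solve seeded from the dilution-only steady state;
    if that fails (or lands at an unphysical point) the system is
    integrated for ``residence_times`` V/q_tot and polished with a final
    Newton step.  Returns ``(state, converged)`` where ``converged`` also
    requires ``||dC/dt||_inf <= tol * max(1, ||C||_inf)``.
    """
    theta = model.coerce_theta(theta)
    load = model.coerce_loading(loading)
    q = np.asarray(flows, dtype=float)
    qtot = q.sum()
    if qtot <= 0:
        raise ValueError("total flow must be positive")
    V = reactor.volume_ul
    stock = reactor.stock_matrix(model.species)
    feed = q @ stock / V
    dil = qtot / V
    comp = model.compiled

    def fun(c):
        return feed - dil * c + comp.f(c, theta, load)

    def jac(c):
        return comp.jac_c(c, theta, load) - dil * np.eye(len(c))

    def ok(c):
        return (np.all(c >= -1e-9)
                and np.linalg.norm(fun(c), np.inf)
                <= tol * max(1.0, np.abs(c).max()))

    guesses = ([np.asarray(x0, dtype=float)] if x0 is not None else []) \
        + [feed / dil]  # washout (dilution-only) fixed point
    for guess in guesses:
        sol = root(fun, guess, jac=jac, method="hybr", tol=1e-12)
        if sol.success and ok(sol.x):
            return np.maximum(sol.x, 0.0), True

    horizon = residence_times * V / qtot
    profile = FlowProfile.constant(q, horizon)
    try:
        traj = simulate(model, theta, profile, reactor, [horizon],
                        rtol=1e-7, atol=1e-9)
    except SimulationError:
        return guesses[-1], False
    c_end = traj.states[-1]
    sol = root(fun, c_end, jac=jac, method="hybr", tol=1e-12)
    if sol.success and ok(sol.x):
        return np.maximum(sol.x, 0.0), True
    return np.maximum(c_end, 0.0), ok(c_end)


def conversion_efficiency(outflow, feed) -> float:
    """Percent of fed nucleobases emerging as triphosphates.

    ``outflow`` maps species -> steady-state concentration (mM);
    ``feed`` maps the inlet substrates to dilution-weighted inflow
    concentrations.  The ATP fed to the reactor is subtracted from the ATP
    output, so only newly formed triphosphate counts; a negative net ATP is
    allowed to subtract (reported as-is).
    """
    base_feed = sum(float(feed.get(s, 0.0)) for s in NUCLEOBASE_FEEDS)
    if base_feed <= 0:
        raise ValueError("conversion efficiency undefined without "
                         "nucleobase feed")
    net_ntp = (float(outflow.get("UTP", 0.0)) + float(outflow.get("GTP", 0.0))
               + float(outflow.get("ATP", 0.0)) - float(feed.get("ATP", 0.0)))
    return 100.0 * net_ntp / base_feed


def predict_outcome(condition, ensemble, model: NetworkModel,
                    reactor: ReactorConfig, loading=None,
                    max_members: int = 20) -> ControlOutcome:
    """Ensemble steady-state prediction for one input condition.

    Each member (up to ``max_members``) is driven to steady state; the NTP
    outputs are summarised as mean and SD, the blend ratio and conversion
    efficiency are computed from the means.  Non-converged members flag
    the outcome.
    """
    if not isinstance(condition, InputCondition):
        condition = InputCondition(tuple(np.asarray(condition, dtype=float)))
    members = list(getattr(ensemble, "members", ensemble))[:max_members]
    if len(members) < 1:
        raise ValueError("ensemble must be non-empty")
    flows = np.asarray(condition.flows)
    ntp_idx = [model.species.index(s) for s in NTPS]
    values = np.empty((len(members), len(NTPS)))
    flagged = False
    prev = None  # ensemble members are similar: warm-start from the last
    seen: dict[bytes, np.ndarray] = {}
    for i, member in enumerate(members):
        key = model.coerce_theta(member).tobytes()
        if key in seen:
            values[i] = seen[key]
            continue
        state, converged = steady_state(model, member, flows, reactor,
                                        loading=loading, x0=prev)
        flagged |= not converged
        if converged:
            prev = state
        values[i] = state[ntp_idx]
        seen[key] = values[i]

    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=0)
    feed = condition.feed_concentrations(reactor)
    outflow = dict(zip(NTPS, map(float, mean)))
    eff = conversion_efficiency(outflow, feed)
    atp, utp, gtp = outflow["ATP"], outflow["UTP"], outflow["GTP"]
    total = atp + utp + gtp
    if total > 0:
        ratio = np.array([atp, utp, gtp]) / total
    else:
        ratio = np.full(3, np.nan)
        flagged = True
    return ControlOutcome(
        condition=condition,
        ntp_mean=outflow,
        ntp_sd=dict(zip(NTPS, map(float, sd))),
        ratio=ratio,
        efficiency_pct=float(eff),
        total_feed_mM=float(sum(feed.values())),
        flagged=flagged,
    )


def screen_conditions(flows: np.ndarray, ensemble, model: NetworkModel,
                      reactor: ReactorConfig, loading=None,
                      max_members: int = 20) -> pd.DataFrame:
    """Predict outcomes for an (n, 6) array of conditions.

    Returns one row per condition: flows, NTP means/SDs, ratio components
    (ATP, UTP, GTP order), efficiency, total feed and the flag.
    """
    rows = []
    for f in np.atleast_2d(flows):
        out = predict_outcome(f, ensemble, model, reactor, loading=loading,
                              max_members=max_members)
        row = {f"q_{s}": float(v) for s, v in zip(reactor.inlets, f)}
        row.update({f"mean_{s}": out.ntp_mean[s] for s in NTPS})
        row.update({f"sd_{s}": out.ntp_sd[s] for s in NTPS})
        row.update({
            "ratio_ATP": out.ratio[0], "ratio_UTP": out.ratio[1],
            "ratio_GTP": out.ratio[2],
            "efficiency_pct": out.efficiency_pct,
            "total_feed_mM": out.total_feed_mM,
            "flagged": out.flagged,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def select_conditions(outcomes: pd.DataFrame, k: int = 7,
                      eff_min: float = 60.0) -> dict:
    """Pick ``k`` diverse test conditions meeting the efficiency constraint.

    Survivors (efficiency >= ``eff_min``, unflagged) are embedded in the
    joint space of ratio-simplex coordinates and min-max-scaled total feed
    concentration; selection is greedy farthest-point, seeded by the
    survivor farthest from the simplex centroid (which is also the k=1
    answer).  When ``k >= 7`` the final slot is filled with a deliberate
    near-duplicate of the first pick's ratio (a repeated-blend control,
    mirroring a repeated test condition), so selected ratios are pairwise
    distinct except for that designated pair.

    Returns a dict with ``indices`` (into ``outcomes``), the designated
    ``duplicate_pair`` (or None) and a ``warning`` when fewer than ``k``
    survivors exist.
    """
    ok = (outcomes["efficiency_pct"] >= eff_min) & (~outcomes["flagged"])
    survivors = outcomes.index[ok].to_numpy()
    if len(survivors) == 0:
        warnings.warn("no conditions meet the efficiency constraint")
        return {"indices": [], "duplicate_pair": None,
                "warning": "no survivors"}
    ratios = outcomes.loc[survivors, ["ratio_ATP", "ratio_UTP", "ratio_GTP"]
                          ].to_numpy()
    feed = outcomes.loc[survivors, "total_feed_mM"].to_numpy()
    span = feed.max() - feed.min()
    feed_scaled = (feed - feed.min()) / span if span > 0 else np.zeros_like(feed)
    features = np.column_stack([ratios, feed_scaled])

    centroid = np.full(3, 1.0 / 3.0)
    first = int(np.argmax(np.linalg.norm(ratios - centroid, axis=1)))

    if len(survivors) <= k:
        warnings.warn(f"only {len(survivors)} conditions survive the "
                      f"constraint; returning all")
        return {"indices": [int(i) for i in survivors],
                "duplicate_pair": None,
                "warning": f"{len(survivors)} < k={k} survivors"}

    n_greedy = k - 1 if k >= 7 else k
    chosen = [first]
    dist = np.linalg.norm(features - features[first], axis=1)
    while len(chosen) < n_greedy:
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist,
                          np.linalg.norm(features - features[nxt], axis=1))
    duplicate_pair = None
    if k >= 7:
        ratio_dist = np.linalg.norm(ratios - ratios[first], axis=1)
        ratio_dist[chosen] = np.inf
        dup = int(np.argmin(ratio_dist))
        chosen.append(dup)
        duplicate_pair = (int(survivors[first]), int(survivors[dup]))
    return {"indices": [int(survivors[i]) for i in chosen],
            "duplicate_pair": duplicate_pair, "warning": None}
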
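"""Forward parameter sensitivities, Fisher information and the D-criterion.

The sensitivity matrix S = dC/dtheta is propagated alongside the state by
the variational (augmented) ODE system

    dS/dt = (J_reaction(C) - q_tot/V I) S + df/dtheta,

with S(0) = 0 because the initial state does not depend on the kinetic
parameters.  Design scoring uses *scaled* sensitivities
``s~ = (dy_o/dtheta_p) * theta_p / sigma_o`` so the information criterion is
invariant to parameter units (catalytic rates and Km values live on
different scales), and assembles the Fisher information matrix

    F = sum_k sum_o  s~_ok s~_ok^T .

The D-criterion is ``log det(F + eps I)`` with a small spectral ridge; a
larger score means the design constrains a larger volume of parameter
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .network import NetworkModel, OBSERVABLES
from .reactor import (FlowProfile, ReactorConfig, SimulationError,
                      Trajectory, _capped)

__all__ = [
    "SensitivityTrajectory",
    "FisherInformation",
    "forward_sensitivities",
    "fisher_information",
    "d_score",
    "sensitivity_correlations",
]


@dataclass
class SensitivityTrajectory:
    """Raw observable sensitivities dy_o(t_k)/dtheta_p plus the state."""

    times: np.ndarray
    S: np.ndarray              # (n_times, n_observables, n_parameters), raw
    states: np.ndarray         # (n_times, n_species)
    observables: tuple[str, ...]
    parameter_names: tuple[str, ...]
    S_full: np.ndarray | None = None  # (n_times, n_species, n_parameters)

    @property
    def n_parameters(self) -> int:
        return self.S.shape[2]

    def scaled(self, theta, sigma) -> np.ndarray:
        """Unit-free sensitivities S * theta_p / sigma_o.

        ``sigma`` may be scalar, per-observable (n_obs,), or per-point
        (n_times, n_obs).
        """
        theta = np.asarray(theta, dtype=float)
        sig = np.asarray(sigma, dtype=float)
        if sig.ndim == 0:
            sig = np.full(len(self.observables), float(sig))
        if sig.ndim == 1:
            sig = np.broadcast_to(sig, (len(self.times), len(self.observables)))
        if np.any(sig <= 0):
            raise ValueError("sigma must be strictly positive")
        return self.S * theta[None, None, :] / sig[:, :, None]

    def trajectory(self) -> Trajectory:
        return Trajectory(self.times, self.states, tuple(self._species))

    _species: tuple[str, ...] = ()


@dataclass
class FisherInformation:
    """Fisher information matrix with the noise weights that produced it."""

    matrix: np.ndarray
    sigma: np.ndarray
    parameter_names: tuple[str, ...] = ()
    ridge: float | None = None

    def __post_init__(self) -> None:
        F = np.asarray(self.matrix, dtype=float)
        if F.ndim != 2 or F.shape[0] != F.shape[1]:
            raise ValueError("FIM must be square")
        if not np.isfinite(F).all():
            raise ValueError("FIM contains non-finite entries")
        if not np.allclose(F, F.T, atol=1e-10 * max(1.0, np.abs(F).max())):
            raise ValueError("FIM must be symmetric")
        scale = np.linalg.norm(F, 2) if F.size else 0.0
        if F.size and np.linalg.eigvalsh(F).min() < -1e-8 * max(scale, 1.0):
            raise ValueError("FIM must be positive semi-definite")
        self.matrix = F

    @property
    def n_parameters(self) -> int:
        return self.matrix.shape[0]


def _sens_exact(model, theta, load, profile, reactor, times, rtol, atol):
    """Augmented-system integration (state + all sensitivity columns)."""
    ns, npar = model.n_species, model.n_parameters
    stock = reactor.stock_matrix(model.species)
    V = reactor.volume_ul
    comp = model.compiled

    y = np.zeros(ns * (1 + npar))
    out = np.empty((len(times), ns * (1 + npar)))
    filled = np.zeros(len(times), dtype=bool)
    at_zero = np.isclose(times, 0.0, atol=1e-12)
    out[at_zero] = y
    filled[at_zero] = True

    for seg in range(profile.n_segments):
        t0 = float(profile.t_start[seg])
        t1 = t0 + float(profile.duration[seg])
        q = profile.rates[seg]
        feed = q @ stock / V
        dil = q.sum() / V

        def rhs(t, yv):
            c = yv[:ns]
            S = yv[ns:].reshape(npar, ns).T  # (ns, npar)
            dc = feed - dil * c + comp.f(c, theta, load)
            J = comp.jac_c(c, theta, load)
            dS = J @ S + comp.dfdtheta(c, theta, load) - dil * S
            return np.concatenate([dc, dS.T.ravel()])

        sel = (~filled) & (times > t0 + 1e-12) & (times <= t1 + 1e-12)
        t_eval = np.unique(np.concatenate([times[sel], [t1]]))
        try:
            sol = solve_ivp(_capped(rhs, seg), (t0, t1), y, method="LSODA",
                            t_eval=t_eval, rtol=rtol, atol=atol)
        except (ArithmeticError, ValueError) as exc:
            raise SimulationError(
                f"sensitivity integration diverged in segment {seg}: {exc}",
                seg) from exc
        if not sol.success:
            raise SimulationError(
                f"sensitivity integration failed in segment {seg}: "
                f"{sol.message}", seg)
        y = sol.y[:, -1]
        if sel.any():
            pos = np.searchsorted(sol.t, times[sel])
            out[sel] = sol.y[:, pos].T
            filled[sel] = True
    if not filled.all():
        raise SimulationError("some requested times were not covered")
    states = out[:, :ns]
    S_full = out[:, ns:].reshape(len(times), npar, ns).transpose(0, 2, 1)
    return states, S_full


def _sens_staggered(model, theta, load, profile, reactor, times, rtol, atol,
                    max_step_min):
    """Staggered propagation: solve the state ODE, then advance the linear
    sensitivity system with an exponential midpoint rule.

    Over each step the Jacobian A = J(C) - dil*I and forcing G = df/dtheta
    are frozen at the interval midpoint and the linear ODE dS/dt = A S + G
    is solved exactly via a block matrix exponential.  Fast decaying modes
    are handled without tiny steps; the O(h^2) freezing error is bounded
    by capping the step at ``max_step_min``.
    """
    from scipy.linalg import expm

    ns, npar = model.n_species, model.n_parameters
    stock = reactor.stock_matrix(model.species)
    V = reactor.volume_ul
    comp = model.compiled
    eye = np.eye(ns)

    S = np.zeros((ns, npar))
    c0 = np.zeros(ns)
    out_states = np.empty((len(times), ns))
    out_S = np.empty((len(times), ns, npar))
    filled = np.zeros(len(times), dtype=bool)
    at_zero = np.isclose(times, 0.0, atol=1e-12)
    out_states[at_zero] = 0.0
    out_S[at_zero] = 0.0
    filled[at_zero] = True

    for seg in range(profile.n_segments):
        t0 = float(profile.t_start[seg])
        t1 = t0 + float(profile.duration[seg])
        q = profile.rates[seg]
        feed = q @ stock / V
        dil = q.sum() / V

        def rhs(t, c):
            return feed - dil * c + comp.f(c, theta, load)

        def jac(t, c):
            return comp.jac_c(c, theta, load) - dil * eye

        try:
            sol = solve_ivp(_capped(rhs, seg), (t0, t1), c0, method="LSODA",
                            jac=jac, rtol=rtol, atol=atol,
                            dense_output=True)
        except (ArithmeticError, ValueError) as exc:
            raise SimulationError(
                f"state integration diverged in segment {seg}: {exc}",
                seg) from exc
        if not sol.success:
            raise SimulationError(
                f"state integration failed in segment {seg}: {sol.message}",
                seg)
        c0 = sol.y[:, -1]

        sel = (~filled) & (times > t0 + 1e-12) & (times <= t1 + 1e-12)
        req = times[sel]
        # fixed step grid (capped at max_step) plus the requested output
        # times; the state solver's dense output supplies the midpoints.
        # Solver-accepted steps are deliberately not reused: stiff
        # parameter draws can accept tens of thousands of steps, and the
        # frozen-Jacobian exponential update does not need them.
        n_sub = max(4, int(np.ceil((t1 - t0) / max_step_min)))
        grid = np.unique(np.concatenate([
            np.linspace(t0, t1, n_sub + 1), req]))
        block = np.zeros((2 * ns, 2 * ns))
        req_pos = np.searchsorted(grid, req)
        take = {}
        for idx, g in zip(np.nonzero(sel)[0], req_pos):
            take.setdefault(int(g), []).append(idx)
        for g in take.get(0, ()):  # exactly at segment start
            out_states[g] = sol.sol(t0)
            out_S[g] = S
            filled[g] = True
        for i in range(len(grid) - 1):
            a, b = grid[i], grid[i + 1]
            h = b - a
            cm = sol.sol(0.5 * (a + b))
            A = comp.jac_c(cm, theta, load) - dil * eye
            G = comp.dfdtheta(cm, theta, load)
            block[:ns, :ns] = A * h
            block[:ns, ns:] = eye * h
            block[ns:, :] = 0.0
            E = expm(block)
            S = E[:ns, :ns] @ S + E[:ns, ns:] @ G
            for g in take.get(i + 1, ()):
                out_states[g] = sol.sol(b)
                out_S[g] = S
                filled[g] = True
    if not filled.all():
        raise SimulationError("some requested times were not covered")
    return out_states, out_S


def forward_sensitivities(
    model: NetworkModel, theta, profile: FlowProfile, reactor: ReactorConfig,
    times, loading=None, *, rtol: float = 1e-8, atol: float = 1e-10,
    observables=OBSERVABLES, keep_full: bool = False,
    method: str = "exact", max_step_min: float = 1.0,
) -> SensitivityTrajectory:
    """Forward sensitivities of the observables at the requested times.

    ``method="exact"`` integrates the full augmented (variational) system
    with LSODA; ``method="staggered"`` solves the state first and then
    propagates the linear sensitivity equations with an exponential
    midpoint rule — several-fold faster and accurate to ~1e-3, used for
    fitting Jacobians and design scoring.  Both restart at every
    flow-segment boundary.
    """
    theta = model.coerce_theta(theta)
    load = model.coerce_loading(loading)
    times = np.asarray(times, dtype=float)
    # reduced models (toys, variants) may track only part of the panel
    observables = tuple(s for s in observables if s in model.species)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < -1e-9 or times[-1] > profile.horizon + 1e-9:
        raise ValueError("requested times outside the profile horizon")

    if method == "exact":
        states, S_full = _sens_exact(model, theta, load, profile, reactor,
                                     times, rtol, atol)
    elif method == "staggered":
        states, S_full = _sens_staggered(model, theta, load, profile,
                                         reactor, times, rtol, atol,
                                         max_step_min)
    else:
        raise ValueError(f"unknown sensitivity method {method!r}")
    if not (np.isfinite(states).all() and np.isfinite(S_full).all()):
        raise SimulationError("sensitivity propagation produced non-finite "
                              "values (parameters in a blow-up region)")
    obs_idx = [model.species.index(s) for s in observables]
    sens = SensitivityTrajectory(
        times=times, S=S_full[:, obs_idx, :], states=states,
        observables=tuple(observables),
        parameter_names=model.parameter_names,
        S_full=S_full if keep_full else None,
    )
    sens._species = model.species
    return sens


def fisher_information(sens: SensitivityTrajectory, sigma, theta,
                       ) -> FisherInformation:
    """Assemble F = sum over timepoints and observables of the outer
    products of the scaled sensitivities."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (sens.n_parameters,):
        raise ValueError("theta length does not match sensitivities")
    st = sens.scaled(theta, sigma)           # (nt, no, p)
    A = st.reshape(-1, sens.n_parameters)
    F = A.T @ A
    F = 0.5 * (F + F.T)
    sig = np.asarray(sigma, dtype=float)
    return FisherInformation(F, sig, sens.parameter_names)


def d_score(F: FisherInformation | np.ndarray, ridge: float | None = None
            ) -> float:
    """D-criterion log det(F + eps I).

    The default ridge ``eps = 1e-8 * trace(F)/p`` keeps the score finite
    for rank-deficient information matrices; it is recorded on the
    FisherInformation object.  ``ridge=0`` requests the bare determinant
    and raises for singular F.
    """
    obj = F if isinstance(F, FisherInformation) else None
    M = F.matrix if obj is not None else np.asarray(F, dtype=float)
    p = M.shape[0]
    if ridge is None:
        ridge = 1e-8 * np.trace(M) / p if np.trace(M) > 0 else 1e-12
    if obj is not None:
        obj.ridge = float(ridge)
    sign, logdet = np.linalg.slogdet(M + ridge * np.eye(p))
    if sign <= 0:
        raise np.linalg.LinAlgError(
            "information matrix singular; use a positive ridge")
    return float(logdet)


def sensitivity_correlations(sens: SensitivityTrajectory, theta=None,
                             sigma=1.0):
    """Pearson correlations between per-parameter sensitivity vectors.

    Each parameter contributes one vector: its scaled sensitivities
    concatenated over timepoints and observables.  Returns ``(corr, flags)``
    where ``flags`` marks zero-variance parameters whose correlations are
    reported as 0.
    """
    if len(sens.times) < 2:
        raise ValueError("need at least 2 timepoints")
    theta = np.ones(sens.n_parameters) if theta is None \
        else np.asarray(theta, dtype=float)
    A = sens.scaled(theta, sigma).reshape(-1, sens.n_parameters)
    A = A - A.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(A, axis=0)
    flags = norms <= 1e-300
    safe = np.where(flags, 1.0, norms)
    corr = (A / safe).T @ (A / safe)
    corr[flags, :] = 0.0
    corr[:, flags] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return corr, flags
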
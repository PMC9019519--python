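"""Deterministic analysis: ODE integration, steady states, dose-response.

The stiff LSODA integrator is used throughout (phosphotransfer rates
exceed dilution by three orders of magnitude, so the dynamics are
genuinely stiff), with rtol 1e-8 / atol 1e-10 and the network's analytic
Jacobian.  Steady states are found by long integration (default horizon
1e5 min, ten dilution time constants at the nominal delta) followed by
Newton root polishing to residual norm < 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import ReactionNetwork, build_network
from .params import Scenario

__all__ = [
    "Trajectory",
    "DoseResponse",
    "SteadyStateError",
    "simulate",
    "steady_state",
    "dose_response",
    "step_response",
    "overshoot",
]

RTOL = 1e-8
ATOL = 1e-10
SETTLE_T = 1e5  # min


class SteadyStateError(RuntimeError):
    """Steady-state search failed; message carries solver diagnostics."""


@dataclass
class Trajectory:
    """Time grid (min) and state matrix (time x species)."""

    t: np.ndarray
    x: np.ndarray
    network: ReactionNetwork

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.t.ndim != 1 or self.x.shape != (self.t.size, self.network.n_species):
            raise ValueError("trajectory shapes inconsistent with network")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("non-finite state values in trajectory")

    def series(self, species: str) -> np.ndarray:
        return self.x[:, self.network.index(species)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=list(self.network.species))
        df.insert(0, "time_min", self.t)
        return df


@dataclass
class DoseResponse:
    """Steady-state output concentration over an inducer grid."""

    architecture: str
    P: float
    inducer: np.ndarray  # mM
    output: np.ndarray  # nM
    species: str = "Output"

    def __post_init__(self):
        self.inducer = np.asarray(self.inducer, dtype=float)
        self.output = np.asarray(self.output, dtype=float)
        if self.inducer.shape != self.output.shape:
            raise ValueError("inducer and output grids differ in length")
        if np.any(self.output < 0):
            raise ValueError("steady-state outputs must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "architecture": self.architecture, "P": self.P,
            "I_mM": self.inducer, "species": self.species,
            "value": self.output, "units": "nM",
        })


def simulate(network: ReactionNetwork, x0, t_end: float, *,
             t_eval=None, rtol: float = RTOL, atol: float = ATOL) -> Trajectory:
    """Integrate the network ODE from ``x0`` to ``t_end`` minutes."""
    if not (t_end > 0):
        raise ValueError(f"t_end must be > 0, got {t_end!r}")
    x0 = np.asarray(x0, dtype=float)
    sol = solve_ivp(
        lambda t, x: network.rhs(x), (0.0, float(t_end)), x0,
        method="LSODA", jac=lambda t, x: network.jacobian(x),
        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise SteadyStateError(f"ODE integration failed: {sol.message}")
    return Trajectory(sol.t, sol.y.T, network)


def _conserved_x_row(network: ReactionNetwork):
    # crosstalk kinase total is conserved -> singular Jacobian; replace the
    # redundant Xp equation by the conservation residual when polishing
    if "X" in network.species:
        return network.index("X"), network.index("Xp")
    return None


def steady_state(network: ReactionNetwork, x0=None, *,
                 t_settle: float = SETTLE_T, tol: float = 1e-10) -> np.ndarray:
    """Steady state via long integration plus Newton polishing.

    Raises :class:`SteadyStateError` with diagnostics if the residual
    norm cannot be brought below ``tol``.
    """
    if x0 is None:
        x0 = network.default_x0()
    traj = simulate(network, x0, t_settle)
    xT = np.maximum(traj.x[-1], 0.0)
    cons = _conserved_x_row(network)

    def fun(x):
        f = network.rhs(np.maximum(x, 0.0))
        if cons is not None:
            iX, iXp = cons
            f = f.copy()
            f[iXp] = x[iX] + x[iXp] - network.X_tot
        return f

    def jac(x):
        J = network.jacobian(np.maximum(x, 0.0))
        if cons is not None:
            iX, iXp = cons
            J = J.copy()
            J[iXp, :] = 0.0
            J[iXp, iX] = 1.0
            J[iXp, iXp] = 1.0
        return J

    sol = root(fun, xT, jac=jac, method="hybr", tol=1e-13)
    cand = np.maximum(sol.x, 0.0)
    res = float(np.linalg.norm(network.rhs(cand)))
    if res < tol:
        return cand
    # fall back to the integrated endpoint if polishing wandered
    res_T = float(np.linalg.norm(network.rhs(xT)))
    if res_T < tol:
        return xT
    raise SteadyStateError(
        f"steady state not converged for {network!r}: residual {res:.3e} "
        f"after polishing ({sol.message}), {res_T:.3e} at t={t_settle:g} min")


def dose_response(scenario: Scenario, *, architecture: str | None = None,
                  **build_kw) -> list[DoseResponse]:
    """One dose-response curve per feedback strength in the scenario.

    For architectures without a feedback strength (wild type, open
    loops) a single curve is returned.
    """
    arch = architecture or scenario.architecture
    closed = arch.startswith("closed_loop") or arch.endswith("_feedback")
    P_values = scenario.P_grid if closed else (scenario.params.P,)
    curves = []
    for P in P_values:
        params = scenario.params.replace(P=P)
        out = np.empty(len(scenario.inducer_grid))
        guess = None
        for k, I in enumerate(scenario.inducer_grid):
            net = build_network(arch, params, I, **build_kw)
            try:
                ss = steady_state(net, x0=guess)
            except SteadyStateError as e:
                raise SteadyStateError(
                    f"dose_response failed at I={I:g} mM, P={P:g}: {e}") from e
            out[k] = ss[net.index("Output")]
            guess = ss
        curves.append(DoseResponse(arch, P, np.asarray(scenario.inducer_grid), out))
    return curves


def step_response(architecture: str, params, I: float, *, t_end: float = 3000.0,
                  n_points: int = 600, **build_kw) -> Trajectory:
    """Response to an inducer step 0 -> I from the pre-step steady state."""
    net0 = build_network(architecture, params, 0.0, **build_kw)
    x0 = steady_state(net0)
    net = build_network(architecture, params, I, **build_kw)
    t_eval = np.linspace(0.0, t_end, n_points)
    t_eval[0] = 0.0
    return simulate(net, x0, t_end, t_eval=t_eval)


def match_comparison_feedback(architecture: str, params, I_grid=None, *,
                              P: float = 1.0, log10_bounds=(-4.0, 2.0),
                              **build_kw) -> float:
    """Fit the comparison feedback's strength constant to the dichotomous one.

    The molecular-sequestration (fit: k_ann) and transcriptional (fit:
    K_tf) comparison architectures have a free constant with no direct
    counterpart in the dichotomous feedback.  It is chosen by least
    squares so that the comparison architecture's dose-response curve
    matches the phosphorylation-sequestration closed loop's on
    ``I_grid`` at feedback strength ``P``.  Returns the fitted constant.
    """
    from scipy.optimize import minimize_scalar

    if architecture not in ("molecular_seq_feedback", "transcriptional_feedback"):
        raise ValueError(f"no matching constant for {architecture!r}")
    field = "k_ann" if architecture == "molecular_seq_feedback" else "K_tf"
    if I_grid is None:
        I_grid = (0.1, 0.5, 1.0, 2.0, 5.0, 10.0)
    pp = params.replace(P=P)
    ref = np.array([
        steady_state(net := build_network("closed_loop_phos_seq", pp, I))
        [net.index("Output")] for I in I_grid])

    def sse(log10_val):
        cand = pp.replace(**{field: 10.0 ** float(log10_val)})
        try:
            out = np.array([
                steady_state(net := build_network(architecture, cand, I,
                                                  **build_kw))
                [net.index("Output")] for I in I_grid])
        except SteadyStateError:
            return 1e12
        return float(np.sum((out - ref) ** 2))

    res = minimize_scalar(sse, bounds=log10_bounds, method="bounded",
                          options={"xatol": 1e-4})
    return float(10.0 ** res.x)


def overshoot(traj: Trajectory, species: str, *, settle_frac: float = 0.1,
              settle_tol: float = 1e-3) -> float:
    """Fractional overshoot (max - final)/final of one species, floored at 0.

    The trajectory must be settled: over the final ``settle_frac`` of the
    time window the species may vary by no more than ``settle_tol``
    (relative to the final value), otherwise an error advises a longer
    ``t_end``.
    """
    y = traj.series(species)
    t = traj.t
    final = y[-1]
    tail = y[t >= t[-1] - settle_frac * (t[-1] - t[0])]
    scale = abs(final) if final != 0 else max(y.max(), 1.0)
    if (tail.max() - tail.min()) > settle_tol * scale:
        raise ValueError(
            f"trajectory not settled for {species}: final-window variation "
            f"{(tail.max() - tail.min()):.3e} exceeds {settle_tol:g} x final; "
            f"increase t_end")
    if final <= 0:
        return 0.0
    return max((y.max() - final) / final, 0.0)
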
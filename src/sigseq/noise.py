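"""Intrinsic-noise quantification: Gillespie SSA and linear noise approximation.

Noise is summarized by the coefficient of variation eta = sd/mean of a
species at a probe time (default 1000 min, roughly ten dilution time
constants from an empty cell, so the statistics are effectively
stationary).  The linear noise approximation propagates the mean along
the macroscopic rate equation and the covariance along the time-varying
Lyapunov equation dSigma/dt = J Sigma + Sigma J^T + D with D =
S diag(a) S^T; the SSA cross-check samples the chemical master equation
exactly with the direct method.

Concentrations are converted to copy numbers with a configurable system
size Omega (copies = Omega x nM); the default Omega = 1 reads the nM
concentrations directly as copy numbers, and eta scales as 1/sqrt(Omega).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._ssa import ssa_ensemble_states, ssa_run
from .network import (BILINEAR, CONSTANT, HILL, LINEAR, REPRESSED, Reaction,
                      ReactionNetwork, build_network)
from .dynamics import Trajectory
from .params import Scenario

__all__ = [
    "NoiseSummary",
    "scale_to_copies",
    "ssa_simulate",
    "ssa_ensemble",
    "lna_moments",
    "lna_cv",
    "cv_vs_mean_curve",
]

DEFAULT_T_PROBE = 1000.0  # min

#: reference system size for the noise study: copies = NOISE_OMEGA x nM,
#: putting RR_tot at ~2000 copies (E. coli response-regulator scale) where
#: the system-size expansion behind the LNA is accurate
NOISE_OMEGA = 4.0

#: reference (architecture, P, I) probes for the LNA/SSA cross-check,
#: spanning the low-to-high mean range of the cv-vs-mean curves
CROSSCHECK_POINTS = (
    ("wild_type", 0.0, 0.5),
    ("wild_type", 0.0, 1.0),
    ("closed_loop_phos_seq", 0.4, 2.0),
    ("closed_loop_phos_seq", 0.7, 1.0),
    ("closed_loop_phos_seq", 1.0, 2.0),
    ("closed_loop_phos_seq", 1.0, 5.0),
)


@dataclass
class NoiseSummary:
    """Mean/variance/coefficient of variation of one species at one time."""

    species: str
    time: float
    mean: float
    variance: float
    cv: float | None  # None when the mean is zero (cv undefined)
    method: str  # "SSA" or "LNA"
    n_runs: int = 0
    seed: int = 0
    se_mean: float = 0.0
    se_cv: float = 0.0

    def __post_init__(self):
        if self.variance < -1e-9:
            raise ValueError("variance must be >= 0")


def scale_to_copies(network: ReactionNetwork, omega: float) -> ReactionNetwork:
    """Rescale a concentration-based network to copy numbers (x -> Omega x).

    Zeroth-order rates and Hill/repression maxima scale by Omega,
    bimolecular rates by 1/Omega, half-saturation constants by Omega;
    unary rates are unchanged.
    """
    if omega == 1.0:
        return network
    rx = []
    for r in network.reactions:
        rate, K = r.rate, r.K
        if r.kind == CONSTANT:
            rate *= omega
        elif r.kind == BILINEAR:
            rate /= omega
        elif r.kind in (HILL, REPRESSED):
            rate *= omega
            K *= omega
        rx.append(Reaction(r.name, r.stoich, r.kind, rate, r.species, K, r.n))
    return ReactionNetwork(network.architecture, network.species, rx,
                           network.params, network.inducer,
                           X_tot=network.X_tot * omega)


def _run_seeds(seed: int, n_runs: int) -> np.ndarray:
    # one independent 32-bit stream seed per run, derived from the master seed
    return np.random.SeedSequence(seed).generate_state(n_runs).astype(np.int64)


def ssa_simulate(network: ReactionNetwork, x0, t_end: float, seed: int, *,
                 t_save=None, omega: float = 1.0) -> Trajectory:
    """One exact realization of the chemical master equation.

    ``x0`` must be integer-valued copy numbers.  The piecewise-constant
    trajectory is sampled on ``t_save`` (default: 201 uniform points).
    """
    net = scale_to_copies(network, omega)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or np.any(x0 != np.round(x0)):
        raise ValueError("SSA initial state must be nonnegative integers")
    if t_save is None:
        t_save = np.linspace(0.0, float(t_end), 201)
    t_save = np.asarray(t_save, dtype=float)
    tables = net.ssa_tables()
    states, _ = ssa_run(x0, *tables, t_save, int(_run_seeds(seed, 1)[0]))
    return Trajectory(t_save, states, net)


def ssa_ensemble(network: ReactionNetwork, x0, t_probe: float, n_runs: int,
                 seed: int, *, omega: float = 1.0) -> dict:
    """Sample mean/variance/cv per species at ``t_probe`` over ``n_runs``.

    Returns a dict species -> :class:`NoiseSummary` with standard errors
    (delta-method for the cv).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    net = scale_to_copies(network, omega)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0) or np.any(x0 != np.round(x0)):
        raise ValueError("SSA initial state must be nonnegative integers")
    tables = net.ssa_tables()
    states = ssa_ensemble_states(x0, *tables, float(t_probe),
                                 _run_seeds(seed, n_runs))
    out = {}
    for i, sp in enumerate(net.species):
        xs = states[:, i]
        m = float(xs.mean())
        v = float(xs.var(ddof=1))
        if m > 0:
            cv = float(np.sqrt(v) / m)
            se_cv = cv * np.sqrt(1.0 / (2.0 * (n_runs - 1)) + cv * cv / n_runs)
        else:
            cv, se_cv = None, 0.0
        out[sp] = NoiseSummary(sp, float(t_probe), m, v, cv, "SSA",
                               n_runs=n_runs, seed=seed,
                               se_mean=float(np.sqrt(v / n_runs)),
                               se_cv=float(se_cv))
    return out


# ----------------------------------------------------------------------
# linear noise approximation
# ----------------------------------------------------------------------
def lna_moments(network: ReactionNetwork, x0, t_grid, *, omega: float = 1.0,
                psd_tol: float = 1e-8):
    """Mean trajectory and covariance matrices of the LNA.

    Integrates the macroscopic rate equation together with the Lyapunov
    covariance equation from a deterministic initial condition
    (Sigma(0) = 0).  The covariance is symmetrized at every save time
    and checked for positive semidefiniteness within ``psd_tol``
    (relative to its trace); violation raises naming the time.

    Returns ``(mean_traj, covs)`` with covs of shape (nt, ns, ns).
    """
    net = scale_to_copies(network, omega)
    ns = net.n_species
    x0 = np.asarray(x0, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    S = net.stoich.astype(float)

    def rhs(t, y):
        x = y[:ns]
        Sig = y[ns:].reshape(ns, ns)
        a = net.propensities(x)
        J = S @ net.propensity_jacobian(x)
        D = (S * a) @ S.T
        dSig = J @ Sig + Sig @ J.T + D
        return np.concatenate([S @ a, dSig.ravel()])

    y0 = np.concatenate([x0, np.zeros(ns * ns)])
    sol = solve_ivp(rhs, (0.0, float(t_grid[-1])), y0, method="LSODA",
                    rtol=1e-8, atol=1e-10, t_eval=t_grid)
    if not sol.success:
        raise RuntimeError(f"LNA integration failed: {sol.message}")
    means = sol.y[:ns].T
    covs = sol.y[ns:].T.reshape(-1, ns, ns)
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
    for k, t in enumerate(sol.t):
        scale = max(np.trace(covs[k]), 1.0)
        lam_min = float(np.linalg.eigvalsh(covs[k])[0])
        if lam_min < -psd_tol * scale:
            raise RuntimeError(
                f"LNA covariance lost positive semidefiniteness at "
                f"t={t:g} min (min eigenvalue {lam_min:.3e})")
    return Trajectory(sol.t, means, net), covs


def lna_cv(network: ReactionNetwork, t_probe: float = DEFAULT_T_PROBE, *,
           x0=None, omega: float = 1.0) -> dict:
    """LNA coefficient of variation per species at ``t_probe``."""
    if x0 is None:
        x0 = network.default_x0()
    traj, covs = lna_moments(network, x0, np.array([0.0, float(t_probe)]),
                             omega=omega)
    out = {}
    for i, sp in enumerate(traj.network.species):
        m = float(traj.x[-1, i])
        v = max(float(covs[-1, i, i]), 0.0)
        cv = float(np.sqrt(v) / m) if m > 0 else None
        out[sp] = NoiseSummary(sp, float(t_probe), m, v, cv, "LNA")
    return out


def cv_vs_mean_curve(scenario: Scenario, t_probe: float = DEFAULT_T_PROBE, *,
                     omega: float = 1.0, species: str = "Output",
                     include_wild_type: bool = True) -> pd.DataFrame:
    """LNA cv against mean output across the scenario grids.

    One row per (architecture, P, I); the wild-type reference curve is
    appended unless disabled.  Rows are sorted by mean.
    """
    rows = []
    combos = [(scenario.architecture, P) for P in scenario.P_grid]
    if include_wild_type and scenario.architecture != "wild_type":
        combos.append(("wild_type", 0.0))
    for arch, P in combos:
        params = scenario.params.replace(P=P)
        for I in scenario.inducer_grid:
            net = build_network(arch, params, I)
            summ = lna_cv(net, t_probe, omega=omega)[species]
            rows.append({
                "architecture": arch, "P": P, "I_mM": I,
                "mean": summ.mean, "cv": summ.cv,
                "mean_units": "copies", "cv_units": "dimensionless",
            })
    return (pd.DataFrame(rows)
            .sort_values("mean", kind="mergesort")
            .reset_index(drop=True))


def lna_ssa_crosscheck(params, points=CROSSCHECK_POINTS, *,
                       n_runs: int = 10_000, seed: int = 0,
                       omega: float = NOISE_OMEGA,
                       t_probe: float = DEFAULT_T_PROBE,
                       species: str = "Output") -> pd.DataFrame:
    """Compare SSA and LNA coefficients of variation at probe points.

    One row per (architecture, P, I): SSA cv with its standard error,
    LNA cv, and the discrepancy z = |cv_SSA - cv_LNA| / SE.
    """
    rows = []
    for k, (arch, P, I) in enumerate(points):
        net = build_network(arch, params.replace(P=float(P)), float(I))
        x0 = net.default_x0() * omega
        ssa = ssa_ensemble(net, x0, t_probe, n_runs, seed + k,
                           omega=omega)[species]
        lna = lna_cv(net, t_probe, omega=omega)[species]
        z = abs(ssa.cv - lna.cv) / ssa.se_cv if ssa.cv is not None else np.inf
        rows.append({"architecture": arch, "P": P, "I_mM": I,
                     "cv_ssa": ssa.cv, "se_cv_ssa": ssa.se_cv,
                     "cv_lna": lna.cv, "z": z,
                     "mean_ssa": ssa.mean, "mean_lna": lna.mean,
                     "n_runs": n_runs})
    return pd.DataFrame(rows)
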
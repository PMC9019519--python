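"""Closed-form steady-state theory and structural property checks.

Contents
--------
* Closed-form steady-state approximations of [RRp] for the two
  sequestration motifs (phosphorylation sequestration and
  dephosphorylation enhancement), valid when phosphotransfer is fast
  relative to autophosphorylation and the phosphorylated fractions are
  small; :func:`check_assumptions` quantifies both conditions as ratios
  against a configurable "much greater than" margin (default 10x).
* The resource-competition steady state for shared
  transcription/translation machinery.
* The reduced three-state model of the phosphorylation-sequestration
  motif (states [HK], [RR], [SR], obtained by eliminating the
  phosphorylated forms through the asymptotic totals), its invariant box
  S, the algebraic local-stability condition of the bare two-component
  system, a numerical monotonicity (cooperativity) check, and the
  corner-trajectory global-attractivity diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import autophosphorylation_rate, hill
from .params import RateParams

__all__ = [
    "ApproxReport",
    "ResourceParams",
    "StabilityReport",
    "ReducedPhosSeq",
    "rrp_star_phos_seq",
    "rrp_star_dephos",
    "check_assumptions",
    "resource_steady_state",
    "resource_ode_rhs",
    "local_stability_condition",
    "monotone_structure_check",
    "corner_convergence",
    "rr_star_vs_beta_sr",
]


# ----------------------------------------------------------------------
# closed-form steady states
# ----------------------------------------------------------------------
def rrp_star_phos_seq(params: RateParams, I: float) -> float:
    """Approximate steady state of [RRp] under phosphorylation sequestration.

    (kap/kp) * kt*RR_tot/(kt*RR_tot + ktc*SR_tot + delta)
             * kp*HK_tot/(kp*HK_tot + delta)

    Each bracketed factor is <= 1, so the value is bounded by kap/kp and
    strictly decreasing in SR_tot.
    """
    p = params
    if p.kp == 0:
        raise ZeroDivisionError("kp = 0: closed-form [RRp]* undefined")
    kap = autophosphorylation_rate(I, p)
    return (kap / p.kp
            * p.kt * p.RR_tot / (p.kt * p.RR_tot + p.ktc * p.SR_tot + p.delta)
            * p.kp * p.HK_tot / (p.kp * p.HK_tot + p.delta))


def rrp_star_dephos(params: RateParams, I: float) -> float:
    """Approximate steady state of [RRp] under dephosphorylation enhancement.

    (kap/kp) * kt*RR_tot/(kt*RR_tot + delta)
             * kp*HK_tot/(delta + kpc*PH_tot + kp*HK_tot)

    Coincides with :func:`rrp_star_phos_seq` when both totals vanish —
    the 'duality' of the two motifs.
    """
    p = params
    if p.kp == 0:
        raise ZeroDivisionError("kp = 0: closed-form [RRp]* undefined")
    kap = autophosphorylation_rate(I, p)
    return (kap / p.kp
            * p.kt * p.RR_tot / (p.kt * p.RR_tot + p.delta)
            * p.kp * p.HK_tot / (p.delta + p.kpc * p.PH_tot + p.kp * p.HK_tot))


@dataclass
class ApproxReport:
    """Closed form vs full model, with the assumption ratios behind it."""

    motif: str
    approx_value: float
    full_value: float
    relative_error: float
    assumption_ratios: dict
    margin: float
    valid: bool


def check_assumptions(params: RateParams, I: float, motif: str, *,
                      margin: float = 10.0) -> ApproxReport:
    """Evaluate the validity conditions of the closed-form steady states.

    Ratios reported (all should exceed ``margin`` for validity):

    * ``timescale`` — left/right sides of the fast-transfer inequality
      (delta + kt RR_tot [+ ktc SR_tot] versus kap scaled by the
      kinase-turnover quotient);
    * ``RR_sum/RRp`` and, for the phosphorylation-sequestration motif,
      ``SR_sum/SRp`` — the small-phosphorylated-fraction conditions,
      evaluated at the numerically computed full-model steady state;
    * ``HK_substitution`` — the closed forms replace [HK] by HK_tot,
      contributing a relative error of about
      ([HKp]/[HK_sum]) * (delta + kpc PH_tot)/(delta + kpc PH_tot + kp HK_tot);
      the reported ratio is the reciprocal of that bound.  When kp and
      kt differ widely the timescale ratio alone does not control this
      term, so it is required separately.
    """
    from .dynamics import steady_state  # local import: avoid cycle
    from .network import build_network

    if motif not in ("phos_seq", "dephos"):
        raise ValueError(f"motif must be 'phos_seq' or 'dephos', got {motif!r}")
    p = params
    kap = autophosphorylation_rate(I, p)
    tiny = np.finfo(float).tiny

    if motif == "phos_seq":
        lhs = p.delta + p.kt * p.RR_tot + p.ktc * p.SR_tot
        rhs = kap * (p.delta + p.kt * p.HK_tot) / (p.delta + p.kp * p.HK_tot)
        net = build_network("open_loop_phos_seq", p, I)
        approx = rrp_star_phos_seq(p, I)
    else:
        lhs = p.delta + p.kt * p.RR_tot
        rhs = (kap * (p.delta + p.kpc * p.PH_tot + p.kt * p.HK_tot)
               / (p.delta + p.kpc * p.PH_tot + p.kp * p.HK_tot))
        net = build_network("open_loop_dephos", p, I)
        approx = rrp_star_dephos(p, I)

    ss = steady_state(net)
    rr, rrp = ss[net.index("RR")], ss[net.index("RRp")]
    hk, hkp = ss[net.index("HK")], ss[net.index("HKp")]
    full = float(rrp)
    ph_term = p.kpc * p.PH_tot if motif == "dephos" else 0.0
    hk_sub_coeff = (p.delta + ph_term) / (p.delta + ph_term + p.kp * p.HK_tot)
    ratios = {
        "timescale": lhs / max(rhs, tiny),
        "RR_sum/RRp": (rr + rrp) / max(rrp, tiny),
        "HK_substitution": (hk + hkp) / max(hkp * hk_sub_coeff, tiny),
    }
    if motif == "phos_seq" and p.SR_tot > 0:
        sr, srp = ss[net.index("SR")], ss[net.index("SRp")]
        ratios["SR_sum/SRp"] = (sr + srp) / max(srp, tiny)

    if full == 0.0 and approx == 0.0:
        rel = 0.0
    else:
        rel = abs(approx - full) / max(abs(full), tiny)
    valid = all(r > margin for r in ratios.values())
    return ApproxReport(motif, float(approx), full, float(rel), ratios,
                        margin, valid)


# ----------------------------------------------------------------------
# resource competition
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ResourceParams:
    """Shared-resource expression model for two proteins Y and S.

    T_Y, T_S: baseline expression rates (nM/min); beta_Y, beta_S:
    expression initiation rates; J_Y, J_S: resource-usage measures
    (dimensionless per initiation rate); delta: dilution (1/min).
    """

    T_Y: float
    T_S: float
    beta_Y: float
    beta_S: float
    J_Y: float
    J_S: float
    delta: float

    def __post_init__(self):
        for name in ("T_Y", "T_S", "beta_Y", "beta_S", "J_Y", "J_S", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    @property
    def K_Y(self) -> float:
        """Lumped basal-expression parameter T_Y/delta."""
        return self.T_Y / self.delta


def resource_steady_state(rp: ResourceParams) -> float:
    """Steady state of Y under resource competition.

    [Y]* = K_Y beta_Y / (1 + J_Y beta_Y + J_S beta_S); reduces to
    K_Y beta_Y in the resource-abundant limit J_Y = J_S = 0.
    """
    return rp.K_Y * rp.beta_Y / (1.0 + rp.J_Y * rp.beta_Y + rp.J_S * rp.beta_S)


def resource_ode_rhs(rp: ResourceParams, y):
    """RHS of the two-species resource-competition ODE, state (Y, S)."""
    denom = 1.0 + rp.J_Y * rp.beta_Y + rp.J_S * rp.beta_S
    Y, S = y
    return np.array([
        rp.T_Y * rp.beta_Y / denom - rp.delta * Y,
        rp.T_S * rp.beta_S / denom - rp.delta * S,
    ])


# ----------------------------------------------------------------------
# reduced three-state model and structural checks
# ----------------------------------------------------------------------
class ReducedPhosSeq:
    """Reduced phosphorylation-sequestration model, states ([HK],[RR],[SR]).

    The phosphorylated forms are eliminated through the totals
    HK_tot = beta_HK/delta etc., giving a cooperative (monotone) system
    on the box S = [0,HK_tot] x [0,RR_tot] x [0,SR_tot].  With
    ``closed=True`` the constitutive SR production beta_SR is replaced
    by the feedback law P*kout(RR_tot - [RR]) and a fourth state
    [SR_sum] tracks the produced total.
    """

    def __init__(self, params: RateParams, I: float, *, closed: bool = False):
        self.params = params
        self.I = float(I)
        self.kap = autophosphorylation_rate(I, params)
        self.closed = bool(closed)
        self.states = ("HK", "RR", "SR", "SR_sum") if closed else ("HK", "RR", "SR")

    # feedback law u = P*kout(RR_tot - RR)
    def _u(self, rr: float) -> float:
        p = self.params
        rrp = max(p.RR_tot - rr, 0.0)
        return p.P * p.kout_max * float(hill(rrp, p.Kdr, p.n))

    def _du_drr(self, rr: float) -> float:
        from .network import hill_deriv
        p = self.params
        rrp = max(p.RR_tot - rr, 0.0)
        return -p.P * p.kout_max * float(hill_deriv(rrp, p.Kdr, p.n))

    def rhs(self, x) -> np.ndarray:
        p, kap = self.params, self.kap
        if self.closed:
            hk, rr, sr, srs = x
            u = self._u(rr)
            sr_cap = srs
        else:
            hk, rr, sr = x
            u = p.beta_SR
            sr_cap = p.SR_tot
        hkp = p.HK_tot - hk
        f_hk = p.beta_HK - p.delta * hk - kap * hk + p.kt * hkp * rr + p.ktc * hkp * sr
        f_rr = p.beta_RR - p.delta * rr - p.kt * hkp * rr + p.kp * hk * (p.RR_tot - rr)
        f_sr = u - p.delta * sr - p.ktc * hkp * sr + p.kpc * hk * (sr_cap - sr)
        if self.closed:
            return np.array([f_hk, f_rr, f_sr, u - p.delta * srs])
        return np.array([f_hk, f_rr, f_sr])

    def jac(self, x) -> np.ndarray:
        p, kap = self.params, self.kap
        if self.closed:
            hk, rr, sr, srs = x
            sr_cap = srs
        else:
            hk, rr, sr = x
            sr_cap = p.SR_tot
        hkp = p.HK_tot - hk
        J = np.zeros((len(self.states),) * 2)
        J[0, 0] = -p.delta - kap - p.kt * rr - p.ktc * sr
        J[0, 1] = p.kt * hkp
        J[0, 2] = p.ktc * hkp
        J[1, 0] = p.kt * rr + p.kp * (p.RR_tot - rr)
        J[1, 1] = -p.delta - p.kt * hkp - p.kp * hk
        J[2, 0] = p.ktc * sr + p.kpc * (sr_cap - sr)
        J[2, 2] = -p.delta - p.ktc * hkp - p.kpc * hk
        if self.closed:
            du = self._du_drr(rr)
            J[2, 1] = du
            J[2, 3] = p.kpc * hk
            J[3, 1] = du
            J[3, 3] = -p.delta
        return J

    # ------------------------------------------------------------------
    def box(self) -> np.ndarray:
        """The invariant set S as (lower, upper) bounds, open-loop only."""
        if self.closed:
            raise ValueError("the box S is defined for the open-loop model")
        p = self.params
        return np.array([[0.0, 0.0, 0.0], [p.HK_tot, p.RR_tot, p.SR_tot]])

    def corners(self):
        lo, hi = self.box()
        return lo, hi

    def simulate(self, x0, t_end: float, t_eval=None):
        sol = solve_ivp(lambda t, x: self.rhs(x), (0.0, float(t_end)),
                        np.asarray(x0, dtype=float), method="LSODA",
                        jac=lambda t, x: self.jac(x),
                        rtol=1e-10, atol=1e-12, t_eval=t_eval)
        if not sol.success:
            raise RuntimeError(f"reduced-model integration failed: {sol.message}")
        return sol.t, sol.y.T

    def steady_state(self, x0=None, t_settle: float = 1e5) -> np.ndarray:
        if x0 is None:
            x0 = np.zeros(len(self.states))
        _, x = self.simulate(x0, t_settle)
        sol = root(self.rhs, x[-1], jac=self.jac, method="hybr", tol=1e-13)
        cand = sol.x
        if np.linalg.norm(self.rhs(cand)) < 1e-10:
            return cand
        return x[-1]


@dataclass
class StabilityReport:
    stable: bool          # full determinant condition
    simplified: bool      # sufficient fractional-occupancy condition
    margin: float         # lhs - rhs of the full condition (1/min^2)


def local_stability_condition(ss, params: RateParams, I: float) -> StabilityReport:
    """Algebraic local-stability test for the bare two-component system.

    ``ss`` is a steady state ([HK]*, [RR]*) of the reduced model with
    beta_SR = 0.  The equilibrium is locally asymptotically stable if

        (delta + kap + kt[RR]*)(delta + kt[HKp]* + kp[HK]*)
            > kt[HKp]* (kt[RR]* + kp[RRp]*)

    with [HKp]* = HK_tot - [HK]* and [RRp]* = RR_tot - [RR]*.  A simpler
    sufficient condition is 1 > [HKp]*/HK_tot + [RRp]*/RR_tot.
    """
    p = params
    hk, rr = float(ss[0]), float(ss[1])
    if not (-1e-9 <= hk <= p.HK_tot * (1 + 1e-9)):
        raise ValueError(f"[HK]*={hk:g} outside [0, HK_tot={p.HK_tot:g}]")
    if not (-1e-9 <= rr <= p.RR_tot * (1 + 1e-9)):
        raise ValueError(f"[RR]*={rr:g} outside [0, RR_tot={p.RR_tot:g}]")
    kap = autophosphorylation_rate(I, p)
    hkp = p.HK_tot - hk
    rrp = p.RR_tot - rr
    lhs = (p.delta + kap + p.kt * rr) * (p.delta + p.kt * hkp + p.kp * hk)
    rhs = p.kt * hkp * (p.kt * rr + p.kp * rrp)
    simplified = 1.0 > hkp / p.HK_tot + rrp / p.RR_tot if p.HK_tot * p.RR_tot > 0 else True
    return StabilityReport(stable=lhs > rhs, simplified=bool(simplified),
                           margin=float(lhs - rhs))


def monotone_structure_check(model, *, n_samples: int = 1000, seed: int = 0,
                             box=None, tol: float = 1e-12):
    """Numerically verify cooperativity (monotonicity) on sampled states.

    Samples states uniformly in the model's invariant box and checks
    that every off-diagonal Jacobian entry is >= -tol.  Returns
    ``(True, None)`` or ``(False, witness_state)``.
    """
    if box is None:
        box = model.box()
    lo, hi = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    ndim = lo.size
    for _ in range(n_samples):
        x = lo + (hi - lo) * rng.random(ndim)
        J = model.jac(x)
        off = J - np.diag(np.diag(J))
        if np.any(off < -tol):
            return False, x
    return True, None


def corner_convergence(params: RateParams, I: float, *, t_end: float = 2e5,
                       tol: float = 1e-6):
    """Global-attractivity diagnostic for the reduced open-loop model.

    Integrates from the two corner states of S (all-zero and all-total);
    if both trajectories converge to the same point, monotonicity
    implies that point is globally attractive in S.  Returns
    (converged, x_star, gap).
    """
    model = ReducedPhosSeq(params, I, closed=False)
    lo, hi = model.corners()
    _, xa = model.simulate(lo, t_end)
    _, xb = model.simulate(hi, t_end)
    scale = np.maximum(model.box()[1], 1.0)
    gap = float(np.max(np.abs(xa[-1] - xb[-1]) / scale))
    return gap < tol, 0.5 * (xa[-1] + xb[-1]), gap


def rr_star_vs_beta_sr(params: RateParams, I: float, beta_sr_grid) -> np.ndarray:
    """Steady-state [RR]* of the reduced model along a beta_SR scan."""
    out = np.empty(len(beta_sr_grid))
    guess = None
    for k, b in enumerate(beta_sr_grid):
        model = ReducedPhosSeq(params.replace(beta_SR=float(b)), I)
        ss = model.steady_state(x0=guess)
        out[k] = ss[1]
        guess = ss
    return out
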
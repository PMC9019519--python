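"""Frequency-domain robustness analysis of the feedback architectures.

The closed loop is split into a *process* (the two-component core) and a
*controller* (the sequestration species, annihilator or repressor),
linearized at the closed-loop steady state.  Following the standard
feedback bookkeeping, with G_yu the process transfer matrix from the
controlled input u to the measured outputs y, G_yz the transfer from the
external (inducer) channel z, and K the controller,

    Y = (I - G_yu K)^-1 G_yz Z  +  (I - G_yu K)^-1 W
        '------ T ------'          '------ S -----'

so S maps process disturbances to outputs and its spectral-norm
magnitude quantifies robustness (the classical design rule of thumb is a
peak ||S||_Hinf <= 1.2).  No extra sign is injected: the negative action
of the loop is carried by the signs of the linearized coefficients.

Process reductions used per architecture (all around the steady state,
where the response-regulator total equals RR_tot exactly):

* ``closed_loop_phos_seq`` — process states ([HK],[RRp]) with the kinase
  total fixed; controller states ([SR],[SR_sum]); u=[SR], y=([HK],[RRp]).
* ``closed_loop_dephos`` — same process states; one-state controller
  [PH]; u=[PH], y=[RRp]; K(jw) = P h'([RRp]*)/(jw+delta).
* ``molecular_seq_feedback`` — the annihilator changes the kinase total,
  so the process keeps ([HK],[HKp],[RRp]); controller [M];
  u=[M], y=([HK],[HKp],[RRp]) (the states the annihilator senses).
* ``transcriptional_feedback`` — process ([HK],[HKp],[RRp]); controller
  [TF]; u=[TF], y=[RRp].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .dynamics import steady_state
from .network import (autophosphorylation_rate, build_network, hill,
                      hill_deriv)
from .params import RateParams

__all__ = [
    "LinearizedSystem",
    "FrequencyResponse",
    "default_omega_grid",
    "linearize_process",
    "linearize_controller",
    "sensitivity_response",
    "sensitivity_grid_max",
]

_FEEDBACK_ARCHS = ("closed_loop_phos_seq", "closed_loop_dephos",
                   "molecular_seq_feedback", "transcriptional_feedback")


def default_omega_grid(lo: float = 1e-6, hi: float = 1e2,
                       per_decade: int = 200) -> np.ndarray:
    """Log-spaced frequency grid (rad/min)."""
    ndec = np.log10(hi / lo)
    return np.logspace(np.log10(lo), np.log10(hi),
                       int(round(ndec * per_decade)) + 1)


@dataclass
class LinearizedSystem:
    """State-space piece (A, B_u, B_z, C) evaluated at an operating point."""

    A: np.ndarray
    B_u: np.ndarray
    B_z: np.ndarray
    C: np.ndarray
    operating_point: np.ndarray  # full-network steady state
    states: tuple
    inputs: tuple
    outputs: tuple
    architecture: str = ""

    def transfer(self, s: complex) -> np.ndarray:
        """C (sI - A)^-1 B_u at one complex frequency."""
        n = self.A.shape[0]
        return self.C @ np.linalg.solve(s * np.eye(n) - self.A, self.B_u)

    def transfer_z(self, s: complex) -> np.ndarray:
        n = self.A.shape[0]
        return self.C @ np.linalg.solve(s * np.eye(n) - self.A, self.B_z)


@dataclass
class FrequencyResponse:
    """Sensitivity/complementary responses on a frequency grid."""

    omega: np.ndarray  # rad/min
    S: np.ndarray  # (n_omega, ny, ny) complex
    T: np.ndarray  # (n_omega, ny, nz) complex
    magnitudes: np.ndarray  # spectral norm of S per omega
    hinf: float  # max magnitude (after local refinement)
    argmax_omega: float


def _operating_point(architecture: str, params: RateParams, I: float,
                     **build_kw):
    net = build_network(architecture, params, I, **build_kw)
    ss = steady_state(net)
    val = {sp: ss[net.index(sp)] for sp in net.species}
    # stationarity of the response-regulator total gives RR+RRp = RR_tot
    val["SR_sum"] = val.get("SR", 0.0) + val.get("SRp", 0.0)
    return net, ss, val


def linearize_process(architecture: str, params: RateParams, I: float,
                      **build_kw) -> LinearizedSystem:
    """Linearized process block at the closed-loop steady state.

    The external input z perturbs the autophosphorylation rate kap; the
    controlled input u is the controller's output species.
    """
    if architecture not in _FEEDBACK_ARCHS:
        raise ValueError(f"no process/controller split for {architecture!r}; "
                         f"expected one of {_FEEDBACK_ARCHS}")
    p = params
    kap = autophosphorylation_rate(I, p)
    net, ss, v = _operating_point(architecture, p, I, **build_kw)
    hk, rrp = v["HK"], v["RRp"]
    eig_check = None

    if architecture == "closed_loop_phos_seq":
        sr = v["SR"]
        A = np.array([
            [-(p.kt * (p.RR_tot - rrp) + p.ktc * sr) - kap - p.delta,
             -p.kt * (p.HK_tot - hk)],
            [-p.kt * (p.RR_tot - rrp) - p.kp * rrp,
             -p.delta - p.kt * (p.HK_tot - hk) - p.kp * hk],
        ])
        B_u = np.array([[p.ktc * (p.HK_tot - hk)], [0.0]])
        B_z = np.array([[-hk], [0.0]])
        C = np.eye(2)
        states, inputs, outputs = ("HK", "RRp"), ("SR",), ("HK", "RRp")
    elif architecture == "closed_loop_dephos":
        ph = v["PH"]
        A = np.array([
            [-kap - p.delta - p.kt * (p.RR_tot - rrp),
             -p.kt * (p.HK_tot - hk)],
            [-p.kt * (p.RR_tot - rrp) - p.kp * rrp,
             -p.delta - p.kt * (p.HK_tot - hk) - p.kp * hk - p.kpc * ph],
        ])
        B_u = np.array([[0.0], [-p.kpc * rrp]])
        B_z = np.array([[-hk], [0.0]])
        C = np.array([[0.0, 1.0]])
        states, inputs, outputs = ("HK", "RRp"), ("PH",), ("RRp",)
    else:
        hkp = v["HKp"]
        # three-state process: the comparison feedbacks change the kinase
        # total, so HK and HKp stay separate states
        a_ann = p.k_ann * v.get("M", 0.0)
        phos_only = bool(build_kw.get("mol_seq_phos_only", False))
        ann_hk = 0.0 if (architecture != "molecular_seq_feedback" or phos_only) \
            else a_ann
        ann_hkp = a_ann if architecture == "molecular_seq_feedback" else 0.0
        A = np.array([
            [-p.delta - kap - ann_hk, p.kt * (p.RR_tot - rrp),
             -p.kt * hkp],
            [kap, -p.delta - p.kt * (p.RR_tot - rrp) - ann_hkp,
             p.kt * hkp],
            [-p.kp * rrp, p.kt * (p.RR_tot - rrp),
             -p.delta - p.kt * hkp - p.kp * hk],
        ])
        if architecture == "molecular_seq_feedback":
            B_u = np.array([[-p.k_ann * hk if not phos_only else 0.0],
                            [-p.k_ann * hkp], [0.0]])
            C = np.eye(3)
            outputs = ("HK", "HKp", "RRp")
        else:  # transcriptional_feedback
            tf = v["TF"]
            B_u = np.array([[-p.beta_HK / p.K_tf / (1.0 + tf / p.K_tf) ** 2],
                            [0.0], [0.0]])
            C = np.array([[0.0, 0.0, 1.0]])
            outputs = ("RRp",)
        B_z = np.array([[-hk], [hk], [0.0]])
        states = ("HK", "HKp", "RRp")
        inputs = ("M",) if architecture == "molecular_seq_feedback" else ("TF",)

    lin = LinearizedSystem(A, B_u, B_z, C, ss, states, inputs, outputs,
                           architecture)
    if np.max(np.linalg.eigvals(A).real) >= 0:
        raise RuntimeError(
            f"process linearization of {architecture} at I={I:g} is not "
            f"stable (eigenvalues {np.linalg.eigvals(A)})")
    return lin


def linearize_controller(architecture: str, params: RateParams, I: float,
                         **build_kw) -> LinearizedSystem:
    """Linearized controller block; its inputs are the process outputs y."""
    if architecture not in _FEEDBACK_ARCHS:
        raise ValueError(f"no process/controller split for {architecture!r}")
    p = params
    net, ss, v = _operating_point(architecture, p, I, **build_kw)
    hk, rrp = v["HK"], v["RRp"]
    dh = p.P * p.kout_max * float(hill_deriv(rrp, p.Kdr, p.n))

    if architecture == "closed_loop_phos_seq":
        sr, srs = v["SR"], v["SR_sum"]
        A = np.array([
            [-p.delta - p.ktc * (p.HK_tot - hk) - p.kpc * hk, p.kpc * hk],
            [0.0, -p.delta],
        ])
        # inputs y = (HK, RRp)
        B = np.array([
            [p.ktc * sr + p.kpc * (srs - sr), dh],
            [0.0, dh],
        ])
        C = np.array([[1.0, 0.0]])
        states, inputs, outputs = ("SR", "SR_sum"), ("HK", "RRp"), ("SR",)
    elif architecture == "closed_loop_dephos":
        A = np.array([[-p.delta]])
        B = np.array([[dh]])  # input y = RRp
        C = np.array([[1.0]])
        states, inputs, outputs = ("PH",), ("RRp",), ("PH",)
    elif architecture == "molecular_seq_feedback":
        m = v["M"]
        hkp = v["HKp"]
        phos_only = bool(build_kw.get("mol_seq_phos_only", False))
        loss = p.k_ann * (hkp if phos_only else hk + hkp)
        A = np.array([[-p.delta - loss]])
        B = np.array([[0.0 if phos_only else -p.k_ann * m,
                       -p.k_ann * m, dh]])  # inputs (HK, HKp, RRp)
        C = np.array([[1.0]])
        states, inputs, outputs = ("M",), ("HK", "HKp", "RRp"), ("M",)
    else:  # transcriptional_feedback
        A = np.array([[-p.delta]])
        B = np.array([[dh]])
        C = np.array([[1.0]])
        states, inputs, outputs = ("TF",), ("RRp",), ("TF",)

    return LinearizedSystem(A, B, np.zeros((A.shape[0], 1)), C, ss,
                            states, inputs, outputs, architecture)


def _loop_matrices(process: LinearizedSystem, controller: LinearizedSystem,
                   s: complex):
    G_yu = process.transfer(s)
    G_yz = process.transfer_z(s)
    K = controller.transfer(s)
    return G_yu, G_yz, K


def sensitivity_response(process: LinearizedSystem,
                         controller: LinearizedSystem,
                         omega_grid=None, *, refine: bool = True,
                         identity_tol: float = 1e-10) -> FrequencyResponse:
    """Sensitivity S and complementary map T on a frequency grid.

    S = (I - G_yu K)^-1 and T = S G_yz; the return-difference identity
    S (I - G_yu K) = I is verified at every grid point to
    ``identity_tol``.  The grid maximum of the spectral norm ||S|| is
    polished by a bounded scalar search between the neighbouring grid
    points (guards peak aliasing).
    """
    if omega_grid is None:
        omega_grid = default_omega_grid()
    omega_grid = np.asarray(omega_grid, dtype=float)
    ny = process.C.shape[0]
    nz = process.B_z.shape[1]
    S = np.empty((omega_grid.size, ny, ny), dtype=complex)
    T = np.empty((omega_grid.size, ny, nz), dtype=complex)
    mags = np.empty(omega_grid.size)
    Iy = np.eye(ny)
    for k, w in enumerate(omega_grid):
        G_yu, G_yz, K = _loop_matrices(process, controller, 1j * w)
        ret_diff = Iy - G_yu @ K
        cond = np.linalg.cond(ret_diff)
        if not np.isfinite(cond) or cond > 1e12:
            raise RuntimeError(
                f"return difference I - G_yu K nearly singular at "
                f"omega={w:g} rad/min (cond={cond:.2e})")
        Sk = np.linalg.inv(ret_diff)
        if np.max(np.abs(Sk @ ret_diff - Iy)) > identity_tol:
            raise RuntimeError(
                f"return-difference identity violated at omega={w:g}")
        S[k] = Sk
        T[k] = Sk @ G_yz
        mags[k] = np.linalg.norm(Sk, 2)

    kmax = int(np.argmax(mags))
    hinf, w_at = mags[kmax], omega_grid[kmax]
    if refine and 0 < kmax < omega_grid.size - 1:
        lo, hi = np.log10(omega_grid[kmax - 1]), np.log10(omega_grid[kmax + 1])

        def neg_mag(logw):
            G_yu, _, K = _loop_matrices(process, controller,
                                        1j * 10.0 ** logw)
            return -np.linalg.norm(np.linalg.inv(Iy - G_yu @ K), 2)

        res = minimize_scalar(neg_mag, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        if -res.fun > hinf:
            hinf, w_at = -res.fun, 10.0 ** res.x
    return FrequencyResponse(omega_grid, S, T, mags, float(hinf), float(w_at))


def sensitivity_grid_max(architecture: str, params: RateParams, I_list,
                         P_list, omega_grid=None, **build_kw):
    """Maximum of ||S(jw)|| over an (inducer, feedback-strength) grid.

    Returns ``(hinf, argmax)`` where argmax is a dict with the achieving
    I, P and omega.  Deterministic.
    """
    if len(list(I_list)) == 0 or len(list(P_list)) == 0:
        raise ValueError("I_list and P_list must be non-empty")
    best, arg = -np.inf, None
    for P in P_list:
        pp = params.replace(P=float(P))
        for I in I_list:
            proc = linearize_process(architecture, pp, I, **build_kw)
            ctrl = linearize_controller(architecture, pp, I, **build_kw)
            fr = sensitivity_response(proc, ctrl, omega_grid)
            if fr.hinf > best:
                best = fr.hinf
                arg = {"I": float(I), "P": float(P),
                       "omega": fr.argmax_omega}
    return float(best), arg
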
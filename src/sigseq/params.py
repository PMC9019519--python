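"""Kinetic parameter sets and named study scenarios.

Every other module consumes :class:`RateParams`; no external data are
required anywhere in the package.  Units are fixed package-wide: time in
minutes, inducer in mM, protein species in nM (with the default system
size the numbers double as molecule copy numbers in the stochastic
module).

``nominal_params`` returns the package's reference parameter set for an
*E. coli*-like two-component system: dilution on the cell-cycle scale,
phosphotransfer well above dilution, the response regulator in large
excess over its kinase (RR_tot = 500 nM, HK_tot = 25 nM).
``PROVENANCE`` flags, per field, whether the value
comes from the published reference value (``literature``),
fitted by the package's own matching procedure (``fitted``), or a
documented default (``default``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateParams",
    "Scenario",
    "PROVENANCE",
    "ARCHITECTURES",
    "nominal_params",
    "perturb_params",
    "scenario",
    "list_scenarios",
]

#: architectures understood by :func:`sigseq.network.build_network`
ARCHITECTURES = (
    "wild_type",
    "open_loop_phos_seq",
    "open_loop_dephos",
    "closed_loop_phos_seq",
    "closed_loop_dephos",
    "molecular_seq_feedback",
    "transcriptional_feedback",
)


@dataclass(frozen=True)
class RateParams:
    """Kinetic/production constants of the two-component system model.

    Attributes
    ----------
    kap_max : float
        Maximal HK autophosphorylation rate (1/min).
    Kda : float
        Inducer dissociation constant of the autophosphorylation
        Michaelis–Menten function (mM).
    kt : float
        HKp -> RR phosphotransfer rate (1/(nM min)).
    kp : float
        RRp dephosphorylation-by-HK rate (1/(nM min)).
    ktc : float
        HKp -> SR phosphotransfer rate (1/(nM min)).
    kpc : float
        SRp dephosphorylation / phosphatase (PH) action rate (1/(nM min)).
    delta : float
        Dilution rate for all produced proteins (1/min).
    beta_HK, beta_RR, beta_SR, beta_PH : float
        Constitutive production rates (nM/min).
    kout_max : float
        Maximal output-promoter initiation rate (nM/min).
    Kdr : float
        RRp dissociation constant of the output Hill function (nM).
    n : float
        Hill cooperativity of the output promoter (>= 1).
    P : float
        Feedback strength: dimensionless multiplier on the
        output-promoter-driven production of the sequestration protein.
    kap_X : float
        Constant phosphorylation rate of the crosstalk kinase X (1/min);
        0 switches crosstalk off.
    k_ann : float
        Bimolecular annihilation rate of the molecular-sequestration
        comparison feedback (1/(nM min)).
    K_tf : float
        Repression constant of the transcriptional comparison feedback (nM).
    """

    kap_max: float = 0.046
    Kda: float = 1.0
    kt: float = 2.2e-4
    kp: float = 2e-3
    ktc: float = 0.012
    kpc: float = 2e-3
    delta: float = 0.01
    beta_HK: float = 0.25
    beta_RR: float = 5.0
    beta_SR: float = 0.0
    beta_PH: float = 0.0
    kout_max: float = 0.5
    Kdr: float = 6.0
    n: float = 2.0
    P: float = 0.0
    kap_X: float = 0.0
    k_ann: float = 1.792e-2
    K_tf: float = 3.339

    # -- derived totals -------------------------------------------------
    @property
    def HK_tot(self) -> float:
        return self.beta_HK / self.delta

    @property
    def RR_tot(self) -> float:
        return self.beta_RR / self.delta

    @property
    def SR_tot(self) -> float:
        return self.beta_SR / self.delta

    @property
    def PH_tot(self) -> float:
        return self.beta_PH / self.delta

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f.name} must be finite and >= 0, got {v!r}")
        if self.delta <= 0:
            raise ValueError("delta must be > 0 (totals beta/delta must exist)")
        if self.n < 1:
            raise ValueError("Hill cooperativity n must be >= 1")

    def replace(self, **changes) -> "RateParams":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


#: provenance of each nominal value: 'literature' = published reference
#: value, 'fitted' = produced by the package's dose-response matching
#: procedure (sigseq.freq.match_comparison_feedback), 'default' = documented
#: package default chosen on physiological grounds (see docs/methods.md).
PROVENANCE: dict[str, str] = {
    "kap_max": "default",
    "Kda": "default",
    "kt": "default",
    "kp": "default",
    "ktc": "default",
    "kpc": "default",
    "delta": "default",
    "beta_HK": "default",
    "beta_RR": "default",
    "beta_SR": "default",
    "beta_PH": "default",
    "kout_max": "default",
    "Kdr": "default",
    "n": "default",
    "P": "default",
    "kap_X": "literature",  # 0.08 1/min when crosstalk is enabled
    "k_ann": "fitted",
    "K_tf": "fitted",
}

#: rate-like fields subject to log-normal perturbation
_RATE_FIELDS = (
    "kap_max", "Kda", "kt", "kp", "ktc", "kpc", "delta",
    "beta_HK", "beta_RR", "beta_SR", "beta_PH", "kout_max", "Kdr",
)

#: crosstalk phosphorylation rate of kinase X when enabled (1/min)
CROSSTALK_KAP_X = 0.08


def nominal_params(*, crosstalk: bool = False, P: float = 0.0, **overrides) -> RateParams:
    """Reference parameter set (see module docstring for unit choices).

    Parameters
    ----------
    crosstalk : bool
        If True, switch the crosstalk kinase on at its reference rate
        kap_X = 0.08 1/min; the default leaves crosstalk off.
    P : float
        Feedback strength of the closed-loop architectures.
    **overrides
        Field-by-field overrides applied on top.
    """
    p = RateParams(P=P, kap_X=CROSSTALK_KAP_X if crosstalk else 0.0)
    return p.replace(**overrides) if overrides else p


def perturb_params(base: RateParams, log_scale_sd: float, seed: int) -> RateParams:
    """Multiply every rate-like field by an independent log-normal factor.

    The factors have median 1 (log-mean 0), so the perturbation is
    median-preserving; ``log_scale_sd`` is the standard deviation of the
    log-factor.  Structural fields (n, P, kap_X, k_ann, K_tf) are left
    untouched.  Same seed => identical output.
    """
    if not (log_scale_sd > 0):
        raise ValueError(f"log_scale_sd must be > 0, got {log_scale_sd!r}")
    rng = np.random.default_rng(seed)
    factors = rng.lognormal(mean=0.0, sigma=log_scale_sd, size=len(_RATE_FIELDS))
    changes = {f: getattr(base, f) * fac for f, fac in zip(_RATE_FIELDS, factors)}
    return base.replace(**changes)


@dataclass(frozen=True)
class Scenario:
    """A named, fully specified study condition."""

    name: str
    architecture: str
    params: RateParams
    inducer_grid: tuple[float, ...]
    P_grid: tuple[float, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; known: {ARCHITECTURES}"
            )
        for gname, grid in (("inducer_grid", self.inducer_grid), ("P_grid", self.P_grid)):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0:
                raise ValueError(f"{gname} must be non-empty")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{gname} must be strictly increasing")


def _log_inducer_grid(lo_decade: float, hi_decade: float, per_decade: int = 25):
    npts = int(round((hi_decade - lo_decade) * per_decade)) + 1
    return tuple(np.logspace(lo_decade, hi_decade, npts))


#: the reference feedback-strength and inducer grids of the robustness study
SENSITIVITY_P_GRID = (0.1, 0.4, 0.7, 1.0)
SENSITIVITY_I_GRID = (0.5, 1.0, 2.0, 5.0, 10.0)
COMPARISON_I_GRID = (0.1, 1.0, 2.0, 5.0, 10.0)


def _scenarios() -> dict[str, Scenario]:
    nom = nominal_params()
    return {
        "wild_type": Scenario(
            "wild_type", "wild_type", nom,
            _log_inducer_grid(-2, 1.5), (0.0,), seed=0),
        "dose_response": Scenario(
            "dose_response", "closed_loop_phos_seq", nom,
            _log_inducer_grid(-2, 1.5), SENSITIVITY_P_GRID, seed=0),
        "sensitivity": Scenario(
            "sensitivity", "closed_loop_phos_seq", nom,
            SENSITIVITY_I_GRID, SENSITIVITY_P_GRID, seed=0),
        "noise": Scenario(
            "noise", "closed_loop_phos_seq", nom,
            tuple(np.logspace(-1.0, 1.0, 9)), SENSITIVITY_P_GRID, seed=0),
        "crosstalk": Scenario(
            "crosstalk", "closed_loop_phos_seq",
            nominal_params(crosstalk=True),
            (0.0,) + tuple(np.logspace(-1.5, 1.0, 11)),
            SENSITIVITY_P_GRID, seed=0),
    }


def list_scenarios() -> tuple[str, ...]:
    return tuple(_scenarios())


def scenario(name: str) -> Scenario:
    """Return a named scenario; raises listing known names otherwise."""
    table = _scenarios()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; known scenarios: {sorted(table)}"
        ) from None
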
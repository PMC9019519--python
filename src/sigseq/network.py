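"""Chemical reaction networks for every feedback architecture.

A :class:`ReactionNetwork` is the single source of truth shared by the
deterministic ODE integrator, the Gillespie simulator and the linear
noise approximation.  Each reaction carries an integer-stoichiometry
column and a propensity descriptor that is either mass-action (constant,
unary or bimolecular) or one of two named nonlinear forms: the Hill
activation of the output promoter and the hyperbolic repression used by
the transcriptional comparison feedback.

Architectures
-------------
``wild_type``
    The bare two-component system: histidine kinase HK autophosphorylates
    at an inducer-dependent Michaelis–Menten rate, passes the phosphoryl
    group to the response regulator RR, and dephosphorylates RRp; RRp
    drives Output production through a Hill promoter.
``open_loop_phos_seq`` / ``closed_loop_phos_seq``
    A second response regulator SR competes for the phosphorylated
    kinase (phosphorylation sequestration).  Open loop: constitutive SR
    production at beta_SR.  Closed loop: SR produced from the output
    promoter at rate P*kout(RRp) — the dichotomous feedback.
``open_loop_dephos`` / ``closed_loop_dephos``
    An added phosphatase PH dephosphorylates RRp (dephosphorylation
    enhancement); same open/closed distinction with beta_PH vs
    P*kout(RRp).
``molecular_seq_feedback``
    Comparison motif: an annihilator M produced at P*kout(RRp)
    irreversibly binds HK and HKp (or only HKp with
    ``mol_seq_phos_only=True``).
``transcriptional_feedback``
    Comparison motif: a repressor TF produced at P*kout(RRp) divides HK
    production by (1 + [TF]/K_tf).

Setting ``params.kap_X > 0`` adds a crosstalk kinase X (held at constant
total ``X_tot``) that phosphorylates/dephosphorylates RR — and SR where
present — at the same transfer rates as HK.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ARCHITECTURES, RateParams

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "autophosphorylation_rate",
    "output_initiation_rate",
    "hill",
    "hill_deriv",
    "build_network",
    "ode_rhs",
]

# propensity kind codes (shared with the numba SSA kernel)
CONSTANT, LINEAR, BILINEAR, HILL, REPRESSED = 0, 1, 2, 3, 4

#: negative state entries above this magnitude are rejected; smaller
#: undershoot (stiff-solver noise) is clamped to 0 before rate evaluation
NEGATIVE_STATE_TOL = 1e-6

#: default total crosstalk kinase (nM) when kap_X > 0; configurable per
#: network because only X's phosphorylation rate is externally fixed
DEFAULT_X_TOT = 10.0


def hill(x, K, n):
    """Activating Hill function x^n / (K^n + x^n), in the (x/K)^n form."""
    u = (np.asarray(x, dtype=float) / K) ** n
    return u / (1.0 + u)


def hill_deriv(x, K, n):
    """d/dx of :func:`hill`; finite at 0 for n >= 1."""
    x = np.asarray(x, dtype=float)
    u = (x / K) ** n
    return (n / K) * (x / K) ** (n - 1.0) / (1.0 + u) ** 2


def autophosphorylation_rate(I: float, params: RateParams) -> float:
    """Inducer-dependent HK autophosphorylation rate kap(I) (1/min).

    Michaelis–Menten in the inducer: kap_max * I / (I + Kda); monotone
    nondecreasing in I and bounded by kap_max.
    """
    if I < 0:
        raise ValueError(f"inducer concentration must be >= 0, got {I!r}")
    if I == 0:
        return 0.0
    return params.kap_max * I / (I + params.Kda)


def output_initiation_rate(rrp: float, params: RateParams) -> float:
    """Output promoter initiation rate kout([RRp]) (nM/min).

    Hill in RRp: kout_max * (rrp/Kdr)^n / ((rrp/Kdr)^n + 1); half-max at
    rrp = Kdr independently of n, bounded by kout_max.
    """
    if rrp < 0:
        raise ValueError(f"[RRp] must be >= 0, got {rrp!r}")
    return params.kout_max * float(hill(rrp, params.Kdr, params.n))


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: net stoichiometry plus a propensity descriptor."""

    name: str
    stoich: dict  # species -> net integer change
    kind: int
    rate: float  # rate constant / maximal rate
    species: tuple = ()  # species entering the propensity
    K: float = 0.0
    n: float = 1.0

    def rate_law(self) -> str:
        s = self.species
        if self.kind == CONSTANT:
            return f"{self.rate:g}"
        if self.kind == LINEAR:
            return f"{self.rate:g}*[{s[0]}]"
        if self.kind == BILINEAR:
            return f"{self.rate:g}*[{s[0]}]*[{s[1]}]"
        if self.kind == HILL:
            return (f"{self.rate:g}*([{s[0]}]/{self.K:g})^{self.n:g}"
                    f"/(1+([{s[0]}]/{self.K:g})^{self.n:g})")
        if self.kind == REPRESSED:
            return f"{self.rate:g}/(1+[{s[0]}]/{self.K:g})"
        raise ValueError(self.kind)


class ReactionNetwork:
    """Species, integer stoichiometry matrix and propensity descriptors."""

    def __init__(self, architecture: str, species, reactions, params: RateParams,
                 inducer: float, X_tot: float = 0.0):
        self.architecture = architecture
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.params = params
        self.inducer = float(inducer)
        self.X_tot = float(X_tot)
        ns, nr = len(self.species), len(self.reactions)
        idx = {s: i for i, s in enumerate(self.species)}
        self.stoich = np.zeros((ns, nr), dtype=np.int64)
        self._kind = np.zeros(nr, dtype=np.int64)
        self._rate = np.zeros(nr)
        self._i1 = np.zeros(nr, dtype=np.int64)
        self._i2 = np.zeros(nr, dtype=np.int64)
        self._K = np.ones(nr)
        self._n = np.ones(nr)
        for r, rx in enumerate(self.reactions):
            for sp, change in rx.stoich.items():
                self.stoich[idx[sp], r] = change
            self._kind[r] = rx.kind
            self._rate[r] = rx.rate
            if rx.species:
                self._i1[r] = idx[rx.species[0]]
                if len(rx.species) > 1:
                    self._i2[r] = idx[rx.species[1]]
            self._K[r] = rx.K if rx.K else 1.0
            self._n[r] = rx.n

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def default_x0(self) -> np.ndarray:
        """All-zero initial state, except the conserved crosstalk kinase."""
        x0 = np.zeros(self.n_species)
        if "X" in self.species:
            x0[self.index("X")] = self.X_tot
        return x0

    # ------------------------------------------------------------------
    def _clean_state(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(
                f"state dimension {x.shape} does not match species count "
                f"{self.n_species}")
        if np.any(x < -NEGATIVE_STATE_TOL):
            raise ValueError(f"negative state components: {x}")
        return np.maximum(x, 0.0)

    def propensities(self, x) -> np.ndarray:
        """Per-reaction rates at state ``x`` (>= 0 on the orthant)."""
        x = self._clean_state(x)
        a = np.empty(self.n_reactions)
        for r in range(self.n_reactions):
            k = self._kind[r]
            if k == CONSTANT:
                a[r] = self._rate[r]
            elif k == LINEAR:
                a[r] = self._rate[r] * x[self._i1[r]]
            elif k == BILINEAR:
                a[r] = self._rate[r] * x[self._i1[r]] * x[self._i2[r]]
            elif k == HILL:
                a[r] = self._rate[r] * hill(x[self._i1[r]], self._K[r], self._n[r])
            else:  # REPRESSED
                a[r] = self._rate[r] / (1.0 + x[self._i1[r]] / self._K[r])
        return a

    def propensity_jacobian(self, x) -> np.ndarray:
        """d propensities / d state, analytic, shape (n_reactions, n_species)."""
        x = self._clean_state(x)
        dA = np.zeros((self.n_reactions, self.n_species))
        for r in range(self.n_reactions):
            k = self._kind[r]
            if k == LINEAR:
                dA[r, self._i1[r]] = self._rate[r]
            elif k == BILINEAR:
                dA[r, self._i1[r]] += self._rate[r] * x[self._i2[r]]
                dA[r, self._i2[r]] += self._rate[r] * x[self._i1[r]]
            elif k == HILL:
                dA[r, self._i1[r]] = self._rate[r] * hill_deriv(
                    x[self._i1[r]], self._K[r], self._n[r])
            elif k == REPRESSED:
                K = self._K[r]
                dA[r, self._i1[r]] = -self._rate[r] / K / (1.0 + x[self._i1[r]] / K) ** 2
        return dA

    def rhs(self, x) -> np.ndarray:
        """Mass-action ODE right-hand side stoich . propensities (nM/min).

        Accumulated reaction-by-reaction in declaration order, so
        architectures that extend a base network with zero-rate or
        zero-stoichiometry reactions reproduce the base vector field
        bit-for-bit on the shared species.
        """
        a = self.propensities(x)
        f = np.zeros(self.n_species)
        for r in range(self.n_reactions):
            f += self.stoich[:, r] * a[r]
        return f

    def jacobian(self, x) -> np.ndarray:
        """Analytic Jacobian of :meth:`rhs`."""
        return self.stoich @ self.propensity_jacobian(x)

    # ------------------------------------------------------------------
    def ssa_tables(self):
        """Flat descriptor arrays consumed by the numba SSA kernel."""
        return (self.stoich.T.astype(np.int64).copy(), self._kind.copy(),
                self._rate.copy(), self._i1.copy(), self._i2.copy(),
                self._K.copy(), self._n.copy())

    def to_text(self) -> str:
        """Human-readable structured-text export (species + rate laws)."""
        lines = [f"# architecture: {self.architecture}",
                 f"# inducer: {self.inducer:g} mM",
                 "species: " + " ".join(self.species), "reactions:"]
        for rx in self.reactions:
            lhs = " + ".join(f"{-c}*{s}" if c < -1 else s
                             for s, c in rx.stoich.items() if c < 0) or "0"
            rhs_ = " + ".join(f"{c}*{s}" if c > 1 else s
                              for s, c in rx.stoich.items() if c > 0) or "0"
            lines.append(f"  {rx.name}: {lhs} -> {rhs_} ; rate = {rx.rate_law()}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"ReactionNetwork({self.architecture!r}, I={self.inducer:g}, "
                f"{self.n_species} species, {self.n_reactions} reactions)")


def ode_rhs(network: ReactionNetwork, state) -> np.ndarray:
    """Functional alias for :meth:`ReactionNetwork.rhs`."""
    return network.rhs(state)


# ----------------------------------------------------------------------
def build_network(architecture: str, params: RateParams, I: float, *,
                  leak: float = 0.0, X_tot: float | None = None,
                  mol_seq_phos_only: bool = False) -> ReactionNetwork:
    """Assemble the reaction network for one architecture at inducer I.

    Parameters
    ----------
    architecture : str
        One of :data:`sigseq.params.ARCHITECTURES`.
    params : RateParams
    I : float
        Inducer concentration (mM); enters only through kap(I).
    leak : float
        Constitutive (RRp- and I-independent) output production (nM/min).
    X_tot : float, optional
        Total crosstalk kinase (nM) when ``params.kap_X > 0``; defaults
        to the HK total.
    mol_seq_phos_only : bool
        Molecular-sequestration variant annihilating only HKp.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {architecture!r}; known: {ARCHITECTURES}")
    p = params
    kap = autophosphorylation_rate(I, p)
    has_SR = architecture in ("open_loop_phos_seq", "closed_loop_phos_seq")
    has_PH = architecture in ("open_loop_dephos", "closed_loop_dephos")
    closed = architecture.startswith("closed_loop")
    crosstalk = p.kap_X > 0

    species = ["HK", "HKp", "RR", "RRp"]
    if has_SR:
        species += ["SR", "SRp"]
    if has_PH:
        species += ["PH"]
    species += ["Output"]
    if architecture == "molecular_seq_feedback":
        species += ["M"]
    if architecture == "transcriptional_feedback":
        species += ["TF"]
    if crosstalk:
        species += ["X", "Xp"]

    rx: list[Reaction] = []
    add = rx.append

    # two-component core
    add(Reaction("autophos", {"HK": -1, "HKp": +1}, LINEAR, kap, ("HK",)))
    add(Reaction("transfer", {"HKp": -1, "RR": -1, "HK": +1, "RRp": +1},
                 BILINEAR, p.kt, ("HKp", "RR")))
    add(Reaction("dephos_by_HK", {"RRp": -1, "RR": +1},
                 BILINEAR, p.kp, ("HK", "RRp")))
    if architecture == "transcriptional_feedback":
        add(Reaction("prod_HK", {"HK": +1}, REPRESSED, p.beta_HK, ("TF",),
                     K=p.K_tf))
    else:
        add(Reaction("prod_HK", {"HK": +1}, CONSTANT, p.beta_HK))
    add(Reaction("prod_RR", {"RR": +1}, CONSTANT, p.beta_RR))
    add(Reaction("prod_Output", {"Output": +1}, HILL, p.kout_max, ("RRp",),
                 K=p.Kdr, n=p.n))
    if leak > 0:
        add(Reaction("leak_Output", {"Output": +1}, CONSTANT, leak))
    diluted = ["HK", "HKp", "RR", "RRp", "Output"]

    if has_SR:
        add(Reaction("transfer_SR", {"HKp": -1, "SR": -1, "HK": +1, "SRp": +1},
                     BILINEAR, p.ktc, ("HKp", "SR")))
        add(Reaction("dephos_SR", {"SRp": -1, "SR": +1},
                     BILINEAR, p.kpc, ("HK", "SRp")))
        if closed:
            add(Reaction("prod_SR", {"SR": +1}, HILL, p.P * p.kout_max,
                         ("RRp",), K=p.Kdr, n=p.n))
        else:
            add(Reaction("prod_SR", {"SR": +1}, CONSTANT, p.beta_SR))
        diluted += ["SR", "SRp"]

    if has_PH:
        add(Reaction("dephos_by_PH", {"RRp": -1, "RR": +1},
                     BILINEAR, p.kpc, ("PH", "RRp")))
        if closed:
            add(Reaction("prod_PH", {"PH": +1}, HILL, p.P * p.kout_max,
                         ("RRp",), K=p.Kdr, n=p.n))
        else:
            add(Reaction("prod_PH", {"PH": +1}, CONSTANT, p.beta_PH))
        diluted += ["PH"]

    if architecture == "molecular_seq_feedback":
        add(Reaction("prod_M", {"M": +1}, HILL, p.P * p.kout_max, ("RRp",),
                     K=p.Kdr, n=p.n))
        if not mol_seq_phos_only:
            add(Reaction("ann_HK", {"M": -1, "HK": -1},
                         BILINEAR, p.k_ann, ("M", "HK")))
        add(Reaction("ann_HKp", {"M": -1, "HKp": -1},
                     BILINEAR, p.k_ann, ("M", "HKp")))
        diluted += ["M"]

    if architecture == "transcriptional_feedback":
        add(Reaction("prod_TF", {"TF": +1}, HILL, p.P * p.kout_max, ("RRp",),
                     K=p.Kdr, n=p.n))
        diluted += ["TF"]

    if crosstalk:
        add(Reaction("phos_X", {"X": -1, "Xp": +1}, LINEAR, p.kap_X, ("X",)))
        add(Reaction("transfer_X", {"Xp": -1, "RR": -1, "X": +1, "RRp": +1},
                     BILINEAR, p.kt, ("Xp", "RR")))
        add(Reaction("dephos_by_X", {"RRp": -1, "RR": +1},
                     BILINEAR, p.kp, ("X", "RRp")))
        if has_SR:
            add(Reaction("transfer_X_SR",
                         {"Xp": -1, "SR": -1, "X": +1, "SRp": +1},
                         BILINEAR, p.ktc, ("Xp", "SR")))
            add(Reaction("dephos_X_SR", {"SRp": -1, "SR": +1},
                         BILINEAR, p.kpc, ("X", "SRp")))

    for sp in diluted:
        add(Reaction(f"dil_{sp}", {sp: -1}, LINEAR, p.delta, (sp,)))

    xt = (DEFAULT_X_TOT if X_tot is None else float(X_tot)) if crosstalk else 0.0
    return ReactionNetwork(architecture, species, rx, p, I, X_tot=xt)
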
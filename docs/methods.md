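# Methods

## Model

The core process is a bacterial two-component signalling system (TCSS).
A histidine kinase HK autophosphorylates at an inducer-dependent
Michaelis–Menten rate kap(I) = kap_max·I/(I + Kda), transfers the
phosphoryl group to a response regulator RR at rate kt·[HKp][RR], and
also acts as the phosphatase of RRp at rate kp·[HK][RRp].  RRp drives
expression of an output protein through an activating Hill promoter
kout([RRp]) = kout_max·(RRp/Kdr)^n / (1 + (RRp/Kdr)^n).  All produced
proteins dilute at δ, giving asymptotic totals HK_tot = β_HK/δ,
RR_tot = β_RR/δ etc.

Negative feedback by **signal sequestration** is added in two dual
ways: a second response regulator SR that competes for HKp
(phosphorylation sequestration, rates ktc/kpc) or a phosphatase PH that
drains RRp (dephosphorylation enhancement, rate kpc).  The loop closes
— *dichotomous feedback* — by producing the sequestration protein from
the output promoter at rate P·kout([RRp]), with feedback strength
P ∈ [0, 1].  Two comparison motifs are implemented: an annihilator M
produced at P·kout([RRp]) that irreversibly binds HK and HKp (molecular
sequestration; a flag restricts binding to HKp), and a transcriptional
repressor TF that divides HK production by (1 + [TF]/K_tf).

Every architecture is one `ReactionNetwork` (integer stoichiometry +
propensity descriptors), the single source of truth for the ODE model,
the Gillespie simulator and the linear noise approximation.  The
enzymatic dephosphorylation steps are modelled as written — bimolecular
mass action with the catalyst unchanged — not as Michaelis–Menten
enzymes.

Units: time in minutes, inducer in mM, proteins in nM.  With the
stochastic module's system size Ω (copies = Ω·nM) the same numbers
serve as copy numbers.

## Reference parameter set

No measured rate set exists for this design; `nominal_params()` is the
package's reference condition, chosen once on physiological grounds
(each value flagged in `PROVENANCE`; only the crosstalk phosphorylation
rate kap_X = 0.08 min⁻¹ is a literature-fixed quantity):

| parameter | value | rationale |
|---|---|---|
| δ | 0.01 min⁻¹ | ~70 min doubling time |
| β_HK, β_RR | 0.25, 5 nM/min | HK_tot = 25 nM, RR_tot = 500 nM: response regulator in large excess over its kinase, as in EnvZ/OmpR |
| kap_max | 0.046 min⁻¹ | ~20–40 % of the kinase phosphorylated at saturation |
| Kda | 1 mM | dose–response centred near 1 mM inducer |
| kt | 2.2·10⁻⁴ nM⁻¹min⁻¹ | phosphotransfer flux ≫ dilution, ≈ kp·HK_tot |
| kp | 2·10⁻³ nM⁻¹min⁻¹ | kp·HK_tot = 5δ: the kinase is the dominant but not overwhelming RRp phosphatase |
| ktc, kpc | 1.2·10⁻², 2·10⁻³ | sequestration flux comparable to kt·RR_tot at full feedback |
| kout_max | 0.5 nM/min | output plateau ~40 nM |
| Kdr, n | 6 nM, 2 | promoter saturating at full induction |
| k_ann, K_tf | 1.792·10⁻², 3.339 | *fitted* by the dose-response matching procedure (below) |

The regime was selected so that the architecture's qualitative claims
are all simultaneously expressible: (i) kt·RR_tot ≈ kp·HK_tot + δ makes
the loop's cross-channel gains order one, so the sensitivity-function
peak is meaningful rather than dominated by unit mismatch between the
[HK] and [RRp] channels; (ii) kp·HK_tot ≈ 5δ gives the comparison
feedbacks — which act only by lowering the kinase total — real
steady-state authority, letting their dose–response curves match the
dichotomous loop's; (iii) the promoter saturates at full induction, so
under crosstalk the feedback suppresses the (promoter-sensitive) basal
response more than the (saturated) maximal response.  A consequence of
(ii) is documented under *Limitations*.

`perturb_params` multiplies every rate-like field by independent
log-normal factors (median-preserving), providing the randomized
parameter scans used by the property tests.

## Deterministic analysis

LSODA with rtol 10⁻⁸ / atol 10⁻¹⁰ and the analytic Jacobian integrates
all ODEs (phosphotransfer exceeds dilution by orders of magnitude, so
the systems are stiff).  Steady states come from a 10⁵-min settling
integration followed by Newton polishing to residual < 10⁻¹⁰; with a
crosstalk kinase the conserved X + Xp total replaces the redundant
equation during polishing.  Stiff-solver micro-undershoot below 0 is
clamped before rate evaluation (tolerance 10⁻¹²; larger negative states
are rejected).

Overshoot of a settled step response is (max − final)/final, floored at
0; a trajectory qualifies as settled when the final 10 % of the time
window varies < 0.1 % of the final value.  The 1 % threshold separating
"no overshoot" from "overshoot" is a documented convention.

**Matching procedure.**  The comparison feedbacks carry one free
constant each (k_ann, K_tf) with no counterpart in the dichotomous
loop.  Following the principle that comparisons should be made at
matched steady-state behaviour, the constant is fitted by least squares
so the comparison architecture's dose–response at P = 1 matches the
phosphorylation-sequestration closed loop's on a six-point inducer
grid.  The fitted values are stored as defaults (provenance `fitted`)
and re-fitted from scratch by the acceptance script.

**Dose–response shape.**  The open-loop motif (constitutive SR) is, in
the closed-forms' validity regime, a nearly uniform rescaling of the
wild type, so "graded vs sigmoidal" is *not* captured by the maximum
normalized slope (a formalization tried first); the property actually
exhibited is robustness at high induction, tested as: at matched
plateau the closed loop reaches 90 % of its plateau at a lower inducer
concentration and rises strictly less over the top decade.

## Closed-form steady states and validity

For the open-loop motifs the phosphorylated response regulator admits
closed forms

    [RRp]* ≈ (kap/kp) · kt·RR_tot/(kt·RR_tot + ktc·SR_tot + δ)
                       · kp·HK_tot/(kp·HK_tot + δ)          (phos. seq.)
    [RRp]* ≈ (kap/kp) · kt·RR_tot/(kt·RR_tot + δ)
                       · kp·HK_tot/(δ + kpc·PH_tot + kp·HK_tot)  (dephos.)

valid when transfer is fast relative to autophosphorylation and the
phosphorylated fractions are small.  `check_assumptions` reports each
condition as a ratio against a configurable margin (default 10×):
the stated timescale inequality, [RR_sum]/[RRp] (and [SR_sum]/[SRp]),
and additionally an *HK-substitution* ratio — the reciprocal of the
error incurred by replacing [HK] with HK_tot, about
([HKp]/[HK_sum])·(δ + kpc·PH_tot)/(δ + kpc·PH_tot + kp·HK_tot) —
because when kt and kp differ widely the printed timescale ratio alone
does not bound that substitution.  The validity ladder used by the
tests runs on symmetric-rate families (kt = kp = kpc) with the
sequestration term at ~20–30 % of the transfer flux, solving for
kap_max so the minimum ratio sits at 10/30/100; measured errors are
0.4–3 % at the 10× rung and fall monotonically.

## Reduced model and structural properties

Eliminating the phosphorylated forms through the totals yields a
three-state model in ([HK], [RR], [SR]) whose off-diagonal Jacobian
entries are nonnegative on the box
S = [0, HK_tot]×[0, RR_tot]×[0, SR_tot]: the system is cooperative
(monotone), hence no stable limit cycles, order-preserving flow, and a
corner-trajectory test for global attractivity (both corners of S
converging to one point certifies it).  `monotone_structure_check`
verifies the sign pattern numerically on 10³ sampled states rather than
symbolically.  For the bare TCSS (β_SR = 0) local asymptotic stability
of ([HK]*, [RR]*) is equivalent (2×2 Routh–Hurwitz) to

    (δ + kap + kt[RR]*)(δ + kt[HKp]* + kp[HK]*) > kt[HKp]*(kt[RR]* + kp[RRp]*),

with the sufficient form 1 > [HKp]*/HK_tot + [RRp]*/RR_tot; the test
suite cross-checks it against the Jacobian spectrum on 200 random
parameter sets.

A separate two-protein resource-competition model
([Y]* = K_Y β_Y/(1 + J_Y β_Y + J_S β_S)) captures the same
sequestration algebra for shared transcription/translation machinery.

## Stochastic analysis

The direct Gillespie method (numba kernel, counter-derived per-run
seeds from `SeedSequence`) samples the chemical master equation
exactly; Hill/Michaelis–Menten propensities are used directly as
mesoscopic rates, matching the model granularity.  The linear noise
approximation integrates the macroscopic mean together with
dΣ/dt = JΣ + ΣJᵀ + D (D = S·diag(a)·Sᵀ), with symmetry enforcement and
a PSD check (tolerance 10⁻⁸) at save times.

Noise is summarized by the coefficient of variation of Output at
t = 1000 min from an empty cell (≥ 10 dilution time constants, so the
statistics are effectively stationary).  The reference system size is
Ω = 4 (RR_tot ≈ 2000 copies, typical response-regulator abundance):
the LNA is a system-size expansion and Ω places the study where that
expansion is accurate while keeping 10⁴-run ensembles affordable; cv
scales as 1/√Ω, so Ω is documented prominently.  The LNA/SSA
cross-check uses six (architecture, P, I) probes spanning the
cv-vs-mean range and requires agreement within 3 standard errors at
≥ 5 of them at 10⁴ runs per probe.

At this copy-number scale the output's intrinsic birth–death noise
contributes substantially to its cv, so at *fixed inducer* stronger
feedback (lower mean) raises cv ∝ 1/√mean.  The noise-reduction claim
is therefore evaluated as the cv-vs-mean comparison: at matched mean
output — restricted to each curve's tunable range, means between 20 %
of the wild-type plateau and 85 % of the curve's own plateau, outside
of which the architectures degenerate into each other — the closed
loop's cv lies below the wild type's, and further below at higher P.

## Frequency-domain analysis

Each closed loop is split into a process and a controller, linearized
at the closed-loop steady state (where the response-regulator total
equals RR_tot exactly, so the reduction is exact at the operating
point; the test suite verifies that the reassembled blocks reproduce
the full network Jacobian's slow spectrum to machine precision).  With
G_yu, G_yz the process transfer matrices and K the controller,
S = (I − G_yu K)⁻¹ maps output disturbances to outputs and
T = S·G_yz maps the inducer channel; no extra sign is injected — the
loop's negative action is carried by the linearized coefficients.  The
magnitude is the spectral norm; the frequency grid is log-spaced
10⁻⁶–10² rad/min at 200 points/decade with a bounded scalar refinement
around the grid argmax (the peak is grid-converged to < 0.1 % under
2× refinement).  Process/controller splits per architecture:
phosphorylation sequestration — process ([HK],[RRp]), controller
([SR],[SR_sum]), y = ([HK],[RRp]); phosphatase — same process,
one-state controller, y = [RRp] (K(jω) = P·h′([RRp]*)/(jω+δ));
molecular sequestration — process ([HK],[HKp],[RRp]) (the annihilator
changes the kinase total, so no total-based reduction), controller
[M], y = all three process states the annihilator senses;
transcriptional — same three-state process, controller [TF],
y = [RRp].  The architectures' S matrices therefore differ in
dimension; their peak magnitudes are comparable as robustness indices,
not entrywise.

## Crosstalk

A second kinase X at constant total X_tot (default 10 nM; only its
phosphorylation rate, 0.08 min⁻¹, is externally specified) is
phosphorylated constitutively and exchanges phosphoryl groups with RR
— and SR where present — at the same rates as HK.  Reports give the
basal (I = 0) output, the maximal output (top of the inducer grid),
and both normalizations.  A constitutive output leak adds a floor
leak/δ that equalizes the basal response across feedback strengths
once it dominates the regulated initiation rate.

## What the generator does and does not emulate

The synthetic scenarios reproduce the *structure* of the study — the
architectures, grids ([0.5, 1, 2, 5, 10] mM × P ∈ [0.1, 0.4, 0.7, 1]),
probe time, and run counts — under the reference parameter regime
documented above, not any organism's measured rates.  Passing tests
demonstrate the architectural claims (plateau tunability, noise
reduction at matched mean, overshoot-free step response, crosstalk
suppression, monotone/stable structure) in a physiologically sensible
regime; absolute numbers (plateaus in nM, cv values, sensitivity
peaks) are properties of this regime and would shift with measured
rates.  Extrinsic noise, spatial effects, multi-step phosphorelays and
resource-coupled expression of the TCSS proteins themselves are not
modelled.

## Known limitations

* The sensitivity peaks of the dichotomous loop (≈1.5 at this regime)
  and the comparison feedbacks are regime-dependent; the 2×2 spectral
  norm mixes the [HK] and [RRp] channels, and regimes with a small
  phosphorylated-kinase fraction inflate the cross-channel gain
  sharply.
* Because the comparison feedbacks act through the kinase total, and
  the kinase is a major RRp phosphatase in any regime where those
  feedbacks have dose-response authority, they substantially *raise*
  the crosstalk-driven basal response here (+ ~70 %) instead of
  leaving it unchanged; within this model the two behaviours could not
  be reconciled in a single parameter set.
* SSA ensembles at 10⁴ runs take a few minutes per six-point
  cross-check at the reference Ω; the run counts and grid sizes in the
  tests are chosen at desk scale and are flags/arguments, not limits
  of the implementation.
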
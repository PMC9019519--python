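# sigseq

Analysis toolkit for **dichotomous feedback** — negative feedback built
from signal sequestration — in bacterial two-component signalling
systems (TCSS).

## The problem

A TCSS consists of a histidine kinase HK that autophosphorylates in
response to an inducer and a response regulator RR that receives the
phosphoryl group; phosphorylated RR (RRp) activates an output promoter.
Such systems are switch-like: intermediate outputs are hard to reach,
and crosstalk from other kinases raises the basal response.  Instead of
annihilating molecules (molecular sequestration), one can *sequester
the signal*: divert the phosphotransfer flux through a second response
regulator SR (phosphorylation sequestration) or drain RRp with a
phosphatase PH (dephosphorylation enhancement).  Closing the loop by
expressing SR or PH from the output promoter at rate

    β_SR ≜ P · kout([RRp]),        kout(x) = kout_max (x/Kdr)^n / (1 + (x/Kdr)^n),

with feedback strength `P`, yields a controller that tunes the output
plateau, attenuates intrinsic noise, is robust in the
sensitivity-function sense, and suppresses crosstalk.  `sigseq`
implements the full computational analysis for this design and its
comparison motifs (kinase-annihilating molecular sequestration,
transcriptional repression of the kinase):

* **reaction networks** for every architecture from one description
  (ODE, Gillespie SSA and linear noise approximation share it);
* **deterministic analysis** — stiff integration, steady states,
  dose–response curves, step-response overshoot;
* **closed-form theory** — steady-state approximations for both motifs
  with quantified validity ratios, the algebraic stability condition,
  monotone-systems structure checks, resource-competition steady state;
* **stochastic analysis** — exact SSA (numba) and LNA coefficient-of-
  variation curves, cross-validated against each other;
* **frequency-domain robustness** — process/controller linearization,
  sensitivity function S(jω) = (I − G_yu K)⁻¹ and its grid maxima;
* **crosstalk** — basal/maximal response under a constitutively
  phosphorylated second kinase.

## Worked example

```python
import numpy as np
from sigseq import (nominal_params, Scenario, dose_response,
                    sensitivity_grid_max, step_response, overshoot)

p = nominal_params()                      # reference parameter set (nM, min, mM)
grid = tuple(np.logspace(-2, 1.5, 25))

wt = dose_response(Scenario("demo", "wild_type", p, grid, (0.0,)))[0]
cl = dose_response(Scenario("demo", "closed_loop_phos_seq", p, grid,
                            (0.1, 1.0)))
print(f"wild-type plateau : {wt.output[-1]:.1f} nM")
for c in cl:
    print(f"closed loop P={c.P:<4}: {c.output[-1]:.1f} nM")

hinf, arg = sensitivity_grid_max("closed_loop_phos_seq", p,
                                 (0.5, 1, 2, 5, 10), (0.1, 0.4, 0.7, 1.0))
print(f"peak |S|          : {hinf:.4f} at I={arg['I']} mM, P={arg['P']}")

tr = step_response("closed_loop_phos_seq", p.replace(P=1.0), 10.0,
                   t_end=8000.0)
print(f"step overshoot    : {100 * overshoot(tr, 'Output'):.2f} %")
```

prints

```
wild-type plateau : 43.8 nM
closed loop P=0.1 : 42.0 nM
closed loop P=1.0 : 26.7 nM
peak |S|          : 1.5165 at I=10.0 mM, P=1.0
step overshoot    : 0.00 %
```

— the feedback strength tunes the plateau continuously below the
wild-type's, the sensitivity peak stays near the classical ≤ 1.2–1.5
design band, and the dichotomous loop settles without overshoot
(the comparison feedbacks overshoot by 15–50 % under the same step;
see `docs/methods.md` for the model, units and parameter rationale).

A CLI mirrors the library:

```bash
sigseq dose-response --scenario dose_response --out curves.csv
sigseq sensitivity  --scenario sensitivity --out sens.csv
sigseq noise        --scenario noise --method lna --out cv.csv
sigseq crosstalk    --P 0.1,0.4,0.7,1 --out crosstalk.csv
```

Each command writes a CSV table with explicit unit columns and a JSON
summary with a provenance block (version, config hash, seed).

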
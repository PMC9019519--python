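"""Crosstalk reduction by dichotomous feedback.

A second histidine kinase X, phosphorylated through an unspecified
mechanism at a constant rate kap_X (reference value 0.08 1/min), passes
phosphoryl groups to the response regulator at the same transfer rates
as HK, raising the output even at zero inducer.  Because the
sequestration protein is phosphorylated by X as well, closing the
dichotomous loop siphons the crosstalk flux and lowers the basal
response while the system keeps responding to the inducer.

X is held at a constant total (no production/dilution), configurable
per scan since only its phosphorylation rate is externally specified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import SteadyStateError, steady_state
from .network import build_network
from .params import RateParams

__all__ = ["CrosstalkReport", "crosstalk_scan", "basal_leak_variant"]


@dataclass
class CrosstalkReport:
    """Basal/maximal output and normalized dose-response under crosstalk."""

    architecture: str
    P: float
    inducer: np.ndarray  # mM, first entry 0 (basal)
    output: np.ndarray  # nM
    basal_output: float  # steady output at I = 0
    max_output: float  # steady output at the top of the grid

    def __post_init__(self):
        self.inducer = np.asarray(self.inducer, dtype=float)
        self.output = np.asarray(self.output, dtype=float)
        if np.any(self.output < 0):
            raise ValueError("outputs must be >= 0")

    @property
    def curve_max_normalized(self) -> np.ndarray:
        """Output divided by the saturating response (in [0, 1])."""
        return self.output / self.max_output if self.max_output > 0 \
            else np.zeros_like(self.output)

    @property
    def curve_basal_normalized(self) -> np.ndarray:
        """Output divided by the basal (I = 0) response."""
        if self.basal_output <= 0:
            return np.full_like(self.output, np.nan)
        return self.output / self.basal_output

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "architecture": self.architecture, "P": self.P,
            "I_mM": self.inducer, "output_nM": self.output,
            "output_over_max": self.curve_max_normalized,
            "output_over_basal": self.curve_basal_normalized,
        })


def _scan_one(architecture: str, params: RateParams, I_grid, **build_kw):
    I_grid = np.asarray(I_grid, dtype=float)
    if I_grid[0] != 0.0:
        I_grid = np.concatenate([[0.0], I_grid])
    out = np.empty(I_grid.size)
    guess = None
    for k, I in enumerate(I_grid):
        net = build_network(architecture, params, float(I), **build_kw)
        try:
            ss = steady_state(net, x0=guess)
        except SteadyStateError as e:
            raise SteadyStateError(
                f"crosstalk scan failed for {architecture} at I={I:g}, "
                f"P={params.P:g}: {e}") from e
        out[k] = ss[net.index("Output")]
        guess = ss
    return CrosstalkReport(architecture, params.P, I_grid, out,
                           basal_output=float(out[0]),
                           max_output=float(out[-1]))


def crosstalk_scan(params: RateParams, P_list, I_grid, *,
                   architecture: str = "closed_loop_phos_seq",
                   X_tot: float | None = None, leak: float = 0.0
                   ) -> list[CrosstalkReport]:
    """Basal and dose-response reports under crosstalk, per feedback strength.

    ``params.kap_X`` must be positive.  Returns the wild-type reference
    report followed by one report per P.
    """
    if not (params.kap_X > 0):
        raise ValueError("crosstalk requires kap_X > 0 "
                         "(use nominal_params(crosstalk=True))")
    kw = dict(X_tot=X_tot, leak=leak)
    reports = [_scan_one("wild_type", params.replace(P=0.0), I_grid, **kw)]
    for P in P_list:
        reports.append(_scan_one(architecture, params.replace(P=float(P)),
                                 I_grid, **kw))
    return reports


def basal_leak_variant(params: RateParams, leak: float, P_list, I_grid, *,
                       architecture: str = "closed_loop_phos_seq",
                       X_tot: float | None = None) -> list[CrosstalkReport]:
    """Crosstalk scan with constitutive output production ``leak`` (nM/min).

    With a promoter leak independent of RRp and I, the basal response
    acquires a floor leak/delta shared by all feedback strengths.
    """
    if leak < 0:
        raise ValueError("leak must be >= 0")
    return crosstalk_scan(params, P_list, I_grid, architecture=architecture,
                          X_tot=X_tot, leak=leak)
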
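"""Numba kernel for the direct-method Gillespie simulator.

The kernel consumes the flat reaction-descriptor arrays produced by
:meth:`sigseq.network.ReactionNetwork.ssa_tables` and samples the exact
trajectory of the chemical master equation, recording the state at the
requested save times (the trajectory is piecewise constant between
events).  Hill / repression propensities are used directly as
mesoscopic rates, matching the model granularity of the deterministic
module.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["ssa_run", "ssa_ensemble_states"]


@njit(cache=True)
def _propensities(x, kind, rate, i1, i2, K, n, a):
    for r in range(kind.size):
        k = kind[r]
        if k == 0:
            a[r] = rate[r]
        elif k == 1:
            a[r] = rate[r] * x[i1[r]]
        elif k == 2:
            a[r] = rate[r] * x[i1[r]] * x[i2[r]]
        elif k == 3:
            if x[i1[r]] <= 0.0:
                a[r] = 0.0
            else:
                u = (x[i1[r]] / K[r]) ** n[r]
                a[r] = rate[r] * u / (1.0 + u)
        else:
            a[r] = rate[r] / (1.0 + x[i1[r]] / K[r])
        if a[r] < 0.0:
            # negative propensity signals a corrupted state
            a[r] = np.nan
    return a


@njit(cache=True)
def ssa_run(x0, stoichT, kind, rate, i1, i2, K, n, t_save, seed):
    """One direct-method realization; states sampled at ``t_save``.

    Returns (out, n_events) where out has shape (len(t_save), n_species).
    """
    np.random.seed(seed)
    ns = x0.size
    nr = kind.size
    x = x0.copy()
    a = np.zeros(nr)
    out = np.zeros((t_save.size, ns))
    t = 0.0
    isave = 0
    n_events = 0
    t_end = t_save[t_save.size - 1]
    while isave < t_save.size:
        _propensities(x, kind, rate, i1, i2, K, n, a)
        a0 = 0.0
        for r in range(nr):
            if np.isnan(a[r]):
                raise ValueError("negative propensity encountered in SSA")
            a0 += a[r]
        if a0 <= 0.0:
            # absorbing state: fill the remaining save points
            while isave < t_save.size:
                for s in range(ns):
                    out[isave, s] = x[s]
                isave += 1
            break
        tau = -np.log(np.random.random()) / a0
        t_next = t + tau
        while isave < t_save.size and t_save[isave] < t_next:
            for s in range(ns):
                out[isave, s] = x[s]
            isave += 1
        if t_next > t_end:
            break
        # pick the firing reaction
        u = np.random.random() * a0
        acc = 0.0
        rfire = nr - 1
        for r in range(nr):
            acc += a[r]
            if u <= acc:
                rfire = r
                break
        for s in range(ns):
            x[s] += stoichT[rfire, s]
        t = t_next
        n_events += 1
    return out, n_events


@njit(cache=True)
def ssa_ensemble_states(x0, stoichT, kind, rate, i1, i2, K, n, t_probe,
                        seeds):
    """States at ``t_probe`` for one independent run per seed."""
    t_save = np.empty(1)
    t_save[0] = t_probe
    out = np.zeros((seeds.size, x0.size))
    for run in range(seeds.size):
        states, _ = ssa_run(x0, stoichT, kind, rate, i1, i2, K, n, t_save,
                            seeds[run])
        for s in range(x0.size):
            out[run, s] = states[0, s]
    return out
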
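"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the code under
test: fine-grid quadrature of the generating kinetic model, step-wise ODE
integration of the voiding bladder, explicit double-loop MIRD summation, and
exhaustive case analysis of the ICRP-60 remainder splitting rule.
"""
from __future__ import annotations

import numpy as np
from scipy.integrate import quad

from petdosim.constants import LAMBDA_P_PER_H


def quad_residence_time(f_peak: float, k_up: float, k_bio: float, t_max_h: float = 200.0) -> float:
    """Fine quadrature of the uptake–washout model times physical decay."""

    def integrand(t):
        return f_peak * (1 - np.exp(-k_up * t)) * np.exp(-(k_bio + LAMBDA_P_PER_H) * t)

    val, _ = quad(integrand, 0.0, t_max_h, limit=1000)
    return val


def ode_bladder_residence(f_u: float, lambda_b: float, interval_h: float, n_cycles: int | None = None, steps_per_cycle: int = 4000) -> float:
    """Residence time of the bladder content under periodic instantaneous
    voiding, by explicit fine-grid integration cycle by cycle.

    Within a cycle starting at t_k the non-decay-corrected content is
    integrated on a fine grid from its exact expression
    ``f_u exp(-lp t) (exp(-lb t_k) - exp(-lb t))``; voids reset it to zero.
    Cycles are accumulated until the physical decay makes the tail negligible.
    """
    lp = LAMBDA_P_PER_H
    if n_cycles is None:
        n_cycles = max(int(np.ceil(45.0 / (lp * interval_h))), 10)
    tau = 0.0
    for k in range(n_cycles):
        t0 = k * interval_h
        t = np.linspace(t0, t0 + interval_h, steps_per_cycle + 1)
        content = f_u * np.exp(-lp * t) * (np.exp(-lambda_b * t0) - np.exp(-lambda_b * t))
        tau += np.trapezoid(content, t)
    return float(tau)


def brute_force_doses(taus: dict[str, float], frame) -> dict[str, float]:
    """MIRD contraction by explicit double loop over targets and sources."""
    out = {}
    for target in frame.index:
        d = 0.0
        for source in frame.columns:
            d += taus.get(source, 0.0) * frame.loc[target, source]
        out[target] = d
    return out


def exhaustive_effective_dose(
    h_weighted: dict[str, float],
    weights: dict[str, float],
    remainder: dict[str, tuple[float, float]],  # organ -> (dose, mass)
) -> float:
    """ICRP-60 effective dose with the splitting rule evaluated by explicit
    case analysis: try both branches and pick the one whose precondition
    holds."""
    e = sum(weights[t] * h for t, h in h_weighted.items())
    w_rem = weights["remainder"]
    organs = sorted(remainder)
    doses = np.array([remainder[o][0] for o in organs])
    masses = np.array([remainder[o][1] for o in organs])
    h_max = max(h_weighted.values())

    fires = doses.max() > h_max
    if fires:
        i = int(np.argmax(doses))
        rest = [j for j in range(len(organs)) if j != i]
        mw_rest = float((doses[rest] * masses[rest]).sum() / masses[rest].sum())
        return e + 0.5 * w_rem * float(doses[i]) + 0.5 * w_rem * mw_rest
    return e + w_rem * float((doses * masses).sum() / masses.sum())
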
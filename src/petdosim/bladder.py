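"""Urinary bladder cumulated activity: VOI bookkeeping and the dynamic model.

Two estimators of the bladder-content residence time are implemented, as in
the study design:

1. :func:`bladder_residence_voi` — direct bookkeeping from the bladder VOI
   concentrations of the eight scans and the three timed urine-volume
   measurements, with the content reset to zero at each void.
2. :func:`bladder_residence_dynamic` — the dynamic bladder voiding model: a
   single biologic excretion half-life is estimated from the urine
   collections (assuming urine is the only excretion route), and the bladder
   content between periodic instantaneous voids is integrated in closed form
   to infinity.

The dynamic model is the one fed to the dosimetry, evaluated at modeled
1-h and 3.5-h voiding intervals.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .constants import LAMBDA_P_PER_H
from .tac import ResidenceTime

logger = logging.getLogger(__name__)

__all__ = [
    "UrineCollection",
    "BladderKinetics",
    "VoidingSchedule",
    "fit_excretion",
    "bladder_residence_dynamic",
    "bladder_residence_voi",
    "urine_total_residence",
]


@dataclass(frozen=True)
class UrineCollection:
    """One urine collection interval.

    ``fraction_ia`` is the decay-corrected (to injection time) fraction of
    the injected activity contained in the collection, which makes cumulative
    sums directly comparable to excreted-percentage figures.
    """

    t_start_min: float
    t_end_min: float
    volume_ml: float
    fraction_ia: float

    def __post_init__(self) -> None:
        if self.t_end_min <= self.t_start_min:
            raise ValueError("collection must end after it starts")
        if self.fraction_ia < 0:
            raise ValueError("negative activity in collection")
        if self.volume_ml < 0:
            raise ValueError("negative collection volume")


@dataclass(frozen=True)
class BladderKinetics:
    """Fitted urinary excretion: total urine fraction and biologic rate."""

    f_u: float
    lambda_b_per_h: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_u <= 1.0:
            raise ValueError("f_u must be a fraction in [0, 1]")
        if self.lambda_b_per_h < 0:
            raise ValueError("lambda_b must be non-negative")


@dataclass(frozen=True)
class VoidingSchedule:
    """Periodic voiding every ``interval_h`` hours, starting at injection."""

    interval_h: float

    def __post_init__(self) -> None:
        if self.interval_h <= 0:
            raise ValueError("voiding interval must be positive")


def _check_collections(collections: Sequence[UrineCollection]) -> list[UrineCollection]:
    post = sorted(
        (c for c in collections if c.t_end_min > 0), key=lambda c: c.t_start_min
    )
    for a, b in zip(post, post[1:]):
        if b.t_start_min < a.t_end_min - 1e-9:
            raise ValueError("urine collections overlap")
    return post


def fit_excretion(
    collections: Sequence[UrineCollection], subject_id: str | None = None
) -> BladderKinetics:
    """Fit ``F(t) = f_u (1 - exp(-lambda_b t))`` to cumulative excretion.

    The cumulative decay-corrected excreted fraction is evaluated at each
    post-injection collection's end time (a collection empties the bladder at
    the void, so its activity is attributed to its end).  Least squares with
    bounds ``0 <= f_u <= 1``, ``lambda_b >= 0``.
    """
    post = _check_collections(collections)
    if len(post) < 2:
        raise ValueError("need at least 2 post-injection collections")

    t_h = np.array([c.t_end_min for c in post]) / 60.0
    cum = np.cumsum([c.fraction_ia for c in post])

    if cum[-1] <= 0:
        warnings.warn(
            f"{subject_id or 'subject'}: all urine collections empty; "
            "degenerate kinetics f_u = 0",
            stacklevel=2,
        )
        return BladderKinetics(0.0, 0.0)

    f0 = min(1.0, 2.0 * float(cum[-1]))
    lb0 = 1.0 / float(t_h[-1])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                lambda t, f, lb: f * (1.0 - np.exp(-lb * t)),
                t_h,
                cum,
                p0=[f0, lb0],
                bounds=([0.0, 0.0], [1.0, np.inf]),
                xtol=1e-12,
                maxfev=20000,
            )
    except RuntimeError as err:
        raise RuntimeError(
            f"urinary excretion fit failed to converge for "
            f"{subject_id or 'subject'}: {err}"
        ) from err
    return BladderKinetics(float(popt[0]), float(popt[1]))


def bladder_residence_dynamic(
    kinetics: BladderKinetics, voiding: VoidingSchedule
) -> ResidenceTime:
    """Closed-form bladder-content residence time under periodic voiding.

    Between voids at ``t_k = k T`` the decay-corrected content is
    ``f_u (exp(-lambda_b t_k) - exp(-lambda_b t))``; applying physical decay
    and summing the integrals of all cycles to infinity gives

        tau = f_u [ (1-e^(-lp T))/lp - (1-e^(-(lp+lb) T))/(lp+lb) ]
                  / (1 - e^(-(lp+lb) T))

    with ``lp`` the physical and ``lb`` the biologic rate.  For
    ``lambda_b * T`` below 1e-8 the numerator suffers catastrophic
    cancellation and the first-order series in ``lambda_b`` is used; the
    limit vanishes only because ``f_u * lambda_b -> 0``.
    """
    lp = LAMBDA_P_PER_H
    lb = kinetics.lambda_b_per_h
    T = voiding.interval_h
    f_u = kinetics.f_u

    if lb * T < 1e-8:
        # d/dlb of the expression at lb=0: tau ≈ f_u lb (1 - e^(-lp T)(1+lp T))
        #                                          / (lp^2 (1 - e^(-lp T)))
        e = np.exp(-lp * T)
        tau = f_u * lb * (1.0 - e * (1.0 + lp * T)) / (lp**2 * (1.0 - e))
        return ResidenceTime("urinary_bladder_content", float(tau))

    x = (lp + lb) * T
    num = (1.0 - np.exp(-lp * T)) / lp - (1.0 - np.exp(-x)) / (lp + lb)
    tau = f_u * num / (1.0 - np.exp(-x))
    return ResidenceTime("urinary_bladder_content", float(tau))


def urine_total_residence(kinetics: BladderKinetics) -> float:
    """Residence time (h) of the whole urine compartment, bladder plus voided.

    ``integral of f_u (1 - exp(-lambda_b t)) exp(-lambda_p t) dt`` from 0 to
    infinity ``= f_u lambda_b / (lambda_p (lambda_p + lambda_b))``.  Voiding
    only moves activity from the bladder to the voided fraction, so this
    total — and hence the remainder of the body — does not depend on the
    voiding schedule; the bladder-content residence
    :func:`bladder_residence_dynamic` is bounded above by it.
    """
    lp = LAMBDA_P_PER_H
    lb = kinetics.lambda_b_per_h
    return kinetics.f_u * lb / (lp * (lp + lb))


def bladder_residence_voi(
    scan_times_min: Sequence[float],
    voi_concentrations_per_ml: Sequence[float],
    volume_measurements: Sequence[tuple[float, float]],
    void_times_min: Sequence[float],
) -> ResidenceTime:
    """Bladder-content residence time from VOI concentrations and volumes.

    The bladder activity series (fraction of injected activity, decay
    corrected) is built by multiplying each session's measured urine volume
    by the VOI concentration values of its scans: the first volume applies to
    the scans preceding the first volume measurement, the second to scans up
    to the second, and so on.  The decay-corrected content is held constant
    from the last scan of a session to the following void, reset to zero at
    the void, and assumed to rise linearly to the next scan.  The
    non-decay-corrected series is integrated by trapezoids, plus a
    physical-decay tail after the last scan.
    """
    t = np.asarray(scan_times_min, dtype=float)
    conc = np.asarray(voi_concentrations_per_ml, dtype=float)
    if t.shape != conc.shape or t.size == 0:
        raise ValueError("scan times and VOI values must have equal length")
    if np.any(conc < 0):
        raise ValueError("negative VOI concentration")
    vols = sorted(volume_measurements)
    if len(vols) == 0 or any(v <= 0 for _, v in vols):
        raise ValueError("missing or non-positive volume measurement")

    # assign each scan the volume measured at the end of its session
    vol_times = np.array([vt for vt, _ in vols])
    vol_values = np.array([v for _, v in vols])
    idx = np.searchsorted(vol_times, t, side="left")
    if np.any(idx >= len(vols)):
        raise ValueError("scan after the last volume measurement has no volume")
    activity = conc * vol_values[idx]  # decay-corrected fraction of IA

    # node list (time_min, decay-corrected fraction): origin, scans, voids
    nodes: list[tuple[float, float]] = [(0.0, 0.0)]
    voids = sorted(vt for vt in void_times_min if vt > t[0])
    scan_i = 0
    for vt in voids + [np.inf]:
        while scan_i < len(t) and t[scan_i] < vt:
            nodes.append((float(t[scan_i]), float(activity[scan_i])))
            scan_i += 1
        if np.isinf(vt) or vt > t[-1]:
            break
        nodes.append((float(vt), nodes[-1][1]))  # held until the void
        nodes.append((float(vt), 0.0))  # instantaneous void

    tn = np.array([n[0] for n in nodes]) / 60.0
    an = np.array([n[1] for n in nodes])
    nd = an * np.exp(-LAMBDA_P_PER_H * tn)
    tau = 0.0
    for j in range(len(nd) - 1):
        tau += 0.5 * (nd[j] + nd[j + 1]) * (tn[j + 1] - tn[j])
    tau += nd[-1] / LAMBDA_P_PER_H  # physical-decay tail after the last scan
    return ResidenceTime("urinary_bladder_content", float(tau))
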
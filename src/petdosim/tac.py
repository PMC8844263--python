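"""Time–activity curves, washout fitting and cumulated activities.

Organ time–activity curves from quantitative PET are decay-corrected
fractions of injected activity sampled at the acquisition mid-times.  This
module normalizes them per 1 MBq injected and to the reference phantom organ
masses, fits a mono-exponential biologic washout to the descending part of
each curve, and integrates the non-decay-corrected curve to infinity to
obtain the cumulated activity per unit injected activity (the residence
time, in hours) that the MIRD schema consumes.

Conventions
-----------
* Input curves are decay-corrected, as PET scanners report them; all
  integrals re-apply the physical decay ``exp(-lambda_p * t)`` explicitly,
  so the fitted washout rate is purely biologic.
* Times are minutes post-injection in I/O; residence times are hours.
* A curve whose global maximum is the last sample ("continuing uptake") gets
  a biologic rate of zero: its tail decays by physical decay only.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import F18_MEAN_LIFE_H, LAMBDA_P_PER_H

logger = logging.getLogger(__name__)

__all__ = [
    "TimeActivityCurve",
    "NormalizedTAC",
    "ExponentialFit",
    "ResidenceTime",
    "normalize",
    "fit_washout",
    "residence_time",
    "remainder_residence",
    "blood_curve_summary",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TimeActivityCurve:
    """Sampled decay-corrected activity of one source region.

    ``values`` may be absolute activities (MBq) or fractions of injected
    activity; :func:`normalize` handles both via ``values_in``.
    """

    organ_name: str
    times_min: np.ndarray
    values: np.ndarray
    voi_volume_ml: float | None = None

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_min.ndim != 1 or self.times_min.size < 2:
            raise ValueError(f"{self.organ_name}: need at least 2 samples")
        if self.times_min.shape != self.values.shape:
            raise ValueError(f"{self.organ_name}: times/values length mismatch")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError(f"{self.organ_name}: times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError(f"{self.organ_name}: negative activity values")


@dataclass
class NormalizedTAC:
    """Activity per organ per 1 MBq injected, at reference organ mass."""

    organ_name: str
    times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError(f"{self.organ_name}: negative normalized values")


@dataclass(frozen=True)
class ExponentialFit:
    """Mono-exponential biologic washout fitted to the descending segment."""

    A0: float
    k_bio_per_h: float
    t_start_min: float
    rss: float
    degenerate: bool = False


@dataclass(frozen=True)
class ResidenceTime:
    """Cumulated activity per unit injected activity for one source (hours)."""

    organ_name: str
    tau_h: float

    def __post_init__(self) -> None:
        if self.tau_h < 0:
            raise ValueError(f"{self.organ_name}: negative residence time")
        if self.tau_h > F18_MEAN_LIFE_H * (1 + 1e-9):
            raise ValueError(
                f"{self.organ_name}: tau {self.tau_h:.4f} h exceeds the F-18 "
                f"mean life {F18_MEAN_LIFE_H:.4f} h"
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize(
    tac: TimeActivityCurve,
    injected_mbq: float,
    phantom_masses_g: dict[str, float],
    subject_organ_mass_g: float | None = None,
    values_in: str = "MBq",
) -> NormalizedTAC:
    """Normalize a curve to 1 MBq injected and to the reference organ mass.

    Parameters
    ----------
    injected_mbq:
        Administered activity.  Absolute (MBq) input values are divided by
        it; values already expressed as fractions of injected activity are
        per-1-MBq by definition and pass through unchanged.
    phantom_masses_g:
        Reference organ masses; must contain ``tac.organ_name``.
    subject_organ_mass_g:
        Subject-specific organ mass if known.  The curve is rescaled by
        ``reference_mass / subject_mass``; defaults to the reference mass
        (identity scaling) when unknown.
    values_in:
        ``"MBq"`` for absolute activities, ``"fraction"`` for fractions of
        injected activity.
    """
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if tac.organ_name not in phantom_masses_g:
        raise KeyError(f"unknown organ {tac.organ_name!r}: not in phantom")
    if values_in not in ("MBq", "fraction"):
        raise ValueError("values_in must be 'MBq' or 'fraction'")

    ref_mass = phantom_masses_g[tac.organ_name]
    subj_mass = ref_mass if subject_organ_mass_g is None else subject_organ_mass_g
    if subj_mass <= 0:
        raise ValueError("subject organ mass must be positive")

    values = tac.values / injected_mbq if values_in == "MBq" else tac.values.copy()
    values = values * (ref_mass / subj_mass)
    return NormalizedTAC(tac.organ_name, tac.times_min.copy(), values)


def _peak_index(values: np.ndarray) -> int:
    """Index of the global maximum; ties resolved to the latest tied sample
    (maximizes the number of descending points)."""
    return len(values) - 1 - int(np.argmax(values[::-1]))


def fit_washout(ntac: NormalizedTAC) -> ExponentialFit:
    """Fit ``A0 * exp(-k_bio * (t - t_start))`` to the descending segment.

    The segment runs from the curve's global maximum (latest tied sample) to
    the end.  Measurement noise on PET VOI values is multiplicative, so the
    least-squares fit is performed on the logarithm of the positive samples
    (the maximum-likelihood estimate under lognormal noise, and exact on
    noise-free data); ``k_bio`` is constrained non-negative.

    A curve whose maximum is the final sample is treated as continuing
    uptake: the fit degenerates to ``k_bio = 0`` with ``A0`` equal to the
    last value, so the tail beyond the observations decays by physical decay
    only.
    """
    t_h = ntac.times_min / 60.0
    y = ntac.values
    ipk = _peak_index(y)

    if ipk >= len(y) - 1:
        if y[ipk] > 0:
            # continuing uptake: the peak is the final sample; the tail decays
            # by physical decay only
            logger.debug("%s: continuing uptake, k_bio = 0", ntac.organ_name)
            return ExponentialFit(float(y[-1]), 0.0, float(ntac.times_min[-1]), 0.0, False)
        warnings.warn(
            f"{ntac.organ_name}: fewer than 2 usable descending points; "
            "degenerate fit with k_bio = 0",
            stacklevel=2,
        )
        return ExponentialFit(float(y[-1]), 0.0, float(ntac.times_min[-1]), 0.0, True)

    tt = t_h[ipk:] - t_h[ipk]
    yy = y[ipk:]
    if np.all(yy <= 0):
        warnings.warn(
            f"{ntac.organ_name}: all-zero descending segment; degenerate fit",
            stacklevel=2,
        )
        return ExponentialFit(0.0, 0.0, float(ntac.times_min[ipk]), 0.0, True)

    pos = yy > 0
    if pos.sum() < 2:
        warnings.warn(
            f"{ntac.organ_name}: fewer than 2 positive descending points; "
            "degenerate fit with k_bio = 0",
            stacklevel=2,
        )
        return ExponentialFit(float(yy[0]), 0.0, float(ntac.times_min[ipk]), 0.0, True)

    log_y = np.log(yy[pos])
    slope, intercept = np.polyfit(tt[pos], log_y, 1)
    if slope >= 0:  # noise made the tail rise on average: physical decay only
        a0, k = float(np.exp(log_y.mean())), 0.0
    else:
        a0, k = float(np.exp(intercept)), float(-slope)
    rss = float(np.sum((a0 * np.exp(-k * tt) - yy) ** 2))
    return ExponentialFit(a0, k, float(ntac.times_min[ipk]), rss)


def _segment_integral(nd_a: float, nd_b: float, dt_h: float) -> float:
    """Integral of an exponential interpolant through two positive samples of
    the non-decay-corrected curve; falls back to the trapezoid when an
    endpoint is zero or the segment is flat."""
    if nd_a > 0 and nd_b > 0 and abs(nd_a - nd_b) > 1e-14 * nd_a:
        return (nd_a - nd_b) * dt_h / np.log(nd_a / nd_b)
    return 0.5 * (nd_a + nd_b) * dt_h


def residence_time(ntac: NormalizedTAC, fit: ExponentialFit) -> ResidenceTime:
    """Cumulated activity per unit injected activity (hours).

    The observed decay-corrected curve is converted to physical activity by
    multiplying with ``exp(-lambda_p t)`` and integrated: a linear rise from
    (0, 0) to the first sample, trapezoids up to the peak, exponential
    segment interpolation after the peak (the curve is a decaying exponential
    there, which plain trapezoids systematically overestimate at this
    schedule's wide late gaps), and the analytic tail
    ``A(t_last) e^(-lambda_p t_last) / (lambda_p + k_bio)`` beyond the last
    sample.
    """
    if np.any(ntac.values < 0):
        raise ValueError(f"{ntac.organ_name}: negative values in curve")

    t_h = ntac.times_min / 60.0
    nd = ntac.values * np.exp(-LAMBDA_P_PER_H * t_h)
    ipk = _peak_index(ntac.values)

    tau = 0.5 * t_h[0] * nd[0]  # leading edge: linear rise from (0, 0)
    if ipk > 0:
        tau += float(np.trapezoid(nd[: ipk + 1], t_h[: ipk + 1]))
    for j in range(ipk, len(nd) - 1):
        tau += _segment_integral(nd[j], nd[j + 1], t_h[j + 1] - t_h[j])
    tau += nd[-1] / (LAMBDA_P_PER_H + max(fit.k_bio_per_h, 0.0))

    return ResidenceTime(ntac.organ_name, float(tau))


def remainder_residence(
    organ_taus: Iterable[ResidenceTime],
    bladder_tau: ResidenceTime,
    urine_voided: Sequence[tuple[float, float]],
) -> ResidenceTime:
    """Residence time of the remainder of the body.

    Whole-body accounting: the total-body residence time is the F-18 mean
    life; each void at ``t_void`` (minutes) removes its decay-corrected
    voided fraction from the body, costing ``v * exp(-lambda_p t) /
    lambda_p`` hours of residence.  What is not in an explicit source organ,
    the bladder or the voided urine is the remainder; a negative balance is
    clamped to zero with a warning.
    """
    total = F18_MEAN_LIFE_H
    total -= sum(rt.tau_h for rt in organ_taus)
    total -= bladder_tau.tau_h
    for t_void_min, voided_fraction in urine_voided:
        if voided_fraction < 0:
            raise ValueError("voided fractions must be non-negative")
        total -= voided_fraction * np.exp(-LAMBDA_P_PER_H * t_void_min / 60.0) / LAMBDA_P_PER_H
    if total < 0:
        warnings.warn(
            f"remainder residence time negative ({total:.4f} h); clamped to 0",
            stacklevel=2,
        )
        total = 0.0
    return ResidenceTime("remainder", float(total))


def blood_curve_summary(
    samples_per_subject: Sequence[Sequence[tuple[float, float]]],
) -> pd.DataFrame:
    """Pointwise cohort mean of whole-blood concentration curves.

    Descriptive only (it is not used in the dosimetry): returns the mean and
    SD over subjects at each sampling time of the venous schedule.  Subjects
    must share the sampling times.
    """
    if not samples_per_subject:
        raise ValueError("no subjects")
    frames = []
    for i, samples in enumerate(samples_per_subject):
        if len(samples) < 2:
            raise ValueError("need at least 2 blood samples per subject")
        t, v = zip(*samples)
        frames.append(pd.Series(v, index=np.asarray(t, dtype=float), name=i))
    wide = pd.concat(frames, axis=1)
    out = pd.DataFrame(
        {
            "time_min": wide.index.to_numpy(),
            "mean": wide.mean(axis=1).to_numpy(),
            "sd": wide.std(axis=1, ddof=1).fillna(0.0).to_numpy(),
            "n": wide.notna().sum(axis=1).to_numpy(),
        }
    ).reset_index(drop=True)
    return out
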
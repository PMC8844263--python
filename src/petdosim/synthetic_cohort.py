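"""Synthetic biodistribution cohorts for an F-18 PSMA-ligand PET study.

Generates subjects — organ time–activity curves, urine collections, bladder
volume measurements, whole-blood samples — with the statistical structure the
dosimetry pipeline assumes, calibrated so that cohort means reproduce the
published biodistribution of 18F-rhPSMA-7.3 in healthy volunteers: the 1-min
organ uptake fractions and the cumulative urinary excretion at the three
session ends.

Kinetic model
-------------
Each organ's decay-corrected fraction of injected activity follows

    A(t) = f_peak * (1 - exp(-k_up t)) * exp(-k_bio t)

the simplest form distinguishing continuing uptake from washout.  Organs with
printed 1-min uptake use an effectively instantaneous ``k_up`` (600/h) and
``f_peak`` back-calculated so the noise-free 1-min value equals the printed
mean exactly.  Inter-subject variability is lognormal with unit mean (so
cohort means stay calibrated) and CVs derived from the printed subject ranges
via range ≈ ±2 SD for n = 6; measurement noise is multiplicative lognormal
with unit mean.

Urinary excretion is mono-exponential, ``F(t) = f_u (1 - exp(-lambda_b t))``,
with defaults pinned so the noise-free curve passes exactly through the
published session-3 cumulative fraction (14.8% at 263 min) — ``f_u`` bounded
by whole-body mass balance — giving 7.18 / 11.62 / 14.80% at the three
session ends against the published 7.2 / 11.4 / 14.8%.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import reference
from .bladder import UrineCollection
from .tac import TimeActivityCurve

__all__ = [
    "ScanSchedule",
    "OrganKinetics",
    "SubjectRecord",
    "default_kinetics",
    "generate_cohort",
    "organ_fraction",
    "urine_cumulative_fraction",
    "mass_balance_frame",
    "write_cohort",
    "URINE_F_U",
    "URINE_LAMBDA_B_PER_H",
    "FEMALE_ONLY_ORGANS",
    "MALE_ONLY_ORGANS",
]


# ---------------------------------------------------------------------------
# Scan schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSchedule:
    """Three scan sessions, eight whole-body acquisitions, two between-session
    voids, and a final collection/volume measurement after session 3.

    Defaults follow the study timeline: sessions at 1–90, 150–178 and
    220–248 min post-injection; six acquisitions in session 1 and one in each
    later session (exact per-scan mid-times are configurable assumptions).
    """

    session_windows: tuple[tuple[float, float], ...] = ((1.0, 90.0), (150.0, 178.0), (220.0, 248.0))
    acquisition_midtimes_min: tuple[float, ...] = (1.0, 7.0, 20.0, 40.0, 65.0, 88.0, 164.0, 234.0)
    void_times_min: tuple[float, ...] = (111.0, 194.0)
    collection_end_times_min: tuple[float, ...] = (111.0, 194.0, 263.0)

    def __post_init__(self) -> None:
        mids = np.asarray(self.acquisition_midtimes_min)
        if np.any(np.diff(mids) <= 0):
            raise ValueError("acquisition mid-times must be strictly increasing")
        counts = []
        for lo, hi in self.session_windows:
            if hi <= lo:
                raise ValueError("session window must have positive duration")
            counts.append(int(np.sum((mids >= lo) & (mids <= hi))))
        if sum(counts) != len(mids):
            raise ValueError("every acquisition mid-time must fall inside a session window")
        for vt in self.void_times_min:
            between = any(
                self.session_windows[i][1] < vt < self.session_windows[i + 1][0]
                for i in range(len(self.session_windows) - 1)
            )
            if not between:
                raise ValueError(f"void at {vt} min is not strictly between sessions")
        ends = self.collection_end_times_min
        if any(b <= a for a, b in zip(ends, ends[1:])):
            raise ValueError("collection end times must be increasing")

    @property
    def session_of_scan(self) -> tuple[int, ...]:
        out = []
        for t in self.acquisition_midtimes_min:
            for i, (lo, hi) in enumerate(self.session_windows):
                if lo <= t <= hi:
                    out.append(i)
                    break
        return tuple(out)


# ---------------------------------------------------------------------------
# Organ kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganKinetics:
    organ_name: str
    f_peak: float
    k_up_per_h: float
    k_bio_per_h: float
    cv_inter: float
    sigma_meas: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_peak <= 1.0:
            raise ValueError(f"{self.organ_name}: f_peak must be in [0, 1]")
        if self.k_up_per_h < 0 or self.k_bio_per_h < 0:
            raise ValueError(f"{self.organ_name}: rates must be non-negative")
        if self.cv_inter < 0 or self.sigma_meas < 0:
            raise ValueError(f"{self.organ_name}: noise parameters must be non-negative")


def organ_fraction(kin: OrganKinetics, t_min: np.ndarray | float) -> np.ndarray | float:
    """Noise-free decay-corrected fraction of injected activity at ``t_min``."""
    t_h = np.asarray(t_min, dtype=float) / 60.0
    out = kin.f_peak * (1.0 - np.exp(-kin.k_up_per_h * t_h)) * np.exp(-kin.k_bio_per_h * t_h)
    return float(out) if np.ndim(t_min) == 0 else out


#: Default total urinary excretion fraction.  Bounded by whole-body mass
#: balance (sum of organ peak fractions + f_u <= 1).
URINE_F_U: float = 0.368

#: Biologic urinary excretion rate (1/h): pins the noise-free cumulative
#: curve exactly to the published session-3 fraction, 0.148 at 263 min.
URINE_LAMBDA_B_PER_H: float = -math.log(1.0 - 0.148 / URINE_F_U) / (263.0 / 60.0)

#: Inter-subject CVs of total urine fraction and of the excretion rate.  The
#: f_u CV matches the published session-1 range (4.4–9.0% around 7.2%).
URINE_CV_F_U: float = 0.16
URINE_CV_LAMBDA_B: float = 0.10

#: Mean urine production rate and CV of voided volumes.
URINE_FLOW_ML_PER_MIN: float = 1.3
URINE_VOLUME_CV: float = 0.25

#: Whole-blood volume (L) used to convert blood-pool activity into a
#: concentration, and the venous sampling schedule (minutes).
BLOOD_VOLUME_L: float = 5.3
BLOOD_SAMPLE_TIMES_MIN: tuple[float, ...] = (
    0.5, 1.0, 1.5, 4.5, 5.0, 6.0, 7.0, 8.0, 15.0, 31.0, 47.0, 75.0, 120.0, 180.0, 250.0,
)

_FAST_UPTAKE_PER_H = 600.0  # effectively instantaneous on this schedule

# organs with a printed 1-min uptake: (value at 1 min, k_bio/h, cv)
_CALIBRATED_1MIN: dict[str, tuple[float, float, float]] = {
    "liver": (0.158, 0.10, 0.049),
    "muscle": (0.243, 0.25, 0.104),
    "heart_content": (0.074, 0.60, 0.091),
    "cortical_bone": (0.035, 0.18, 0.100),
    "brain": (0.008, 0.30, 0.156),
    "pancreas": (0.006, 0.25, 0.208),
}

# remaining organs: (f_peak, k_up/h, k_bio/h, cv); peaks respect the printed
# upper bounds (<1% or <3% of injected activity over the scan period) and the
# delayed-uptake descriptions (spleen, red marrow, kidneys, salivary and
# lacrimal glands peak after 1 min)
_PEAK_SPECIFIED: dict[str, tuple[float, float, float, float]] = {
    "kidneys": (0.030, 6.0, 0.05, 0.18),
    "spleen": (0.007, 2.0, 0.02, 0.20),
    "red_marrow": (0.009, 1.5, 0.00, 0.20),
    "lungs": (0.008, _FAST_UPTAKE_PER_H, 0.40, 0.15),
    "heart_wall": (0.008, _FAST_UPTAKE_PER_H, 0.20, 0.15),
    "small_intestine": (0.008, 30.0, 0.15, 0.20),
    "stomach_wall": (0.004, 60.0, 0.10, 0.20),
    "adrenals": (0.003, 60.0, 0.05, 0.30),
    "parotid_glands": (0.004, 3.0, 0.05, 0.25),
    "submandibular_glands": (0.0035, 3.0, 0.05, 0.30),
    "sublingual_glands": (0.0012, 3.0, 0.05, 0.35),
    "lacrimal_glands": (0.001, 2.5, 0.00, 0.40),
    "thymus": (0.001, _FAST_UPTAKE_PER_H, 0.80, 0.30),
    "thyroid": (0.001, _FAST_UPTAKE_PER_H, 0.80, 0.30),
    "testes": (0.0008, 60.0, 0.10, 0.30),
    "gallbladder_content": (0.0006, 60.0, 0.05, 0.30),
    "trabecular_bone": (0.004, _FAST_UPTAKE_PER_H, 0.10, 0.20),
    "uli_content": (0.003, 10.0, 0.05, 0.30),
    "lli_content": (0.0025, 5.0, 0.05, 0.30),
    "breasts": (0.0025, _FAST_UPTAKE_PER_H, 0.20, 0.25),
    "uterus": (0.0015, 60.0, 0.10, 0.30),
    "ovaries": (0.0005, 60.0, 0.10, 0.30),
}

FEMALE_ONLY_ORGANS: frozenset[str] = frozenset({"breasts", "uterus", "ovaries"})
MALE_ONLY_ORGANS: frozenset[str] = frozenset({"testes"})


def default_kinetics(sigma_meas: float = 0.05) -> dict[str, OrganKinetics]:
    """Default organ kinetics calibrated to the published biodistribution.

    Noise-free simulation of these defaults reproduces the printed 1-min
    uptake fractions exactly (liver 0.158, muscle 0.243, heart content 0.074,
    cortical bone 0.035, brain 0.008, pancreas 0.006).
    """
    kin: dict[str, OrganKinetics] = {}
    t1_h = 1.0 / 60.0
    for organ, (v1, k_bio, cv) in _CALIBRATED_1MIN.items():
        shape = (1.0 - math.exp(-_FAST_UPTAKE_PER_H * t1_h)) * math.exp(-k_bio * t1_h)
        kin[organ] = OrganKinetics(organ, v1 / shape, _FAST_UPTAKE_PER_H, k_bio, cv, sigma_meas)
    for organ, (f_peak, k_up, k_bio, cv) in _PEAK_SPECIFIED.items():
        kin[organ] = OrganKinetics(organ, f_peak, k_up, k_bio, cv, sigma_meas)

    total = sum(k.f_peak for k in kin.values()) + URINE_F_U
    if total > 1.0:
        raise ValueError(f"mass balance violated: sum f_peak + f_u = {total:.4f} > 1")
    return kin


def urine_cumulative_fraction(
    t_min: np.ndarray | float, f_u: float = URINE_F_U, lambda_b: float = URINE_LAMBDA_B_PER_H
) -> np.ndarray | float:
    """Noise-free cumulative decay-corrected urinary excretion at ``t_min``."""
    t_h = np.asarray(t_min, dtype=float) / 60.0
    out = f_u * (1.0 - np.exp(-lambda_b * t_h))
    return float(out) if np.ndim(t_min) == 0 else out


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    subject_id: str
    sex: str  # "male" | "female"
    injected_mbq: float
    organ_tacs: list[TimeActivityCurve]
    urine_collections: list[UrineCollection]
    bladder_volume_measurements: list[tuple[float, float]]  # (time min, mL)
    bladder_voi_concentrations: np.ndarray  # fraction of IA per mL, per scan
    blood_samples: list[tuple[float, float]]  # (time min, fraction of IA per L)
    true_params: dict = field(default_factory=dict)  # generator ground truth

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        lo = reference.INJECTED_TARGET_MBQ * (1 - reference.INJECTED_TOLERANCE)
        hi = reference.INJECTED_TARGET_MBQ * (1 + reference.INJECTED_TOLERANCE)
        if not lo <= self.injected_mbq <= hi:
            raise ValueError(f"injected activity {self.injected_mbq} MBq outside target ±10%")
        organs = {t.organ_name for t in self.organ_tacs}
        forbidden = MALE_ONLY_ORGANS if self.sex == "female" else FEMALE_ONLY_ORGANS
        if organs & forbidden:
            raise ValueError(f"{self.subject_id}: sex-mismatched organs {organs & forbidden}")

    def tac(self, organ: str) -> TimeActivityCurve:
        for t in self.organ_tacs:
            if t.organ_name == organ:
                return t
        raise KeyError(f"{self.subject_id} has no TAC for {organ!r}")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal factor with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_cohort(
    n_subjects: int,
    seed: int,
    schedule: ScanSchedule | None = None,
    kinetics: Mapping[str, OrganKinetics] | None = None,
    urine_f_u: float = URINE_F_U,
    urine_lambda_b: float = URINE_LAMBDA_B_PER_H,
    urine_cv_f_u: float = URINE_CV_F_U,
    urine_cv_lambda_b: float = URINE_CV_LAMBDA_B,
    urine_sigma_meas: float = 0.05,
) -> list[SubjectRecord]:
    """Generate a synthetic cohort; a fixed seed gives a bit-identical cohort.

    Sexes alternate male/female so a 6-subject cohort has the study's 3/3
    split.  Sex-specific organs are only simulated for the matching sex.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    schedule = schedule or ScanSchedule()
    kinetics = dict(kinetics) if kinetics is not None else default_kinetics()
    for organ, kin in kinetics.items():
        if kin.organ_name != organ:
            raise ValueError(f"kinetics key {organ!r} != organ_name {kin.organ_name!r}")

    t_scan = np.asarray(schedule.acquisition_midtimes_min, dtype=float)
    sessions = np.asarray(schedule.session_of_scan)
    coll_ends = schedule.collection_end_times_min

    master = np.random.SeedSequence(seed)
    cohort: list[SubjectRecord] = []
    for i, child in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        sex = "male" if i % 2 == 0 else "female"
        skip = FEMALE_ONLY_ORGANS if sex == "male" else MALE_ONLY_ORGANS
        injected = float(rng.uniform(*reference.INJECTED_RANGE_MBQ))

        tacs: list[TimeActivityCurve] = []
        organ_truth: dict[str, tuple[float, float, float]] = {}
        for organ, kin in kinetics.items():
            scale = float(_lognormal_unit_mean(rng, kin.cv_inter))
            noise = _lognormal_unit_mean(rng, kin.sigma_meas, size=t_scan.size)
            f_i = kin.f_peak * scale
            values = f_i * (1.0 - np.exp(-kin.k_up_per_h * t_scan / 60.0)) * np.exp(
                -kin.k_bio_per_h * t_scan / 60.0
            ) * noise
            if organ in skip:
                continue
            tacs.append(TimeActivityCurve(organ, t_scan.copy(), values, voi_volume_ml=None))
            organ_truth[organ] = (f_i, kin.k_up_per_h, kin.k_bio_per_h)

        # urinary excretion: subject-level mono-exponential truth
        fu_i = min(0.95, urine_f_u * float(_lognormal_unit_mean(rng, urine_cv_f_u)))
        lb_i = urine_lambda_b * float(_lognormal_unit_mean(rng, urine_cv_lambda_b))
        cum = fu_i * (1.0 - np.exp(-lb_i * np.asarray(coll_ends) / 60.0))
        increments = np.diff(np.concatenate([[0.0], cum]))
        increments = increments * _lognormal_unit_mean(rng, urine_sigma_meas, size=increments.size)

        collections = [UrineCollection(-5.0, 0.0, float(rng.uniform(80.0, 200.0)), 0.0)]
        volumes: list[tuple[float, float]] = []
        prev = 0.0
        for t_end, frac in zip(coll_ends, increments):
            vol = URINE_FLOW_ML_PER_MIN * (t_end - prev) * float(
                _lognormal_unit_mean(rng, URINE_VOLUME_CV)
            )
            collections.append(UrineCollection(prev, float(t_end), vol, float(max(frac, 0.0))))
            volumes.append((float(t_end), vol))
            prev = float(t_end)

        # bladder VOI concentrations: content since the last void divided by
        # the session's measured urine volume (the study's bookkeeping)
        voided_before = np.zeros_like(t_scan)
        for k, vt in enumerate(schedule.void_times_min):
            voided_before[t_scan > vt] = cum[k]
        content = fu_i * (1.0 - np.exp(-lb_i * t_scan / 60.0)) - voided_before
        sess_vol = np.array([volumes[s][1] for s in sessions])
        conc = content / sess_vol * _lognormal_unit_mean(rng, urine_sigma_meas, size=t_scan.size)

        blood_scale = organ_truth["heart_content"][0] / kinetics["heart_content"].f_peak
        kin_b = kinetics["heart_content"]
        blood_t = np.asarray(BLOOD_SAMPLE_TIMES_MIN)
        blood_vals = (
            blood_scale
            * organ_fraction(kin_b, blood_t)
            / BLOOD_VOLUME_L
            * _lognormal_unit_mean(rng, kin_b.sigma_meas, size=blood_t.size)
        )
        blood = list(zip(blood_t.tolist(), blood_vals.tolist()))

        cohort.append(
            SubjectRecord(
                subject_id=f"S{i + 1:02d}",
                sex=sex,
                injected_mbq=injected,
                organ_tacs=tacs,
                urine_collections=collections,
                bladder_volume_measurements=volumes,
                bladder_voi_concentrations=conc,
                blood_samples=blood,
                true_params={"organs": organ_truth, "f_u": fu_i, "lambda_b": lb_i},
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# Bookkeeping and I/O
# ---------------------------------------------------------------------------


def mass_balance_frame(cohort: Sequence[SubjectRecord], schedule: ScanSchedule | None = None) -> pd.DataFrame:
    """Cohort-mean activity bookkeeping at each acquisition time.

    Columns: summed organ fractions, urine (bladder content + voided), their
    total, and the implied remainder ``1 - total``.  With unit-mean noise the
    total must not exceed 1 beyond noise tolerance.
    """
    schedule = schedule or ScanSchedule()
    t_scan = np.asarray(schedule.acquisition_midtimes_min)
    rows = []
    for s in cohort:
        organs = np.sum([t.values for t in s.organ_tacs], axis=0)
        fu_i, lb_i = s.true_params["f_u"], s.true_params["lambda_b"]
        urine = fu_i * (1.0 - np.exp(-lb_i * t_scan / 60.0))
        rows.append(organs + urine)
    total = np.mean(rows, axis=0)
    return pd.DataFrame(
        {
            "time_min": t_scan,
            "organs_plus_urine": total,
            "remainder": 1.0 - total,
        }
    )


def write_cohort(
    cohort: Sequence[SubjectRecord],
    outdir: str | Path,
    seed: int | None = None,
    schedule: ScanSchedule | None = None,
) -> dict[str, Path]:
    """Write the cohort as CSV: tacs.csv, urine.csv, subjects.csv, bladder.csv.

    The seed is recorded in `#`-prefixed header comment lines.  Floats are
    written with fixed precision so repeated runs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = schedule or ScanSchedule()
    header = f"# generator: petdosim synthetic cohort\n# seed: {seed}\n"

    tac_rows, urine_rows, subj_rows, bladder_rows = [], [], [], []
    for s in cohort:
        subj_rows.append({"subject_id": s.subject_id, "sex": s.sex, "injected_mbq": s.injected_mbq})
        for t in s.organ_tacs:
            for tm, v in zip(t.times_min, t.values):
                tac_rows.append(
                    {
                        "subject_id": s.subject_id,
                        "organ": t.organ_name,
                        "time_min": tm,
                        "fraction_ia": v,
                        "voi_volume_ml": t.voi_volume_ml if t.voi_volume_ml is not None else "",
                    }
                )
        for c in s.urine_collections:
            urine_rows.append(
                {
                    "subject_id": s.subject_id,
                    "t_start_min": c.t_start_min,
                    "t_end_min": c.t_end_min,
                    "volume_ml": c.volume_ml,
                    "fraction_ia": c.fraction_ia,
                }
            )
        for tm, vol in s.bladder_volume_measurements:
            bladder_rows.append(
                {"subject_id": s.subject_id, "kind": "volume", "time_min": tm, "value": vol}
            )
        for tm, conc in zip(schedule.acquisition_midtimes_min, s.bladder_voi_concentrations):
            bladder_rows.append(
                {"subject_id": s.subject_id, "kind": "voi_conc_per_ml", "time_min": tm, "value": conc}
            )

    paths = {}
    for name, rows in (
        ("tacs", tac_rows),
        ("urine", urine_rows),
        ("subjects", subj_rows),
        ("bladder", bladder_rows),
    ):
        path = outdir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(header)
            pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.10g")
        paths[name] = path
    return paths
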
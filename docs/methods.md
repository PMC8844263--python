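# Methods

This note documents the models, conventions, numerical choices and known
limitations of `petdosim`.  The package reimplements, as a tested pipeline,
the internal-dosimetry analysis of a first-in-humans PET biodistribution
study of an F-18 PSMA ligand: six healthy volunteers (3 men, 3 women),
~225 MBq ± 10% administered, three scan sessions (1–90, 150–178 and
220–248 min post-injection) with eight whole-body acquisitions, voiding
between sessions, and urine collected over four intervals.

## Decay-correction convention

PET scanners report decay-corrected activity.  All curve values in the
package are therefore decay-corrected fractions of injected activity, and
every integral re-applies the physical decay `exp(-lambda_p t)` explicitly.
The washout rate fitted to a curve is purely biologic, and the F-18 decay
constant is fixed from the standard half-life, 109.77 min (mean life
2.6394 h, the hard upper bound on any residence time per unit injected
activity).  Times are minutes in all I/O, hours internally.

## Organ curves and residence times

Each organ curve is normalized per 1 MBq injected and rescaled by
`reference_mass / subject_mass` (identity when the subject mass is unknown).
The descending part of the curve — from the global maximum, ties resolved to
the latest tied sample — is fitted with a single exponential.  Because VOI
measurement noise is multiplicative, the least-squares fit is performed on
the logarithm of the positive samples; this is the maximum-likelihood
estimator under lognormal noise, is median-unbiased (median relative bias of
the recovered rate is well below 5% at the default noise level), and is
exact on noise-free data.  A curve whose maximum is the last sample counts
as continuing uptake: its biologic rate is zero and its tail decays by
physical decay only — a deliberately conservative choice.

The residence time integrates the non-decay-corrected curve:

* a linear rise from (0, 0) to the first sample (the first acquisition is at
  ~1 min, so this segment is small but must be deterministic);
* trapezoids up to the peak;
* exponential (log-trapezoid) segment interpolation after the peak.  The
  post-peak curve is a decaying exponential, and plain trapezoids
  overestimate it by up to ~3% across this schedule's wide late gaps
  (88→164→234 min); the exponential interpolant is exact for pure
  exponential segments and keeps the integrator within 1% of fine quadrature
  for every default organ;
* the analytic tail `A(t_last) e^(-lambda_p t_last) / (lambda_p + k_bio)`.

The remainder-of-body residence time closes the whole-body balance: the
total-body residence is the mean life, minus all organ residence times,
minus the total urine compartment.  In the pipeline the urine compartment is
accounted as a whole, `f_u lambda_b / (lambda_p (lambda_p + lambda_b))`,
because voiding merely moves activity from the bladder (a source organ) to
voided urine (outside the body): this keeps the remainder — and hence every
organ dose except the bladder wall's — independent of the modeled voiding
interval, which is exactly the behavior the study reported.  A general
bookkeeping variant that subtracts an explicit bladder residence plus
per-void losses `v · e^(-lambda_p t_void) / lambda_p` is also provided;
negative balances clamp to zero with a warning.

## Urinary bladder

Two estimators of the bladder-content residence time are implemented.

**VOI bookkeeping.** Each session's measured urine volume multiplies the
bladder VOI concentration values of that session's scans (volume 1 × scans
1–6, volume 2 × scan 7, volume 3 × scan 8); the decay-corrected content is
held from the last scan of a session to the void, reset to zero at the void,
rises linearly to the next scan, and the non-decay-corrected series is
integrated by trapezoids with a physical-decay tail after the last scan.

**Dynamic voiding model.** A single biologic excretion curve
`F(t) = f_u (1 - exp(-lambda_b t))` is fitted by bounded least squares to
the cumulative decay-corrected collection totals, each collection attributed
to its end time (a collection empties the bladder at the void).  Under
periodic instantaneous voiding every `T` hours from injection the content
integrates in closed form (see README).  For `lambda_b T < 1e-8` the closed
form cancels catastrophically and a first-order series in `lambda_b` is
used; the residence time vanishes in the limit only because
`f_u·lambda_b → 0`.  Voiding is modeled as periodic from t = 0 (the
convention of the standard dosimetry software), not at the subjects' actual
void times, because reported bladder doses refer to modeled 1-h and 3.5-h
intervals.  The closed form is verified against step-wise fine-grid
integration of the voiding compartment to 1e-6 relative over a 27-point
parameter grid.  The dynamic model feeds the dosimetry; fits are per subject
and residence times are averaged afterwards, never the reverse.

## Dose engine

`D(target) = Σ_sources τ_S · S(target←source)` on the Cristy–Eckerman 70-kg
hermaphroditic adult phantom.  The four added glands (parotid 25 g,
submandibular 12.5 g, sublingual 12.5 g, lacrimal 5 g) have no geometry in
phantom S-value tables: their self-dose uses the nonpenetrating sphere model
`D = τ Δ_np / m` with absorbed fraction 1 (Δ_np from the F-18 mean positron
energy 0.2498 MeV at 96.73% yield; photon cross-dose to the glands is
ignored), and their residence time is routed to the remainder source for all
other targets.  Sources missing from a table's columns are likewise routed
to the remainder, with a warning.  S-value tables are CSV with a
`# units:` comment; `mGy/(MBq.s)` tables are converted at load.

Real phantom S-value tables are licensed data and are not shipped.  The
built-in synthetic table is built from first principles — annihilation-photon
energy spread uniformly over the body mass, nonpenetrating energy absorbed
locally, walled organs receiving a quarter of their content's equilibrium
dose constant, small bone-to-marrow/surface fractions — which gives the
right structure (self-dose dominant, row maxima on the diagonal) and
magnitudes, but organ doses computed with it are not comparable to published
per-organ values.  Supply a real table through the config to reproduce
organ-level dosimetry.

**Effective dose.** ICRP-60 tissue weighting factors (the software named in
the study predates ICRP-103), radiation weighting factor 1.  Surrogates:
gonads = mean of testes and ovaries (the phantom is hermaphroditic and a
sex-averaged E is reported; configurable by editing the weights), colon =
mass-weighted mean of the ULI and LLI walls, esophagus = thymus, bone
surface = osteogenic cells.  Two remainder conventions are implemented:

* `icrp60` — mass-weighted mean over the nine remainder organs (adrenals,
  brain, small intestine, kidneys, muscle, pancreas, spleen, thymus,
  uterus), with the splitting rule: if a single remainder organ exceeds the
  highest dose among the weighted tissues, it takes w = 0.025 and the
  mass-weighted mean of the rest takes 0.025.
* `olinda` (default) — unweighted mean of the remainder-organ doses, no
  splitting.

The default was chosen by validation against the study's published numbers:
applied to the published mean organ doses, the textbook mass-weighted rule
gives 0.0113 mSv/MBq (−20%) and its splitting variant 0.0157 (+12%, the rule
fires on the adrenals), while the unweighted mean reproduces both published
effective doses (0.01375 vs 0.0141 at the 3.5-h interval, 0.01345 vs 0.0138
at 1 h, −2.5% each).  The original software's remainder handling is not
publicly documented; the unweighted-mean convention is evidently what it
used, and the residual −2.5% is accepted as its remaining undocumented
detail.

Cohort reports compute doses per subject, then average; the SD is across
subjects, and organs are sorted by descending mean dose.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline is testable
without patient data.  Each organ follows
`A(t) = f_peak (1 - e^(-k_up t)) e^(-k_bio t)` — the simplest form that
distinguishes continuing uptake from washout; the study reports sampled
values, not an organ model, so this form is the package's own.

Calibration, fixed at design time:

* Organs with published 1-min uptake (liver 15.8%, muscle 24.3%, heart
  content 7.4%, cortical bone 3.5%, brain 0.8%, pancreas 0.6% of injected
  activity) use an effectively instantaneous uptake rate (600/h) and a
  back-calculated `f_peak`, so the noise-free 1-min value equals the
  published mean exactly.
* Organs described as near-zero (testes, gallbladder, thymus, thyroid,
  lacrimal glands) have `f_peak ≤ 0.001`; delayed-uptake organs (kidneys,
  spleen, red marrow, salivary and lacrimal glands) have uptake rates
  placing their peak well after 1 min.  All other peak fractions respect the
  published upper bounds (<1% or <3% of injected activity over the scan
  period) and are otherwise the package's own choices.
* Urinary excretion is mono-exponential with `f_u = 0.368` and
  `lambda_b = 0.11737/h`: the curve passes exactly through the published
  session-3 cumulative fraction (14.8% at 263 min) with `f_u` bounded by
  whole-body mass balance (Σ f_peak + f_u ≤ 1); sessions 1 and 2 then come
  out at 7.18% and 11.62% against the published 7.2% and 11.4%.  A single
  exponential cannot pass through all three published points at once; the
  session-3 point is privileged because it is the calibration target of the
  cohort-level checks.
* Inter-subject variability is lognormal with **unit mean** (so cohort means
  stay on the calibration) and CVs derived from the published subject ranges
  via range ≈ ±2 SD for n = 6 (liver 4.9%, muscle 10.4%, urine 16%, …);
  measurement noise is multiplicative lognormal, default 5%, also unit mean.
* Sexes alternate (3/3 at n = 6); breasts/uterus/ovaries exist only for
  female subjects, testes only for males.  Injected activity is uniform on
  the published 210–228 MBq range.  Bladder volumes come from a 1.3 mL/min
  urine flow with 25% CV; bladder VOI concentrations divide the
  content-since-last-void by the session's measured volume, matching the
  study's bookkeeping.  Whole-blood concentrations are the blood-pool
  (cardiac content) curve divided by a 5.3 L blood volume, at the venous
  sampling schedule.

All randomness flows from a single `numpy` `SeedSequence`, spawned per
subject: the same seed gives a bit-identical cohort across processes.

What the generator does **not** emulate: image-level effects
(partial-volume, VOI misplacement, reconstruction noise correlations),
plasma metabolites, multi-compartment excretion, organ-mass variability, or
any covariance between organs within a subject.  Tests passing on this
generator therefore validate the pipeline's bookkeeping, estimators and dose
arithmetic — not the biological fidelity of any particular kinetic
parameter.

## Problem sizes and tolerances

Calibration checks run 200 replicate six-subject cohorts (1200 subjects, a
few seconds) and compare cohort means at 3 standard errors over replicates;
parameter-recovery checks use 300–1000 noisy realizations.  The bladder
closed form is verified to 1e-6 relative; the residence-time integrator to
1% of fine quadrature at the eight-point schedule; fits recover noise-free
parameters to 1e-6–1e-8 relative (solver-limited).  Dose reports round to
0.001 mGy/MBq in text output, the precision at which the two voiding
intervals give identical non-bladder organ doses.

## Known limitations

* Organ-level absorbed doses with the synthetic S table are structurally
  sensible but not quantitatively comparable to phantom Monte Carlo values;
  the published bladder-wall dose (0.012 mGy/MBq at 3.5 h) can only be
  matched with a real table.  The package instead verifies the
  interval ratio τ(3.5 h)/τ(1 h) ≈ 3.0, consistent with the published
  doubling of the bladder-wall dose once fixed cross-dose is included.
* Mono-exponential washout and excretion only; multi-exponential organ
  kinetics and multi-compartment urinary entry are out of scope.
* The effective dose uses ICRP-60 weights; ICRP-103 weights can be supplied
  via `weights_csv` but no ICRP-103 remainder logic is provided.
* No image/voxel simulation, no DICOM ingestion, no Monte Carlo transport.
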
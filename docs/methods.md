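# Methods

This note documents the models, numerical choices and limitations of
`barogeo`: what each stage computes, why its defaults are what they
are, and what the synthetic-data tests do and do not demonstrate.

## Signal stage

Raw multi-channel records (ECG, continuous blood pressure, respiratory
flow) are linearly detrended per channel; samples deviating from the
channel mean by ≥ 3 SD are treated as artifacts and **replaced by
linear interpolation** between neighbours rather than deleted —
deletion would break the uniform sampling grid that every later
windowing step relies on.  The same 3·SD edit is applied once more to
each extracted event series (ectopic beats, detection glitches), so
cleaning happens both before and after event detection.

R peaks are detected with a Pan–Tompkins-family detector (5–15 Hz
band-pass, squared derivative, 150 ms moving-window integration,
refractory distance 250 ms, fiducial refinement to the band-passed
extremum).  Breath onsets are negative-to-positive zero crossings of
the mean-removed flow low-passed at 1 Hz; "breath period" has no
universal onset convention, and the zero-crossing rule is deterministic
and phase-stable.  Per-beat SBP/DBP are the extrema of the pressure
wave in each inter-beat window `[t_i, t_{i+1})`; extrema are taken on
the outlier-repaired but *not* detrended pressure trace, because
detrending destroys the physical mmHg offset.

All four event series are linearly interpolated onto one common 1 Hz
grid spanning the interval from the latest first event to the earliest
last event (the synchronization contract), then decimated to 0.25 Hz
by a zero-phase 8th-order FIR low-pass (0.1 Hz cutoff) followed by
keeping every 4th sample.  Plain subsampling is never used: without the
anti-alias filter, cardiac-band power would fold into the respiratory
band.  The sub-space analysis runs entirely on the 0.25 Hz grid, the
rate at which respiratory-scale changes are observable, and the only
way the per-index (ΔBBI, ΔTT, ΔXv) triplet is well defined.

## Δ-series and sub-spaces

ΔX_n = X_{n+1} − X_n, z-scored **per subject and per series** (sample
SD, n−1).  Per-subject scope keeps subjects exchangeable and makes
thresholds comparable across subjects; a pooled-normalization mode is
not provided because pooled scaling would leak cohort composition into
single-subject features.  The vascular threshold is
Th = α·(max ΔXv − min ΔXv)/2 with α = 0.15; samples exactly at ±Th
belong to the no-change band (boundary inclusive on both sides).  The
threshold is recomputed per subject.  Both drivers (ΔSBP, ΔDBP)
produce independent partitions, and every downstream feature exists
per driver.

## Polygon model

The containment rule — "a polygon containing 95% of the points" — is
underdetermined; the implemented rule is: keep the ⌈0.95·n⌉ points
nearest (Euclidean) to the cloud mean, ties broken by point index, and
take their convex hull.  This is deterministic, rotation- and
translation-invariant, and produces the convex outline minus extreme
points that the method's scatterplots show.  Area and centroid follow
the shoelace formula (signed area internally; the reported area is the
absolute value, so vertex orientation never matters).  The morphology
comes from the centroid fan: triangle i is (C, V_i, V_{i+1}) with area
Ar_i, angle β_i at the centroid, θ_i defined as the **mean of the two
base angles** at V_i and V_{i+1} (the "vertex angle" is ambiguous for a
fan triangle; the mean of the base pair is symmetric under vertex
relabelling), and occupancy = number of kept points inside the
triangle, boundary points assigned to the lowest-index triangle so the
occupancies always sum to the kept count.  Fewer than 4 points, or a
collinear cloud, yields a degenerate model: area 0 and all morphology
indices missing (NaN), never imputed.

## Index inventory (168)

Per driver (2) × sub-space (3): 8 statistics for ΔBBI and 8 for ΔTT
(m, sd, K, Sk, IQR, CV, occupancy probability p, mean absolute
deviation d) plus 10 joint polygon indices
(A, An = A/points, Av = A/vertices, n = vertex count, dc = mean
sample–centroid distance, θ, β, θβ = θ−β, pr = mean per-triangle
occupancy, Ar = mean triangle area): 26 × 6 = 156.  The remaining 12
are the six descriptive statistics applied globally to ΔSBP and ΔDBP.
The global statistics are computed on the **unnormalized** Δ-series:
after z-scoring, the global mean and SD are fixed at 0 and 1 by
construction and a global CV would divide by a numerically-zero mean.
Kurtosis is non-excess (a normal distribution scores 3); skewness is
the Fisher moment coefficient; quantiles use linear interpolation.
Note that ∆BBIp and ∆TTp within one driver/sub-space coincide by
construction (occupancy is a property of the driver partition); the
schema keeps both names so every block is uniform.
Occupancy p is sub-space occupancy (a scalar per sub-space, which is
what a screened classifier input must be); per-triangle occupancy
lives in ∆XYpr.

## Screening and classification

Mann–Whitney U, two-sided: exact enumeration when n₁+n₂ ≤ 12 without
ties, otherwise normal approximation with tie and continuity
corrections.  Significance at p ≤ 0.05.  Significant indices are paired
when |Spearman ρ| < 0.7 — the conventional collinearity cut;
configurable.  Each pair feeds soft-margin SVMs (precomputed Gram
matrices; the scikit-learn SMO solver) over Gaussian, Laplace and
ANOVA kernels with default grids C ∈ {0.5, 1, 2.2, 5, 10},
σ ∈ {0.5, 0.8, 1, 1.5, 2, 3}, d ∈ {1, 2, 3}, chosen to bracket the
optima this family of problems reports (C ≈ 1–5, σ ≈ 0.8–2).
Features are standardized with training-fold statistics only.

Two validation protocols exist because they answer different
questions.  **paper mode** screens once on all subjects and then
grid-searches pairs by LOOCV accuracy — the protocol of the original
study, retained for fidelity, with the known optimistic bias of
selecting on the same data that is cross-validated.  **honest mode**
(default) repeats the entire selection inside every training fold:
screening, pair choice (lowest combined p among admissible pairs) and
hyperparameter choice (maximal training accuracy, ties broken by fewer
support vectors, then kernel order, then smaller C, σ, d) see only the
n−1 training subjects, and the held-out subject is predicted by that
fold's model.  Nested inner cross-validation is deliberately out of
scope; training accuracy is the in-fold selector.  The label-shuffle
test in the suite confirms honest-mode accuracy sits at chance under
the null.  The honest-mode report describes the modal per-fold
selection; per-fold choices are retained in the results object.
A `max_pairs` cap (default 10, ranked by combined screening p-value)
bounds the candidate set; `None` restores an exhaustive search.

Sensitivity is reported for the *positive* class: the patient group in
patient-vs-control comparisons, and the second-listed group otherwise;
an explicit `positive=` argument overrides.  Metrics satisfy
acc = (TP+TN)/n, sn = TP/(TP+FN), sp = TN/(TN+FP) by construction.
Subjects missing either feature of a pair are excluded from that
pair's evaluation and counted in the report.

## Synthetic generator

The generator emulates 15-minute resting supine recordings at the
beat/breath level.  Per-beat SBP is an AR(1) process (φ = 0.8,
innovation SD 3 mmHg) around a subject-specific set point
(120 ± 8 mmHg across subjects) with a 1.5 mmHg respiratory
modulation; DBP follows at a 40 mmHg pulse-pressure offset.  The heart
period (900 ± 40 ms across subjects) responds to the previous beat's
SBP deviation with a baroreflex gain (default 4 ms/mmHg, pressure rise
→ interval lengthening), carries a 25 ms respiratory sinus arrhythmia
and AR(1) noise (25 ms, φ = 0.8).  Breath cycles last 3.6 ± 0.3 s
across subjects with 0.25 s breath-to-breath jitter, and each new
cycle length responds to the standardized change in mean SBP between
the two preceding breaths with gain `tt_sbp_gain_s` — the respiratory
arm of the baroreflex.  Both couplings are first-order linear: the
simplest mechanism that produces the sub-space-conditional contrasts
the indices measure.

Because per-subject z-scoring erases any pure variance scaling (every
subject's ΔBBI has unit SD by construction), group contrasts must be
**coupling-mediated**: raising the respiratory gain drives the
SBP-∆TTm-d index negative (breathing speeds up while pressure falls),
and raising the baroreflex gain lowers SBP-∆BBIsd-nc (cardiac
variability conditional on stable pressure shrinks when ΔBBI is slaved
to ΔSBP).  Group effect sizes (`tt_effect`, `brs_effect`) are defined
in units of the between-subject SD of those downstream indices under
default conditions; the mapping constants (0.115 s gain per TT-index
SD, 2.2 ms/mmHg per BBI-index SD) were fixed once by a reference
calibration run of the default cohort through the full pipeline and
are frozen in `simulate.py`.  The TT response saturates above roughly
3 effect-SD, so large nominal effects are compressed.

Raw waveforms, when requested, are rendered from the event truth:
Gaussian QRS/T templates at beat times, per-beat pressure pulses whose
extrema equal the injected SBP/DBP, and a phase-continuous sinusoidal
flow.  Default raw sampling rate is 250 Hz — ample for R-peak timing at
the millisecond scale — with the rate configurable upward for fidelity
runs.  The generator does **not** model waveform pathology (ST
changes, ectopy, pulsus alternans), hemodynamic PDEs, or nonstationary
autonomic drift; passing tests demonstrate that the pipeline recovers
what the generator injects, not that the indices behave identically on
clinical recordings.

## Test problem sizes

The suite's cohort-level checks use 20 + 20 subjects × 20 replicate
cohorts for effect recovery and null calibration, and 15 + 15 × 10
seeds for the end-to-end model search — sizes at which the planted
1-SD contrast has ≈ 85–90% detection power and a full honest-mode
model search runs in seconds per cohort.  The null-calibration check
compares the **median per-replicate** false-positive fraction against
the binomial 99% band for 168 tests at level 0.05: the indices are
mutually correlated, so a pooled count over replicates × indices would
be over-dispersed relative to a binomial reference, while the median
of per-cohort fractions is robust to that correlation.

## Known limitations

* The containment polygon is convex by construction; concave point
  clouds are summarised optimistically (alpha-shapes are out of scope).
* The θ angle definition (mean base angle) is one of several readings
  of "the angle at the vertex with the centroid"; an alternative
  single-vertex convention would shift θ and θβ systematically but
  consistently across groups.
* Honest-mode hyperparameter selection by training accuracy can
  under-regularize on very small folds; with ≲ 10 subjects per group,
  paper-mode results should be read as optimistic and honest-mode ones
  as noisy.
* WFDB/EDF readers are not included; raw records enter via CSV
  (columns `time_s, ecg, bp, rf`), event series via tidy CSV.
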
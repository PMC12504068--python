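# Methods

This note documents the measurement conventions, the synthetic-data model,
the numerical choices, and the known limits of what the test suite shows.

## Geometric measurements

A contour cine is `F` frames × `P` ordered 2-D points (mm); x is
anterior(+)/posterior(−), y cranial(+)/caudal(−).  Only the points inside
the per-patient `cti_index_range` (half-open; default: IVC midpoint index
`(P−1)//2` to the TV-side contour end) enter any CTI metric.  Which contour
indices delimit the CTI is genuinely not derivable from the point export,
so it is explicit metadata with a configurable default.

* **Curvilinear length** — sum of consecutive point distances of the CTI
  polyline; the primary length for all kinetic quantities.
* **Linear length** — distance between the two CTI endpoints, reported in
  RA diastole.
* **Pouch depth** — maximum perpendicular distance of interior CTI points
  from the *infinite* line through the endpoints (the same line that
  defines the linear length), reported in RA diastole.  Using the infinite
  line rather than the segment keeps the quantity consistent with the
  linear-length construction.
* **Phase frames** — RA systole is the frame of minimal CTI curvilinear
  length, diastole the maximal one, ties to the earliest frame.  Image
  data offers no ECG gating at this level; the length-extreme criterion is
  the one convention that makes elongation and NE internally consistent,
  and it is recorded in every geometry output (`phase_criterion`).
* **NE** = (L_dia − L_sys)/L_sys, reported unrounded; cohort summary tables
  round to one decimal.
* **Median split** — even cohorts use the midpoint of the two central order
  statistics; the rule is strict (`< threshold` → low group).  An explicit
  exclusion list supports removing flagged outliers before the median is
  computed.

## Kinetics

Per point: trajectory differentials Δₙ = pos(tₙ) − pos(tₙ₋₁) (n = 2..F),
instantaneous velocities Δₙ/Δt, net displacement (last − first frame), and
maximum displacement per axis relative to the *first* frame,
`max_n |coord(t_n) − coord(t_1)|`.  The cine is cyclic, so net displacement
is ≈ 0 and uninformative; segmental summaries therefore average the
per-point maxima.  The first frame is the reference because it is the only
anchor every cine defines.  When no frame interval is recorded, Δt defaults
to one cycle at 68 bpm divided by F (0.0353 s at F = 25), the cohort-mean
heart rate the generator also uses.

The CTI is partitioned into five contiguous segments of near-equal size;
remainder points are assigned TV-side, where motion is larger and finer
sampling is conservative.  Motion phenotypes: amplitude A = mean over
segments of the mean maximum Euclidean displacement; ratio R = mean AP
max / mean CC max; hypokinetic if A < t_low, hyperkinetic if A > t_high
(defaults: cohort quartiles, making the labels cohort-relative), otherwise
AP-dominant if R ≥ 0.5 falls above the band and CC-dominant below
(r_lo = 1/2, r_hi = 2); AP wins the in-between band because AP motion
dominates this anatomy.

## Statistics

Spearman (average ranks, t approximation with n−2 df), point-biserial
(≡ Pearson with 0/1 coding), and two-sample KS with the asymptotic
two-sided p-value only — at the n ≈ 30 cohort scale its measured size is
~4% at nominal 5%, verified by simulation in the acceptance suite.  Ordinal
covariates are binarized before the point-biserial test (NYHA ≥ 2,
BMI ≥ 30 kg/m² by default).

The EC comparison pools per-point, per-transition values (dx, dy, vx, vy)
across patients by EC status.  Pooled points within a patient are not
independent; the pooled p-values are calibrated only under an
exchangeable-patients null, which is how the acceptance suite tests them
(all patient-level draws degenerate).  A `pooling="patient"` option reduces
each patient to a mean absolute value first for heterogeneous cohorts.

## NE clustering

1-D k-means (Lloyd, best of 10 restarts, fixed seed) on patient NE.  The
elbow is formalized as the k (2 ≤ k ≤ k_max−1) maximizing the second
difference of **log** WCSS.  On the linear scale the first large drop of
the curve dominates the curvature and the rule collapses to k = 2–3 even
for clearly separated groups; log-scale curvature measures *relative*
drops and recovers the group count in the regime that matters here (three
compliance groups plus one extreme outlier).  A manual `k_override`
supports visual selection.  Clusters of size ≤ 1 are flagged as outliers
and removed; remaining clusters are renamed low / intermediate / high by
ascending centroid *without* re-clustering (removal-then-analysis
workflow).  With three group means (0.29/0.72/1.23) at sd 0.12 and
n ≈ 10 per group, the 3-vs-4 elbow decision is intrinsically ambiguous in
roughly one cohort in five (the groups sit ~3.5 σ apart); the clustering
suite therefore asserts a ≥ 70% three-group recovery rate with ≥ 90%
correct membership among recovering cohorts, and this ambiguity is a known
limitation, not an implementation defect.

## Prediction

* **EC classifier** — ridge-penalized logistic regression on the
  concatenated trajectory-differential vectors of one CTI segment
  (axis x, y, or per-transition Euclidean norm).  One observation per
  (patient, segment); the train/test split (70/30) is grouped by patient to
  prevent within-patient leakage.  Default C = 0.01: with ~120 features
  and ~22 training patients, strong shrinkage is required.  Confusion
  matrices are reported as (TN, FP, FN, TP) on the held-out set.
* **Lasso length models** — target systolic (or diastolic) curvilinear
  length; features: the complementary curvilinear length, pouch depth,
  linear length, and optionally the EC / smoker / dyslipidaemia flags.
  Features are standardized before the penalty; coefficients are reported
  on both scales.  α = "cv" minimizes mean squared CV error over 10
  shuffled folds (fixed seed); MAE and R² come from cross-validated
  held-out predictions with the same folds.  α = 0 is solved as OLS.
  Solutions are verified in the tests against the stationarity (KKT)
  conditions of the objective to 1e-6.

## Synthetic cohort generator

The generator emulates the statistical structure of a ~32-patient atrial
flutter ablation cohort.  Per patient it draws: diastolic-baseline CTI
length (N(40, 11.4) mm, truncated), pouch depth (N(3.2, 2.0) mm), smoker
and dyslipidaemia flags (each 53%), EC flag (47%), BMI N(29, 4), age
N(66, 10), NYHA class, procedural time (N(44.8, 22.5) min, −12 min for EC
patients, reflecting the shorter-procedure trend in cardioverted patients)
and ablation duration (N(18.9, 10.5) min).

**Baseline geometry.** The CTI span is a shallow parabolic pouch between
the IVC critical point (origin) and the TV end, its chord solved (Brent)
so the CTI polyline length equals the drawn baseline length; the non-CTI
half of the RA wall is a circular arc closing upward.  The CTI chord lies
along x, reproducing the anterior–posterior dominance of CTI motion.

**Motion.** Every point moves along a fixed vector with a raised-cosine
phase profile φ(n) = sin²(πn/F) normalized to exactly 1 at frame F//2 and
0 at frame 0; the virtual frame F coincides with frame 0 (cyclic cine).
Two modes:

* *Contraction mode* (segment amplitudes `None`): uniform scaling of the
  contour toward the IVC anchor reaching the patient's contraction ratio
  s at peak; polyline lengths scale exactly, so ground-truth
  NE = 1/s − 1 holds to machine precision.  Per-patient NE is drawn from
  a three-group mixture (means 0.29/0.72/1.23, sd 0.12) unless a fixed
  ratio is configured.
* *Amplitude mode* (default): the per-axis peak excursion of each CTI
  point is pinned to its segment's configured amplitude — AP defaults
  (8.1, 10.375, 12.65, 14.925, 17.2) mm and CC (1.6, 2.325, 3.05, 3.775,
  4.5) mm, i.e. the observed segment-1 and segment-5 cohort means with
  linearly interpolated interior segments — directed away from the static
  IVC anchor (TV side stretched forward, CC motion cranial).  The
  configured gradients are then realized exactly in the noise-free cine,
  while elongation, NE and phase ordering are emergent and recorded in
  the ground truth after construction.  A single displacement field
  cannot pin both the segmental displacement gradient and the length
  ratio, which is why the two modes exist; each exactness guarantee holds
  in its own mode.

**Heterogeneity.** A per-patient kinetic scale multiplies all motion:
log-additive covariate effects (smoker ×0.65, dyslipidaemia ×0.65, BMI
−0.06/unit, age −0.008/yr, NYHA −0.05/class, lognormal residual sd 0.30)
and an EC stunning attenuation (×0.6 by default, configurable) for
cardioverted patients.  Scales are renormalized to unit cohort sample
mean, so configured segment amplitudes are *cohort-calibrated means* — the
quantity a cohort table reports — rather than per-patient constants.
Effect sizes were set so that cohort point-biserial correlations between
NE and EC/smoking/dyslipidaemia/BMI land near −0.3 with negative sign in
≥ 95% of cohorts, the association structure the generator emulates.
Finally, i.i.d. Gaussian noise (sd 0.5 mm per coordinate per frame) models
delineation error.

**What the generator does not emulate.** Real contour software propagates
contours with temporally correlated errors, real wall motion is not a
single-phase raised cosine, covariates are assumed independent (their true
covariance is unknown), and in amplitude mode NE is emergent rather than
prescribed, with cohort-mean NE lower than in contraction mode.  Passing
recovery tests therefore demonstrates pipeline correctness under a
known-truth phenomenological model, not clinical validity on real cines.

One measurement property worth knowing: the maximum-displacement estimator
`max_n |coord(t_n) − coord(t_1)|` is positively biased under i.i.d. point
noise (the maximum of noisy near-peak frames), by ≈ +0.3 mm at 17 mm
amplitudes and ≈ +0.5 mm at 4.5 mm amplitudes for 0.5 mm noise and 25
frames.  Recovered cohort displacement means sit above the configured
amplitudes by exactly this bias; it vanishes at zero noise.

## Problem sizes

The test and acceptance runs use 200-patient cohorts for displacement
calibration, 32-patient cohorts (the emulated study size) for statistical
and prediction experiments, 2000 null simulations for test-size
calibration, and 40–100 repeated cohorts for rate assertions; these sizes
keep every Monte-Carlo rate stable at the asserted margins.
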
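# Methods

## Scope and model

The package derives personalized TMS stimulation coordinates in the
left DLPFC from resting-state BOLD data, under the standard circuit
model in which the therapeutically relevant DLPFC site is the one most
*anticorrelated* with the subgenual anterior cingulate (sgACC).  Two
algorithms are implemented against a common volumetric substrate
(NIfTI-1 volumes, RAS+ world coordinates in mm, 0-based voxel indices
internally; all distances computed in world mm, never voxel units),
together with reliability metrics for the 2-day × 2-phase-encoding
four-run design, permutation inference, and a symptom-association
analysis.

### Denoising pipeline

Order is fixed: Gaussian smoothing → nuisance regression → ideal FFT
band-pass.  Defaults: FWHM 5 mm, 6 motion parameters plus
backward-difference derivatives (first row zero) when supplied, 5
white-matter + 5 CSF principal components (aCompCor), band 0.01–0.1 Hz.

* Smoothing uses reflective boundaries, so constant volumes are exactly
  invariant; σ = FWHM / (2√(2 ln 2)) converted per-axis to voxels.
* aCompCor components are extracted from the **unsmoothed** data.
  Smoothing first would smear gray-matter signal into the tissue masks;
  on small synthetic tissue compartments the first WM component then
  becomes a near-copy of the global signal (r > 0.99) and the nuisance
  step silently performs global signal regression.  Extracting before
  smoothing, as standard pipelines do, keeps GSR an explicit, separate
  choice.
* GSR, when enabled, adds the brain-mean series as an extra column of
  the *same* nuisance regression rather than a sequential second
  regression, so no removed variance is reintroduced.  Residuals are
  exactly orthogonal to every confound column; the regression is
  idempotent.
* The band-pass zeroes Fourier coefficients outside [low, high] Hz and
  removes the mean.  The hard cutoff makes the in-band/out-of-band
  contracts exact for bin-centered components; finite-length tones off
  the Fourier grid leak spectrally, which is a property of the data,
  not the filter.

### Seed-based algorithm (RSA)

Per subject: (1) sgACC seed map = Pearson correlation of the mean sgACC
series with every brain voxel; (2) population weight map = NaN-aware
voxelwise mean of individual maps (a voxel is NaN only if NaN in every
subject; raw r averaged by default, Fisher-z averaging available);
(3) sgACC representative signal = mean over brain voxels outside the
DLPFC of weight × time series, signed weights used as-is; (4) DLPFC
voxels ranked ascending by correlation with that signal — the most
anticorrelated fraction (default 0.5, sweepable 0.1–1.0) is retained,
round-half-up, ties broken by linearized voxel index; (5) target =
unweighted centroid of the largest 26-connected retained cluster (6/18
configurable; size ties broken by the component containing the lowest
linearized voxel index).

Retained sets are nested across the fraction sweep by construction.
"Ascending" retention encodes the anticorrelation premise; the opposite
ordering is available for sensitivity analysis.

### Hierarchical clustering algorithm (HCA)

Per region (DLPFC and sgACC separately): pairwise Spearman distance
1 − ρ between voxel series; spatially constrained agglomerative
clustering from singletons, merging the adjacent cluster pair with the
smallest **average linkage** (maintained by the Lance–Williams update,
hence always the mean of the original pairwise distances) until the
minimum adjacent-pair linkage exceeds 0.5.  Two clusters are adjacent
iff any cross-pair of member voxels is adjacent (26-connectivity by
default).  Disconnected mask components can never merge.  All
tie-breaks (merge order, representative voxels, composite winners) use
the lowest linearized voxel index / lowest cluster id, making the
result invariant to voxel enumeration order.

Subunit summaries: median time course (elementwise median), the
representative voxel is the member best Pearson-correlated with it;
concentration = size / mean pairwise world-mm distance, defined as 0
for singletons (no pairs exist; this deliberately penalizes degenerate
one-voxel "clusters").

Scoring: for DLPFC subunit *i*, the weighted correlation sum is
Σ_j r_ij·n_j over sgACC subunits (representative-voxel Pearson
correlations, sgACC sizes n_j).  The three parameters — weighted sum,
concentration, size — are z-scored (sample SD) across DLPFC subunits
and summed into the composite.  **The weighted-correlation column
enters the composite negated** (z-score of −Σ r·n): the circuit model
seeks the *anticorrelated* subunit, and scoring raw correlation high
would select the subunit most positively coupled to sgACC, the exact
opposite of the therapeutic premise.  A zero-variance parameter column
yields zeros rather than NaN.  A single DLPFC subunit is an error
(z-scores undefined) that signals a mask/threshold problem upstream.

Where the procedure says only "correlation", Pearson is used; Spearman
is reserved for the within-region distance matrices where it is
explicit.  Linkage choice (average) and adjacency (26) are recorded in
target provenance.

### Reliability metrics

With targets T(day, phase) and d = Euclidean distance in mm:

    IntraDD = (d(T1LR, T1RL) + d(T2LR, T2RL)) / 2
    InterDD = (d(T1LR, T2RL) + d(T1RL, T2LR)) / 2
    IntraPD = (d(T1LR, T2LR) + d(T1RL, T2RL)) / 2
    InterPD = InterDD        (identical defining pairs)

plus the six-pair mean over all C(4,2) run pairs.  InterDD ≡ InterPD is
asserted in code: the two names exist because the day×algorithm and
phase×algorithm factorial decompositions use the same quantity in
different roles.  Variability reports use sample SDs (n−1; four runs,
inferential use).  Discriminability: intra = mean of the 6
within-subject pair distances; inter = flat mean over all other
subjects of the 4 matching-(day, phase) distances; ratio = inter/intra,
+∞ (flagged) when intra is exactly 0.  The "reliable subject" summary
counts six-pair means below 10 mm.

### Permutation inference

Every comparison is within-subject, so the null is built by independent
sign flips of paired differences; the default statistic is the median
difference (medians are the reported effect summaries), the mean is
available.  Two-sided p with the add-one estimator
(1 + #{|T_perm| ≥ |T_obs|}) / (n_iter + 1): never zero, observed
statistic always in its own null.  All-zero differences short-circuit
to p = 1 with a degenerate flag.  The 2×2 factorial tests sign-flip
(a) the per-subject difference of factor-B-averaged values (main effect
A), (b) symmetrically for B, (c) the double difference for the
interaction.  Bonferroni: α/m (0.05/3 ≈ 0.0166, 0.05/4 = 0.0125).
Default 10,000 iterations; a seeded PCG64 generator is mandatory and
recorded in every result.

### Symptom association

8-mm spherical ROI around each subject's target; ROI-mean series
correlated with every sgACC voxel (Fisher-z by default, |z| capped at
atanh(1 − 1e−7); the transform never changes a sign).  Voxelwise OLS of
score ~ intercept + FC + age + sex; t and two-sided p for the FC
coefficient with n − 4 df.  Cluster-extent correction: suprathreshold
voxels (p < voxel_p, default 0.001) split by t sign, 26-connected
components, k ≥ 4 in small-volume mode and k > 18 (strict) in
whole-brain mode — fixed defaults standing in for smoothness-based
Monte-Carlo thresholds, with an optional permutation null (scores
shuffled across subjects, 95th percentile of the max null cluster size)
as a data-driven alternative.  Sex is coded {0, 1}.

## The synthetic generator

Cohorts of four runs per subject ((day, phase) ∈ {1,2} × {LR,RL}) on a
24³ grid of 2-mm voxels (TR 0.72 s, nt 300 — a deliberately scaled-down
acquisition that keeps a full pipeline run in seconds on one CPU).
Masks are geometric primitives written as real NIfTI so the I/O path is
exercised end to end: a 21-mm brain sphere; an elongated capsule DLPFC
(all voxels within 6 mm of a 16-mm segment — an extended search region
in the spirit of the multi-sphere union masks used on real data);
spheres for sgACC (r 6), WM (r 5), CSF (r 4); gray matter = brain minus
WM/CSF.

Signal model per subject: one band-limited (0.01–0.1 Hz) unit-variance
latent sgACC signal s(t); sgACC voxels carry s plus noise; a planted
4-mm blob at the DLPFC capsule's middle couples at strength c (default
−0.8; per-subject jitter SD 0.1) via x = c·s + √(1−c²)·η with η
band-limited; all other voxels get iid background couplings
(SD 0.15) — the ~5-mm spatial correlation length of real connectivity
maps then arises from the pipeline's smoothing step, exactly as for
real EPI data.  Couplings are perturbed per acquisition day (SD 0.05),
making same-day runs more alike.  Data are written as
baseline 1000 + 20 × signal, giving realistic tSNR.

The global-signal component required three properties to behave like
its real counterpart, and each is load-bearing:

1. **Spatially heterogeneous loading** (mean 1, SD 0.5): a uniform
   shared component shifts every seed correlation equally and can never
   reorder a ranking.
2. **Smooth (12-mm FWHM) and redrawn per run**: a loading pattern fixed
   across runs biases targets without destabilizing them, and a
   spatially white pattern is averaged away by centroid extraction;
   only a session-varying, spatially coherent pattern moves the
   retained-cluster centroid between runs — which is also the mechanism
   the reliability literature attributes to the global signal.
3. **Expressed in gray matter only**: were it present identically in
   WM/CSF, aCompCor would already remove it and GSR would be moot,
   contrary to the real-data fact that WM/CSF components do not capture
   the gray-matter global signal.

The default amplitude 0.06 leaves the global component ~15 % of
post-smoothing gray-matter variance (voxel-to-global-mean correlations
≈ 0.4–0.5), the residual level typical after nuisance regression.  The
**global-heavy condition** (`global_heavy_spec`) raises the amplitude
to 2.0 *and* weakens the planted coupling to −0.25 — the realistic
magnitude of individual sgACC–DLPFC coupling.  Both changes define the
condition: with a dominant −0.8 blob the retained cluster is anchored
and no contamination can destabilize the centroid, so the GSR
reliability effect is only expressible on a shallow anticorrelation
landscape.

Symptom cohorts exist at two levels: full-volume cohorts whose scores
follow intercept + slope × (true noiseless blob coupling) + age/sex
effects + noise, and connectivity-level cohorts (`simulate_fc_cohort`)
that generate per-sgACC-voxel FC vectors directly with a planted
compact cluster — the regression-level construction used for recovery
and calibration checks at n = 60, where simulating 4D volumes would add
nothing but runtime.  Its default noise levels are deliberately small
(score noise 0.1, per-voxel FC noise 0.02: slope SE ≈ 0.09, attenuation
< 2 %): a high-signal regime for recovery checks, not a realistic
clinical effect size.

### What passing tests do and do not show

The generator emulates the acquisition *structure* (runs, days, phase
labels, geometry, metadata) and the *mechanisms* the algorithms depend
on (planted anticorrelation, heterogeneous background, session-varying
global signal, day effects).  It does not emulate head motion, EPI
distortion, hemodynamic convolution, anatomical variability, or
realistic between-subject anatomy — so passing recovery tests show the
algorithms find planted structure under controlled noise, not that
they attain any particular accuracy on real cohorts.  Reliability
magnitudes here (a few mm) are not comparable to real-data values
(~10 mm medians): the synthetic search region is an order of magnitude
smaller than a real DLPFC mask, which bounds how far targets can
wander.  Directional and comparative conclusions (GSR improves
seed-based reliability; recovery rates; calibration of the tests) are
the meaningful outputs.

## Problem sizes used in tests and the reproduction script

Chosen to exercise every code path at desk scale: recovery studies use
5 subjects × 4 runs (24³ grid, nt 300); the GSR study 10 subjects; the
symptom study n = 60 subjects at the connectivity level with 20
replicates; permutation calibration 500 null replicates of n = 30 pairs
at 1,000 iterations (10,000 iterations wherever a single test is
reported).  Oracle-equivalence checks run 100 random instances each
(≤ 12-voxel masks for clustering; 12³ volumes at all three
connectivities for component labeling).

## Known limitations

* Average linkage, 26-connectivity, Pearson-for-unspecified-correlations
  and ascending retention are defensible defaults for genuinely open
  choices; all are configurable and recorded in target provenance, but
  alternative settings may move targets on real data.
* The fixed cluster-extent defaults (k ≥ 4, k > 18) inherit their
  calibration from smoothness assumptions that synthetic data does not
  reproduce; the permutation null is the principled in-package
  alternative.
* `read_volume` trusts NIfTI headers for TR and affine; no slice-timing
  correction is provided (synthetic data is generated "already
  corrected", and short-TR multiband data rarely needs it).
* The inter-subject discriminability mean is a flat mean over
  subject-pairs × runs; averaging per subject-pair first would weight
  subjects differently when cohorts are unbalanced.
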
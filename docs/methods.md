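# Methods

This note documents the models, conventions and numerical choices behind
`movieloc`, in the order data flow through the package.

## Conventions

Voxel linear indices are 0-based, C-order (`numpy.ravel` defaults) and are
the serialization format for ROIs; TR indices are 0-based internally and
1-based in all user-facing reports (events JSON, spike-regressor names).
A TR (repetition time) of 2 s and a 168-TR movie run are the defaults
throughout. A config-supplied TR overrides the NIfTI header TR with a
logged warning, because header TRs in pediatric datasets are often wrong.

## Preprocessing

Stages run strictly in this order: artifact detection → nearest-neighbor
interpolation → nuisance regression → high-pass filter → ROI averaging →
NaN-ing of artifact TRs. Interpolating before regression and filtering
keeps artifact energy from leaking through the linear operators; NaN-ing
last keeps the per-TR record aligned across subjects.

* **Composite motion.** The toolbox convention this follows reports a
  scalar displacement per TR: rotations (radians) are converted to
  worst-case surface displacement on a 65-mm-radius head sphere, and the
  composite is the Euclidean norm of the six converted parameter deltas
  between consecutive TRs. A TR is an artifact if this exceeds 2 mm
  (strict inequality), or if the global signal (mean over the union of
  parcels, unless a brain mask is supplied) deviates more than 3 sample
  SDs from its run mean. The mean and SD are computed over the full run,
  candidate artifacts included — simple and deterministic; an
  exclude-then-recompute variant is not offered. TR 0 can only be flagged
  by the global-signal criterion. Subjects with ≥ 1/3 artifact TRs fail QC.
* **Interpolation.** Flagged TRs take the value of the nearest unflagged
  TR; ties break toward the earlier TR (deterministic).
* **Noise components.** The component-based correction takes the
  white-matter mask eroded by two voxels (6-connectivity, grid boundary
  counts as outside), interpolates artifact TRs in the voxel × T matrix
  ("scrubbed"), removes each voxel's temporal mean, and keeps the first 5
  right singular vectors as unit-norm, exactly zero-mean, mutually
  orthogonal component timecourses, variance-ordered. Sign is fixed by
  making each component's largest-magnitude spatial loading positive, so
  reruns are bit-identical. Singular values at numerical noise level mark
  degenerate components, which are dropped with a warning.
* **Nuisance regression.** Per voxel, OLS on [intercept, one indicator
  column per artifact TR, the noise components]; residuals are exactly
  orthogonal to every retained column. Rank-deficient nuisance matrices
  are handled by pseudo-inverse with a warning.
* **High-pass.** Realized as regression on a discrete-cosine basis: all
  cosines with frequency below 1/cutoff (default cutoff 100 s), plus the
  mean. This is the dominant fMRI convention for a "100 s cutoff", exactly
  linear, and trivially testable against projections computed by hand. At
  T = 168, TR = 2 s it removes 6 cosine components.

## Localizer GLM

Condition boxcars are built on a 10× oversampled grid (block onsets need
not be TR multiples — 19.8-s blocks are not), convolved with a
double-gamma hemodynamic response and decimated at TR times. The kernel's
response gamma peaks at exactly 6 s and the undershoot gamma at 16 s
(scale 1, so shapes 7 and 17), undershoot ratio 1/6, peak-normalized.
Fits are plain OLS — no prewhitening; the synthetic data carry no AR
structure beyond what the generator smooths in, and the type-I tests
confirm the t statistics hold their nominal level there. Missing
(NaN-ed) TRs are deleted listwise from data and design. Contrast t values
use the textbook formula with df = n_used − rank(X); voxels with residual
variance below 1e−12 get t capped at ±1e6 and a degeneracy flag, keeping
the ranking total in noiseless limits.

## ROI definition

* **Traditional / counter ssROIs**: parcel voxels ranked by the localizer
  contrast t (faces>objects for FFA and pSTS, scenes>objects for OPA, PPA,
  RSC, objects>scrambled for LOC, scrambled>objects for EVC); top 100 are
  the ssROI, bottom 100 the counter ROI. Ties break by ascending linear
  index; parcels smaller than k return everything with a warning.
* **Movie ssROIs**: per-voxel OLS of the cleaned movie timecourse on an
  intercept plus the 14 predictors (7 region + 7 counter mean timecourses
  from other subjects' traditional ROIs), contrast per the region table
  (FFA>LOC, pSTS>LOC, OPA>LOC, PPA>LOC, RSC>LOC, LOC>EVC, EVC>LOC), top
  100 by t. The regression includes an intercept — without one, mean
  offsets would masquerade as selectivity. Predictor columns are ordered
  deterministically (contrast columns first, remaining names sorted) and
  pruned greedily when collinear, with a warning; this makes the selection
  invariant to the order predictors were supplied in, and makes the exact
  noiseless limit (counter = −w × region latent) well-posed. Counter
  predictors are strongly anticorrelated with their region predictors by
  construction (≈ −0.95 on synthetic cohorts); they are covariates, not
  contrast terms, so the induced variance inflation is shared across
  voxels and does not disturb the within-parcel ranking.
* **Split-half splice**: half A = TRs 1–82 (1-based), guard = TRs 83–85
  (never analyzed), half B = TRs 86–168. ROIs defined on each half;
  half-A timecourse extracted from half-B-defined ROIs and vice versa;
  concatenated length 82 + 83 = 165 TRs. Split point, guard width and k
  are config keys.
* **Leave-one-out hygiene**: a subject's own data contribute to no
  predictor used on them; provenance (contributors, left-out id) is
  recorded on every predictor set and asserted structurally in tests.
* **Hemispheres**: parcels are treated as already-bilateral masks.
  Per-hemisphere definition is supported by passing left/right parcels
  and averaging the resulting timecourses at the timecourse level.

## Reverse correlation

Subject region timecourses are z-normalized (sample SD, missing entries
preserved); each TR's group values are tested against 0 with a one-tailed
one-sample t-test; events are maximal runs of ≥ 2 consecutive significant
TRs (≥ 4 s — single-TR blips are discarded as unreliable). α defaults to
0.05, uncorrected and one-tailed, exposed as a config key and echoed in
every output header. TRs with fewer than 3 contributing subjects are
defined non-significant rather than erroring, since artifact NaNs make
ragged group matrices routine. Under an iid null the expected number of
events is p²(1 + (T−2)(1−p)) — the run-start counting argument — which the
calibration suite checks against simulation. Event responses are means of
a subject's z-scored timecourse over the event-TR union; age trends use
Spearman partial correlations (midranks for ties, residual method on
ranks, t approximation with n−3 df) controlling for the number of
artifact timepoints, which is not normally distributed.

## Inter-regional correlations

Correlations are Pearson over pairwise-complete TRs (artifact NaNs differ
per subject), with the pair count reported so downstream tests can weight
or filter. Fisher z = atanh(r) with r clipped at 1−1e−15 and a degeneracy
flag, keeping group statistics total. Partial correlations residualize
both series on [intercept + other targets] over the common complete TRs —
equivalent to the precision-matrix formula for complete data, and the
test suite proves the equivalence numerically. A series numerically inside
the span of the covariates has no unique variance left; its partial
correlation is 0 by convention, flagged. Lag shifts move a series earlier
(shift −1: output TR t takes input TR t+1) or later, with vacated TRs set
missing. All reported p values are two-sided except the per-TR
reverse-correlation test, which is one-tailed by construction.

## Synthetic cohorts

The generator emulates exactly the structure the analyses assume, not
real-brain physics:

* **Latents.** One timecourse per region: white noise smoothed with a
  Gaussian kernel (FWHM 3 TRs — a cheap stand-in for hemodynamic
  autocorrelation; the analyses need realistic smoothness, not a
  biophysical model), mixed through the matrix square root of a target
  correlation structure, re-standardized. The default structure couples
  FFA–LOC at 0.6 (the strongest observed coupling in this literature),
  within-domain scene regions at 0.45, FFA–pSTS at 0.4, everything else
  weakly (0.1–0.3).
* **Voxels.** Per parcel, 100 planted selective voxels carry
  gain × weight × latent; the other parcel voxels carry a weak
  anti-preference (−0.15 × latent). Per-subject shared noise (smoothed,
  SD 0.25) and iid voxel noise (SD 0.5) are added. These SNR knobs are
  synthetic conventions: the source literature does not characterize
  movie-evoked amplitude, so they were fixed once at values a simulation
  study would call moderate signal (per-voxel latent correlation ≈ 0.9
  for selective voxels) and are config keys.
* **Localizer runs** (adults only, default 2): palindromic 415.8-s design —
  two palindromes, each a seeded permutation of the four conditions
  followed by its mirror, five fixation blocks (start, three middle
  flanking the palindrome halves, end), 19.8-s blocks; acquisition length
  208 TRs at TR 2 s (the paradigm length is not a TR multiple). Selective
  voxels respond to their preferred condition at amplitude 2.0 and to
  others at 0.5 through the same canonical HRF the GLM uses (guaranteeing
  model match in the noiseless limit); non-selective voxels respond
  non-preferentially at 0.3.
* **Artifacts.** Planted TRs get persistent ±3-mm translation steps with
  alternating sign — a step, not an impulse, so the composite-motion rule
  fires exactly at the planted TRs and not at a return-to-baseline — plus
  an impulse global-signal excursion of 8 clean-GS SDs added to every
  brain and white-matter voxel. Background motion is 0.1-mm SD. Default
  artifact rates: 2% of TRs for adults, 6% for children (matching the
  roughly 3 vs 10 artifact timepoints per 168-TR run reported for such
  cohorts). Designated QC-failure subjects use a 45% rate.
* **White matter.** An 8-voxel-thick block (so two erosions survive)
  whose voxels load on 3 smoothed noise components plus the shared noise —
  what the component-based correction should find and remove.
* **Development.** Children get a response gain rising linearly from 0.5
  at age 3 to 1.0 at age 8 (event responses therefore grow with age); a
  fraction of the FFA latent mixed into pSTS, 0.6 at age 3 decaying to 0
  by age 8 (reduced differentiation); and a +1 TR pSTS response lag below
  age 5. The default cohort is 12 adults plus two child groups of 17
  (3-year-olds and 8–12-year-olds), the group sizes the developmental
  contrasts need.
* **Seeding.** One root seed fans out through `SeedSequence` spawns per
  subject; the ground-truth manifest records every subject's parameters
  and artifact TRs, the planted voxel sets, and the latents themselves.

## What the synthetic validation does and does not show

Passing tests show the implementation is faithful to its own definitions:
statistics hold their nominal levels under the null, planted structure is
recovered at the stated SNR, and the relative orderings the method
predicts (movie ssROI > group ROI selectivity, traditional ≥ movie,
age-specific pSTS function, lag detection) emerge through the complete
pipeline. They do not show that the SNR, noise spectra, spatial
autocorrelation, or artifact topology of real pediatric BOLD data are
matched — the generator has no spatial smoothness, no physiological noise,
and treats hemodynamics as a fixed smoothing kernel. Real-data use should
treat the absence of prewhitening (OLS, not AR(1)-corrected GLS) as the
main caveat: with autocorrelated noise, localizer t values are inflated,
which affects absolute selectivity values but not the voxel rankings ROI
definition depends on.

## Problem sizes

Default test and acceptance runs use the 24×24×18-voxel grid (seven
6×6×6 parcels of 216 voxels, k = 100), 168-TR movie runs, cohorts of up
to 46 subjects, 200 null-calibration draws and 20-seed recovery loops —
sizes chosen so the full suite and the acceptance script each complete in
well under a minute on one CPU while keeping every group test at the
study's nominal n (12 adults, 17 per child group).
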
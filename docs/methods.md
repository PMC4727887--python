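# Methods

This document describes the generative model, the analysis chain, every
user-facing parameter, and the numerical choices behind them.

## 1. Generative model

### 1.1 Display and scanpath

Twelve objects are laid out on a 4 × 3 lattice over a 1280 × 960 px screen,
each lattice position jittered by a uniform offset (`grid_jitter_px`, default
30 px); one object is the search target.  A scanpath is a sequence of
fixations, each with:

- a **class**: `target` (fixation lands within 2.5° of the target object),
  `nontarget` (within 2.5° of another object) or `background` (elsewhere),
  drawn with probabilities `class_probs` (default 0.15 / 0.55 / 0.30).  A
  target fixation is never followed immediately by another target fixation,
  and an object is never refixated immediately — both mirror inhibition of
  return during search and, practically, keep successive fixation centroids
  at least `min_centroid_separation_px` (150 px) apart so that the dispersion
  detector cannot merge adjacent fixations.
- a **duration** drawn from a truncated normal with class-specific means and
  SDs (`fix_duration_means_ms` = 270 / 281 / 241 ms,
  `fix_duration_sds_ms` = 38 / 37 / 29 ms, truncated below at
  `min_fix_duration_ms` = 60 ms).  Duration is realized as a whole number of
  gaze samples: `duration = n_samples / fs_gaze`.
- a **centroid** inside the class-appropriate region, with isotropic Gaussian
  within-fixation jitter (`within_fixation_jitter_px`, 3 px ≈ 0.075°).

Consecutive fixations are joined by a 30 ms constant-velocity saccade whose
interior gaze samples are placed only over the middle of the trajectory
(fractions 0.4–0.6).  With centroids ≥ 150 px apart this keeps every saccade
sample ≥ 60 px from both endpoints — outside the 40 px dispersion radius — so
a saccade sample can never extend a fixation's dispersion run.  This is a
deliberate idealization (see § 6).

### 1.2 EEG/EOG recording

Sixteen channels at `fs` = 256 Hz: 12 EEG (Fz, F3, F4, Cz, C3, C4, Pz, P3,
P4, PO7, PO8, Oz) and 4 EOG (vertical pair above/below the right eye,
horizontal pair at the outer canthi).  The recording is a sum of:

1. **Fixation-related potential.**  At each fixation onset a Gaussian-shaped
   component is added: peak latency `frp_peak_latency_ms` = 400 ms, width
   (SD) `frp_width_ms` = 100 ms, amplitude per class `frp_amplitude_uv`
   (default 6 / 1 / 1 µV for target / nontarget / background), distributed
   over channels by a fixed parieto-central topography (maximal at Pz,
   falling off frontally — the spatial signature of a P300-like response).
2. **Background noise.**  Ten independent AR(1) sources
   (`noise_ar_coef` = 0.95, i.e. 1/f-like low-frequency dominance;
   `noise_sd_uv` = 10 µV stationary SD) with **Laplace** innovations, mixed
   into the 12 EEG channels by a random unit-row-norm matrix, plus 1 µV white
   sensor noise per channel (`sensor_noise_sd_uv`).  Each EOG channel gets
   its own independent AR(1) + sensor noise.  The rank-10 spatial mixing and
   super-Gaussian innovations are what make the ICA source model
   *identifiable*: with 12 channels carrying 10 mixed noise sources, one FRP
   topography and one artifact topography, a square unmixing matrix exists,
   and non-Gaussianity lets Infomax find it.
3. **Saccadic artifact.**  During each 30 ms saccade a half-sine pulse of
   amplitude `saccade_artifact_uv` = 200 µV is injected, scaled per channel
   by a fixed ocular gain pattern: near-unity on the EOG channels (±0.8–1.0),
   ~0.12–0.15 on frontal EEG, ~0.01–0.02 posteriorly — the corneo-retinal
   dipole falls off steeply with distance from the eyes.  200 µV is a
   realistic deflection for the large (≥ 150 px ≈ 3.75°) saccades this
   layout produces.

`reference_high_snr_config()` returns the configuration used as a known-good
operating point by the higher-level checks: 200 fixations per subject and a
15 µV target amplitude, all other parameters at their defaults.  It was fixed
by a one-off calibration of the amplitude → AUC curve (intra-subject
target-vs-rest mean AUC ≈ 0.67 / 0.83 / 0.94 / 0.99 at 6 / 10 / 15 / 20 µV,
three seeds each): 15 µV is the smallest calibrated level comfortably above
an AUC of 0.85 without fully saturating.

## 2. Fixation detection and labelling

Detection is dispersion-based: a window of consecutive valid gaze samples is
grown while every member stays within a circle of radius
`dispersion_deg / 2` (default diameter 2°, i.e. 40 px radius at 40 px/°)
around the running centroid; a run is accepted as a fixation if it spans at
least `min_duration_ms` = 60 ms.  A single invalid sample inside a run is
tolerated (`max_gap_samples` = 1); longer gaps break the run.  The reported
duration is `n_samples / fs_gaze`, matching the generator's convention.

Labelling assigns each fixation to the nearest object center within
`onto_object_radius_deg` = 2.5° (`target`/`nontarget`), else `background`.

## 3. Ocular-artifact removal

Extended Infomax ICA is estimated on the 12 EEG channels of the (artifact-
bearing) recording: channels are demeaned, symmetrically sphered
(`C^(-1/2)` via eigendecomposition), and the rotation is estimated by
`mne.preprocessing.infomax(extended=True)` with a fixed seed.  Estimation
requires more than `20 · n_channels²` samples and full-rank data.  Components
whose activation correlates with *any* EOG channel at |r| ≥ 0.7 are flagged
(an automated stand-in for manual scalp-map inspection) and the EEG is
back-projected with those components zeroed; EOG channels are left untouched.

## 4. Epochs, filtering and features

Epochs start at the fixation-onset sample and span 800 ms:
`round(0.8 · fs)` = **205 samples** per channel at 256 Hz.  Fixations whose
window would overrun the recording are dropped with a logged warning.

Each epoch is bandpass filtered 0.5–10 Hz with a 4th-order Butterworth
applied forward and backward (zero phase).  Two numerical details matter at
this segment length: (a) the channel mean is removed first, because an
800 ms segment is far shorter than the 0.5 Hz high-pass time constant and the
DC component would otherwise survive as a slow transient; (b) initial
conditions use Gustafsson's method (`filtfilt(..., method="gust")`), which
minimizes the edge transients that dominate default padding at 205 samples
(stopband attenuation of a 50 Hz tone improves from ~68 % to ~97 %).

Features are the channel-wise concatenation of an epoch over a channel
subset: 12 × 205 = **2460** dimensions for EEG, 820 for EOG, 3280 for all
channels.  PCA (economy SVD of the centered training matrix) retains the
smallest number of components whose cumulative explained variance reaches
`pca_criterion` = 0.999; at the reference operating point this is roughly
130–140 of 200 possible components.

## 5. Classifier and evaluation

### 5.1 Shrinkage-regularized Fisher discriminant analysis

With class means μ_C, their unweighted average μ, and class counts N_C:

- between-class scatter  S_b = Σ_C N_C (μ_C − μ)(μ_C − μ)ᵀ
- within-class scatter   S_w = Σ_C Σ_{i∈C} (x_i − μ_C)(x_i − μ_C)ᵀ,
  giving the pooled covariance Σ = S_w / (n − C).

The covariance is regularized toward an equal-diagonal target,

  Σ\* = λ ν I + (1 − λ) Σ,  ν = trace(Σ)/d,

with λ chosen analytically (Schäfer–Strimmer estimate computed on the
within-class-centered data; cross-checked against the Ledoit–Wolf estimator).
The projection solves the generalized eigenproblem S_b v = λ Σ\* v; the top
C − 1 eigenvectors form the discriminant subspace.  For two classes this
reduces to w = Σ\*⁻¹(μ₊ − μ₋) with bias b = −wᵀ(μ₊ + μ₋)/2; multi-class
prediction assigns the nearest projected class mean.

### 5.2 ROC and cross-validation

Decision scores are min-max mapped to [0, 1] and swept against K = 100
equally spaced thresholds; the AUC is the trapezoidal area under the
resulting TPR(FPR) curve (closed at (0,0) and (1,1)).  The construction is
verified against the exact rank-based (Mann–Whitney) AUC.  Chance is 0.5
regardless of class priors.

Two schemes:

- **intra-subject** — stratified 10-fold cross-validation.  Binary contrasts
  keep the natural class imbalance and report AUC; the 3-class condition
  first balances the classes by seeded down-sampling and reports accuracy
  (chance 1/3).  PCA, the shrinkage intensity and the discriminant are fit
  on training folds only; `leak=True` deliberately violates this as a
  negative control.
- **inter-subject** — leave-one-subject-out: train on the pooled epochs of
  all other subjects, test on the held-out subject, one AUC per subject.

Condition comparisons use two-tailed paired t-tests (`paired_ttest`), with
zero-variance difference vectors handled explicitly.

## 6. Generator realism limits

- FRPs are deterministic Gaussian bumps; real components have trial-to-trial
  latency and amplitude jitter, asymmetric shapes, and several subcomponents.
- Saccade kinematics are constant-velocity with sparse interior sampling so
  that saccade samples can never join a dispersion run; real detectors must
  contend with saccade samples landing inside the dispersion circle, glissades
  and smooth pursuit.
- The ocular artifact topography and the noise mixing are time-invariant, and
  exactly one artifact source exists — blink artifacts, muscle noise and line
  noise are absent, which is why ICA cleaning is near-perfect here.
- Overlapping activity from neighbouring fixations is present (an 800 ms
  epoch typically spans the next fixation's onset), and because fixation
  durations are class-specific this creates genuine, realistic class
  information beyond the injected amplitude difference; it is what keeps
  nontarget-vs-background above chance despite equal response amplitudes.

## 7. Numerical choices

- All stochastic stages consume explicit `numpy` generators; subject- and
  stage-level seeds derive from one master seed via `SeedSequence.spawn`, so
  identical configurations reproduce outputs byte for byte.
- Sphering and PCA use symmetric eigendecomposition / economy SVD rather
  than covariance inversion; the generalized eigenproblem is solved with
  `scipy.linalg.eigh(S_b, Σ*)` (both operands symmetric, Σ\* positive
  definite for any λ > 0).
- Eigenvector signs are fixed (largest-magnitude entry positive) to make
  fitted models reproducible across BLAS implementations.

## 8. Limitations

- The analytic shrinkage intensity is estimated in PCA space (dimension ≈
  number of retained components), not in the raw 2460-dimensional space.
- The ROC's 100-threshold grid quantizes the curve; for very small test sets
  the trapezoidal AUC can differ from the rank AUC by up to ~0.01.
- Inter-subject generalization benefits from all synthetic subjects sharing
  one FRP topography; real across-subject transfer is harder.
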
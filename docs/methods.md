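# Methods

## Model and procedure

`thalnet` treats thalamocortical functional connectivity as a two-level
object. At the first level, every thalamic voxel *t* of a subject defines a
whole-brain connectivity map `z_t(v) = atanh(r(x_t, x_v))`, the Fisher
z-transformed Pearson correlation of the preprocessed voxel series.
Stacking these maps (one frame per thalamic voxel, frames ordered by
ascending voxel index) and concatenating subjects subject-major yields a 4D
dataset whose frames are observations over brain-voxel variables. Spatial
ICA of this dataset factors it into K component maps — cortical networks
that covary with thalamic seed location consistently across subjects — and
per-frame mixing weights.

At the second level, dual regression localizes each network in each
subject: stage 1 regresses every timepoint's image on the component maps
(spatial regressors plus intercept), giving a timecourse per component;
stage 2 regresses every voxel's series on all timecourses jointly
(temporal regressors plus intercept), giving a beta map per component. The
stage-2 stack restricted to the thalamus is the subject's set of functional
thalamic subdivisions — a soft parcellation in which overlap is allowed and
meaningful, in deliberate contrast to winner-takes-all assignment.

Group inference is nonparametric throughout. A per-voxel GLM with group,
age and sex yields a t map for the group contrast; the null distribution of
the maximum enhanced statistic over permutations gives family-wise-error
corrected p values. Nuisance covariates are handled by the Freedman–Lane
scheme (permute residuals of the nuisance-only model, add the nuisance fit
back, refit the full model); one-sample tests use sign flipping. When the
requested permutation count reaches the size of the exchangeability space
(n! relabelings, 2^n sign patterns) the space is enumerated and p is exact.

## Enhancement

TFCE integrates cluster extent and height over all thresholds:
`TFCE(p) = Σ_h e(h, p)^E · h^H · dh`, with defaults E = 0.5, H = 2,
dh = h_max/100 and 26-connectivity — the enhancement's standard
parameterization. The negative tail is enhanced on the negated map and the
output is signed; corrected p values are two-sided via the max of |TFCE|.
Cluster-extent correction thresholds |t| at a forming threshold (default
2.3, configurable) and uses the max cluster size as the null statistic.
Enhancement runs on the bounding box of the analysis mask; since clusters
of positive-threshold voxels cannot connect through zero-filled off-mask
space, this is exact, not an approximation.

## Preprocessing

Fixed order: trim initial frames (default 4) → highpass → confound
regression. The highpass is a frequency-domain filter with a raised-cosine
rolloff of width 0.002 Hz about the cutoff (default 0.01 Hz); voxel means
are restored after filtering. Confound regression uses OLS on
[intercept | motion ×6 | WM | CSF]; constant confound columns are dropped
(they duplicate the intercept), and residuals are exactly orthogonal to the
retained columns. Whether filtering should precede or follow confound
regression is not dictated by the underlying analysis; the fixed order here
is a convention of this package. No spatial smoothing exists anywhere in
the pipeline.

## Numerical choices

- Correlations are clipped to ±(1 − 1e−7) before `atanh`, so a seed's
  self-correlation maps to a large finite z (≈ 8.4) rather than infinity.
  Zero-variance series yield r = 0 with a warning, keeping the pipeline
  total on masked edge voxels.
- Spatial ICA = PCA reduction + fixed-point symmetric rotation with tanh
  (logcosh) contrast, tolerance 1e−6, max 1000 iterations, up to 5 seeded
  restarts on non-convergence (scikit-learn's FastICA provides the
  rotation). Each frame is variance-normalized within the mask before the
  fit, equalizing subjects' global correlation levels. Maps are fixed to
  unit variance over mask voxels with the largest-|value| voxel positive;
  z-maps additionally divide by a robust (MAD-based) noise SD.
- The group ICA runs on cortex (brain minus thalamus). The components are
  cortical networks by construction, and at reduced grid scales the clipped
  self-correlation spikes — one ≈ 8.4-z voxel per frame, always inside the
  thalamus — otherwise contribute a high-rank diagonal structure that
  pollutes the PCA subspace. On full-resolution data the choice is
  inconsequential (spikes are a vanishing fraction of brain voxels); at
  fixture scale it is load-bearing.
- Dual-regression stage 1 is likewise fit on brain-minus-thalamus: the
  thalamic signal is the quantity stage 2 estimates, and letting it enter
  the stage-1 normal equations (through the intercept/maps span) leaks a
  small bias into the timecourses. With cortex-only fitting, the noiseless
  planted subject is recovered exactly. Stage-1 timecourses are
  variance-normalized before stage 2 (the "des-norm" convention) so stage-2
  betas are comparable across subjects, which group comparison requires.
- The permutation p convention includes the observed labeling:
  p = (1 + #{null ≥ obs}) / (n_perm + 1), guaranteeing p ≥ 1/(n_perm + 1).
- Exact-fit voxels (zero residual variance) get t = 0 via a scale-relative
  floor on the standard error, rather than 0/0 noise.

## Synthetic cohorts

The generator plants K networks on a 3 mm grid (default 18×22×18): a
central ellipsoidal "thalamus", a surrounding ellipsoidal "brain", K
peripheral Gaussian cortical blobs (pairwise spatial correlation < 0.2) and
K Gaussian thalamic weight maps whose supports overlap and jointly cover
the thalamus. Each component k has an AR(1) latent timecourse
(coefficient 0.3 — resting-state signals are autocorrelated, which
exercises the highpass and correlation stages); a voxel's series is the
loading-weighted sum of timecourses plus white Gaussian noise
(SD 0.5) and a small confound leak (smooth nuisance series scaled by a
random spatial profile) so confound regression has real work to do.
Defaults follow the emulated study design: 116 timepoints at TR 3.5 s,
trim 4; cohorts of 12 per group for end-to-end checks; patient-group
effects are multiplicative factors on the thalamic weights of designated
components (e.g. 0.5 = halved thalamocortical coupling), matching a
hypo-/hyperconnectivity readout localized to thalamic subregions.

The noise SD of 0.5 puts a component's share of variance at its peak
cortical voxel near 70%, tapering to zero off-blob — a strong but not
degenerate network signal appropriate for a generator whose job is to make
every pipeline stage identifiable at desk scale.

What the generator does *not* emulate: hemodynamic response shapes, scanner
noise spectra (drift, spikes, physiological aliasing), head motion, spatial
autocorrelation of noise, and registration error. Passing tests therefore
demonstrate the correctness and calibration of the algorithms under the
stated generative model, not robustness to real-scanner artifacts.

## Problem sizes used in validation

Validation scales the study's computation to a single CPU while keeping
every contract intact: the permutation-calibration check uses 300 simulated
null cohorts (8 vs 8) at 250 permutations each, with the acceptance band
widened to the 2σ binomial interval implied by 300 replicates
([0.02, 0.08] around the nominal 0.05); the end-to-end cohort is 12 vs 12
at 500 permutations; ICA recovery uses 60-frame planted stacks. The
606-voxel × 80-subject stack arithmetic is checked symbolically and on a
57-voxel × 3-subject fixture.

## Known limitations

- The ICA model order K must be chosen by the user (default 20 at study
  scale, 3 in fixtures); no automatic order estimation is provided, and
  component stability across restarts is not assessed beyond convergence
  retries.
- Cluster-forming threshold for cluster-extent correction defaults to
  t = 2.3; cluster-level inference is sensitive to this choice.
- Per-component inference is reported without additional correction across
  components; users comparing all K components should apply their own
  cross-component control.
- The pipeline consumes already-aligned volumes; no registration, motion
  correction or distortion handling is performed.
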
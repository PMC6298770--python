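# Methods

`tmrpipe` implements the analysis chain of an olfactory targeted-memory-
reactivation (TMR) study: during slow-wave sleep, odors that were paired
with object categories during wake learning are re-presented, and the
question is whether odor-evoked multivoxel fMRI patterns re-express the
cued category's wake representation — and whether the degree of that
re-expression predicts the behavioral memory benefit after sleep.  All
stages run on a synthetic phantom with known ground truth, so every
estimator in the chain is validated by parameter recovery rather than by
re-analysis of unavailable raw scans.

## Core model

**Category templates.**  From 12 wake runs, a GLM with one HRF-convolved
boxcar per condition yields beta patterns `b(c, run, voxel)`.  The
template of category *c* is the run average minus the across-category
mean at each voxel:

    T_c = mean_run b(c, run, .) − mean_c' mean_run b(c', run, .)

so the four templates sum to zero voxelwise and encode only
category-specific structure.

**Pattern discrimination (voxel selection).**  At every searchlight
sphere (radius 3.7 voxels, 203 lattice offsets), leave-one-run-out
train/test correlations are computed between condition patterns, with
the condition mean removed from training and test sets separately within
each fold.  Correlations are Fisher-Z transformed and the statistic is

    D = mean_folds [ mean_c z(train_c, test_c)
                     − mean_{c ≠ c'} z(train_c, test_c') ]

`D > 0` marks spheres carrying category information.  A one-tailed
one-sample t across subjects (maps smoothed 6 mm) at p < 0.001
uncorrected defines the explicit mask for the sleep analysis.

**Reactivation index.**  The sleep GLM estimates one beta pattern per
odor (canonical HRF; no condition-mean removal — with only two odors,
centring would manufacture anticorrelated vectors).  Per sphere and odor
*o* cueing category `cued(o)`:

    R_o = atanh r(s_o, T_cued(o)) − mean_{c ≠ cued(o)} atanh r(s_o, T_c)
    R   = (R_1 + R_2) / 2

Variants: *cued-only* (compare the two cued templates against each
other), *ROI* (one index over an anatomical region instead of spheres),
and *FIR time course* (indices recomputed from 10 per-volume finite-
impulse-response betas spanning −7.5 s to +15 s around odor onset).

**Group inference.**  The per-subject reactivation maps are correlated
across subjects with the cued memory benefit (posttest retention as a
percentage of pretest, cued minus non-cued categories), one-tailed.
Family-wise error at the peak is controlled by max-statistic
permutation: the benefit vector is shuffled across subjects (10,000
draws by default; 2,000 in the pipeline config), the maximum t inside
the explicit mask recorded, and `p_FWE = (1 + #{max_perm ≥ max_obs}) /
(n_perm + 1)`.  Under exchangeability this is exact, requires no
smoothness estimation, and replaces parametric random-field correction.
One-sample questions (main effect of reactivation; univariate odor
activation inside an olfactory ROI) use the same machinery with random
sign flips.

## Synthetic phantom

The phantom is a 20³ grid of nominal 2 mm voxels with an ellipsoidal
brain mask and four disjoint spherical regions: `vmpfc_like`,
`fusiform_like`, `hippocampus_like` (signal regions where category
templates live) and `control` (pure noise).  All subjects share the
space; no spatial normalisation is simulated or needed.

Generating process, with defaults fixed once in
`tmrpipe.phantom` / `PipelineConfig`:

- wake run patterns: template (unit-amplitude Gaussian per voxel in
  signal regions) + iid N(0, 1) noise, 12 runs;
- sleep spatial pattern per odor: `rho·T_cued + (1 − rho)·noise`,
  `rho ~ Uniform(0, 0.8)` per subject and odor (reactivation strength
  has no physical scale, so the range is a package choice: it spans
  "absent" to "strong" while keeping single-subject correlation
  estimates away from saturation);
- sleep BOLD: HRF-convolved 16 s on / 16 s off odor boxcars (15 blocks
  per odor, alternating odors) × spatial pattern + slow drift + iid
  N(0, 1) noise at TR 2.5 s;
- respiration: ~0.25 Hz sinusoid with phase jitter at 25 Hz; inhalation
  onsets are positive-derivative zero crossings;
- motion: bounded random walk (±1 voxel translations, ±0.02 rad
  rotations), entering only as nuisance regressors;
- behavior: object-level recall on a 16-cell grid (chance 6.25%),
  pretest accuracy 0.73, base retention 0.775; posttest retention for
  cued categories adds `a + b·mean(rho)` with `(a, b) = (0.02, 0.30)`
  and N(0, 0.04) noise, so the cued benefit is linear in reactivation
  strength by construction and independent of it when `b = 0`;
- EEG: 1/f-amplitude noise at 100 Hz scaled to ~20 µV RMS, identical
  generating spectrum during odor-on and odor-off blocks under the null;
  an optional multiplicative 1–4 Hz power boost during odor-on models an
  arousal confound.  The scripted hypnogram guarantees ≥ 2 min of
  continuous stage 2 before the first odor block.

Default noise levels were fixed once so that wake discrimination maps
reach group significance (p < 0.001) in the labeled regions and the
reactivation index recovers injected `rho` (Spearman ≥ 0.7 over
subjects) — i.e. so that the phantom operates in the regime the analysis
was designed for.  What the phantom does **not** emulate: realistic
anatomy and spatial autocorrelation of BOLD noise, physiological noise
beyond drift, inter-subject anatomical variability, EEG artifacts, and
sleep-stage dynamics beyond a scripted hypnogram.  Passing tests
therefore demonstrate correctness and statistical calibration of the
estimators, not performance on real scanner data.

## Numerical choices

- Fisher-Z uses `atanh` with `|r|` clipped at `1 − 1e-7`; degenerate
  zero-variance patterns score r = 0 and raise a warning.
- OLS without prewhitening; subject-level serial correlation only costs
  efficiency because all inference is at the group level.  Rank
  deficiency raises an error naming the collinear columns; all-zero
  nuisance columns are dropped silently.
- Derivative regressors are backward differences with a zero first row.
- The even−odd slice-quality index is computed on slice means along the
  third axis; spike regressors flag volumes with framewise displacement
  above 0.9 × voxel size (a config value; no field-standard threshold
  exists).
- Respiration is down-sampled by averaging within each TR window.
- Searchlight centers require ≥ 10 in-mask sphere voxels (edge rule;
  partial spheres otherwise keep their in-mask voxels).  The
  convolution-based fast path (`reactivation_map_fast`) computes
  per-sphere correlation sums via sphere-kernel convolutions and is
  numerically identical to the per-center loop (tested to 1e-10).
- Welch PSD: 4 s Hann segments, 50% overlap (0.25 Hz native
  resolution), band-averaged onto the 0.5 Hz grid between 0.5 and
  20 Hz.  The condition × frequency repeated-measures ANOVA reports the
  classical univariate df (39, 39·(n−1)) with the Greenhouse–Geisser
  corrected p.
- Retention is the post/pre correct-count ratio pooled over each cueing
  condition's two categories (capped at 200%); an item-conditional
  variant is available behind a flag.  The Wilcoxon test uses the
  normal approximation without continuity correction, matching a
  Z-statistic report at n = 18.  The binomial test is exact; for 15/18
  the one-tailed value is 988/262144 ≈ 0.0038.
- PPI takes the seed × psychological product at the BOLD level with both
  factors centred — a deliberate simplification of generalized PPI
  (no hemodynamic deconvolution of the seed); both main effects are
  always in the model so the interaction is identified.

## Design choices that were genuinely open

- Group-level FWE by permutation (benefit shuffling / sign flipping)
  instead of random-field theory: exact under exchangeability and free
  of smoothness assumptions.
- The sleep odor regressors use the canonical HRF in the main model;
  the FIR model provides the assumption-free time course.
- Follow-up clusters are taken from the covariate model at p < 0.001
  uncorrected, falling back to the peak voxel when empty (tiny phantoms).
- No nuisance covariates enter the group correlation.
- One-tailed tests throughout, since every hypothesis is directional.

## Problem sizes

The default pipeline analyses 18 subjects on the 20³ phantom with 2,000
permutations.  Simulation batteries use a 12³ phantom with radius-2
spheres: the null-calibration battery runs 1,000 groups × 1,000
permutations (rejection rate at α = 0.05: 5% within ±2 points;
permutation peak-p super-uniform by one-sided KS); the recovery battery
runs 200 subjects through full BOLD synthesis, the nuisance GLM and the
ROI index (Spearman ≥ 0.7 against injected rho).  These sizes keep each
battery's Monte-Carlo error well inside its acceptance band.

## Known limitations

- At the default conditions, the across-subject benefit carries
  item-level sampling noise (64 recall items per cueing condition) on
  top of the configured retention noise; a single 18-subject group
  therefore often lacks the power to reach peak-FWE significance in the
  covariate analysis.  The package's validated claims are calibration
  (false-positive control) and parameter recovery, not single-group
  significance.

- The permutation test assumes exchangeable subjects; the generator
  satisfies this by construction, real multi-site data might not.
- The reactivation index inherits correlation's insensitivity to
  pattern scale: uniform activation changes are invisible by design.
- The respiration model has no odor-locked breathing changes, so
  inhalation alignment shifts onsets but cannot create confounds.
- With two odors, cued-only and full indices are strongly correlated on
  this phantom; distinguishing them needs richer cue sets.
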
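# Methods

## Task and session designs

A chord trial instructs three of the five fingers (1 = thumb … 5 =
little) to press isometrically to 2.5 N while the remaining two hold a
0.5 N baseline. Two session layouts are modelled. The *training*
session is self-paced: each block cycles through the five training
configurations (345, 123, 124, 245, 135), four repetitions each, in
randomised order; onsets are nominal. The *scanner* session is timed:
instructions last 1.3 s, the press must fall inside a 2.3 s window, a
block is three back-to-back trials of one configuration (6.9 s), and
each of the five scanner configurations (145, 234, 134, 125, 235) is
repeated in three blocks per run — 45 trials per run, four runs of 141
volumes at TR 1.5 s. Blocks are separated by a 6 s rest (free
parameter `inter_block_s`; the design builder raises if blocks plus
rests exceed the run). Block order is randomised per run from an
explicit seed; designs are pure functions of their arguments and seed.

## Force simulation

Force traces are sampled at 100 Hz (free parameter; recording hardware
rates vary). Instructed channels follow a cubic-smoothstep press
profile: a 300 ms rise from baseline to the 2.5 N plateau at press
onset (0.6 s into the trial by default) and a matching fall at press
offset (1.7 s). A smoothstep rather than a logistic is used so the
commanded plateau is reached *exactly*, which keeps the package's
closed-form checks (plateau force 2.5 N, perfect-trial deviance 0)
exact rather than asymptotic; within sensor noise the two shapes are
indistinguishable. Noninstructed channel `f` receives coupled force
`γ · Σ_{g∈I} E[g,f]` shaped by the same profile, where `E` is the
enslavement matrix and `γ` the coupling gain. White Gaussian noise of
standard deviation `noise_sd` (N) is added per sample and all channels
are floored at 0 N. Skill learning is a multiplicative decay: after
`k` completed blocks, `noise_sd` and `γ` are scaled by
`learning_rate^k` — the simplest mechanism that yields the canonical
decreasing deviance curves.

## Deviance scoring

Response onset is the first sample at which any channel reaches 1.5 N;
trials that never cross are marked invalid (excluded from block means,
with counts logged) rather than raised. Release is the first sample —
after the press has actually risen — at which all instructed channels
drop below baseline + 0.1 N, falling back to the final sample if the
force is never released; the 0.1 N band is a package choice, as the
release event has no standard numerical definition. Deviance averages,
over the inclusive [onset, release] window, the summed *absolute*
deviations of noninstructed channels from 0.5 N plus the summed
absolute deviations of instructed channels from their instantaneous
common mean. Absolute rather than squared residuals preserve newton
units and match the "summed up and averaged" construction; a squared
variant is selectable (`residual="squared"`).

## Chord difficulty

The enslavement matrix is symmetrised as `(E + Eᵀ)/2` with the diagonal
zeroed (the model does not distinguish enslavement direction). For a
chord with instructed set I and noninstructed set N:
`E1 = Σ_{{a,b}⊂I} S[a,b]`, `E2 = Σ_{{a,b}⊂N} S[a,b]`,
`E3 = Σ_{a∈I, b∈N} S[a,b]` — unordered pairs counted once. The score
`E1 + E2 − E3` ranks chords easy (high) to difficult (low); ties break
lexicographically by label. The package ships only a **synthetic**
fixture matrix (neighbouring fingers couple more strongly, the thumb is
more independent) because measured inter-finger enslavement tables
live in the specialised motor-control literature; any 5×5 CSV can be
supplied, and published easy/difficult splits should be reproduced only
with the measured matrix they came from.

## First-level model

Condition regressors are boxcars over each configuration's trials
convolved with a canonical double-gamma response (gamma-density
difference, peak 6 / undershoot 16 / ratio 1:6, unit-peak normalised,
peaking near 5 s), computed on a 50 ms grid and sampled at the TR.
Temporal derivatives are first-order finite differences of the sampled
columns. The per-run fit is ordinary least squares; residuals are
returned alongside the condition patterns because the RSA stage needs
them for noise normalisation. No prewhitening or autocorrelation
modelling is applied — the downstream estimator consumes patterns and
residual covariance, not GLM inference — and no motion/high-pass
nuisance modelling is simulated.

## Pattern simulation with known geometry

Target RDMs are interpreted in per-voxel crossnobis units
(`d = ‖Δ‖²/P`). Classical MDS embeds the target into a latent
configuration whose squared distances equal `d·P` exactly; a random
row-orthonormal map embeds the latents into voxel space, preserving
all pairwise distances, and a hemisphere-specific signal scale
multiplies the patterns (distances scale quadratically). Run-wise
patterns add Gaussian noise with the specified voxel covariance, drawn
independently per run, so cross-validated distance estimates are
unbiased for the target by construction; matching residual series from
the same covariance let the noise model be estimated the same way it
would be from GLM residuals. The ipsilateral latent configuration is
`h·U + √(1−h²)·W` with `W` an independent configuration of matched
norm: `h = 1` duplicates the contralateral geometry, `h = 0` is
independent. What this generator does *not* emulate: hemodynamic
nonlinearity, motion, physiological noise spectra, or any spatial
structure in the signal (only the noise covariance is structured) —
passing recovery tests shows estimator correctness, not robustness to
those real-data complications.

## Crossnobis estimation

The residual voxel covariance is pooled across runs (each run
demeaned) and shrunk toward its diagonal with an analytically chosen
weight (Schäfer–Strimmer-style variance ratio of the off-diagonal
entries, clipped to [0, 1]; explicit weights selectable, 1 = diagonal
model). Whitening uses the inverse symmetric square root with an
eigenvalue floor of 1e−10 relative to the largest. Distances average
over all ordered run pairs `m ≠ n` and are divided by the voxel count
`P` so regions of different size are comparable. Homotopy and
typicality correlate the 10 pair values — Pearson by default, Spearman
selectable, since figure conventions in this literature are ambiguous
between the two — and Fisher z uses r clipped to ±(1 − 1e−12). The
control template for typicality is the entrywise mean of control
contralateral RDMs, excluding the scored subject when they are
themselves a control. Condition correspondence across hemispheres is by
chord label (anatomical finger identity), not mirror remapping.

## Tract metrics

The per-direction streamline counts and mean FA/MD are combined as
`vw = (N_{L→R} m_{L→R} + N_{R→L} m_{R→L}) / (N_{L→R} + N_{R→L})`.
Counts are accepted as non-integers because supersampled seeding yields
fractional effective counts; the result always lies between the two
directional means and is invariant to rescaling both counts.

## Group statistics

The mixed ANCOVA uses the classical univariate split-plot strata. Cell
means per subject are transformed with orthonormal (Helmert) contrasts;
each within-subject effect's scores are regressed on sum-coded group
and the de-meaned covariate, with Type-III model comparisons providing
effect and error sums of squares. The covariate is additive (no
group × covariate interaction) and consumes one denominator degree of
freedom in every stratum, matching the common rmANCOVA reporting
convention (e.g. a three-way interaction with 43 subjects in 3 groups
reports F(2, 39)); with no covariate the procedure reduces exactly to
the repeated-measures ANOVA (verified against pingouin). No sphericity
correction is applied. Partial eta squared is
`SS_effect / (SS_effect + SS_error)` within each stratum.
Covariate-adjusted contrasts report raw p values together with the
Bonferroni-adjusted α (α/k), rather than adjusted p values.
Freedman–Lane permutes residuals of the nuisance-only model, adds back
the nuisance fit, and recomputes the effect's partial F;
`p = (1 + #{F* ≥ F}) / (1 + n_perm)`. Only the fixed-effects
(between-subject) case is implemented; random-effects permutation
schemes for mixed designs are out of scope, as is Bayes-factor
computation.

## Synthetic cohort defaults

Group sizes and age distributions follow the scanned cohort the design
emulates: 14 controls, 16 amputees, 13 one-handers, ages ≈ 44–49 ± 12.
Skill parameters encode the qualitative group structure the analyses
assume — controls learn well everywhere; one-handers learn difficult
chords poorly (learning rate 0.99 on difficult vs 0.90–0.92 elsewhere);
amputees perform intermediately. Pattern parameters give amputees
elevated ipsilateral signal (scale 0.75 vs 0.40–0.45) and higher
interhemispheric coupling (h = 0.65 vs 0.25). Tract parameters are
identical across groups (FA 0.45, MD 0.80 × 10⁻³ mm²/s, ~400
streamlines per direction, 10 % lognormal jitter): the tract stage is
generated under a group-null. A per-subject lognormal skill factor
(CV 0.25) provides between-subject variance; without it group effects
would be inflated to absurdity because trial sampling would be the only
within-group error source. All per-stage seeds derive from one master
seed via named seed sequences, so a re-run is bit-identical.

## Numerical choices and problem sizes

Design matrices are built on a 50 ms oversampling grid; rank
deficiency is reported with the names of the collinear columns.
The demo pipeline uses 60 voxels per region and 1,000 permutations;
the validation suite uses 10,000 signal-free replicates (M = 4,
P = 100) for the null-bias check, 100 simulations (P = 200) for RDM
recovery, and 1,000 simulated datasets for type-I calibration of the
permutation test and the ANCOVA — sizes chosen so the whole suite runs
comfortably on a laptop while keeping Monte-Carlo error well below the
tolerances tested.

## Known limitations

Deviance is sensitive to the release-band choice for noisy trials near
baseline. The difficulty fixture matrix is synthetic; rankings from it
are illustrative only. The MDS construction requires the target RDM to
be Euclidean-embeddable (true for any RDM derived from real patterns).
The ANCOVA assumes balanced within-subject designs and will refuse
unbalanced tables rather than approximate them. Homotopy estimates are
attenuated toward zero by estimation noise in the ipsilateral RDM, so
generator-level coupling is recovered in ordering but not magnitude.
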
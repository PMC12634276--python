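# Methods

`rewardrs` implements a trial-to-trial neural-consistency analysis of
reward receipt — the mean pairwise correlation between single-trial
multivoxel activation patterns, here called representational similarity
(RS) — on fully synthetic fMRI cohorts that emulate a two-group
adolescent study (anorexia nervosa, AN, versus controls, CON). This note
describes the generative model, each analysis stage, the numerical
choices, and what the synthetic setting can and cannot demonstrate.

## Task and acquisition model

Each participant completes two scanning sessions, one with
anxiety-provoking word stimuli and one with neutral words. A session
holds 60 trials inside a 487-volume run at TR = 1 s. A trial is: fractal
cue 2000 ms → jittered ISI → word 2000 ms → 250 ms gap → reward/
non-reward feedback → jittered ISI. Reward is Bernoulli(0.5),
independent of behaviour. Jitters live on the discrete grid
{1250, 1500, …, 2500} ms.

Unconstrained i.i.d. jitters average 1875 ms, and 60 trials would then
average ≈ 540 s — longer than the 487 s run. Real designs resolve this
with jitter optimization software, which is out of scope here. Instead,
per-jitter increments above the 1250 ms floor are sampled sequentially
under the total run-length budget and then randomly permuted across the
120 jitter slots. The design therefore always fits, jitters remain on
the discrete grid, and no slot is systematically shorter than another;
the cost is mild negative correlation between jitters within a session,
which none of the downstream statistics are sensitive to. Feedback
duration is not part of the task description we emulate; it defaults to
1000 ms and is configurable.

Word stimuli: each synthetic participant rates a pool of words (1–9
anxiety scale); the 20 highest-rated disorder-specific (AN) or general
anxiety (CON) words form the anxiety set, and the 20 lowest-rated
neutral words are chosen, resolving rating ties in favour of the subset
whose mean syllable count best matches the anxiety set. Word identity
carries no signal downstream; the selection logic is modelled because
it is part of the study design.

## Generative model for multivoxel patterns

The phantom brain is a small voxel grid (24³ by default, 16³ in the demo
profile) carrying seven disjoint cubic ROIs named for the reward and
cognitive-reward-control regions of the study mask (NAcc, VTA,
basolateral amygdala, mOFC, dlPFC, vlPFC, SMA). Volumes are generated
already aligned, so no registration exists anywhere in the pipeline.

Within a condition, trial *i*'s feedback amplitude pattern over ROI
voxels is

    p_i = sqrt(ρ) · c + sqrt(1 − ρ) · ε_i

with `c` a per-subject, per-condition template and `ε_i` fresh noise,
both standard normal per voxel. Both components have unit variance, so
the expected Pearson correlation between any two trial patterns equals
ρ exactly — the single generative parameter the whole RS pipeline is
validated against. The two rewarded-condition templates share a
correlation κ (default 0.5), giving an analytic expected
cross-condition RS of κ·sqrt(ρ_A·ρ_B).

BOLD synthesis: each feedback event contributes its pattern times the
HRF-convolved event boxcar; fractal and word phases contribute separate
random nuisance patterns; voxel noise is AR(1) (φ = 0.3, marginal sd 2.0
by default) on top of a constant baseline of 1000; volumes listed as
spikes receive a global intensity jump (default 12, i.e. 6 noise sds).
Spike counts per run are Poisson with mean 12, capped at 65 — matching
the censoring range reported for the real acquisition (0–65 of 487
volumes, ≈ 0–13%).

Cohort defaults follow the study sample: 25 AN / 22 CON, PDS (pubertal
development score, range 5–20) drawn at 14.2 ± 4.3 (AN) and 17.9 ± 1.4
(CON), adjusted-BMI percentiles at 27 ± 18 vs 63 ± 23, and clinical
scores (EDE, BAS, CDRS, HAM-A, YBC-EDS) centred on the reported group
means. Reliability means encode the study's key finding as ground
truth: ρ(neutral rewarded) = 0.12 (AN) vs 0.20 (CON), with all other
conditions equal across groups at 0.16–0.18. These ρ values are in the
range typically recovered by trial-level RSA and produce mask-level RS
z-values of ≈ 0.1–0.2, comparable in magnitude to published
single-trial consistency estimates.

What the generator does **not** emulate: hemodynamic nonlinearity,
physiological (cardiac/respiratory) noise, spatial autocorrelation of
the noise, susceptibility dropout, motion beyond global intensity
spikes, or behaviour. Passing tests therefore show that the estimators
are correct and well-calibrated under the stated model — not that the
pipeline is robust to every artifact of real data.

## Censoring and single-trial estimation

DVARS is the root-mean-square volume-to-volume intensity change within
the union ROI mask, computed after rescaling the run to a within-mask
median of 1000 (making the metric invariant to global intensity
scaling; the value at index 0 is 0). Volumes above the boxplot fence
Q75 + 1.5·IQR of the run's own DVARS values are censored by row
deletion, which is equivalent to spike regressors for OLS point
estimates.

Single-trial betas use the least-squares-sum (LSS) scheme: one GLM per
feedback event with regressors [target event, sum of all other feedback
events, fractal-phase sum, word-phase sum, cosine high-pass drift basis
(100 s cutoff), intercept], all event regressors convolved with a
canonical double-gamma HRF (response gamma peaking near 5 s, undershoot
at 16 s with ratio 1/6, 32 s support, boxcars built on a 10× oversampled
grid). Regressors that are identically zero (e.g. no other trials) are
dropped; a design left rank-deficient by censoring raises an error
naming the offending columns, and the estimation loop can optionally
skip such trials with a warning — mirroring the "approximately 30
retained trials per condition" character of censored real data.

A note on identifiability: LSS collapses all non-target trials into one
summed regressor, so with overlapping responses it recovers
heterogeneous per-trial amplitudes only approximately (exactly, when
responses do not overlap or when only two trials exist). The tests pin
the exact cases to machine precision and bound the approximation in the
realistic overlapping regime at the level that matters: the RS statistic
computed from estimated betas tracks the RS of the generating patterns
to within 0.05.

## RS statistics

- **Similarity matrix**: trial × trial Pearson correlations across
  voxels; zero-variance patterns are excluded with a logged warning.
- **Mask-level RS**: the mean of the N(N−1)/2 strictly-lower-triangle
  entries (each unordered pair once, diagonal never included).
- **Fisher transform**: z = atanh(r) with r clipped to 1 − 1e−7 in
  magnitude so degenerate noiseless fixtures stay finite.
- **Searchlight**: spheres of 2-voxel radius (33 voxels when fully
  interior) centred on every mask voxel, intersected with the mask at
  boundaries; spheres below 5 voxels yield a missing value. The map
  value is the mean pairwise trial correlation within the sphere.
- **Aggregation modes**: the per-participant summary either averages
  z-transformed searchlight voxel values over the mask (default) or
  z-averages the pairwise correlations of one whole-mask similarity
  matrix. Both are computed and reported side by side in the pipeline
  output — they are distinct estimands and are never silently mixed;
  on simulated cohorts they rank participants nearly identically
  (Spearman ≥ 0.9).
- **Cross-condition RS**: the mean z over all N_A × N_B correlations
  between rewarded-trial patterns of the anxiety and neutral sessions,
  aggregated in the same two modes.

## Group inference

RS summaries are log-transformed before ANCOVA (log of mean z; when a
cohort contains non-positive values the whole cohort is shifted by
−min + 0.01 and the shift recorded in the output). The ANCOVA is the
linear model value ~ group + PDS with the group F on (1, n−3) df and
η² = SS_group/SS_total (partial η² also emitted). Sensitivity is probed
with leave-one-ROI-out MANOVAs: Wilks' Λ for the group term adjusting
for PDS on the remaining per-ROI RS columns, using Rao's exact F for a
single hypothesis df.

Searchlight maps enter a nonparametric permutation framework:
covariate-adjusted two-sample t maps, Freedman–Lane permutation (data
residualized on [1, PDS], residual rows permuted, nuisance fit added
back, full model refit; simple label permutation available behind a
flag), TFCE enhancement of every permuted map, and voxelwise FWE
p-values from the max-TFCE null distribution with the observed statistic
included (so p ≥ 1/(n_perm+1)). Within-group tests use sign-flipping of
covariate-residualized maps with the covariate mean-centred, making the
tested intercept the covariate-adjusted group mean. Two-tailed inference
runs separate positive/negative TFCE passes with a Bonferroni factor of
2 over tails.

TFCE uses E = 0.5, H = 2, 26-connectivity, and a discrete threshold
step of max(|map|)/100 by default; inside the permutation loop the step
is fixed from the observed map so permuted maxima are commensurable.
The default permutation count is 5000; tests and the demo profile use
500 for desk-scale runtime, which bounds attainable FWE p at 1/501.

The design's power statement is reproduced by solving for the smallest
Cohen's f whose noncentral-F power reaches 80% at α = 0.05 with
df = (1, 44) and noncentrality λ = f²·N (N = 47): f ≈ 0.42.

## Clinical associations

Three mixed-model presets run on the AN group (REML, statsmodels
MixedLM): adjusted-BMI percentile over entry + 6 monthly timepoints with
time × cross-condition-RS interaction; EDE over entry and 6 months; BAS
over entry and 6 months with neutral-reward RS and no interaction. PDS
enters every preset. Random effects are subject intercept and time slope
with an unconstrained 2 × 2 covariance; with only two timepoints a slope
is unidentifiable, so those presets reduce to a random intercept with a
logged warning. Non-convergence is flagged on the result, never silent.

Exploratory baseline associations use partial correlations (Pearson,
and Spearman via rank-transform-then-Pearson) between neutral-reward RS
and symptom measures, residualizing both variables on [1, PDS], with p
from the t transform on n − 3 df. Benjamini–Hochberg FDR adjustment is
applied over an explicitly supplied family (the three whole-sample
tests run together), never inferred. The step-up adjustment is
monotone and order-preserving; it is not idempotent in general, and no
such property is relied on.

## Problem sizes and reproducibility

The demo profile (6 + 6 subjects, 16³ grid, 60-trial sessions, 500
permutations) runs the full pipeline in a few minutes on one CPU; the
test suite validates heavier properties at reduced scale — RS recovery
at 100 replicates × 30 trials × 200 voxels, permutation type-I
calibration at 100 null cohorts × 500 permutations on a 6³ grid, mixed-
model coverage at 200 replicates — sizes chosen so each suite completes
in minutes while keeping Monte-Carlo error well inside the asserted
bounds. Every stochastic stage takes an explicit seed; cohort trees are
bit-reproducible for a fixed seed, and the pipeline manifest records
the config hash and logical checksums of every table so a rerun can be
verified equal.

## Known limitations

- The reliability model is shared-template-plus-idiosyncratic-noise
  with equal variances; amplitude-scaling or voxel-subset forms of
  consistency are not modelled.
- LSS bias under heavy response overlap is inherited from the method
  itself; the pipeline quantifies it only at the RS level.
- The permutation framework supports whole-cohort exchangeability only
  (no blocks); parametric random-field correction and variance
  smoothing are deliberately absent.
- Clinical trajectories are linear-plus-noise with optional RS-linked
  slopes; dropout, floor/ceiling effects and measurement error models
  are not simulated.
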
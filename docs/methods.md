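# Methods

This note documents the models, conventions, and numerical choices behind
`hebbrsa`, and what the synthetic-data tests do and do not establish about
real data.

## Experiment model

A session is 8 runs of 18 trials (144 total). Each trial presents a
nine-tone study sequence over 3 s (200 ms tones, 150 ms gaps), a silent
delay of 3, 6, or 9 s, then a 3 s probe sequence and a match/mismatch
response. Tones come from the maximal geometric ladder between 300 and
2600 Hz with ratio 1.3 (nine frequencies); sequences are permutations of
the full ladder, so every tone is distinct and an adjacent transposition is
always defined. Three sequences (S1–S3) repeat covertly — 24 study trials
each — interleaved with 72 unique novel sequences; the generator rejects
novel draws that collide with S1–S3 or with each other. Counts are balanced
at 36 per sequence-type × probe-type cell and 12 per
sequence-type × probe-type × delay cell (the delay randomization is not
constrained by the task description; balancing it maximizes design
efficiency). Mismatch probes swap one adjacent pair of tones, the stricter
of the two plausible readings of "two elements transposed", matching the
intended task difficulty. The no-back-to-back constraint on repeating
sequences is enforced across run boundaries as well as within runs, and
order sampling retries up to a bounded budget before reporting
infeasibility. ITIs are uniform on [4, 10] s (mean 7 s); trial onsets
accumulate encoding + delay + probe + ITI within each run, and are recorded
to millisecond precision so the events TSV round-trips losslessly.

## Sequence dissimilarity (EMD)

Each sequence is a discrete distribution with mass 1/9 at coordinates
(serial position k, pitch p_k). The ground cost between tone k of one
sequence and tone l of the other is

    c(k, l) = w_pos * |k - l| + w_pitch * |p_a(k) - p_b(l)|,

with both weights defaulting to 1 and pitch measured in pool steps,
log_1.3(f / 300), so one ladder step and one serial position carry equal
cost. This weighted L1 form is the simplest ground metric that makes it
costlier to move tones of different frequency across larger serial
distances; pitch scale (pool steps, semitones, log-Hz) and the two weights
are configuration, flagged for sensitivity analysis, because nothing in the
task fixes them uniquely. With equal unit masses the balanced transport
problem attains its optimum at an assignment, so the solver is the
Hungarian algorithm (`scipy.optimize.linear_sum_assignment`) — an exact
optimum, verified in tests against exhaustive enumeration of all
assignments up to length 6. RDMs store raw EMD without normalization:
the downstream statistic is rank-based, so scale is irrelevant. Ties among
optimal assignments cannot affect the optimal cost.

## Synthetic BOLD generator

The generator emulates the statistical structure the analysis assumes,
not real physiology. Per trial phase, the evoked multivoxel pattern is

    pattern = amp_phase * ( s * template(seq) + sqrt(1 - s^2) * fresh + m ),

where `template(seq)` is a fixed standard-normal voxel vector per sequence,
`fresh` is independent per trial and phase, and m (`mean_activation`,
default 1) is a uniform offset that gives ROIs a univariate response
without affecting pattern correlations. The mixing weight s is the
pattern-stabilization schedule w(r) for repeat trials — linear from 0.2 in
run 1 to 0.8 in run 8 by default, the minimal mechanism that produces
diverging repeat/novel learning trajectories — and `novel_structure_gain`
(default 0) for novel trials. No quantitative effect sizes are available
for the real phenomenon, so defaults are chosen to reproduce its sign and
ordering, not magnitudes.

Patterns are convolved with a canonical double-gamma HRF — gamma densities
with modes placed exactly at the stated peak (6 s) and undershoot (16 s)
times, peak:undershoot ratio 6, normalized to unit peak — using a 0.1 s
internal grid sampled at TR 1.37 s. Every event regressor is scaled to
unit peak, so an amplitude parameter means "peak response height"
regardless of event duration; the same convention is used by the simulator,
the single-trial design matrices, and the phase GLM, keeping the estimators
consistent with the generative model (delay events range 3–9 s, and
un-normalized boxcar convolutions would otherwise confound duration with
amplitude). Default phase amplitudes are 0.5 / 0.2 / 0.08 (encoding /
delay / probe) in units of single-voxel noise SD — single-trial responses
around half the noise floor, a realistic low-SNR regime; the graded
ordering mirrors the phase profile the analysis is meant to recover.
Because the encoding and delay epochs of a trial are adjacent, their
regressors overlap and some cross-phase leakage of estimated betas is
unavoidable (the variable delay only partially decorrelates phases); the
amplitude separation is what keeps the recovered phase ordering stable.

Noise has three parts, mirroring a confound-regressed dataset: Legendre
polynomial drift to degree 5 with random voxel coefficients; five smooth
shared component series (Gaussian-filtered white noise, unit variance) with
random voxel loadings, handed to the estimator as *known* nuisance — they
stand in for component-based physiological confounds that a real pipeline
estimates from tissue masks, which is out of scope here; and stationary
AR(1) voxel noise with rho = 0.3 (BOLD-like and cheap). ROIs are abstract
contiguous voxel blocks with labels; there is no spatial geometry,
smoothness, motion, or susceptibility artifact, so passing tests demonstrate
statistical correctness of the pipeline, not robustness to real-data
artifacts. Behavioral responses are Bernoulli draws with delay-dependent
accuracy defaulting to the observed proportions correct (.63/.57/.50 at
3/6/9 s); the behavioral and neural generators are independent, so the
simulator does not encode any brain–behavior coupling.

## Single-trial estimation

Per run: (1) voxel time series are residualized against the nuisance matrix
(degree-5 polynomial basis + 5 components) by least squares, with a
pseudoinverse fallback and warning if the matrix is rank deficient; (2) the
phase design holds one unit-peak HRF regressor per trial plus a fixed-effect
column equal to the exact row sum of the trial columns, which absorbs the
common evoked response and regularizes trialwise estimates; (3) each voxel's
denoised series is regressed on the design by PLS1. Columns of X are
mean-centered but not variance-scaled, and y is centered per voxel, so betas
keep data units. Nuisance is projected out of Y only, not X (a
`denoise_design` switch documents the alternative); estimation is per run,
with concatenation handled at the RSA stage, matching per-run RDM
bookkeeping.

PLS1 coefficients are computed by restricting the least-squares problem to
the Krylov subspace span{X'y, (X'X)X'y, ...} built with fully
re-orthogonalized Lanczos vectors — the classical equivalence between PLS1
and conjugate-gradient iterations on the normal equations. This yields
coefficients identical to NIPALS/SIMPLS at the same component count
(verified against scikit-learn's `PLSRegression` to 1e-8) and reduces to
the (minimum-norm) OLS solution when the subspace saturates, which anchors
correctness independently of the component count. The default is 5
components: the underlying component count is not pinned down by the
procedure's description, and 5 balances shrinkage against bias for 18–19
columns; component count above rank is clipped with a warning, and a basis
vector is dropped when its norm falls below 1e-12 of the initial gradient.

## RSA

Neural dissimilarity is correlation distance (1 − Pearson) between trial
beta patterns (Euclidean available as configuration); a zero-variance
pattern yields missing entries, excluded pairwise downstream. The RSA
effect is the Spearman correlation between lower triangles of the model and
neural RDMs — rank-based, hence invariant to the EMD's arbitrary scale and
to any monotone transform of either RDM; fewer than 3 valid pairs is an
undefined statistic. Identical-sequence pairs (model dissimilarity 0) are
included in the repeat analysis: they carry the within-sequence similarity
signal that defines the repetition effect. Pairs spanning runs are included
in pooled analyses and excluded per run by construction; the pooled effect
is computed on the concatenated pair set and is *not* the mean of per-run
effects (asserted on a constructed counterexample). The repeat-minus-novel
subtraction is performed at the statistic level, since matrix-level
subtraction is ill-defined across different trial sets.

## Univariate ROI selection

The phase GLM models encoding and delay split by sequence type and probe
split by sequence × probe type (eight condition regressors) plus nuisance;
voxelwise least-squares betas are averaged within ROI and across the split
regressors of each phase. Across subjects, one-sample t-tests per
(ROI, phase) are Benjamini–Hochberg adjusted within phase (the classic
step-up variant, the default of standard adjustment routines), and ROIs are
grouped by the conjunction of encoding/delay significance at alpha = 0.05,
with the boundary value assigned to the not-significant side. Probe-phase
activity is modeled but not used in grouping. A rank-deficient design
raises an error naming the near-collinear columns.

## Group inference

Mixed models are fit by REML with a random subject intercept (random slopes
available through `MixedModelSpec.random`; a singular or non-converged
slope fit falls back to the intercept-only model with a warning, and the
optimizer falls back bfgs → powell → nm). Interaction and main-effect tests
are Wald F-tests on the fixed-effect coefficients with the fixed-effects
residual degrees of freedom — a deliberate, recorded approximation; exact
small-sample df corrections are out of scope, and the null calibration test
confirms the rejection rate is compatible with the nominal level at the
cohort sizes used. Marginal means are model-based cell predictions with
normal-approximation 95% CIs. A two-stage summary-statistics engine
(per-subject cell means → repeated-measures ANOVA) is provided as a clearly
labelled approximation valid for balanced within-subject designs. The
learning test enters run as a centered linear covariate and reports the
sequence-type × run coefficient; positive means the repeat slope exceeds
the novel slope. Per-ROI contrasts of the repeat effect against zero use
two-sided p-values with the sign carried by t (the "above zero" reading is
enforced by requiring t > 0 for significance), BH-corrected across ROIs
within each phase — the correction family is a choice, since none is
prescribed. d′ is Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate) with mismatch
probes as the signal class; the add-0.5/add-1 log-linear correction engages
only when a rate is exactly 0 or 1, so d′ is invariant to trial count at
fixed interior rates.

## Problem sizes and determinism

The recovery studies use a cohort of 8 subjects per seed over 20 seeds
(one 24-voxel ROI, full 8-run sessions), and the null calibration uses 200
reduced simulations (2 runs, 3 × 8 voxels, 5 subjects, zero signal) —
sizes chosen to give stable pass/fail behavior at desk scale; the full
23-subject default remains available via `SimParams.n_subjects`. All
randomness flows through explicit integer seeds (`numpy` Generator
seed sequences keyed by cohort seed and subject), so identical seeds give
byte-identical designs, data, and results; mixed-model optimizers are
deterministic given the data.

## Known limitations

- The generator's stabilization schedule is an explicit modeling assumption;
  the real phenomenon has no measured generative model or effect sizes.
- Cross-phase regressor overlap biases per-phase effects toward each other;
  conclusions about phase ordering hold under the default amplitude
  separation, not for arbitrarily small differences.
- Wald/residual-df inference is approximate for very small cohorts; the
  two-stage engine is exact for balanced designs but discards within-cell
  information.
- Abstract ROIs carry no anatomy: atlas-level claims (which parcels fall in
  which conjunction group) cannot be reproduced without real data.
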
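# Methods

## The analysis model

The package's core quantity is per-room pattern **reliability** at a
searchlight: templates for the 23 rooms are estimated by ordinary least
squares against an HRF-convolved, z-scored block design, separately for two
pre-learning room-video runs; the cross-run Pearson similarity matrix
`S` (rows = run-1 rooms, columns = run-2 rooms; not symmetric and never
symmetrized) gives

    rel_r = S[r, r] − mean_{r' ≠ r} S[r, r'],

using row `r`'s off-diagonal entries. A group reliability map is a
one-sample t-test across participants of the room-averaged reliability per
searchlight, BH-FDR corrected at q < 0.05.

**Decoding.** Condition classifiers are L2-penalized multinomial logistic
models (scikit-learn; C = 1.0, lbfgs, max_iter 200, tol 1e-3) trained on the
stacked GLM templates of the N−1 other participants — 23 rows per training
participant — with within-fold feature standardization (train statistics
applied to test data). Evidence for event TR `t` is computed from the signal
at TR `t + 4` (hemodynamic shift; trailing event TRs without shifted signal
are dropped). Accuracy is argmax agreement over labeled TRs, ties resolving
to the lowest class id. The selection null shuffles class labels across the
maximal contiguous segments of the label sequence (segment boundaries and
lengths fixed), accuracies and null vectors are averaged element-wise
across runs and participants, and the top-k units by
`(true − null mean) / null sd` form a network (k = 50 by default; ties to
the lowest unit id; zero-sd units excluded). ROCN tests object classes on
room-video object-recall runs, POCN object classes on object-video runs,
and RRCN room classes on object-video runs with classifiers trained on
pre-learning room templates — identical operations, different wiring.
Reinstatement scores are TR-pooled means of a class's evidence over the
timepoints it was verbally recalled (all 11 guided runs pooled; free recall
separate), averaged across network members.

**Scaffold statistics.** Within each participant and task, reliability at
the focal searchlight is Pearson-correlated with the paired objects'
reinstatement scores across complete room-object pairs (rows with missing
scores or covariates dropped first; at least 4 complete pairs per cell);
Fisher-z values (r clipped at |r| = 1 − 1e−7) are averaged across
participants, then tasks. The permutation null applies, per participant,
**one** room-label permutation to the score vector shared by both recall
tasks — the pairing that the shuffle breaks is common to the tasks, and
shuffling tasks independently demonstrably understates the null variance of
the task-averaged composite. Missing rows travel with the shuffle, which
makes the scheme exactly exchangeable conditional on the recall sets (the
complete-pair count is permutation-invariant). p-values are two-sided with
an add-one correction, p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm), BH-FDR
across searchlights.

The **participant-specific ΔR²** compares the R² of predicting a
participant's scores from their own reliabilities (simple OLS, so R² is the
squared correlation) with the average R² over refits using each other
participant's room-aligned reliabilities; the same label shuffles supply
the null, and the final mask intersects positive significant ΔR² with the
positive significant raw map. The **partial-correlation control**
residualizes both scores and reliabilities on two RRCN room-reinstatement
covariates (room-recall and object-recall timepoints, pooled across both
recall tasks into one score per room) via OLS with intercept, correlates
the residuals, and shuffles the score residuals in the null using the same
room permutations restricted to the valid subset — which coincides with
the raw shuffle when every room is valid, so constant-zero covariates
reproduce the raw map exactly (constant covariate columns are dropped from
the residualization design). The contrast map is the paired difference of
raw and partial statistics and of their per-permutation nulls.

## The synthetic generator

`palace.sim.simulate_dataset` plants a known causal structure:

* group room/object templates `G_r`, `O_o`: iid unit-normal vertex vectors;
  participant template `P = sqrt(1−τ)·G + sqrt(τ)·η`;
* reliability `λ_{s,r} = clip(λ0 + g_r + u_{s,r}, 0.01, 0.99)` with a
  group-shared room effect `g_r ~ N(0, g_sd²)` and an idiosyncratic
  `u_{s,r} ~ N(0, u_sd²)`; run-k room pattern
  `sqrt(λ)·P + sqrt(1−λ)·fresh noise` (reliability is a signal *share*, so
  the empirical statistic is monotone in it);
* room reinstatement amplitude `m = γλ + N(0, σ_m)`; object amplitude
  `a = α + β_dir·λ + β_med·m + N(0, σ_a)`;
* per run, active condition patterns are weighted by their amplitudes on a
  0.1 s grid, convolved with the HRF, sampled at TR onsets, summed, plus
  white vertex noise, z-scored per vertex per run. Only a configured subset
  of searchlights carries structure; the rest are pure noise. Pre-learning
  room videos present rooms at amplitude 1 (run-specific patterns);
  object videos present objects at amplitude 1 plus the paired room at `m`
  (the task is simultaneously a room-recall task, and RRCN needs that
  signal); room-video object-recall runs carry the cued room at `m` plus
  the recalled object at `a`; recall transcripts interleave room and object
  segments (uniform 3–10 s, small gaps), guided runs along 5-room
  self-avoiding walks on the palace graph, free recall over all rooms.

### Parameters (units, defaults, rationale)

| parameter | default | meaning / why |
|---|---|---|
| `n_participants` | 25 | study cohort size |
| `n_rooms`, `degree_sequence` | 23; 16×deg-2, 6×deg-3, 1×deg-4 | the palace layout |
| `tr_seconds` | 1.3 s | sampling interval |
| `video_seconds`, `isi_seconds` | 10 s, 5 s | block design |
| `n_guided_runs`, `guided_path_len` | 11, 5 | recall task structure |
| `vertices_per_searchlight`, `n_searchlights` | 30, 40 | desk-scale map |
| `signal_searchlight_fraction` | 0.25 | testable map specificity |
| `tau_idiosyncrasy` | 0.3 | across-participant template sharing; 0 → perfect transfer, 1 → chance |
| `lambda0`, `g_sd`, `u_sd` | 0.5, 0.20, 0.15 | reliability centered mid-range with a wide spread (~5% clipping); the spread must dominate the ~0.18 measurement SE of a 30-vertex correlation for planted effects to be recoverable — recoverability is the generator's purpose |
| `alpha`, `beta_direct`, `beta_mediated` | 1.0, 0.5, 0.0 | object amplitude model; α sets recall signal on the video scale |
| `gamma`, `sigma_m`, `sigma_a` | 0.2, 0.05, 0.10 | weak room-reinstatement tracking by default; γ is raised explicitly when a mediated path is wanted |
| `noise_sd` | 1.0 | vertex noise per TR; puts single-TR 23-class cross-participant decoding near 0.9 in signal searchlights and at chance elsewhere — strong, but unsaturated, so evidence remains amplitude-sensitive |

The HRF is a canonical double-gamma (gamma shapes 6 and 16, undershoot
ratio 1/6, truncated at 32 s), normalized to unit area so a sustained block
plateaus at its planted amplitude; the same kernel builds design matrices
(where column z-scoring makes the normalization irrelevant).

### What the generator does not emulate

White noise only (no temporal autocorrelation, drifts, motion or
physiology — the emulated preprocessing removes them); no hemodynamic
nonlinearity; no spatial structure within or between searchlights (meshes
for searchlight construction are synthetic); transcripts are perfectly
timestamped and recall is at ceiling. Passing tests therefore demonstrate
the *statistical machinery* — calibration, recovery, dissociation — under
the planted model, not robustness to fMRI artifacts.

## Numerical choices and degenerate inputs

Zero-variance patterns yield NaN similarity entries (warned) and propagate
to NaN reliabilities, excluded pairwise downstream; zero-variance design
columns stay zero with a warning; rank-deficient template designs raise,
naming collinear condition pairs; zero null-sd units in network selection
get z = −inf and a warning; searchlight reduction removes, among units
whose removal keeps every member at or above the coverage floor, the unit
with the largest summed member coverage (ties → lowest center index;
"most redundant" is otherwise underdetermined); hop radius defaults to 2.
The configuration-model graph builder rejects self-loops, multi-edges and
disconnected draws, bounded at 10,000 retries. TR labeling uses the
midpoint rule on half-open intervals [t·TR, (t+1)·TR) — unbiased for block
stimuli and unambiguous at boundaries. Speaking-time tests operate on
within-participant deviations from the participant's grand mean (the
across-participant variant is a one-line change but loses the pairing).
Consecutive repeated rooms are collapsed before the contiguity statistic.

## Validation scale

The replicated experiments (`palace.experiments`) run at 8 participants,
40 searchlights × 30 vertices (10 with signal), 200 permutations, k = 10:
20 replicate datasets for null calibration (type-I measured ≈ 0.05 at
α = 0.05), 3–4 replicates for planted recovery (β_dir = 0.6 → 100% of
signal searchlights recovered, false positives ≤ 5%), the mediation
dissociation (β_dir = 0, γ = 0.8, β_med = 0.8 → raw map full recovery,
partial composite within its permutation-null spread of zero, contrast
significant everywhere signal was planted; β_dir = 0.6, β_med = 0 →
partial map retained, contrast empty) and the ΔR² comparison (total
reliability spread 0.25 allocated entirely to `u_sd` or to `g_sd`). Each
replicate completes in a few seconds on one core.

## Known limitations

Reliability uses row-wise off-diagonals (the column variant is available
via transposing `S`); the own-vs-other comparison refits OLS on the other
participant's reliabilities rather than transferring coefficients — with
single-predictor OLS the refit R² is scale-free, which is why ΔR² is
exactly zero when all participants share one reliability vector. The
partial-correlation null shuffles residuals (not a full
Freedman–Lane scheme); its type-I behavior is close to, but not exactly,
nominal when covariates explain little variance. Searchlight reduction is
deterministic but its exact membership depends on vertex labeling through
the tie-break; only the structure (unit count, coverage profile) is
label-invariant.
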
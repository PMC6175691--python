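# Methods

This note documents the models implemented in `connlearn`, the conventions
chosen where several are defensible, what the synthetic-data generator does
and does not emulate, and the numerical details that affect results.

## Behavioral skill score

The block-level skill measure is
`ln[(1 − er) / (er · (ln d)^b)]` with `b = 5.424`, where `d` is the mean
movement time of the block in seconds and `er` the fraction of gate events
over- or undershot. Skill learning is the last-minus-first-block difference.

Two conventions needed fixing:

- **Parameterization.** The compact typeset form of the score in
  circulation is ambiguous between `(ln d)^5.424` (the original
  parameterization of this task's speed–accuracy function) and
  `(ln d)/5.424`. The exponent reading is the default — it matches the
  original parameterization — and the divisor reading is selectable via
  `SkillParams(parameterization="divisor")`. The two differ by an affine
  offset per block, so block *differences* under the divisor reading equal
  those under a plain `ln d` denominator.
- **Boundary error rates.** `er = 0` or `1` makes the score infinite. A
  half-count clamp replaces boundary rates with `1/(2G)` or `1 − 1/(2G)`,
  `G` = gate events per block (175 for 35 trials × 5 gates). Disable it to
  get a domain error instead. Durations are in seconds and must exceed 1 s
  so that `ln d > 0`; this task's movement times are seconds-scale.

## Temporal preprocessing

Order: nuisance regression (six motion parameters plus WM/CSF-like
regressors, with intercept) first, then an ideal rectangular band-pass of
0.01–0.1 Hz (DFT components outside the band, including DC, are zeroed).
The ideal filter is idempotent and matches the convention of the common
resting-state toolboxes; edge effects are accepted. Designs with condition
number above 1e8 are rejected, naming the collinear columns.

Framewise displacement at frame t is the sum of absolute backward
differences of the three translations (mm) plus `radius ×` the summed
absolute rotation differences (rad), rotations projected on a 50 mm sphere
(configurable); FD of the first frame is 0. Scrubbing deletes frames with
FD > 0.5 mm and flags a subject for exclusion when more than 10% of frames
are deleted; correlation is then computed on the concatenated retained
frames (no interpolation), and FD is dropped as a covariate since scrubbing
replaces it.

## Graphs and diagnostics

Connectivity is the Pearson correlation of preprocessed node series,
diagonal excluded. Proportional thresholding keeps the
`k = round(d · n(n−1)/2)` strongest **positive** correlations (negative
correlations never become edges); rounding is half-away-from-zero and ties
break by ascending node-index pair, which makes the density ensemble nested
and bit-reproducible. Default grid: 1%–40% in 1% steps.

Metric conventions, each validated against a brute-force oracle in the test
suite (exhaustive triangle/triple counts, Floyd–Warshall distances,
exhaustive partition search, endpoint-degree correlation):

- **Transitivity**: 3 × triangles / connected triples (global ratio).
- **Characteristic path length**: mean shortest path over *reachable*
  ordered pairs only — the convention that stays finite on the disconnected
  graphs that 1% density produces.
- **Global efficiency**: mean inverse distance with 1/∞ = 0.
- **Small-worldness** σ = γ/λ: γ normalizes the **mean local clustering
  coefficient** (so the standalone transitivity metric and σ use distinct
  clustering estimators, as the seven-metric list implies), λ normalizes L;
  references are degree-preserving rewirings with 10·|E| attempted swaps,
  20 per graph by default (σ's Monte-Carlo SD is well under 1% at
  connectome scale). When the references have zero clustering — possible at
  very sparse densities — σ is undefined at that density and skipped with a
  logged count, like assortativity on regular graphs.
- **Modularity Q**: Newman's quality of the best partition found. Graphs of
  ≤ 8 nodes are solved exactly by exhaustive partition enumeration; larger
  graphs use seeded Louvain restarts plus a greedy-agglomerative start, each
  refined by single-node moves (including singleton splits) and pairwise
  community merges to a fixed point, with ties resolved toward the
  lexicographically smallest canonical assignment. Restart count defaults
  to 4.
- **Assortativity**: Pearson correlation of endpoint degrees over both edge
  orientations; undefined (distinct error) on regular graphs.
- **Mean connectivity**: mean off-diagonal r of the *unthresholded* matrix.

Diagnostics are computed per density and averaged arithmetically across the
grid; densities where a metric is undefined are skipped for that metric and
counted.

## Association model and multiple testing

Each density-averaged diagnostic is regressed (OLS) on skill learning with
age, sex, and mean FD as covariates of non-interest; the reported effect
size is the partial correlation `r = t/√(t² + df)`, `df = n − p` with `p`
model columns including the intercept. Two-sided p-values; the family of
seven diagnostics is corrected with Hochberg's step-up rule
`adj(i) = min_{j ≥ i} (m − j + 1) · p(j)` (capped at 1, mapped back to
input order). The implementation is cross-checked against the step-up
routine in statsmodels.

## Network-based statistic

Edge values are Fisher-z transformed by default (|r| clipped at 1 − 1e−6
with a warning count; raw-r mode retained for sensitivity analyses). Each
upper-triangle link gets its own OLS; the primary threshold is the
one-sided Student-t quantile at p = 5 × 10⁻⁴ (positive tail by default,
matching a directed hypothesis; an explicit t threshold may override).
Suprathreshold links form connected components; the component statistic is
the **edge count** (extent). The null distribution of the maximum component
size uses Freedman–Lane permutation: fit the reduced model (intercept +
covariates), permute its residuals, add back the reduced fit, recompute all
edge statistics. This respects the covariates where plain label shuffling
would not. FWE p = (1 + #{null max ≥ size})/(1 + M) — the add-one estimator
never reports zero and is a valid p-value. M defaults to 5,000; all
randomness flows from a single seed.

Two invariants worth knowing: running with the p-threshold or the
equivalent explicit t-threshold selects identical edge sets, and lowering
the primary threshold never shrinks a component (nestedness, the basis of
initial-threshold sensitivity checks).

## Reliability and drug contrast

ICC(2,1) (absolute agreement) and ICC(3,1) (consistency) come from the
two-way ANOVA mean squares; interpretation uses the Fleiss bands (< 0.4
poor, 0.4–0.75 fair to good, > 0.75 excellent). Cross-checked against
pingouin in the tests.

The two-level repeated-measures drug contrast is implemented as a
difference-score regression: the within-subject difference is regressed on
an intercept plus mean-centered covariates; F(1, df) is the squared
intercept t with df = n − 1 − q. For two conditions this is algebraically
the repeated-measures ANCOVA F; df is always reported, never assumed,
because the effective covariate count varies by analysis. A zero-variance
difference (constant shift) is flagged degenerate rather than reported as
an infinite F. The dose relationship is the partial correlation of
residualized dose and subnetwork connectivity, `t = r√(df/(1 − r²))`,
`df = n − q − 2`.

## Synthetic cohorts

The generator emulates a skill-learning study *design*, not its physiology:

- Per subject, a target correlation matrix = shared modular background
  (4 modules, within-module r 0.25, symmetric N(0, 0.03) perturbation,
  drawn once per cohort) with the implanted edges set to
  `clip(base + β·g_s + ε, ±0.95)`, `g_s` the standardized latent skill
  score, `ε ~ N(0, edge_noise_sd)` per subject and edge. The matrix is
  projected to a valid correlation matrix (eigenvalue clipping at 1e−6,
  re-normalization to unit diagonal) and frames are sampled as zero-mean
  correlated Gaussian noise. The ±0.95 clip keeps Fisher z finite.
- Motion traces are smooth random walks with Bernoulli spike frames whose
  translation jumps exceed the 0.5 mm FD threshold (rotations stay smooth —
  enough to exercise FD and scrubbing). Nuisance tables are smoothed noise.
- Covariates: age ~ N(26.6, 7.5) clipped to [18, 60], sex ~ Bernoulli(33/60),
  mean FD computed from the generated motion. Defaults mirror the emulated
  cohort: 60 subjects, 264 nodes, 240 frames at TR = 2 s.
- Retest pairs place a latent value plus session noise on a plausible
  mean-connectivity scale with the between/total variance ratio equal to
  the target ICC. Drug pairs reduce the implanted-edge targets by
  `decrement × dose` and resample both sessions independently.
- Behavior: block mean durations decay geometrically at the learning rate;
  trial durations are Normal around the block mean (5% CV, floored at
  1.01 s); gate misses are Bernoulli with geometrically decaying
  probability. Per-subject behavioral distributions for this task are not
  available, so these are conventions, not calibrations.

What passing tests on this generator shows: the pipeline's error control,
power, reliability estimation, and determinism under the stated model. What
it does not show: robustness to hemodynamics, spatial preprocessing,
atlas choices, autocorrelated noise, or non-Gaussian connectivity — the
generator produces temporally white signals with exactly the implanted
second-order structure.

## Problem sizes and numerical choices

Simulation-based tests run at reduced scale chosen to keep Monte-Carlo
error small relative to the asserted tolerances: NBS family-wise error uses
200 null cohorts of 30 subjects × 60 nodes with M = 200 permutations;
effect recovery uses 20 runs of 40 subjects × 60 nodes. For the
family-wise-error calibration the primary threshold is scale-matched to
p = 0.01 so that the expected suprathreshold edge count per null
permutation (1,770 × 0.01 ≈ 17.7) matches the full 264-node analysis
(34,716 × 5 × 10⁻⁴ ≈ 17.4); at the full-scale threshold a 60-node null
yields under one suprathreshold edge per permutation, the max-component
distribution degenerates to sizes {0, 1, 2}, and the measured rate (~0.012)
reflects discreteness of the component statistic rather than the
permutation machinery being calibrated.

Other numerics: correlation matrices are symmetrized and clipped to
[−1, 1] against floating-point drift; Cholesky sampling adds a 1e−10 jitter;
the t↔r conversions and Hochberg arithmetic are exact. One known
Monte-Carlo sensitivity: ICC estimates at n = 500 carry a sampling SD of
roughly 0.03–0.05 depending on the target, which the ±0.07 recovery
tolerance accommodates.

## Known limitations

- The ideal FFT band-pass assumes stationarity and wraps edges; IIR
  alternatives are not provided.
- Louvain-based modularity above 8 nodes is a heuristic; Q values at
  connectome scale are lower bounds on the optimum (as in all standard
  toolboxes).
- The drug-pair generator shares the placebo session's background with the
  drug session by construction; carry-over or session effects are not
  modeled beyond the randomized order indicator.
- Scrubbing deletes frames; no censoring-aware correlation estimator is
  provided.
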
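# Methods

This note documents the models, conventions and design choices behind
`pdrpnet`, in the order data flows through the package.

## Scaled Subprofile Model / PCA

Regional activities must be strictly positive; preprocessing is
`log → subtract subject mean → subtract cohort mean profile`. Natural log
is used (the conventional choice; any base change is an overall scale
factor absorbed by the downstream z-referencing). Subtracting the
subject's mean log value implements global normalization — it is exactly
division by the subject's geometric mean before the log, so a
multiplicative global scaling of any subject's profile leaves the
residual profiles unchanged (tested at machine tolerance). A single
combined-cohort mean profile is removed; there is no additional
within-group centering.

PCA is computed by singular value decomposition of the residual-profile
matrix rather than by assembling a covariance matrix: numerically stabler
on 66 × 95 matrices and gives the variance-accounted-for directly from
the singular values. Only PC1 is retained; multi-component pattern
combination (e.g. AIC-weighted sums) is out of scope. PC1's sign is
arbitrary, so the pattern is oriented to make the patient mean derivation
score exceed the control mean, and the flip is recorded
(`orientation = ±1`).

Region weights are reported twice: raw (unit Euclidean norm — the
projection basis used for scoring) and standardized over the ROI axis.
Standardization uses the sample (n−1) SD, matching standard statistical
packages. The disease subspace is `|z| ≥ 1` with an inclusive boundary,
split by sign.

## Expression scoring

The topographic profile rating of a profile is the inner product of its
residual profile — built with the *stored* derivation mean profile, so
scoring is strictly prospective — with the unit-norm pattern weights. Any
fixed affine rescaling of the raw score cancels in the z-transform, so no
additional internal scaling constants are applied. The z reference uses
the healthy-control mean and sample SD (n−1); the reference group
therefore maps to 0 ± 1 exactly. The cross-scanner offset is the mean
z-score of the second cohort's own controls; only the mean is corrected,
not the SD — which is why a corrected secondary control group shows
0 ± (something ≠ 1).

## Bootstrap reliability

Resampling is stratified: each replicate draws subjects with replacement
within group, preserving the patient/control sizes, which avoids
degenerate single-group replicates. Each replicate's pattern is
sign-aligned to the point estimate (PC sign is arbitrary per replicate).
The reliability statistic is `point weight / bootstrap SD` (an inverse
coefficient of variation); `bootstrap mean / bootstrap SD` is available
via `statistic="mean_over_sd"`. The threshold (default 3.35) is applied
two-tailed on |Z|. ROIs with exactly zero bootstrap SD receive infinite Z
and are included in the mask; replicates whose residual profiles carry no
variance are redrawn with bounded retries.

## Connectome

Networks are built per group: nodes are an ROI set (whole brain, disease
subspace, or non-subspace), edge strength is |Pearson r| of the two
regions' activities across the group's subjects (diagonal forced to 0).
Fewer than 4 subjects is refused by default (`min_subjects` can be
lowered explicitly for toy analyses, e.g. exact permutation enumeration
on 3-vs-3 pools). Binarization keeps the `floor(s·n(n−1)/2)` strongest
edges — floor guarantees the realized density never exceeds the nominal
sparsity — with ties broken by ascending (i, j) node order so repeated
runs give identical graphs.

Metrics on the binary graph: C is the mean nodal clustering coefficient
with degree-<2 nodes contributing 0; L is the arithmetic mean
shortest-path length over node pairs, computed on the largest connected
component with a `connected=False` flag when the graph is disconnected
(so sweeps remain well-defined at any sparsity); S divides the graph's
C/L by the mean C/L of `n_rand` (default 100) seeded uniform random
graphs with identical node and edge counts — uniform G(n, m), not
degree-preserving rewiring. The random ensemble is memoized per
(n, m, n_rand, seed), which makes sparsity sweeps and permutation loops
cheap. Implementation is dense numpy (triangle counts from the diagonal
of A³) plus breadth-first shortest paths from scipy; the test suite
cross-checks every metric against explicit brute-force enumeration and
networkx. The default sweep grid is 25–50% in 1% steps, the range over
which group networks of this size are typically fully connected; the
minimum fully-connected sparsity search uses 1–50% and reports failure
(None) rather than erroring when no grid value connects the graph.

## Permutation inference

Group differences in C, L or S are tested with a subject-relabeling null:
pool both groups' rows, reassign labels preserving group sizes, recompute
the full pipeline (correlation → threshold → metric) per draw. P-values
are two-sided with the add-one Monte-Carlo correction,
`p = (#{|null| ≥ |obs|} + 1)/(n_perm + 1)`. When the pool admits no more
distinct balanced relabelings than requested draws (or on request), the
test switches to exact enumeration over all C(n, n_A) relabelings and
reports `p = #{|null| ≥ |obs|}/N` (the identity relabeling guarantees
p ≥ 1/N). The group × subspace interaction uses the
difference-of-differences statistic
`[m(A,dis) − m(A,non)] − [m(B,dis) − m(B,non)]` under the same null.

Edge-wise comparisons act on the *signed* correlations (|r| has no
standard two-sample test): Fisher r-to-z per group, difference statistic
with SE `sqrt(1/(n_A−3) + 1/(n_B−3))`, two-sided normal p, and
Benjamini–Hochberg adjustment across all edges of the node set.

## Clinical statistics

The repeated-measures ANOVA partitions the total SS of an n × k
complete-case table into subject, time and error components;
`F = MS_time/MS_error` with df `(k−1, (n−1)(k−1))` and no sphericity
correction (the published df are unadjusted). Complete cases only — for
the packaged DBS table that is the 4 patients scanned three times, giving
df (2, 6). Post hoc tests are pairwise paired t with Bonferroni factor
equal to the number of pairs, capped at 1; the exact post hoc adjustment
variant used by commercial packages differs in detail, so post hoc
p-values are reported but not treated as reference values. Percent
improvement is defined per patient and then averaged (the definition that
reproduces the reported group improvement; the ratio-of-group-means
definition gives a different number). Two-sample comparisons use the
pooled-variance Student t. SUVR is each subject's ROI activity divided by
that subject's whole-brain mean activity, summarized as group mean ± SD.

The packaged per-patient table stores scores at the printed precision
(2 decimals), so SDs recomputed from it can differ from published SDs in
the last digit; means and F statistics reproduce exactly.

## Synthetic cohorts

The generator's model is log-linear, chosen so SSM preprocessing is its
exact inverse:

    activity[i,j] = exp( g_i + b_j + s_i·w_j + f_i·λ_group·|w_j|·1[j∈subspace] + ε_ij )

- `g_i ~ N(0, subject_scale_sd)` — per-subject global scaling, removed
  exactly by subject centering (default 0.2).
- `b_j ~ N(log 100, 0.25)` — baseline regional profile, removed by cohort
  centering.
- `w` — the planted pattern, standardized over ROIs, with exactly
  `n_pos_salient` (default 13) entries ≥ +1, `n_neg_salient` (default 16)
  ≤ −1, and all remaining entries inside (−0.8, 0.8) — a 0.2 margin so
  small recovery error cannot flip the |z| ≥ 1 partition. Found by
  alternating standardization with projection onto per-entry bounds;
  infeasible compositions (including the zero-salient case, impossible
  because a mean-0 SD-1 vector always reaches magnitude 1) raise a
  configuration error. Non-salient entries start as truncated-normal
  draws.
- `s_i` — planted expression scores in control-SD units: controls
  `N(0, score_sd)`, patients `N(score_mean_pd, score_sd)` with defaults
  1.0 and 2.74, so the patient HC-referenced z mean lands near 2.74.
- `f_i ~ N(0,1)` with group strength `λ` (defaults 0.2 controls / 0.5
  patients) — a latent factor confined to the salient subspace with
  per-ROI loading proportional to |w_j|. The proportionality matters: a
  factor loading *uniformly* on the subspace raises all within-subspace
  correlations equally and leaves the thresholded binary topology
  statistically random, so planted group differences in C/L/S would be
  undetectable in principle. Weight-proportional loadings create a
  correlated core among high-salience regions, which is what the graph
  metrics respond to. Detection also needs residual noise comparable to
  the factor term — very low noise saturates all correlations and removes
  the topological signal again — hence the detection tests run at
  noise_sd ≈ 0.3 with λ 0.9 vs 0.
- `ε ~ N(0, noise_sd)` i.i.d. (default 0.1, the "low noise" regime where
  pattern recovery correlation exceeds 0.95).

Longitudinal cohorts multiply each patient's baseline score by fixed
per-timepoint ratios (default (1.0, 0.175, 0.546), the published
complete-case trajectory normalized to baseline), reuse `b_j` and `g_i`
across that patient's scans, redraw `f` and `ε` per scan, scan the first
`n_complete` (default 4) patients three times and the rest twice, and add
a fixed log-space shift of `scanner_offset` (default 0.5) along the
pattern direction to every scan — the cross-scanner offset that the
cohort-offset correction is designed to remove. One seed plants one
pattern shared by the derivation and follow-up generators (named RNG
substreams per quantity, so adding a draw to one stage never perturbs
another).

What the generator does *not* emulate: spatial autocorrelation between
neighboring ROIs, partial-volume and smoothing effects, age/sex
covariates, scanner-specific noise spectra, and any voxel-level
structure. Passing recovery tests therefore demonstrates correctness of
the analytic chain under the model's own assumptions, not performance on
real scans.

## Problem sizes and determinism

Everything is sized for a laptop: derivation cohorts are 66 × 95,
follow-up cohorts 31 scans, bootstrap 100 replicates, permutation tests
1000 draws (the test suite uses 200 and exact enumeration on toy pools),
random-graph ensembles 100 graphs. The full test suite runs in well under
a minute; the acceptance script in about a second. Every stochastic
function takes a seed and reproduces its output exactly; the pipeline
writes a manifest with seeds, parameters and output checksums, and reruns
are byte-identical.

## Known limitations

Quantities that depend on the original scans — PC1 variance accounted
for, real-cohort expression means, printed C/L/S values and
minimum-connectivity sparsities — are data-dependent and are covered by
direction-of-effect checks on planted structure, not numeric targets.
The edge-wise test interprets connection differences on signed
correlations before the absolute value is taken. L uses the arithmetic
(not harmonic) mean of path lengths. Binary undirected graphs only; no
weighted or directed variants, no modularity or hub analysis, no
voxel-level pattern derivation, and no spatial normalization — images
enter only through ROI means extracted against a label volume on an
identical grid.
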
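# Methods

## Pipeline model

The package treats a multi-subject, multi-condition fMRI cohort as a bag of
short-time connectivity observations. Each scan's ROI time series is cut
into overlapping windows; within a window, connectivity is the Fisher
z-transformed Pearson correlation of every ROI pair, so a window is
summarized by a symmetric 10×10 z-matrix whose diagonal is undefined and
excluded everywhere (the z of a self-correlation is infinite and carries no
information). The 45 upper-triangle entries (i < j, row-major) are the
clustering features; this ordering is fixed so centroids are comparable
across runs and machines. Recurrent connectivity states are k-means
centroids over the pooled windows of all scans, and per-scan state label
sequences drive every downstream statistic.

## Window arithmetic

Windows are specified in seconds (defaults: 30-s width, 15-s step) and
converted per scan to TR units. The width is rounded half-up to an integer
TR count; the step is kept as an exact fraction of TRs. The number of
windows is `floor((T - width_tr) / step_tr) + 1` and window i starts at
`round_half_up(i * step_tr)`. Half-up rounding (not banker's) is essential:
at TR 2.0 s the 15-s step is 7.5 TR, realized as start increments
8, 7, 8, 7, …, which yields 39 windows for a 300-volume rest scan and 79
windows for an 804-volume task scan at TR 1.5 s simultaneously. Windows are
rectangular (no detrending or taper) and never span scan or condition
boundaries. Correlations are clipped at |r| = 1 − 1e−7 before atanh
(z_max = atanh(1 − 1e−7) ≈ 8.4) so features stay finite
when two ROIs are collinear within a window; a column that is constant
within a window is an error naming the ROI and window rather than a silent
NaN.

## Choosing the number of states

The cluster count is chosen by majority vote over a census of 13 classical
validity indices, each applied to the same k-means solutions over k = 2…8
with its documented decision rule:

| index | rule |
| --- | --- |
| silhouette | maximize |
| Calinski–Harabasz | maximize |
| Davies–Bouldin | minimize |
| Dunn | maximize |
| Ball–Hall (W/k) | largest successive drop |
| elbow (trace W) | maximum curvature (second difference) |
| gap statistic | one-standard-error rule |
| Hartigan | largest successive drop |
| Krzanowski–Lai | maximize |
| C-index | minimize |
| point-biserial | maximize |
| McClain–Rao | minimize |
| PBM | maximize |

Ties go to the smallest candidate k. The gap statistic uses uniform
reference sets drawn in the principal-component-aligned bounding box (the
rotation-respecting reference of the original proposal); with 45 strongly
correlated features, the raw bounding-box reference makes the gap curve
monotone and the index uninformative. No index is pruned adaptively:
members that saturate on a given dataset (e.g. McClain–Rao drifting to the
largest k on overlapping clusters) simply cast their vote. The census was
chosen as the spec of a majority-rule procedure, not for per-index
accuracy; enlarging it from the seven most common indices to thirteen
substantially stabilizes the vote on overlapping clusters.

Honest behaviour on the default synthetic cohort: the majority selects
k = 5 in roughly three quarters of replicate cohorts, with k = 3 the usual
runner-up. This is not an implementation artifact — forcing k = 5 recovers
the planted centroids at matched r ≥ 0.97 in every replicate — but a
property of the regime: with 15–20-TR windows the per-entry z noise
(sd ≈ 0.27–0.32 once AR(1) smoothing shrinks the effective dof) is
comparable to the 0.35–0.55 planted level differences, and ~38% of windows
straddle a hidden state switch at the 60-s mean dwell, so the window cloud
genuinely blurs toward fewer apparent clusters. Compactness indices then
prefer 3 — the same preference the original index-census procedure shows on
rest-like data.

## State estimation, labelling, matching

k-means uses Euclidean distance on raw z features (no per-feature
standardization — z-values share a scale), 25 iterations and 25 restarts by
default (both configurable; a single restart reproduces the literal
"25 iterations" setting). The best-inertia restart wins; final labels are
recomputed as exact nearest-centroid assignments so the stated invariant
holds even if a restart stopped before convergence, and ties break toward
the lowest label. States are renumbered 1…k by descending mean |z| of the
centroid, so the low-connectivity state deterministically receives the
highest label regardless of seed.

Matching two solutions (replicate cohorts, alternative parcellations,
nested k) maximizes the total Pearson r between centroid z-vectors over all
k! bijections via the Hungarian algorithm; the test suite verifies the
optimum against brute-force enumeration for k = 5. Per matched pair the
report carries r, the two-sided p and the 95% CI of the correlation over
the 45 paired entries.

## Occupancy statistics

Fractional occupancy divides a scan's per-state window counts by its window
total, so each scan's proportions sum to one exactly; states absent from a
scan get proportion zero. Transition tables count consecutive-window label
pairs (including self-transitions; total = windows − 1) and record dwell
runs. No transition-derived inferential statistic is attached — the tables
are descriptive.

The condition × state test fits proportion ~ cell means (one parameter per
condition × state cell) with a random intercept per subject-within-condition
scan, by REML. The interaction Wald F uses q = (C−1)(S−1) contrasts and
containment denominator df = N − n_subjects − (p − 1) (220 − 15 − 14 = 191
for the full three-condition design; 150 − 15 − 9 = 126 when the two rest
conditions are pooled). Post hoc contrasts are EMM differences between
conditions within each state, with t on the same df, Bonferroni adjustment
by an explicit family size (default 5, one per state), and Cohen's
d = difference / √(residual variance).

Two structural facts shape the implementation:

- **Compositional degeneracy.** Because a scan's proportions sum to one,
  every scan's mean over states is exactly 1/k, so the between-group
  variance that the random intercept would model is identically zero and
  REML sits on the boundary. The fit detects (near-)zero random-effect
  variance and evaluates the Wald test in the exact zero-variance limit —
  the fixed-effects fit with residual scale RSS/(N − p) — rather than
  relying on a boundary-converged optimizer; with genuine between-group
  variance (non-compositional responses) the REML mixed model is used. In
  the balanced zero-variance limit the interaction F equals the ordinary
  two-way ANOVA F to machine precision.
- **Anticonservatism on pure sampling noise.** The sum constraint also
  induces exchangeable *negative* within-scan correlation, which a
  (non-negative) random intercept cannot absorb; on strictly compositional
  null data the interaction F is inflated by ≈ (1 − 1/k)⁻¹ = 1.25,
  i.e. a type-I error near 0.13–0.15 at nominal 0.05. This is a property of
  the model, not of the code — the test suite asserts it — and it means
  occupancy p-values should be read as approximate whenever
  between-subject variability does not dominate multinomial window-count
  noise. Under model-conforming noise the test is calibrated (measured
  0.050 at 500 replicates), and with genuine scan-level intercepts the REML
  path shows only the textbook mild Wald-F inflation (~0.05–0.07; no
  Kenward–Roger correction is applied).

The behaviour correlation is a per-state Pearson r (with the exact
t-distribution p) between a per-subject response count and task occupancy.

## Synthetic cohort generator

The generator emulates the study design it validates against: 15 subjects ×
(pre-task rest 300 volumes @ TR 2.0 s, task 804 volumes @ TR 1.5 s,
post-task rest 300 volumes @ TR 2.0 s), with the last subject missing the
post-task scan (44 scans; 585 + 1185 + 546 = 2316 windows). Five planted
state blueprints realize qualitative network structure over DAN/DMN/FPN:
(1) global coupling with a decoupled MPFC; (2) DMN–FPN coupling with an
anticorrelated, internally intact DAN; (3) low inter-network connectivity
with preserved intra-network coupling; (4) a hemispherically split FPN —
right FPN to DMN, left FPN to DAN, left/right FPN mutually decoupled;
(5) DAN–FPN coupling with an anticorrelated DMN. Blueprint z-levels
(high/intra 0.6, low 0.05, anticorrelation −0.3) are free design parameters
chosen for separability — they are not empirical estimates. The implied
correlation matrices (tanh z, unit diagonal) are repaired to the nearest
positive-definite correlation (alternating projections, smallest eigenvalue
clipped at 1e−6); the repair moves no entry by more than 0.05 and is cached
per blueprint.

Each scan hides a per-TR Markov state sequence whose stationary
distribution equals the condition's occupancy profile; switching uses the
one-parameter family P = (1−λ)I + λ·1πᵀ, with λ set so the
stationary-weighted mean dwell equals `dwell_mean_windows` window
equivalents (one equivalent = one 15-s step; default 4 ≈ 60 s, a typical
sliding-window state-dwell scale). Observations are zero-mean Gaussians
with the active state's covariance, smoothed per ROI by a
variance-preserving AR(1) filter (coefficient 0.3 by default). Default
occupancy profiles place 38.1% of pre-task rest in the low-connectivity
state against 25.1% in task (with the split-FPN state rising from 13.8% to
22.1%) — so the planted rest-to-task low-connectivity drop is 0.13, the
effect size the power analysis targets.

What the generator does **not** emulate: hemodynamic convolution,
physiological and motion artifacts, scanner drift, spatially correlated
noise, subject-level deviations from the planted patterns, and
semi-Markovian dwell distributions. Passing recovery tests therefore show
that the pipeline inverts its own observation model at study scale — not
that real fMRI satisfies that model. Two consequences observed at the
defaults and worth knowing: per-scan realized occupancy wanders around the
stationary profile (a 10-min scan holds only ~10–20 dwell episodes), and
windows that straddle state switches blur toward weak-z patterns, which
inflates the low-connectivity state's occupancy and attenuates planted
condition differences by roughly a third at the window level. Condition
means over 15 subjects still recover the planted profiles with RMSE < 0.05.

For statistical simulations two lighter samplers operate directly at the
occupancy level: multinomial window-count draws (sampling noise matched to
the 39/79-window design) and a model-conforming Gaussian sampler (cell mean
+ optional scan intercept + iid noise) used for calibration studies, where
the multinomial's compositional structure would conflate the model's
documented anticonservatism with miscalibration of the implementation.

## Numerical and design choices

- Seeds: every stochastic operation takes an explicit seed (package default
  20210528); cohort simulation derives per-scan seeds from the design seed,
  and pipeline output is a pure function of (data, config, seed). Saved
  runs are byte-identical across repeats.
- k-selection k-means uses the same restart budget as the final fit
  (n_init 25) but a longer iteration cap (50), since validity indices are
  sensitive to under-converged partitions.
- Containment df rather than Satterthwaite/Kenward–Roger: simple, exact in
  the balanced fixed-effects limit, and consistent with the denominator
  structure of the design (191/126-style counts).
- Degenerate inputs: series shorter than one window, constant ROI columns
  (whole-scan or within-window), non-PD repaired covariances, conditions
  with a single subject, and empty condition × state cells are all hard
  errors naming the offending object; nothing is silently imputed. The one
  deliberately tolerated irregularity is a missing subject-condition scan,
  which simply contributes no rows.
- Problem sizes in the test suite and acceptance script (20 replicate
  cohorts for k-selection, 500/200 replicates for calibration/power,
  100k-TR scans for ergodicity checks) were chosen as the smallest sizes at
  which the Monte-Carlo standard error is well below each decision margin.

## Known limitations

- The majority rule's k = 5 recovery rate (~75%) under the default noise
  regime sits below what a well-separated-cluster intuition would suggest;
  see the k-selection section for why, and prefer fixing k from prior
  knowledge when the index vote is split between 3 and 5.
- Occupancy p-values inherit the compositional anticonservatism described
  above.
- The Hungarian matching optimizes summed r; with k > 6 the brute-force
  verification in the tests no longer covers it (the algorithm itself is
  exact for any k).
- The CLI's `windows` archive is a NumPy `.npz` container, readable only
  from Python.
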
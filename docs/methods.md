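# Methods

## Problem and model

Registry survival cohorts in oncology are conventionally stratified by
committee-defined staging rules that map categorical prognostic factors
(tumor extent T, nodal involvement N, distant metastasis M, sometimes an age
band A) to a handful of stages. This package builds the grouping from the
data instead. Patients are first collapsed into *combinations* of factor
levels (for T/N/M up to 4 × 2 × 2 = 16 cells, e.g. `T2N0M0`); each
combination carries a right-censored survival sample, and combinations —
not patients — are the objects that get clustered. The method is an
ensemble clustering of survival curves and makes no proportional-hazards or
other parametric assumption about the event-time distributions; everything
is driven by rank-based two-sample comparisons.

The pipeline has three algorithmic stages plus a model-selection step:

1. **Initial dissimilarity.** For combinations $C_i, C_j$ with samples of
   sizes $m, n$, Gehan's generalized Wilcoxon statistic
   $U = \sum_{k,l} h(k, l)$ scores every cross-pair $(k \in C_i, l \in C_j)$
   as $+1$ / $-1$ / $0$ according to whether one observation definitely
   outlives the other given censoring. With the exact permutation variance
   $\operatorname{Var} U = \frac{mn}{(m+n)(m+n-1)} \sum_k s_k^2$ ($s_k$ the
   pooled Gehan scores), the initial dissimilarity is the r-type effect size
   $\mathrm{dis}_0(C_i, C_j) = |z| / \sqrt{m+n}$, $z = U/\sqrt{\operatorname{Var} U}$.
   This quantity is symmetric, zero for identical samples, empirically
   bounded (about 0.87 for fully separated equal-size samples), and
   stabilized against sample size — unlike $|z|$ itself, which grows with
   $\sqrt{n}$. The underlying reference defines an effect size without
   restating a formula; $|z|/\sqrt{m+n}$ is this package's reading, it is a
   configurable choice, and because clustering depends only on the *ordering*
   of dissimilarities partly, a different monotone variant could change
   groupings at the margin.

2. **Ensemble (consensus) step.** For every $k = 1..n$ (n = number of
   combinations), two-phase Partitioning Around Medoids — classical
   Kaufman–Rousseeuw BUILD followed by steepest-descent SWAP — partitions
   the combinations using $\mathrm{dis}_0$. With indicator
   $\delta_k(i,j) = 1$ when the $k$-cluster partition separates $C_i$ from
   $C_j$, the learned dissimilarity is
   $\mathrm{dis}(C_i, C_j) = \sum_k w_k\, \delta_k(i,j)$ with nonnegative
   weights summing to one (equal weights $w_k = 1/n$ by default). The range
   $k = 1..n$ is kept literally even though $k=1$ never separates and $k=n$
   always does, so with equal weights every off-diagonal entry lies in
   $[1/n, (n-1)/n]$. The consensus matrix is far more stable than
   $\mathrm{dis}_0$ itself: it only remembers how often two combinations
   fall on the same side of a partition, not the noisy magnitudes.

3. **Minimax-linkage hierarchical clustering.** Agglomerative clustering of
   the learned dissimilarities where the cost of merging $G$ and $H$ is the
   minimax radius $\min_{p \in G \cup H} \max_{x \in G \cup H} d(p, x)$.
   Every cluster therefore has a *prototype* combination within the recorded
   radius of all members — useful clinically, because each prognostic group
   can be summarized by a real combination rather than an abstract centroid.
   Minimax linkage can produce height inversions; these are reported as
   computed with a warning, and cutting is by merge count, which stays well
   defined regardless.

4. **Group-count selection.** For each cut $k$, groups are ordered by
   5-year overall survival and each patient receives their group's ordinal
   rank as a risk score; Harrell's C-index of that score is the curve
   $C(k)$, with $C(1) = 0.5$ by convention. The number of groups $n^*$ is
   the knee: the smallest $k$ after which every one-step gain
   $C(j{+}1) - C(j)$, $j \ge k$, stays below a tolerance. The published
   analyses select the knee visually; the forward-difference rule is this
   package's formalization, and a forced $n^*$ is supported for
   replication-style runs.

The finished system has four mutually consistent components: the dendrogram,
the combination→group assignments, the concordance of the final grouping
(with a bootstrap interval), and a Kaplan–Meier curve per group, plus
unadjusted log-rank p-values between adjacent groups (a Bonferroni-style
reading is left to the user; the convention in the figures this mirrors is
unadjusted pairwise tests).

## Comparator

The AJCC 9th-edition rule for pancreatic neuroendocrine tumors is encoded
directly: M1 → stage IV; otherwise T4 or N1 → III; otherwise T2/T3 → II;
T1N0M0 → I. Over the 16 T/N/M combinations this partitions 1/2/5/8 across
stages I–IV. Comparisons of the two systems use the same patients, ordinal
stage/group ranks as risk scores, and a paired patient-level bootstrap of
the C-index difference.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `min_n` | 15 patients | smallest combination admitted to clustering; smaller cells give unstable effect sizes. Exposed as a knob; exclusions are always reported. |
| ensemble weights | equal, $1/n$ | neutral consensus; arbitrary normalized weights accepted. |
| `knee_tol` | 0.005 (absolute C units) | a marginal C gain below half a point per added group is treated as plateau. |
| `n_boot` | 1000 | patient-level bootstrap replicates for C-index CIs and comparisons; percentile intervals, seeded. |
| `degenerate_value` | 1.0 | sentinel dissimilarity when the Gehan variance degenerates (e.g. all-censored pair), so clustering can proceed; always warned. |
| censoring horizon | 156 months | an 8-year accrual window followed to 5 years past its end, the registry convention emulated. |
| 5-year point | 60 months | survival-ordering summary; time unit is months throughout. |
| age cut | 50 years | dichotomization boundary, ≥ 50 → `A2`. |

## Synthetic cohorts: what they do and do not emulate

The generator reproduces the *structure* of a registry extract, not its
biology: per-combination sample sizes (the 16-combination preset uses the
published per-combination counts, total 3278, which also reproduces the
marginal factor frequencies), a 26–95% spread of 5-year survival across
combinations, administrative censoring at the follow-up horizon, and uniform
loss to follow-up (10% in the preset; registry follow-up ascertainment is
high). Event times are exponential by default — one parameter per
combination, closed-form survivor function for oracle checks — with a
Weibull option for shape-misspecification experiments. Real cohorts have
non-constant hazards, covariate-dependent censoring, and correlated factor
effects; none of that is modeled. Consequently, passing recovery tests show
that the pipeline finds the structure it is pointed at under honest noise
and censoring — they do not certify performance on any real registry.

Reproducibility: each combination draws from a child stream keyed by
(master seed, combination label), so adding or removing a combination never
perturbs the others' draws.

The recovery benchmark uses 3 tiers × 4 combinations × 300 patients with
hazards 0.002 / 0.01 / 0.05 per month (5-year survival 89% / 55% / 5%) and
20% loss to follow-up, evaluated over 20 seeds; the calibration study uses
1000 null pairs of 50 + 50 patients. These sizes are the package's chosen
benchmark conditions and run comfortably on a single CPU.

## Numerical and tie-breaking choices

- All stages are deterministic given the input order of combinations:
  PAM seeds, swaps and nearest-medoid assignment break ties by lowest label
  index (each medoid anchors its own cluster, which matters when two
  combinations have zero dissimilarity); minimax merges break ties by the
  lowest pair of smallest-leaf representatives and prototypes by lowest
  index; group relabeling breaks equal 5-year survival by larger restricted
  mean survival, then lexicographic label.
- Harrell comparability follows the standard rules: the shorter time must be
  an observed death; a death tied with a censoring counts (censored patient
  the longer survivor); two deaths at the same time do not; tied risks score
  one half. The package's pair counter is exact and is cross-checked in the
  tests against an independent brute-force enumeration and against
  lifelines, which also provides the fast point estimate inside bootstrap
  loops.
- If any group's follow-up ends before 60 months, severity ordering falls
  back to survival at the largest common follow-up time, with a warning.
- Two-sided p-values throughout; the Gehan test uses the normal
  approximation with its exact permutation variance (enumeration of the
  permutation distribution is used as a test oracle at tiny n, not as a
  runtime mode).

## Known limitations

- **PAM is a local search.** BUILD+SWAP reaches the exhaustive-search
  medoid optimum on the large majority of small unstructured random
  instances (over 90% in the test batch) but not on all — an inherent
  property of the classical algorithm, shared by its canonical R
  implementation. On the structured consensus matrices this pipeline
  actually clusters, no recovery failure attributable to PAM local optima
  has been observed in the test suite.
- **Knee selection at small cohort sizes.** Ordering groups by observed
  survival before scoring them makes $C(k)$ optimistically biased by
  $O(1/\sqrt{N})$, so on a cohort with *no* true structure the default
  tolerance of 0.005 can still admit a second group when $N$ is a few
  hundred per combination; the no-structure tests therefore use a tolerance
  above the measured noise floor. With real effect sizes this bias is
  negligible relative to the gains at the knee.
- The C-index of a staging system is computed on ordinal group rank; using
  another per-group risk summary (e.g. 1 − 5-year survival) would reorder
  nothing but could change the comparability weighting of ties.
- Bootstrap percentile intervals are assumption-free but can undercover at
  extreme concordances; an analytic U-statistic variance is deliberately
  out of scope.
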
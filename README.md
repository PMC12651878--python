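# eaccd

Ensemble clustering of censored survival data into prognostic groups, with a
rule-based TNM staging comparator and a registry-like cohort simulator.

## What problem this solves

Cancer staging systems map categorical prognostic factors — tumor extent
(T), nodal involvement (N), distant metastasis (M), optionally an age band
(A) — to a few stages used for prognosis and treatment planning. For
pancreatic neuroendocrine tumors the committee-defined AJCC rule separates
outcomes poorly between early stages. This package implements the
**Ensemble Algorithm for Clustering Cancer Data (EACCD)**: a data-driven
alternative that clusters the survival curves of factor-level combinations
(e.g. `T2N0M0`) directly, with no proportional-hazards assumption, and
selects the number of prognostic groups where the concordance of the
resulting system stops improving. It is aimed at biostatisticians and
registry analysts who have patient-level survival extracts and want a
reproducible, inspectable grouping pipeline.

## The method in brief

Given combinations $C_1,\dots,C_n$ and weights $w_k \ge 0$, $\sum w_k = 1$:

1. **Initial dissimilarity** — $\mathrm{dis}_0(C_i,C_j) = |z|/\sqrt{m+n}$,
   the effect size of the standardized Gehan–Wilcoxon two-sample statistic
   (exact permutation variance), measuring how separable the two survival
   samples are under censoring.
2. **Ensemble learning** — for each $k = 1..n$, two-phase PAM (BUILD +
   SWAP) partitions the combinations using $\mathrm{dis}_0$; with
   $\delta_k(i,j) = 1$ when $C_i, C_j$ land in different clusters, the
   learned dissimilarity is $\mathrm{dis}(C_i,C_j) = \sum_k w_k \delta_k(i,j)$.
3. **Hierarchical clustering** — minimax linkage on $\mathrm{dis}$, so
   every cluster is represented by a prototype combination; cutting the
   dendrogram at $k$ gives $k$ candidate groups.
4. **Model selection** — patients are scored by the severity rank of their
   group; Harrell's C-index traced over $k$ plateaus, and the group count
   $n^*$ is chosen at the knee of that curve.

The result is a four-component prognostic system: dendrogram, group
assignments, C-index (with bootstrap CI), and Kaplan–Meier curves per
group. The AJCC 9th-edition rule (M1 → IV; else T4 or N1 → III; else T2/T3
→ II; else I) is built in as the comparator. See `docs/methods.md` for
assumptions, parameter rationale and limitations.

## Worked example

`examples/02_build_staging_system.py` simulates the 16-combination T/N/M
preset (3278 patients; combination sizes and 5-year-survival spread modeled
on a SEER pancreatic-NET cohort), builds the EACCD system and compares it
with AJCC staging on the same patients:

```text
combinations: 16, patients: 3278
knee-selected number of prognostic groups n* = 8
  group 1: T1N0M0  (n=1254, deaths=151, 5-yr survival 95%)
  group 2: T2N0M0, T3N0M0  (n=997, deaths=181, 5-yr survival 92%)
  group 3: T1N1M0, T2N1M0, T3N1M0  (n=431, deaths=193, 5-yr survival 77%)
  ...
EACCD C-index = 0.7700 (95% CI 0.7544-0.7841)
AJCC C-index  = 0.7622
difference (EACCD - AJCC) = +0.0078 (95% CI +0.0058 to +0.0100, p = 0.000)
```

The groups are ordered by decreasing 5-year survival (group 1 = least
severe); the positive, CI-excluding-zero difference says the data-driven
grouping orders survival slightly better than the rule on this synthetic
cohort. The other examples show the two-sample statistics on a
hand-checkable dataset (`01_survival_statistics.py`) and the recovery of a
known three-tier structure, where the knee selects exactly three groups
with adjusted Rand index 1.0 against the generating truth
(`03_recovery_simulation.py`).

The same pipeline runs from the shell:

```bash
eaccd run --input cohort.csv --factors T,N,M --min-n 15 --seed 1 --out results/
eaccd compare --input cohort.csv --seed 1 --out results/
```

writing the group table, C-index curve, per-group KM curves, dendrogram
(Newick + JSON), exclusion report and a run manifest that reproduces the
run bit-for-bit.

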
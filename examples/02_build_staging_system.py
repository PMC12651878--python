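"""Build a data-driven staging system on a registry-like T/N/M cohort.

Simulates the 16-combination preset (3278 patients, sizes and survival
spread modeled on a SEER pancreatic-NET cohort), runs the full ensemble-
clustering pipeline, and compares the result with rule-based AJCC staging
on the same patients.
"""

import numpy as np

from eaccd import (
    Observations,
    build_combinations,
    build_prognostic_system,
    compare_cindex,
    seer_like_preset,
    simulate_cohort,
)
from eaccd.prognostic import _patient_arrays, ajcc_stage_rank

SEED = 1

config, _ = seer_like_preset(seed=SEED)
records, _ = simulate_cohort(config)
cohort = build_combinations(records, config.scheme)
system = build_prognostic_system(cohort, n_boot=1000, seed=SEED)

print(f"combinations: {len(cohort.labels)}, patients: {cohort.n_patients}")
print(f"knee-selected number of prognostic groups n* = {system.n_star}")
for g in system.groups:
    print(
        f"  group {g.group_id}: {', '.join(g.members)}  "
        f"(n={g.n_patients}, deaths={g.n_deaths}, "
        f"5-yr survival {100 * g.five_year_survival:.0f}%)"
    )
c = system.concordance
print(f"EACCD C-index = {c.cindex:.4f} (95% CI {c.ci_low:.4f}-{c.ci_high:.4f})")

# the AJCC rule scores each patient by stage I..IV on the same cohort
times, events, combo_idx = _patient_arrays(cohort)
eaccd_risk = np.array([system.assignments[l] for l in cohort.labels], float)[combo_idx]
ajcc_risk = np.array(
    [ajcc_stage_rank(l[:2], l[2:4], l[4:]) for l in cohort.labels], float
)[combo_idx]
cmp = compare_cindex(eaccd_risk, ajcc_risk, Observations(times, events),
                     n_boot=1000, seed=SEED)
print(f"AJCC C-index  = {cmp.cindex_b:.4f}")
print(f"difference (EACCD - AJCC) = {cmp.difference:+.4f} "
      f"(95% CI {cmp.ci_low:+.4f} to {cmp.ci_high:+.4f}, p = {cmp.p:.3f})")
# a positive difference means the data-driven groups order survival better
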
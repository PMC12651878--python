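"""Recover a known three-tier survival structure from simulated data.

Generates 12 combinations in three hazard tiers (the ground truth), runs the
pipeline blind, and checks that the knee rule selects three groups matching
the tiers exactly.
"""

from sklearn.metrics import adjusted_rand_score

from eaccd import build_combinations, build_prognostic_system, make_recovery_fixture, simulate_cohort

config, truth = make_recovery_fixture(
    tiers=3, combos_per_tier=4, n_per_combo=300,
    hazards=[0.002, 0.01, 0.05], seed=7,
)
records, _ = simulate_cohort(config)
cohort = build_combinations(records, config.scheme)
system = build_prognostic_system(cohort, n_boot=0)

labels = cohort.labels
ari = adjusted_rand_score(
    truth.tier_labels(labels), [system.assignments[l] for l in labels]
)
print(f"selected groups n* = {system.n_star} (truth: 3 tiers)")
print(f"adjusted Rand index vs ground truth = {ari:.2f} (1.0 = perfect recovery)")
print(f"C-index of the recovered grouping = {system.concordance.cindex:.4f}")
print("C-index curve:", [f"{v:.3f}" for v in system.curve.values])
# the curve rises steeply to k=3 and is flat beyond: that is the knee
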
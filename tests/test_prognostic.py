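"""Prognostic-system assembly: knee selection, group ordering, AJCC rule."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import make_obs
from eaccd.cohort import CombinationCohort, FactorScheme, Observations, build_combinations
from eaccd.core import minimax_linkage, ensemble_dissimilarity, initial_dissimilarity_matrix, cut_dendrogram
from eaccd.prognostic import (
    CIndexCurve,
    ajcc_stage_rank,
    assign_ajcc_stage,
    assign_patient,
    build_prognostic_system,
    cindex_curve,
    order_groups,
    select_knee,
)
from eaccd.simulate import make_recovery_fixture, simulate_cohort
from eaccd.survival import harrell_cindex


def recovery_cohort(seed=0, tiers=3, combos=4, n=300, hazards=(0.002, 0.01, 0.05)):
    config, truth = make_recovery_fixture(tiers, combos, n, list(hazards), seed=seed)
    records, _ = simulate_cohort(config)
    return build_combinations(records, config.scheme), truth


class TestSelectKnee:
    def test_plateau_example(self):
        curve = CIndexCurve(ks=(1, 2, 3, 4, 5), values=(0.50, 0.60, 0.66, 0.668, 0.669))
        assert select_knee(curve, tol=0.01) == 3

    def test_flat_curve_gives_one_group(self):
        curve = CIndexCurve(ks=(1, 2, 3), values=(0.5, 0.5, 0.5))
        assert select_knee(curve, tol=0.01) == 1

    def test_no_plateau_returns_max_with_warning(self):
        curve = CIndexCurve(ks=(1, 2, 3, 4), values=(0.5, 0.55, 0.6, 0.65))
        with pytest.warns(UserWarning, match="no plateau"):
            assert select_knee(curve, tol=0.01) == 4

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            select_knee(CIndexCurve(ks=(1, 2), values=(0.5, 0.6)), tol=0)


class TestOrderGroups:
    def test_groups_relabelled_by_decreasing_five_year_survival(self):
        cohort, _ = recovery_cohort(seed=5)
        d0 = initial_dissimilarity_matrix(cohort)
        tree = minimax_linkage(ensemble_dissimilarity(d0))
        groups = order_groups(cut_dendrogram(tree, 3), cohort)
        s5 = [g.five_year_survival for g in groups]
        assert [g.group_id for g in groups] == [1, 2, 3]
        assert s5 == sorted(s5, reverse=True)

    def test_single_cluster(self):
        cohort, _ = recovery_cohort(seed=1, tiers=1, combos=2, n=50, hazards=(0.01,))
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        groups = order_groups(cut_dendrogram(tree, 1), cohort)
        assert len(groups) == 1 and groups[0].group_id == 1

    def test_conservation_of_patients_and_deaths(self):
        cohort, _ = recovery_cohort(seed=2)
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        groups = order_groups(cut_dendrogram(tree, 4), cohort)
        pooled = cohort.pooled()
        assert sum(g.n_patients for g in groups) == len(pooled)
        assert sum(g.n_deaths for g in groups) == int(pooled.event.sum())

    def test_short_follow_up_falls_back_with_warning(self):
        scheme = FactorScheme([("G", ["Ga", "Gb"])])
        cohort = CombinationCohort(
            scheme=scheme,
            groups={
                "Ga": make_obs([10, 20, 30], [1, 0, 1]),  # follow-up ends before 60
                "Gb": make_obs([5, 15, 80], [1, 1, 0]),
            },
        )
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        with pytest.warns(UserWarning, match="common follow-up"):
            groups = order_groups(cut_dendrogram(tree, 2), cohort)
        assert {g.group_id for g in groups} == {1, 2}


class TestCIndexCurve:
    def test_single_group_is_one_half_by_convention(self):
        cohort, _ = recovery_cohort(seed=3, tiers=2, combos=2, n=60, hazards=(0.005, 0.03))
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        curve = cindex_curve(tree, cohort)
        assert curve.values[0] == 0.5

    def test_no_signal_cohort_stays_near_one_half(self):
        cohort, _ = recovery_cohort(seed=4, tiers=1, combos=4, n=150, hazards=(0.01,))
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        curve = cindex_curve(tree, cohort)
        assert abs(curve.values[-1] - 0.5) < 0.05

    def test_three_tier_curve_rises_then_plateaus(self):
        cohort, _ = recovery_cohort(seed=6)
        tree = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        curve = cindex_curve(tree, cohort)
        c = curve.values
        assert c[2] > c[1] > c[0]
        assert all(ck - c[2] < 0.01 for ck in c[3:])

    def test_invariant_to_combination_input_order(self):
        cohort, _ = recovery_cohort(seed=7, tiers=2, combos=3, n=80, hazards=(0.004, 0.03))
        reversed_cohort = CombinationCohort(
            scheme=cohort.scheme,
            groups=dict(reversed(list(cohort.groups.items()))),
        )
        t1 = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(cohort)))
        t2 = minimax_linkage(ensemble_dissimilarity(initial_dissimilarity_matrix(reversed_cohort)))
        c1 = cindex_curve(t1, cohort)
        c2 = cindex_curve(t2, reversed_cohort)
        assert np.allclose(c1.values, c2.values)


class TestBuildPrognosticSystem:
    def test_recovers_three_tier_truth(self):
        cohort, truth = recovery_cohort(seed=11)
        system = build_prognostic_system(cohort, n_boot=0)
        assert system.n_star == 3
        labels = cohort.labels
        ari = adjusted_rand_score(
            truth.tier_labels(labels), [system.assignments[l] for l in labels]
        )
        assert ari == 1.0
        # severity order matches the hazard order
        assert system.assignments["R1S1"] == 1 and system.assignments["R3S1"] == 3

    def test_identical_hazards_give_single_group(self):
        # with no true structure the C-index curve is flat up to sampling
        # noise, so a knee tolerance above the noise floor selects one group
        cohort, _ = recovery_cohort(seed=12, tiers=1, combos=4, n=500, hazards=(0.01,))
        system = build_prognostic_system(cohort, n_boot=0, knee_tol=0.03)
        assert max(system.curve.values) - 0.5 < 0.03
        assert system.n_star == 1

    def test_deterministic_rerun(self):
        cohort, _ = recovery_cohort(seed=13, tiers=2, combos=2, n=80, hazards=(0.004, 0.03))
        s1 = build_prognostic_system(cohort, n_boot=50, seed=5)
        s2 = build_prognostic_system(cohort, n_boot=50, seed=5)
        assert s1.assignments == s2.assignments
        assert s1.concordance == s2.concordance
        assert s1.dendrogram.to_json() == s2.dendrogram.to_json()

    def test_concordance_consistent_with_own_assignments(self):
        cohort, _ = recovery_cohort(seed=14)
        system = build_prognostic_system(cohort, n_boot=0)
        risk, times, events = [], [], []
        for label, obs in cohort.groups.items():
            risk.append(np.full(len(obs), system.assignments[label], float))
            times.append(obs.time)
            events.append(obs.event)
        recomputed = harrell_cindex(
            np.concatenate(risk),
            Observations(np.concatenate(times), np.concatenate(events)),
            n_boot=0,
        )
        assert recomputed.cindex == pytest.approx(system.concordance.cindex)

    def test_forced_group_count_and_adjacent_tests(self):
        cohort, _ = recovery_cohort(seed=15)
        system = build_prognostic_system(cohort, n_groups=4, n_boot=0)
        assert system.n_groups == 4
        assert len(system.adjacent_logrank_p) == 3
        assert all(0 <= p <= 1 for p in system.adjacent_logrank_p)


@pytest.fixture(scope="module")
def fitted_system():
    cohort, _ = recovery_cohort(seed=16, tiers=2, combos=2, n=80, hazards=(0.004, 0.03))
    return build_prognostic_system(cohort, n_boot=0)


class TestAssignPatient:
    @pytest.fixture
    def system(self, fitted_system):
        return fitted_system

    def test_known_combination(self, system):
        assert assign_patient(system, {"R": "R1", "S": "S1"}) == system.assignments["R1S1"]

    def test_unknown_combination_is_unassignable(self, system):
        # valid under the scheme but absent from the fitted system
        trimmed = system.__class__(
            **{**system.__dict__, "assignments": {"R1S1": 1, "R2S1": 2}}
        )
        assert assign_patient(trimmed, {"R": "R1", "S": "S2"}) is None

    def test_malformed_level_rejected(self, system):
        with pytest.raises(ValueError):
            assign_patient(system, {"R": "R9", "S": "S1"})


class TestAjccStageRule:
    EXPECTED = {
        "T1N0M0": "I",
        "T2N0M0": "II",
        "T3N0M0": "II",
        "T4N0M0": "III",
        "T1N1M0": "III",
        "T2N1M0": "III",
        "T3N1M0": "III",
        "T4N1M0": "III",
        "T1N0M1": "IV",
        "T2N0M1": "IV",
        "T3N0M1": "IV",
        "T4N0M1": "IV",
        "T1N1M1": "IV",
        "T2N1M1": "IV",
        "T3N1M1": "IV",
        "T4N1M1": "IV",
    }

    def test_all_sixteen_combinations(self):
        for label, stage in self.EXPECTED.items():
            t, n, m = label[:2], label[2:4], label[4:]
            assert assign_ajcc_stage(t, n, m) == stage

    def test_stage_partition_sizes(self):
        from collections import Counter

        counts = Counter(self.EXPECTED.values())
        assert [counts[s] for s in ("I", "II", "III", "IV")] == [1, 2, 5, 8]

    def test_rank_is_ordinal(self):
        assert ajcc_stage_rank("T1", "N0", "M0") == 1
        assert ajcc_stage_rank("T4", "N1", "M1") == 4

    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            assign_ajcc_stage("T5", "N0", "M0")
        with pytest.raises(ValueError):
            assign_ajcc_stage("T1", "N2", "M0")
        with pytest.raises(ValueError):
            assign_ajcc_stage("T1", "N0", "MX")
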
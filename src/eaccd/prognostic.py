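"""Prognostic systems: C-index curve, knee selection, ordered groups, AJCC rule.

A prognostic system built from an EACCD dendrogram has four components: the
dendrogram itself, the assignment of each factor-level combination to one of
n* groups, Harrell's concordance index of those groups, and a Kaplan–Meier
curve per group.  The number of groups n* is chosen at the knee of the
C-index-versus-group-count curve: concordance rises quickly for the first few
groups and plateaus, so n* is the smallest cut after which the marginal gains
stay below a tolerance.

The AJCC 9th-edition staging rule for pancreatic neuroendocrine tumors is
provided as the rule-based comparator: a committee-defined map from T/N/M to
stages I–IV, against which the data-driven grouping is evaluated on the same
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CombinationCohort, FactorScheme
from .core import (
    Dendrogram,
    DissimilarityMatrix,
    EnsembleWeights,
    PartitionLabeling,
    cut_dendrogram,
    ensemble_dissimilarity,
    initial_dissimilarity_matrix,
    minimax_linkage,
)
from .survival import (
    FIVE_YEARS_MONTHS,
    ConcordanceResult,
    KMCurve,
    concordance_point_estimate,
    harrell_cindex,
    km_estimate,
    logrank,
    restricted_mean_survival,
    survival_at,
)

__all__ = [
    "CIndexCurve",
    "PrognosticGroup",
    "PrognosticSystem",
    "cindex_curve",
    "select_knee",
    "order_groups",
    "build_prognostic_system",
    "assign_patient",
    "assign_ajcc_stage",
    "AJCC_STAGES",
    "ajcc_stage_rank",
]


@dataclass(frozen=True)
class CIndexCurve:
    """Harrell's C as a function of the number of dendrogram groups."""

    ks: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ks) != len(self.values):
            raise ValueError("ks and values must align")

    def forward_differences(self) -> np.ndarray:
        return np.diff(np.asarray(self.values))


@dataclass(frozen=True)
class PrognosticGroup:
    """One severity-ordered group: id 1 is the least severe (best survival)."""

    group_id: int
    members: tuple[str, ...]
    km: KMCurve
    five_year_survival: float
    n_patients: int
    n_deaths: int


@dataclass(frozen=True)
class PrognosticSystem:
    """The four-component system plus its selection diagnostics."""

    dendrogram: Dendrogram
    assignments: dict[str, int]
    concordance: ConcordanceResult
    groups: tuple[PrognosticGroup, ...]
    curve: CIndexCurve
    n_star: int
    adjacent_logrank_p: tuple[float, ...]
    initial_dissimilarity: DissimilarityMatrix | None = None
    learned_dissimilarity: DissimilarityMatrix | None = None
    scheme: FactorScheme | None = None

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _patient_arrays(cohort: CombinationCohort):
    """Pooled times/events plus each patient's combination index."""
    times, events, combo_idx = [], [], []
    for i, label in enumerate(cohort.labels):
        obs = cohort.groups[label]
        times.append(obs.time)
        events.append(obs.event)
        combo_idx.append(np.full(len(obs), i))
    return (
        np.concatenate(times),
        np.concatenate(events),
        np.concatenate(combo_idx),
    )


def _severity_order(partition: PartitionLabeling, cohort: CombinationCohort):
    """Cluster ids sorted from best to worst survival.

    Primary key is 5-year survival (descending).  If any cluster's follow-up
    is shorter than 5 years its survival there is undefined; the ordering then
    falls back to survival at the largest follow-up time common to all
    clusters, with a warning.  Ties are broken by larger restricted mean
    survival, then by the lexicographically smallest member label.
    """
    curves = {}
    for cid in range(1, partition.k + 1):
        curves[cid] = km_estimate(cohort.pooled(partition.members(cid)))
    horizon = FIVE_YEARS_MONTHS
    s_primary = {cid: survival_at(c, horizon) for cid, c in curves.items()}
    if any(np.isnan(s) for s in s_primary.values()):
        horizon = min(c.max_follow_up for c in curves.values())
        warnings.warn(
            "5-year survival undefined for at least one group; ordering by "
            f"survival at the common follow-up limit ({horizon:.1f} months)",
            stacklevel=3,
        )
        s_primary = {cid: survival_at(c, horizon) for cid, c in curves.items()}
    keys = {}
    for cid, curve in curves.items():
        rmst = restricted_mean_survival(curve, horizon)
        first_label = min(partition.members(cid))
        keys[cid] = (-s_primary[cid], -rmst, first_label)
    ordered = sorted(curves, key=lambda cid: keys[cid])
    return ordered, curves, s_primary


def order_groups(
    partition: PartitionLabeling, cohort: CombinationCohort
) -> list[PrognosticGroup]:
    """Relabel clusters 1..k by increasing disease severity.

    Group 1 has the highest 5-year overall survival; the last group the
    lowest.  Each group pools its member combinations' observations for the
    Kaplan–Meier curve and death count.
    """
    ordered, curves, _ = _severity_order(partition, cohort)
    groups = []
    for new_id, cid in enumerate(ordered, start=1):
        members = tuple(sorted(partition.members(cid)))
        pooled = cohort.pooled(members)
        curve = curves[cid]
        groups.append(
            PrognosticGroup(
                group_id=new_id,
                members=members,
                km=curve,
                five_year_survival=survival_at(curve, FIVE_YEARS_MONTHS),
                n_patients=len(pooled),
                n_deaths=int(pooled.event.sum()),
            )
        )
    return groups


def _group_ranks(partition: PartitionLabeling, cohort: CombinationCohort) -> dict[str, int]:
    """Severity rank (1 = best survival) of each combination under a partition."""
    ordered, _, _ = _severity_order(partition, cohort)
    rank_of_cluster = {cid: rank for rank, cid in enumerate(ordered, start=1)}
    return {label: rank_of_cluster[cid] for label, cid in partition.assignment.items()}


def cindex_curve(
    tree: Dendrogram, cohort: CombinationCohort, max_groups: int | None = None
) -> CIndexCurve:
    """Harrell's C of the k-group system for every cut k = 1..max_groups.

    For each k the dendrogram is cut into k groups, the groups are ordered by
    severity, and each patient's risk score is the ordinal rank of their
    group; C(1) is 0.5 by convention (a single group carries no ordering
    information).
    """
    n = tree.n
    max_groups = n if max_groups is None else max_groups
    if not 1 <= max_groups <= n:
        raise ValueError(f"max_groups must be in 1..{n}")
    times, events, combo_idx = _patient_arrays(cohort)
    ks, values = [], []
    for k in range(1, max_groups + 1):
        if k == 1:
            ks.append(1)
            values.append(0.5)
            continue
        partition = cut_dendrogram(tree, k)
        ranks = _group_ranks(partition, cohort)
        rank_by_combo = np.array([ranks[l] for l in cohort.labels], dtype=float)
        risk = rank_by_combo[combo_idx]
        ks.append(k)
        values.append(concordance_point_estimate(risk, times, events))
    return CIndexCurve(ks=tuple(ks), values=tuple(values))


def select_knee(curve: CIndexCurve, tol: float = 0.005) -> int:
    """Knee of the C-index curve: where the marginal gains flatten out.

    Returns the smallest k such that every later one-step gain
    C(j+1) - C(j), j >= k, is below ``tol``.  If the curve never settles
    (the last gain still exceeds the tolerance) the maximum k is returned
    with a warning; a flat curve gives k = 1.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if len(curve.ks) < 2:
        raise ValueError("need a curve over at least two group counts")
    diffs = curve.forward_differences()
    big = np.nonzero(diffs >= tol)[0]  # diffs[j] is the gain from k=j+1 to k=j+2
    if big.size == 0:
        return curve.ks[0]
    n_star = curve.ks[int(big[-1]) + 1]
    if n_star == curve.ks[-1]:
        warnings.warn(
            "C-index curve shows no plateau within the examined range; "
            f"using the maximum group count {n_star}",
            stacklevel=2,
        )
    return n_star


def build_prognostic_system(
    cohort: CombinationCohort,
    *,
    weights: EnsembleWeights | None = None,
    knee_tol: float = 0.005,
    n_groups: int | None = None,
    max_groups: int | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    degenerate_value: float = 1.0,
) -> PrognosticSystem:
    """Run the full EACCD pipeline on a filtered cohort.

    Initial dissimilarities -> ensemble PAM consensus -> minimax dendrogram
    -> C-index curve over cuts -> knee selection of n* (or the forced
    ``n_groups``) -> severity-ordered groups with pooled KM curves and the
    concordance of the final group ranks (bootstrap CI with ``n_boot``
    resamples; 0 skips the interval).  Also reports the unadjusted log-rank
    p-value for each pair of adjacent groups.
    """
    d0 = initial_dissimilarity_matrix(cohort, degenerate_value=degenerate_value)
    learned = ensemble_dissimilarity(d0, weights)
    tree = minimax_linkage(learned)
    curve = cindex_curve(tree, cohort, max_groups)
    n_star = n_groups if n_groups is not None else select_knee(curve, knee_tol)
    if not 1 <= n_star <= tree.n:
        raise ValueError(f"number of groups must be in 1..{tree.n}, got {n_star}")
    partition = cut_dendrogram(tree, n_star)
    groups = order_groups(partition, cohort)
    assignments = {
        label: group.group_id for group in groups for label in group.members
    }
    times, events, combo_idx = _patient_arrays(cohort)
    rank_by_combo = np.array([assignments[l] for l in cohort.labels], dtype=float)
    risk = rank_by_combo[combo_idx]
    from .cohort import Observations

    concordance = harrell_cindex(
        risk, Observations(times, events), n_boot=n_boot, seed=seed
    )
    adjacent_p = tuple(
        logrank(
            cohort.pooled(groups[i].members), cohort.pooled(groups[i + 1].members)
        ).p
        for i in range(len(groups) - 1)
    )
    return PrognosticSystem(
        dendrogram=tree,
        assignments=assignments,
        concordance=concordance,
        groups=tuple(groups),
        curve=curve,
        n_star=n_star,
        adjacent_logrank_p=adjacent_p,
        initial_dissimilarity=d0,
        learned_dissimilarity=learned,
        scheme=cohort.scheme,
    )


def assign_patient(
    system: PrognosticSystem, levels: Mapping[str, str] | str
) -> int | None:
    """Prognostic group of a patient's factor-level combination.

    Returns the 1-based group id, or ``None`` when the combination is valid
    but unknown to the system (e.g. excluded by the minimum-size filter) —
    an explicit "unassignable" outcome rather than a guess.  Malformed levels
    raise a ``ValueError``.
    """
    if isinstance(levels, str):
        label = levels
        if system.scheme is not None and label not in (
            set(system.assignments) | set(_all_labels(system.scheme))
        ):
            raise ValueError(f"{label!r} is not a combination of the system's scheme")
    else:
        if system.scheme is None:
            raise ValueError("system carries no factor scheme; pass a label instead")
        label = system.scheme.label(levels)
    return system.assignments.get(label)


def _all_labels(scheme: FactorScheme) -> list[str]:
    from .cohort import enumerate_combinations

    return enumerate_combinations(scheme)


#: AJCC 9th-edition stage of each T/N/M combination for pancreatic NETs.
AJCC_STAGES = ("I", "II", "III", "IV")


def assign_ajcc_stage(t: str, n: str, m: str) -> str:
    """AJCC 9th-edition staging rule for pancreatic neuroendocrine tumors.

    Any distant metastasis is stage IV; otherwise T4 disease or nodal
    involvement is stage III; otherwise tumors beyond T1 are stage II and
    T1N0M0 is stage I.  Over the 16 T/N/M combinations this yields the
    1/2/5/8 partition across stages I-IV.
    """
    if t not in ("T1", "T2", "T3", "T4"):
        raise ValueError(f"invalid T level {t!r}")
    if n not in ("N0", "N1"):
        raise ValueError(f"invalid N level {n!r}")
    if m not in ("M0", "M1"):
        raise ValueError(f"invalid M level {m!r}")
    if m == "M1":
        return "IV"
    if t == "T4" or n == "N1":
        return "III"
    if t in ("T2", "T3"):
        return "II"
    return "I"


def ajcc_stage_rank(t: str, n: str, m: str) -> int:
    """Ordinal risk score of the AJCC stage (I -> 1, ..., IV -> 4)."""
    return AJCC_STAGES.index(assign_ajcc_stage(t, n, m)) + 1
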
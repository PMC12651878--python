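"""Independent reference implementations used only as test oracles.

Each oracle is written as directly as possible (explicit loops, exhaustive
enumeration) and shares no code with the package paths it checks.
"""

from itertools import combinations

import numpy as np


def empirical_survivor(times: np.ndarray, t: float) -> float:
    """Fraction of (uncensored) times strictly greater than t."""
    times = np.asarray(times, float)
    return float((times > t).mean())


def brute_concordance(time, event, risk):
    """Harrell's C by explicit pair enumeration."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    conc = 0.0
    comp = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shorter_dies_first = time[i] < time[j] and event[i] == 1
            tied_death_vs_censor = (
                time[i] == time[j] and event[i] == 1 and event[j] == 0
            )
            if not (shorter_dies_first or tied_death_vs_censor):
                continue
            comp += 1
            if risk[i] > risk[j]:
                conc += 1.0
            elif risk[i] == risk[j]:
                conc += 0.5
    return (conc / comp if comp else float("nan")), comp


def exhaustive_pam(values: np.ndarray, k: int):
    """Globally optimal k-medoid set by enumerating every candidate set."""
    n = values.shape[0]
    best_cost, best_meds = np.inf, None
    for meds in combinations(range(n), k):
        cost = values[:, list(meds)].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost, best_meds = cost, meds
    return float(best_cost), best_meds


def brute_minimax_merges(labels, values):
    """Minimax-linkage merge sequence with brute-force prototype search."""
    n = len(labels)
    active = {i: [i] for i in range(n)}
    next_id = n
    merges = []
    while len(active) > 1:
        best = None
        for a, b in combinations(sorted(active), 2):
            members = sorted(active[a] + active[b])
            cost, proto = min(
                (max(values[p][x] for x in members), p) for p in members
            )
            rep_a, rep_b = min(active[a]), min(active[b])
            key = (cost, min(rep_a, rep_b), max(rep_a, rep_b))
            if best is None or key < best[0]:
                best = (key, a, b, proto, cost)
        _, a, b, proto, cost = best
        left, right = sorted((a, b), key=lambda i: min(active[i]))
        merges.append((left, right, cost, labels[proto]))
        active[next_id] = sorted(active[a] + active[b])
        del active[a], active[b]
        next_id += 1
    return merges


def gehan_u_naive(ta, ea, tb, eb):
    """Gehan's U by explicit double loop over cross-pairs."""
    u = 0
    for t1, e1 in zip(ta, ea):
        for t2, e2 in zip(tb, eb):
            if (t2 < t1 and e2 == 1) or (t2 == t1 and e2 == 1 and e1 == 0):
                u += 1
            elif (t1 < t2 and e1 == 1) or (t1 == t2 and e1 == 1 and e2 == 0):
                u -= 1
    return u


def gehan_permutation_variance(times, events, m):
    """Exact variance of U over all assignments of m of the pooled subjects
    to the first sample (enumeration; feasible only for tiny pools)."""
    n_total = len(times)
    us = []
    for idx in combinations(range(n_total), m):
        in_a = np.zeros(n_total, bool)
        in_a[list(idx)] = True
        u = gehan_u_naive(
            np.asarray(times)[in_a],
            np.asarray(events)[in_a],
            np.asarray(times)[~in_a],
            np.asarray(events)[~in_a],
        )
        us.append(u)
    us = np.asarray(us, float)
    return float(us.var())  # population variance: mean U over permutations is 0
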
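"""Censored-data statistics: Kaplan–Meier, Gehan–Wilcoxon, log-rank, Harrell's C.

The Gehan–Wilcoxon two-sample statistic and the effect size derived from it
are the building blocks of the initial dissimilarity between combinations;
the log-rank test annotates the separation of adjacent prognostic groups; and
Harrell's concordance index scores entire staging systems.  Kaplan–Meier
estimation is delegated to lifelines; the two-sample statistics and the
concordance pair-counting are implemented here because the downstream
clustering needs the raw statistic, its permutation variance and the exact
tie conventions, which library front-ends do not expose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index as _lifelines_cindex
from scipy import stats

from .cohort import Observations

__all__ = [
    "KMCurve",
    "TestResult",
    "ConcordanceResult",
    "CIndexComparison",
    "km_estimate",
    "survival_at",
    "gehan_wilcoxon",
    "effect_size_dissimilarity",
    "logrank",
    "harrell_cindex",
    "concordance_point_estimate",
    "compare_cindex",
    "restricted_mean_survival",
]

FIVE_YEARS_MONTHS = 60.0


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times; ``survival`` the estimate just
    after each event time; ``n_risk``/``n_event`` the at-risk and death
    counts there.  ``max_follow_up`` is the largest observed time (event or
    censored) — the estimate is undefined beyond it.
    """

    times: np.ndarray
    survival: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    max_follow_up: float
    n_total: int

    def survival_at(self, t: float) -> float:
        return survival_at(self, t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


def km_estimate(obs: Observations) -> KMCurve:
    """Kaplan–Meier estimate of the survivor function.

    Uses the standard convention that a censored time tied with an event time
    is still at risk at that time (censoring happens just after the events).
    """
    if len(obs) == 0:
        raise ValueError("cannot estimate a survival curve from no observations")
    fitter = KaplanMeierFitter()
    fitter.fit(obs.time, obs.event)
    table = fitter.event_table
    event_rows = table[table["observed"] > 0]
    # survival just after each event time, from the fitted step function
    times = event_rows.index.to_numpy(dtype=float)
    surv = fitter.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        times=times,
        survival=surv,
        n_risk=event_rows["at_risk"].to_numpy(dtype=int),
        n_event=event_rows["observed"].to_numpy(dtype=int),
        max_follow_up=float(obs.time.max()),
        n_total=len(obs),
    )


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value S(t); NaN beyond follow-up.

    Querying past the largest observed time would be extrapolation, so the
    value is flagged as undefined (NaN) rather than guessed.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    if t > curve.max_follow_up:
        return float("nan")
    idx = np.searchsorted(curve.times, t, side="right")
    if idx == 0:
        return 1.0
    return float(curve.survival[idx - 1])


def restricted_mean_survival(curve: KMCurve, horizon: float | None = None) -> float:
    """Area under the KM curve up to ``horizon`` (default: end of follow-up)."""
    horizon = curve.max_follow_up if horizon is None else min(horizon, curve.max_follow_up)
    grid = np.concatenate([[0.0], curve.times[curve.times <= horizon], [horizon]])
    grid = np.unique(grid)
    heights = np.array([survival_at(curve, t) for t in grid[:-1]])
    return float(np.sum(heights * np.diff(grid)))


@dataclass(frozen=True)
class TestResult:
    """Two-sample test summary: raw statistic, variance, z, two-sided p."""

    statistic: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


def _gehan_h(t_row, e_row, t_col, e_col):
    """Pairwise Gehan scores h(i, j) in {-1, 0, +1}.

    h = +1 when observation i (rows) definitely outlives j (columns) given
    censoring: j's death is observed strictly before i's observed time, or at
    the same time with i censored.  h = -1 in the mirror case; 0 when the
    ordering is indeterminate.
    """
    ti = t_row[:, None]
    ei = e_row[:, None]
    tj = t_col[None, :]
    ej = e_col[None, :]
    longer = ((tj < ti) & (ej == 1)) | ((tj == ti) & (ej == 1) & (ei == 0))
    shorter = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (ej == 0))
    return longer.astype(np.int64) - shorter.astype(np.int64)


def gehan_wilcoxon(a: Observations, b: Observations) -> TestResult:
    """Gehan's generalized Wilcoxon test for two right-censored samples.

    U sums the pairwise scores h(i, j) over all cross-pairs (i in ``a``,
    j in ``b``); a negative U means sample ``a`` tends to die earlier.  The
    variance is the exact permutation variance
    ``mn / ((m+n)(m+n-1)) * sum_k s_k**2`` with ``s_k`` the pooled Gehan
    scores, and the two-sided p-value uses the normal approximation.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples need at least one observation")
    m, n = len(a), len(b)
    u = float(_gehan_h(a.time, a.event, b.time, b.event).sum())
    t_pool = np.concatenate([a.time, b.time])
    e_pool = np.concatenate([a.event, b.event])
    scores = _gehan_h(t_pool, e_pool, t_pool, e_pool).sum(axis=1)
    var = m * n / ((m + n) * (m + n - 1)) * float(np.sum(scores.astype(float) ** 2))
    if var <= 0:
        return TestResult(u, 0.0, float("nan"), float("nan"), degenerate=True)
    z = u / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(u, var, float(z), float(p))


def effect_size_dissimilarity(
    a: Observations, b: Observations, *, degenerate_value: float = 1.0
) -> float:
    """Survival-difference dissimilarity between two censored samples.

    The r-type effect size ``|z| / sqrt(m + n)`` of the standardized Gehan
    statistic: symmetric, zero for identical samples, and stabilized against
    sample size.  When the Gehan variance degenerates (e.g. every pairwise
    ordering is indeterminate), no difference can be measured; a configurable
    sentinel dissimilarity is returned with a warning so clustering can
    proceed.
    """
    result = gehan_wilcoxon(a, b)
    if result.degenerate:
        warnings.warn(
            "degenerate Gehan variance (no determinate pair orderings); "
            f"using sentinel dissimilarity {degenerate_value}",
            stacklevel=2,
        )
        return float(degenerate_value)
    return float(abs(result.z) / np.sqrt(len(a) + len(b)))


def logrank(a: Observations, b: Observations) -> TestResult:
    """Two-sample log-rank test.

    The statistic is the observed-minus-expected death count of sample ``a``
    (positive when ``a`` dies earlier than expected under the null), with the
    usual hypergeometric variance and a chi-square (1 df) two-sided p-value.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples need at least one observation")
    t_pool = np.concatenate([a.time, b.time])
    e_pool = np.concatenate([a.event, b.event])
    in_a = np.concatenate([np.ones(len(a), bool), np.zeros(len(b), bool)])
    if e_pool.sum() == 0:
        return TestResult(0.0, 0.0, float("nan"), float("nan"), degenerate=True)
    event_times = np.unique(t_pool[e_pool == 1])
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = t_pool >= t
        n_total = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dying = (t_pool == t) & (e_pool == 1)
        d = int(dying.sum())
        d_a = int((dying & in_a).sum())
        o_minus_e += d_a - d * n_a / n_total
        if n_total > 1:
            var += (
                d
                * (n_total - d)
                / (n_total - 1)
                * n_a
                * (n_total - n_a)
                / n_total**2
            )
    if var <= 0:
        return TestResult(float(o_minus_e), 0.0, float("nan"), float("nan"), degenerate=True)
    z = o_minus_e / np.sqrt(var)
    p = float(stats.chi2.sf(z * z, df=1))
    return TestResult(float(o_minus_e), float(var), float(z), p)


@dataclass(frozen=True)
class ConcordanceResult:
    """Harrell's C with a bootstrap percentile interval."""

    cindex: float
    ci_low: float
    ci_high: float
    n_comparable: int


def _comparable_pairs(time, event, risk):
    """Concordant/tied/comparable pair counts under Harrell's rules.

    A pair is usable when the shorter time is an observed death (a death tied
    with a censoring counts, with the censored patient the longer survivor;
    two deaths at the same time do not).  Concordance means higher risk on the
    shorter survivor; tied risks count one half.  Row-blocked to keep memory
    bounded for large cohorts.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    risk = np.asarray(risk, float)
    n = time.size
    conc = 0.0
    ties = 0
    comp = 0
    block = 512
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        ti = time[sl][:, None]
        ei = event[sl][:, None]
        ri = risk[sl][:, None]
        usable = ((ti < time[None, :]) & (ei == 1)) | (
            (ti == time[None, :]) & (ei == 1) & (event[None, :] == 0)
        )
        comp += int(usable.sum())
        conc += int((usable & (ri > risk[None, :])).sum())
        ties += int((usable & (ri == risk[None, :])).sum())
    return conc, ties, comp


def concordance_point_estimate(risk, time, event) -> float:
    """Fast Harrell's C point estimate (higher risk should mean shorter survival)."""
    risk = np.asarray(risk, float)
    if np.ptp(risk) == 0:
        return 0.5  # all predictions tied: no discrimination by convention
    return float(_lifelines_cindex(np.asarray(time, float), -risk, np.asarray(event, int)))


def harrell_cindex(
    risk,
    obs: Observations,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ConcordanceResult:
    """Harrell's concordance index of a risk score against censored outcomes.

    C = (concordant + 0.5 * risk-tied) / comparable over Harrell-comparable
    pairs.  The confidence interval is a patient-level bootstrap percentile
    interval (``n_boot`` resamples; set ``n_boot=0`` to skip it).
    """
    risk = np.asarray(risk, dtype=float)
    if risk.shape != obs.time.shape:
        raise ValueError("risk scores must align with the observations")
    if risk.size < 2:
        raise ValueError("need at least two patients")
    conc, ties, comp = _comparable_pairs(obs.time, obs.event, risk)
    if comp == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    c = (conc + 0.5 * ties) / comp
    if n_boot <= 0:
        return ConcordanceResult(float(c), float("nan"), float("nan"), comp)
    rng = np.random.default_rng(seed)
    n = risk.size
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[i] = concordance_point_estimate(risk[idx], obs.time[idx], obs.event[idx])
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    return ConcordanceResult(float(c), float(lo), float(hi), comp)


@dataclass(frozen=True)
class CIndexComparison:
    """Paired-bootstrap comparison of two risk scores on the same cohort."""

    difference: float
    ci_low: float
    ci_high: float
    p: float
    cindex_a: float
    cindex_b: float


def compare_cindex(
    risk_a,
    risk_b,
    obs: Observations,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> CIndexComparison:
    """Compare the C-indexes of two risk scores on the same patients.

    Both concordances are recomputed on each patient-level bootstrap resample,
    giving the paired distribution of C_A - C_B; the interval is the
    percentile interval and the two-sided p-value is twice the smaller tail
    proportion of the bootstrap differences around zero.
    """
    risk_a = np.asarray(risk_a, float)
    risk_b = np.asarray(risk_b, float)
    if risk_a.shape != obs.time.shape or risk_b.shape != obs.time.shape:
        raise ValueError("risk scores must align with the observations")
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    c_a = concordance_point_estimate(risk_a, obs.time, obs.event)
    c_b = concordance_point_estimate(risk_b, obs.time, obs.event)
    rng = np.random.default_rng(seed)
    n = len(obs)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        t, e = obs.time[idx], obs.event[idx]
        diffs[i] = concordance_point_estimate(
            risk_a[idx], t, e
        ) - concordance_point_estimate(risk_b[idx], t, e)
    lo, hi = np.quantile(diffs, [alpha / 2, 1 - alpha / 2])
    p = 2.0 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return CIndexComparison(
        difference=float(c_a - c_b),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(min(p, 1.0)),
        cindex_a=float(c_a),
        cindex_b=float(c_b),
    )
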
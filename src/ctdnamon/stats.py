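"""Statistical tests and survival analysis for cohort comparisons.

Wilcoxon signed-rank and rank-sum compare max-VAF and alteration counts
before/after chemotherapy and their deltas across response groups; t-test /
one-way ANOVA handle cfDNA-concentration style comparisons; chi-square with
Fisher's-exact fallback handles detection-rate contingency tables. Survival
uses the Kaplan-Meier product-limit estimator and a weighted log-rank family
whose Gehan-Breslow-Wilcoxon member (weight = number at risk) is the default
curve comparison; weight = 1 recovers the standard log-rank.

Conventions: two-sided p-values throughout; signed-rank zeros dropped;
Fisher two-sided by the point-probability method; exact enumeration paths at
small sample sizes, normal/chi-square approximations with tie and continuity
corrections beyond them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest class despite the name

    method: str
    statistic: float
    p_value: float
    df: float | None = None
    exact: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

EXACT_SIGNED_RANK_MAX = 25
EXACT_RANK_SUM_MAX = 10


def wilcoxon_signed_rank(differences: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon convention); ties are mid-ranked. Exact null
    enumeration over the 2^m sign patterns when m <= 25 and the absolute
    differences are tie-free, otherwise the normal approximation with tie
    and continuity corrections.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("no differences supplied")
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return TestResult(
            "wilcoxon-signed-rank", 0.0, 1.0, exact=True, note="all differences zero"
        )
    has_ties = len(np.unique(np.abs(d))) < m
    use_exact = m <= EXACT_SIGNED_RANK_MAX and not has_ties
    res = sps.wilcoxon(
        d,
        alternative="two-sided",
        method="exact" if use_exact else "approx",
        correction=not use_exact,
    )
    return TestResult(
        "wilcoxon-signed-rank",
        float(res.statistic),
        float(res.pvalue),
        exact=use_exact,
    )


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the smaller sample has <= 10 observations and the
    pooled data are tie-free; normal approximation with tie correction and
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    use_exact = min(x.size, y.size) <= EXACT_RANK_SUM_MAX and not has_ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
    )
    return TestResult(
        "wilcoxon-rank-sum", float(res.statistic), float(res.pvalue), exact=use_exact
    )


# ---------------------------------------------------------------------------
# means
# ---------------------------------------------------------------------------

def mean_comparison(groups: Sequence[Sequence[float]]) -> TestResult:
    """Pooled-variance two-sided t-test for 2 groups, one-way ANOVA for >= 3."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    if len(arrays) == 2:
        res = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        df = arrays[0].size + arrays[1].size - 2
        return TestResult("t-test", float(res.statistic), float(res.pvalue), df=df)
    res = sps.f_oneway(*arrays)
    df = len(arrays) - 1
    return TestResult("anova", float(res.statistic), float(res.pvalue), df=df)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

EXACT_RC_MAX_TOTAL = 200


def _exact_rc_test(table: np.ndarray) -> float:
    """Two-sided exact test for an r x c table by full enumeration.

    Conditional on both margins, each table has probability
    (prod r_i! prod c_j!) / (N! prod a_ij!); the two-sided p is the total
    probability of tables no more likely than the observed one
    (point-probability method). Enumeration is feasible for N <= 200 on the
    small tables this pipeline produces.
    """
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())

    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    const = log_fact[rows].sum() + log_fact[cols].sum() - log_fact[n]

    def logp(t: np.ndarray) -> float:
        return const - log_fact[t].sum()

    obs_lp = logp(table)
    r, c = table.shape
    total = 0.0

    def rec(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if (last >= 0).all():
                t = np.vstack(acc + [last])
                lp = logp(t)
                if lp <= obs_lp + 1e-9:
                    total += math.exp(lp)
            return
        # enumerate row i cell by cell
        def cells(j: int, left: int, row: list[int]) -> None:
            if j == c - 1:
                if 0 <= left <= remaining_cols[c - 1]:
                    rec(
                        i + 1,
                        remaining_cols - np.array(row + [left]),
                        acc + [np.array(row + [left])],
                    )
                return
            for v in range(min(int(left), int(remaining_cols[j])) + 1):
                cells(j + 1, left - v, row + [v])

        cells(0, int(rows[i]), [])

    rec(0, cols.copy(), [])
    return min(total, 1.0)


def contingency_test(table: Sequence[Sequence[float]]) -> TestResult:
    """Chi-square test of independence with exact-test fallback.

    Pearson chi-square without continuity correction by default. When any
    expected count is below 5: Fisher's exact (two-sided, point-probability)
    for 2x2 tables, full conditional enumeration for larger tables with
    total <= 200. Zero-margin rows/columns are dropped first.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    t = np.round(t).astype(int)
    note = ""
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        note = "zero-margin rows/columns dropped"
        t = t[keep_r][:, keep_c]
    if t.size == 0 or t.sum() == 0:
        raise ValueError("table has no counts")
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table collapsed below 2x2 after dropping empty margins")

    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected < 5).any():
        if t.shape == (2, 2):
            _, p = sps.fisher_exact(t, alternative="two-sided")
            return TestResult("fisher-exact", float("nan"), float(p), exact=True, note=note)
        if t.sum() <= EXACT_RC_MAX_TOTAL:
            p = _exact_rc_test(t)
            return TestResult("exact-rxc", float("nan"), float(p), exact=True, note=note)
        note = (note + "; " if note else "") + "low expected counts, exact infeasible"
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return TestResult("chi-square", float(chi2), float(p), df=dof, note=note)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: bool  # True = death observed
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"survival time must be finite positive, got {self.time}")


@dataclass
class KMCurve:
    """Kaplan-Meier product-limit estimate for one group."""

    event_times: np.ndarray
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    group: str = ""
    n_subjects: int = 0

    def survival_at(self, t: float) -> float:
        """Right-continuous step value S(t); S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )


def km_estimate(records: Sequence[SurvivalRecord], group: str = "") -> KMCurve:
    """Kaplan-Meier estimator. Subjects censored at an event time are counted
    at risk for that time."""
    recs = list(records)
    if not recs:
        raise ValueError("km_estimate requires at least one record")
    times = np.array([r.time for r in recs])
    events = np.array([r.event for r in recs])

    event_times = np.unique(times[events])
    surv, at_risk_out, d_out = [], [], []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk_out.append(n_risk)
        d_out.append(d)
    return KMCurve(
        event_times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk_out),
        n_events=np.array(d_out),
        group=group,
        n_subjects=len(recs),
    )


def gbw_test(
    groups: Mapping[str, Sequence[SurvivalRecord]] | Sequence[Sequence[SurvivalRecord]],
    weight: str = "gbw",
) -> TestResult:
    """Weighted log-rank comparison of survival across groups.

    ``weight="gbw"`` (Gehan-Breslow-Wilcoxon) weights each event time by the
    total number at risk, emphasising early differences; ``weight="logrank"``
    uses weight 1. Chi-square statistic with groups-1 degrees of freedom.
    """
    if isinstance(groups, Mapping):
        labels = list(groups)
        data = [list(groups[k]) for k in labels]
    else:
        data = [list(g) for g in groups]
        labels = [str(i) for i in range(len(data))]
    k = len(data)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in data):
        raise ValueError("every group must be non-empty")
    if weight not in ("gbw", "logrank"):
        raise ValueError(f"unknown weight {weight!r}")

    times = np.concatenate([[r.time for r in g] for g in data])
    events = np.concatenate([[r.event for r in g] for g in data]).astype(bool)
    gidx = np.concatenate([[i] * len(g) for i, g in enumerate(data)])
    if not events.any():
        raise ValueError("no events in any group")

    event_times = np.unique(times[events])
    u = np.zeros(k - 1)
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        risk = times >= t
        n = int(risk.sum())
        d = int((events & (times == t)).sum())
        if n == 0 or d == 0:
            continue
        w = float(n) if weight == "gbw" else 1.0
        n_i = np.array([(risk & (gidx == i)).sum() for i in range(k)], dtype=float)
        d_i = np.array(
            [((events) & (times == t) & (gidx == i)).sum() for i in range(k)],
            dtype=float,
        )
        e_i = d * n_i / n
        u += w * (d_i - e_i)[: k - 1]
        if n > 1:
            # multivariate hypergeometric covariance of d_i
            c = d * (n - d) / (n - 1)
            for a in range(k - 1):
                for b in range(k - 1):
                    if a == b:
                        V[a, b] += w * w * c * n_i[a] * (n - n_i[a]) / n**2
                    else:
                        V[a, b] += -w * w * c * n_i[a] * n_i[b] / n**2

    try:
        stat = float(u @ np.linalg.solve(V, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(V) @ u)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df=k - 1))
    name = "gehan-breslow-wilcoxon" if weight == "gbw" else "log-rank"
    return TestResult(name, stat, p, df=k - 1)
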
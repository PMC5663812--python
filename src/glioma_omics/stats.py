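"""Native statistical primitives used throughout the pipeline.

Every hypothesis test the analysis stages need — Fisher's exact test on
2x2 tables, Welch's unequal-variance t test, the Benjamini-Hochberg
step-up, the Wilcoxon rank-sum test, Kaplan-Meier product-limit
estimation and the (unweighted, Mantel-Haenszel) log-rank test — is
implemented here directly, so the downstream modules depend on a single
audited code path.  Only special functions (log-gamma, the t / normal /
chi-square distribution functions) are delegated to ``scipy.special``.

Conventions
-----------
* All p-values are two-sided.
* Fisher's two-sided rule is the point-probability method: the p-value
  sums hypergeometric point probabilities of every table with the same
  margins whose probability does not exceed that of the observed table
  (relative tie tolerance 1e-7).
* Wilcoxon uses exact enumeration for combined n <= 12 and a
  tie-corrected, continuity-corrected normal approximation above that.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import chdtrc, gammaln, ndtr, stdtr

__all__ = [
    "TestResult",
    "SurvivalRecord",
    "fisher_exact_2x2",
    "welch_t",
    "bh_adjust",
    "wilcoxon_rank_sum",
    "km_estimate",
    "logrank_test",
]

_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (months), death indicator, group label."""

    time: float
    event: bool
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


def _log_hypergeom_pmf(k: int, row1: int, row2: int, col1: int) -> float:
    n = row1 + row2
    return (
        gammaln(row1 + 1)
        - gammaln(k + 1)
        - gammaln(row1 - k + 1)
        + gammaln(row2 + 1)
        - gammaln(col1 - k + 1)
        - gammaln(row2 - col1 + k + 1)
        + gammaln(col1 + 1)
        + gammaln(n - col1 + 1)
        - gammaln(n + 1)
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Rows are the two groups, columns the mutated / unmutated counts.
    The statistic reported is the sample odds ratio (inf when c*b == 0
    and a*d > 0, nan for the all-degenerate case).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(x) for x in counts)
    total = a + b + c + d
    if total == 0:
        raise ValueError("all-zero table is degenerate")

    row1, row2, col1 = a + b, c + d, a + c
    k_min = max(0, col1 - row2)
    k_max = min(row1, col1)
    ks = np.arange(k_min, k_max + 1)
    logp = np.array([_log_hypergeom_pmf(int(k), row1, row2, col1) for k in ks])
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[ks == a][0]
    p_value = float(probs[probs <= p_obs * (1 + _TIE_RTOL)].sum())
    p_value = min(1.0, p_value)

    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    return TestResult(statistic=odds, p_value=p_value, method="fisher")


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance t test (two-sided)."""
    xa = np.asarray(values_a, dtype=float)
    xb = np.asarray(values_b, dtype=float)
    na, nb = xa.size, xb.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    ma, mb = xa.mean(), xb.mean()
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return TestResult(statistic=0.0, p_value=1.0, method="welch_t", df=float(na + nb - 2))
        return TestResult(statistic=math.copysign(math.inf, ma - mb), p_value=0.0,
                          method="welch_t", df=float(na + nb - 2))
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stdtr(df, -abs(t)))
    return TestResult(statistic=float(t), p_value=min(1.0, p), method="welch_t", df=float(df))


def welch_t_matrix(group1: np.ndarray, group2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t over two (features x samples) arrays.

    Vectorized counterpart of :func:`welch_t` for the per-gene / per-probe
    screens; returns (t, p) arrays.  Rows where both variances vanish get
    t = 0, p = 1 when the means agree and p = 0 otherwise.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    na, nb = g1.shape[1], g2.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    se2 = v1 / na + v2 / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / na) ** 2 / (na - 1) + (v2 / nb) ** 2 / (nb - 1))
    p = np.ones_like(t)
    ok = se2 > 0
    p[ok] = 2.0 * stdtr(df[ok], -np.abs(t[ok]))
    degen = ~ok & (m1 != m2)
    t[~ok] = 0.0
    t[degen] = np.inf * np.sign(m1[degen] - m2[degen])
    p[degen] = 0.0
    return t, np.clip(p, 0.0, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    sorted_vals = pooled[order]
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def wilcoxon_rank_sum(
    values_a: Sequence[float], values_b: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact enumeration of all rank assignments when the combined sample
    size is at most ``exact_max_n``; otherwise the normal approximation
    with tie-corrected variance and a 0.5 continuity correction.
    """
    xa = np.asarray(values_a, dtype=float)
    xb = np.asarray(values_b, dtype=float)
    na, nb = xa.size, xb.size
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    n = na + nb
    pooled = np.concatenate([xa, xb])
    ranks = _midranks(pooled)
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    if n <= exact_max_n:
        dev_obs = abs(w - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            ws = ranks[list(combo)].sum()
            total += 1
            if abs(ws - mu) >= dev_obs - 1e-9:
                count += 1
        p = count / total
        return TestResult(statistic=w, p_value=p, method="wilcoxon")

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0, method="wilcoxon")
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * float(ndtr(-z))
    return TestResult(statistic=w, p_value=min(1.0, p), method="wilcoxon")


def km_estimate(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Kaplan-Meier product-limit estimate.

    Returns ``(times, survival)`` where ``times`` are the distinct event
    times in increasing order and ``survival[i]`` is S(t) just after
    ``times[i]``.  S(0) = 1 is implicit; the function is a right-
    continuous step function that drops only at event times.
    """
    if len(records) == 0:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative survival time")
    event_times = np.unique(times[events])
    surv = []
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return event_times, np.asarray(surv)


def logrank_test(records: Sequence[SurvivalRecord]) -> TestResult:
    """Unweighted (Mantel-Haenszel) two-group log-rank test, 1 df."""
    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError("log-rank requires exactly 2 groups")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    is_g1 = np.array([r.group == groups[0] for r in records], dtype=bool)
    if is_g1.all() or (~is_g1).all():
        raise ValueError("one group is empty")
    if not events.any():
        raise ValueError("no events observed")

    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n_tot = int(at_risk.sum())
        n1 = int((at_risk & is_g1).sum())
        d_tot = int(((times == t) & events).sum())
        d1 = int(((times == t) & events & is_g1).sum())
        if n_tot < 2:
            continue
        e1 = d_tot * n1 / n_tot
        v = (d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot)) / (n_tot - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return TestResult(statistic=0.0, p_value=1.0, method="logrank", df=1.0)
    chi2 = o_minus_e**2 / var
    p = float(chdtrc(1, chi2))
    return TestResult(statistic=float(chi2), p_value=min(1.0, p), method="logrank", df=1.0)
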
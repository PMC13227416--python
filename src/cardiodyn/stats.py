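"""Two-group comparison of per-embryo metric means.

Embryo means are compared between females and males with a Mann-Whitney U
test: exact two-sided p by the null distribution of U (count recurrence over
all C(n1+n2, n1) rank assignments) when both groups are small and tie-free,
otherwise the normal approximation with tie and continuity corrections.
Group summaries follow the field's box-plot convention: mean, sample s.d.
(n-1 denominator) and s.e.m. = s.d./sqrt(n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import InsufficientDataError, ValidationError

log = logging.getLogger("cardiodyn")


@dataclass
class GroupSummary:
    n: int
    mean: float
    sd: float  # NaN when n < 2
    sem: float  # NaN when n < 2


@dataclass
class GroupComparison:
    metric: str
    group_labels: tuple[str, str]
    summary1: GroupSummary
    summary2: GroupSummary
    U: float
    p_value: float
    method: str  # "exact" or "normal_approx"


@lru_cache(maxsize=None)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """counts[u] = number of rank assignments of n1-of-(n1+n2) with statistic u.

    Classic recurrence on whether the largest pooled value belongs to the
    first group: N(u; n1, n2) = N(u - n2; n1-1, n2) + N(u; n1, n2-1).
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _u_null_counts(n1 - 1, n2)  # largest value in group 1: adds n2 to U
    b = _u_null_counts(n1, n2 - 1)  # largest value in group 2
    out = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        out[u + n2] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(x, y, exact_max_n: int = 10) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p_value, method)`` where U is the statistic of the first
    sample (U + U' = n1*n2).  The exact null distribution is used when
    ``max(n1, n2) <= exact_max_n`` and the pooled data are tie-free;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction, with the method switch logged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # mid-ranks for ties
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and max(n1, n2) <= exact_max_n:
        counts = np.array(_u_null_counts(n1, n2), dtype=float)
        total = counts.sum()
        ui = int(round(u))
        cdf = counts[: ui + 1].sum()
        sf = counts[ui:].sum()
        p = min(1.0, 2.0 * min(cdf, sf) / total)
        return float(u), float(p), "exact"

    if has_ties and max(n1, n2) <= exact_max_n:
        log.info("ties present: switching Mann-Whitney method to normal approximation")
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t_counts**3 - t_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all pooled values identical
        return float(u), 1.0, "normal_approx"
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return float(u), p, "normal_approx"


def summarize_group(values) -> GroupSummary:
    """n, mean, sample s.d. and s.e.m. of one group of embryo means."""
    v = np.asarray(values, dtype=float)
    if len(v) == 0:
        raise InsufficientDataError("cannot summarize an empty group")
    if len(v) == 1:
        return GroupSummary(n=1, mean=float(v[0]), sd=float("nan"), sem=float("nan"))
    sd = float(np.std(v, ddof=1))
    return GroupSummary(n=len(v), mean=float(v.mean()), sd=sd, sem=sd / math.sqrt(len(v)))


def compare_all_metrics(
    table: pd.DataFrame,
    metrics: list[str],
    groups: tuple[str, str] = ("female", "male"),
    exact_max_n: int = 10,
) -> list[GroupComparison]:
    """One two-group comparison per metric on a per-embryo table.

    ``table`` needs a ``sex`` column; embryos with unknown/unlabelled sex are
    excluded (logged), and embryos missing a metric are excluded from that
    metric only.  A metric with an empty group yields an error-record row
    (NaN statistics) and the run continues.
    """
    if "sex" not in table.columns:
        raise ValidationError("per-embryo table must have a 'sex' column")
    labelled = table[table["sex"].isin(groups)]
    n_dropped = len(table) - len(labelled)
    if n_dropped:
        log.info("excluding %d embryo(s) without a %s/%s label", n_dropped, *groups)
    out = []
    for metric in metrics:
        if metric not in labelled.columns:
            log.warning("metric %s absent from table; skipped", metric)
            continue
        g1 = labelled.loc[labelled["sex"] == groups[0], metric].dropna().to_numpy()
        g2 = labelled.loc[labelled["sex"] == groups[1], metric].dropna().to_numpy()
        if len(g1) == 0 or len(g2) == 0:
            log.warning("metric %s: a group is empty after exclusions", metric)
            nan_sum = GroupSummary(0, float("nan"), float("nan"), float("nan"))
            out.append(
                GroupComparison(
                    metric=metric,
                    group_labels=groups,
                    summary1=summarize_group(g1) if len(g1) else nan_sum,
                    summary2=summarize_group(g2) if len(g2) else nan_sum,
                    U=float("nan"),
                    p_value=float("nan"),
                    method="error",
                )
            )
            continue
        u, p, method = mann_whitney_u(g1, g2, exact_max_n=exact_max_n)
        out.append(
            GroupComparison(
                metric=metric,
                group_labels=groups,
                summary1=summarize_group(g1),
                summary2=summarize_group(g2),
                U=u,
                p_value=p,
                method=method,
            )
        )
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison records into the emitted comparison table."""
    rows = []
    for c in comparisons:
        la, lb = c.group_labels
        rows.append(
            {
                "metric": c.metric,
                f"n_{la}": c.summary1.n,
                f"n_{lb}": c.summary2.n,
                f"mean_{la}": c.summary1.mean,
                f"sd_{la}": c.summary1.sd,
                f"sem_{la}": c.summary1.sem,
                f"mean_{lb}": c.summary2.mean,
                f"sd_{lb}": c.summary2.sd,
                f"sem_{lb}": c.summary2.sem,
                "U": c.U,
                "p_value": c.p_value,
                "method": c.method,
            }
        )
    return pd.DataFrame(rows)
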
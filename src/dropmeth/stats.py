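"""Nonparametric comparison battery and sample-size computation.

Wraps the rank tests a methylation-cohort analysis needs — paired Wilcoxon
signed-rank (tumor vs adjacent tissue), Mann-Whitney (two independent
groups), Kruskal-Wallis (more than two), Spearman correlation — into a
uniform :class:`TestResult`, switching to exact small-sample null
enumeration where it is available (signed-rank at n <= 12, Mann-Whitney at
n1*n2 <= 100, both tie-free), and to tie-corrected normal/chi-square
approximations otherwise. The computational core is scipy.stats.

``required_sample_size`` gives the smallest per-group n achieving a stated
power for a two-group mean comparison, by inverting the noncentral-t (or
two-group ANOVA F) power function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import FTestAnovaPower, TTestIndPower

from .records import CountRecord, DegenerateDataError, SampleMeta, ValidationError

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney",
    "kruskal_wallis",
    "spearman",
    "required_sample_size",
    "compare_groups",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: Tuple[int, ...]
    exact: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size


def wilcoxon_signed_rank(paired_x: Sequence[float], paired_y: Sequence[float]) -> TestResult:
    """Two-sided paired signed-rank test.

    Zero differences are dropped; the exact null (enumeration over the 2^n
    sign patterns) is used for n <= 12 without tied absolute differences,
    the tie-corrected normal approximation otherwise.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateDataError("all paired differences are zero")
    if n < 5:
        raise ValidationError("need at least 5 nonzero paired differences")
    if n <= 12:
        # exact sign-flip enumeration over all 2^n patterns; midranks make
        # this valid under tied absolute differences too
        ranks = sps.rankdata(np.abs(d))
        w_pos = float(ranks[d > 0].sum())
        patterns = np.arange(2**n)[:, None] >> np.arange(n) & 1
        w_all = patterns @ ranks
        p_le = float(np.mean(w_all <= w_pos + 1e-9))
        p_ge = float(np.mean(w_all >= w_pos - 1e-9))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        stat = min(w_pos, float(ranks.sum()) - w_pos)
        return TestResult(stat, p, "wilcoxon_signed_rank", (n,), exact=True)
    res = sps.wilcoxon(d, method="approx")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="wilcoxon_signed_rank",
        n=(n,),
        exact=False,
    )


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test for two independent groups.

    Exact null enumeration when n1*n2 <= 100 and there are no cross-group
    ties; tie-corrected normal approximation otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3 or ya.size < 3:
        raise ValidationError("each group needs at least 3 observations")
    pooled = np.concatenate([xa, ya])
    exact = xa.size * ya.size <= 100 and not _has_ties(pooled)
    res = sps.mannwhitneyu(xa, ya, method="exact" if exact else "asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="mann_whitney",
        n=(int(xa.size), int(ya.size)),
        exact=exact,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Rank ANOVA for more than two groups (tie-corrected chi-square null)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValidationError("need at least 2 groups")
    if any(a.size < 3 for a in arrs):
        raise ValidationError("each group needs at least 3 observations")
    res = sps.kruskal(*arrs)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="kruskal_wallis",
        n=tuple(int(a.size) for a in arrs),
        exact=False,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, TestResult]:
    """Spearman rank correlation; returns (rho, test result).

    Reports are made on rho; square it yourself if an r-squared-style
    summary is wanted — the two are easy to conflate in the literature.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    if xa.size < 4:
        raise ValidationError("spearman needs at least 4 pairs")
    rho, p = sps.spearmanr(xa, ya)
    return float(rho), TestResult(
        statistic=float(rho),
        p_value=float(p),
        method="spearman",
        n=(int(xa.size),),
        exact=False,
    )


def required_sample_size(
    mean1: float,
    mean2: float,
    sd1: float,
    sd2: float,
    alpha: float = 0.05,
    power: float = 0.90,
    design: str = "t",
) -> int:
    """Smallest per-group n reaching the stated power for a mean comparison.

    Effect size is Cohen's d with the root-mean-square of the two SDs as the
    scale. ``design="t"`` inverts the noncentral-t power of the two-sample
    t test; ``design="anova"`` uses the equivalent two-group ANOVA F power.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValidationError("alpha and power must be in (0, 1)")
    if not (math.isfinite(mean1) and math.isfinite(mean2)):
        raise ValidationError("means must be finite")
    if design not in ("t", "anova"):
        raise ValidationError("design must be 't' or 'anova'")
    d = abs(mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0)
    if d == 0:
        raise ValidationError("zero effect size: stated power unachievable")
    if design == "t":
        solver = TTestIndPower()
        if solver.power(effect_size=d, nobs1=2, alpha=alpha, ratio=1.0) >= power:
            return 2
        n = solver.solve_power(effect_size=d, alpha=alpha, power=power)
    else:
        # Cohen's f for two balanced groups is d/2; solve_power returns total n
        solver = FTestAnovaPower()
        if solver.power(effect_size=d / 2.0, nobs=4, alpha=alpha, k_groups=2) >= power:
            return 2
        total = solver.solve_power(effect_size=d / 2.0, alpha=alpha, power=power, k_groups=2)
        n = total / 2.0
    n = float(np.asarray(n).reshape(-1)[0])
    return max(2, math.ceil(n - 1e-9))


def compare_groups(
    metas: Sequence[SampleMeta],
    counts: Sequence[CountRecord],
    by: str,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Per-marker group comparison of positive-droplet counts.

    Groups samples by a metadata field (``class``, ``stage`` or
    ``histology``), drops groups smaller than ``min_group_size``, and runs
    Mann-Whitney for two groups or Kruskal-Wallis for more. Returns a tidy
    table: marker, grouping, groups, method, statistic, p_value, n.
    """
    field_map = {
        "class": lambda m: m.sample_class,
        "stage": lambda m: m.stage,
        "histology": lambda m: m.histology,
    }
    if by not in field_map:
        raise ValidationError(f"cannot group by {by!r}; choose from {sorted(field_map)}")
    label_of = {m.sample_id: field_map[by](m) for m in metas}

    rows = []
    markers = sorted({c.marker for c in counts})
    for marker in markers:
        groups: dict = {}
        for rec in counts:
            if rec.marker != marker:
                continue
            lab = label_of.get(rec.sample_id)
            if lab is None:
                continue
            groups.setdefault(lab, []).append(rec.n_positive)
        groups = {k: v for k, v in groups.items() if len(v) >= min_group_size}
        if len(groups) < 2:
            continue
        labels = sorted(groups)
        if len(labels) == 2:
            res = mann_whitney(groups[labels[0]], groups[labels[1]])
        else:
            res = kruskal_wallis([groups[k] for k in labels])
        rows.append(
            {
                "marker": marker,
                "grouping": by,
                "groups": "|".join(labels),
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": "|".join(str(x) for x in res.n),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "grouping", "groups", "method", "statistic", "p_value", "n"])
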
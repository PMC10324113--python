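"""Downstream statistics on PK outputs.

Group AUC summaries and percent change, equality-of-variance tests (two-sample
variance-ratio F test and Brown-Forsythe for >= 2 groups), one-way ANOVA,
eta-covariate association, Pearson/Spearman correlation, and the 2^-ddCt
relative-quantification formula.  Every test emits a uniform ``TestResult``
record serialisable to JSON.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "GroupSummary",
    "percent_change",
    "variance_ratio_test",
    "brown_forsythe",
    "anova_oneway",
    "eta_covariate_test",
    "pearson",
    "spearman",
    "ddct_fold_change",
    "group_auc_summary",
]


@dataclass
class TestResult:
    """Uniform record for a hypothesis test."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    group_n: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p": self.p,
            "group_n": list(self.group_n),
            **self.extra,
        }


@dataclass
class GroupSummary:
    group: str
    n: int
    mean: float
    variance: float
    ci95: tuple[float, float]


def percent_change(ref_mean: float, new_mean: float) -> float:
    """Signed percent change 100*(new - ref)/ref; requires ref > 0."""
    if ref_mean <= 0:
        raise ValueError(f"reference mean must be > 0, got {ref_mean!r}")
    return 100.0 * (new_mean - ref_mean) / ref_mean


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    return x


def variance_ratio_test(x, y) -> TestResult:
    """Two-sample equality-of-variance F test.

    F = s_x^2/s_y^2 (unbiased variances) on (n_x-1, n_y-1) df; two-sided
    p = 2*min(P(F>=f), P(F<=f)).  Swapping the samples maps F -> 1/F with an
    identical p-value.
    """
    x, y = _clean(x), _clean(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    df1, df2 = x.size - 1, y.size - 1
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance; F undefined")
    if vy == 0 or vx == 0:
        warnings.warn("one sample has zero variance; reporting p = 0", RuntimeWarning)
        f = math.inf if vy == 0 else 0.0
        return TestResult("variance_ratio_F", f, (df1, df2), 0.0, (x.size, y.size))
    f = vx / vy
    dist = stats.f(df1, df2)
    p = 2.0 * min(dist.sf(f), dist.cdf(f))
    return TestResult("variance_ratio_F", float(f), (df1, df2), float(min(p, 1.0)), (x.size, y.size))


def anova_oneway(values, groups) -> TestResult:
    """Standard one-way fixed-effects ANOVA from long-format values + labels."""
    values = _clean(values)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups must have equal length")
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    if n <= k:
        raise ValueError("need total n > number of groups")
    grand = values.mean()
    ssb = ssw = 0.0
    ns = []
    for lab in labels:
        g = values[groups == lab]
        ns.append(g.size)
        ssb += g.size * (g.mean() - grand) ** 2
        ssw += float(np.sum((g - g.mean()) ** 2))
    df1, df2 = k - 1, n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult("anova_oneway", 0.0, (df1, df2), 1.0, tuple(ns))
        return TestResult("anova_oneway", math.inf, (df1, df2), 0.0, tuple(ns))
    f = (ssb / df1) / (ssw / df2)
    return TestResult("anova_oneway", float(f), (df1, df2), float(stats.f.sf(f, df1, df2)), tuple(ns))


def brown_forsythe(*groups) -> TestResult:
    """Equality of variances across >= 2 groups.

    One-way ANOVA on absolute deviations from each group's median; identical
    by construction to ``anova_oneway`` applied to |x - median(group)|.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    devs, labels = [], []
    for idx, g in enumerate(groups):
        g = _clean(g)
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
        devs.append(np.abs(g - np.median(g)))
        labels.append(np.full(g.size, idx))
    res = anova_oneway(np.concatenate(devs), np.concatenate(labels))
    return TestResult("brown_forsythe", res.statistic, res.df, res.p, res.group_n)


def eta_covariate_test(eta_matrix, groups, components=("cl", "v", "ka")) -> pd.DataFrame:
    """One-way ANOVA of each eta component across treatment groups.

    Intended for etas from a no-covariate fit.  Returns a table with raw and
    Bonferroni-adjusted p-values (the multiplicity policy is a choice; both
    are reported).
    """
    eta = np.asarray(eta_matrix, dtype=float)
    if eta.ndim != 2 or eta.shape[1] != len(components):
        raise ValueError(f"eta_matrix must be (n, {len(components)})")
    rows = []
    m = len(components)
    for j, comp in enumerate(components):
        res = anova_oneway(eta[:, j], groups)
        rows.append(
            {
                "component": comp,
                "F": res.statistic,
                "df1": res.df[0],
                "df2": res.df[1],
                "p": res.p,
                "p_bonferroni": min(res.p * m, 1.0),
            }
        )
    return pd.DataFrame(rows)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with two-sided t-based p (df = n - 2)."""
    x, y = _clean(x), _clean(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0:
        return math.copysign(1.0, r), 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), n - 2))


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation (average ranks for ties).

    p-value via the t approximation for n > 9 and by exact enumeration of all
    rank permutations for n <= 9.
    """
    x, y = _clean(x), _clean(y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    rx, ry = _rank(x), _rank(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if n <= 9:
        perms = np.array(list(permutations(ry)))
        rxc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        num = pc @ rxc
        den = math.sqrt(float(rxc @ rxc)) * np.sqrt(np.sum(pc * pc, axis=1))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return math.copysign(1.0, rho), 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return rho, float(2.0 * stats.t.sf(abs(t), n - 2))


def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ddCt against a reference gene and control arm."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def group_auc_summary(estimates, group_order=None) -> list[GroupSummary]:
    """Per-group mean/variance/95% t-CI of individual interval AUCs.

    ``estimates`` is an iterable of IndividualEstimate (or any objects with
    ``group`` and ``auc_tau``).  Groups with a single subject get a NaN
    variance and a degenerate CI at the value.
    """
    by_group: dict[str, list[float]] = {}
    for e in estimates:
        by_group.setdefault(e.group, []).append(float(e.auc_tau))
    if not by_group:
        raise ValueError("no estimates supplied")
    order = list(group_order) if group_order is not None else list(by_group)
    out = []
    for g in order:
        if g not in by_group:
            continue
        vals = np.asarray(by_group[g])
        n = vals.size
        mean = float(vals.mean())
        if n == 1:
            out.append(GroupSummary(g, 1, mean, float("nan"), (mean, mean)))
            continue
        var = float(vals.var(ddof=1))
        half = stats.t.ppf(0.975, n - 1) * math.sqrt(var / n)
        out.append(GroupSummary(g, n, mean, var, (mean - half, mean + half)))
    return out
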
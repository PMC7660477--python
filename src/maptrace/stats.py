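"""Statistical tests and multiple-comparison corrections shared by all stages.

Every test returns a :class:`TestResult` that serialises to JSON with the
sample sizes and options that produced it, so downstream reports carry full
provenance.  Standard distributions and classical tests are delegated to
``scipy.stats``; Dunn's post hoc and the two-way mixed (split-plot) ANOVA are
implemented here because no dependency exposes them in the required form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    test : str
        Name of the test performed.
    statistic : float
        Test statistic (chi-square, U, H, t, F ...).
    df : float | tuple | None
        Degrees of freedom where the reference distribution has any.
    p_value : float
        Two-sided p-value.
    n : dict
        Per-group sample sizes.
    effect : dict
        Group-level summaries (means / medians) for reporting.
    correction : str | None
        Multiple-comparison correction applied, if any.
    extra : dict
        Test-specific extras (post-hoc tables, normality gates ...).
    """

    test: str
    statistic: float
    df: object
    p_value: float
    n: dict = field(default_factory=dict)
    effect: dict = field(default_factory=dict)
    correction: str | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "test": self.test,
            "statistic": _clean(self.statistic),
            "df": _clean(self.df),
            "p_value": _clean(self.p_value),
            "n": _clean(self.n),
            "effect": _clean(self.effect),
            "correction": self.correction,
            **({"extra": _clean(self.extra)} if self.extra else {}),
        }


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction is applied (the trafficking use case has four
    movement classes and hundreds of lysosomes per genotype).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an r x c table with r >= 2 and c >= 2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        test="chi_square_independence",
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        n={"grand_total": int(table.sum())},
    )


def chi_square_p(statistic: float, df: int) -> float:
    """Upper-tail p for a given chi-square statistic and df."""
    return float(sps.chi2.sf(statistic, df))


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "asymptotic", "auto"] = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test from midranks.

    ``auto`` uses exact enumeration when the pooled sample has at most 12
    observations and no ties, otherwise the normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= 12 and not ties) else "asymptotic"
    else:
        method = mode
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        test="mann_whitney",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        n={"x": int(x.size), "y": int(y.size)},
        effect={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
        extra={"method": method},
    )


def kruskal_dunn(
    groups: Sequence[Sequence[float]],
    correction: Literal["bonferroni", "sidak"] = "bonferroni",
) -> TestResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise z contrasts.

    Dunn's test compares mean ranks in the pooled ranking, with the standard
    tie correction in the variance, and applies a Bonferroni-family
    adjustment across the ``k(k-1)/2`` pairs.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use mann_whitney for two groups")
    h, p = sps.kruskal(*groups)
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    # tie correction term for the Dunn variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    idx = np.cumsum([0] + [g.size for g in groups])
    mean_ranks = [ranks[idx[i] : idx[i + 1]].mean() for i in range(len(groups))]
    m = len(groups) * (len(groups) - 1) // 2
    pairwise = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        ni, nj = groups[i].size, groups[j].size
        se = math.sqrt(
            (n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1)))
            * (1.0 / ni + 1.0 / nj)
        )
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = p_adjust([p_raw], correction, m=m)[0]
        pairwise.append(
            {"groups": (i, j), "z": float(z), "p_raw": float(p_raw), "p_adj": float(p_adj)}
        )
    return TestResult(
        test="kruskal_wallis",
        statistic=float(h),
        df=len(groups) - 1,
        p_value=float(p),
        n={str(i): int(g.size) for i, g in enumerate(groups)},
        effect={"mean_ranks": [float(r) for r in mean_ranks]},
        correction=correction,
        extra={"dunn": pairwise},
    )


def p_adjust(
    p: Sequence[float],
    method: Literal["bonferroni", "sidak", "bh"],
    m: int | None = None,
) -> np.ndarray:
    """Adjust p-values for multiple comparisons.

    ``m`` overrides the number of comparisons (defaults to ``len(p)``); it is
    used when a single contrast out of a known family is adjusted.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "bh":
        from .proteomics import bh_adjust  # canonical step-up lives with the cascade

        return bh_adjust(p)
    raise ValueError(f"unknown correction method: {method!r}")


def welch_or_student_t(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    equal_var: bool = False,
    normality_gate: bool = False,
) -> TestResult:
    """Two-sided t test (Welch by default, Student with ``equal_var``).

    A Shapiro-Wilk normality check on the (paired differences or pooled
    centred) residuals is reported alongside; it only switches to
    Mann-Whitney when ``normality_gate`` is set and the gate rejects.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size or x.size < 2:
            raise ValueError("paired test needs >= 2 pairs of equal length")
        resid = x - y
    else:
        if x.size < 2 or y.size < 2:
            raise ValueError("need >= 2 observations per group")
        resid = np.concatenate([x - x.mean(), y - y.mean()])
    shapiro_p = float(sps.shapiro(resid).pvalue) if np.ptp(resid) > 0 else 1.0
    normal = shapiro_p > 0.05
    if normality_gate and not normal:
        res = mann_whitney(x, y)
        res.extra["shapiro_p"] = shapiro_p
        res.extra["gate"] = "non-normal -> Mann-Whitney"
        return res
    if paired:
        if np.ptp(resid) == 0:  # all differences equal
            t, p, df = 0.0 if resid[0] == 0 else math.inf, 1.0 if resid[0] == 0 else 0.0, x.size - 1
        else:
            r = sps.ttest_rel(x, y)
            t, p, df = float(r.statistic), float(r.pvalue), x.size - 1
        name = "paired_t"
    else:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            same = x[0] == y[0]
            t, p = (0.0, 1.0) if same else (math.inf, 0.0)
            df = x.size + y.size - 2
        else:
            r = sps.ttest_ind(x, y, equal_var=equal_var)
            t, p, df = float(r.statistic), float(r.pvalue), float(r.df)
        name = "student_t" if equal_var else "welch_t"
    return TestResult(
        test=name,
        statistic=float(t),
        df=df,
        p_value=float(p),
        n={"x": int(x.size), "y": int(y.size)},
        effect={"mean_x": float(x.mean()), "mean_y": float(y.mean())},
        extra={"shapiro_p": shapiro_p, "normal": bool(normal)},
    )


def mixed_anova(
    data,
    dv: str,
    between: str,
    within: str,
    subject: str,
) -> dict[str, TestResult]:
    """Two-way mixed (split-plot) ANOVA from sums of squares.

    One between-subject factor (group) and one within-subject factor
    (region), subjects nested in groups and crossed with regions, exactly
    one observation per subject x region cell.  The between effect is tested
    against subjects-within-groups, the within and interaction effects
    against the region x subject residual.  No sphericity correction is
    applied by default.
    """
    import pandas as pd

    df = pd.DataFrame(data)[[dv, between, within, subject]].copy()
    cell = df.groupby([subject, within], observed=True)[dv].count()
    n_regions_all = df[within].nunique()
    per_subj = cell.groupby(level=0).size()
    if (cell != 1).any() or (per_subj != n_regions_all).any():
        raise ValueError("each subject must have exactly one value per region")
    subj_group = df.groupby(subject, observed=True)[between].nunique()
    if (subj_group != 1).any():
        raise ValueError("each subject must belong to exactly one group")
    per_group = df.groupby(between, observed=True)[subject].nunique()
    if (per_group < 2).any():
        raise ValueError("need >= 2 subjects per group")

    grand = df[dv].mean()
    n_region = df[within].nunique()
    n_subj = df[subject].nunique()
    n_group = df[between].nunique()

    subj_means = df.groupby(subject, observed=True)[dv].mean()
    group_of = df.groupby(subject, observed=True)[between].first()
    group_means = df.groupby(between, observed=True)[dv].mean()
    region_means = df.groupby(within, observed=True)[dv].mean()
    cell_means = df.groupby([between, within], observed=True)[dv].mean()

    ss_between = n_region * float(
        sum(per_group[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
    )
    ss_subj_within = n_region * float(
        ((subj_means - group_of.map(group_means.to_dict())) ** 2).sum()
    )
    ss_region = n_subj * float(((region_means - grand) ** 2).sum())
    ss_cells = float(
        sum(
            per_group[g] * (cell_means[(g, r)] - grand) ** 2
            for g in group_means.index
            for r in region_means.index
        )
    )
    ss_inter = ss_cells - ss_between - ss_region
    ss_total = float(((df[dv] - grand) ** 2).sum())
    ss_err = ss_total - ss_cells - ss_subj_within

    df_between = n_group - 1
    df_subj = n_subj - n_group
    df_region = n_region - 1
    df_inter = df_between * df_region
    df_err = df_subj * df_region

    def _f(ss, dfn, ss_e, dfe, name):
        ms, mse = ss / dfn, ss_e / dfe
        f = ms / mse if mse > 0 else (0.0 if ss <= 1e-12 else math.inf)
        p = float(sps.f.sf(f, dfn, dfe)) if math.isfinite(f) else 0.0
        return TestResult(
            test=f"mixed_anova_{name}",
            statistic=float(f),
            df=(dfn, dfe),
            p_value=p,
            n={"subjects": int(n_subj), "regions": int(n_region), "groups": int(n_group)},
            extra={"ss": float(ss), "ms": float(ms)},
        )

    return {
        "group": _f(ss_between, df_between, ss_subj_within, df_subj, "group"),
        "region": _f(ss_region, df_region, ss_err, df_err, "region"),
        "interaction": _f(ss_inter, df_inter, ss_err, df_err, "interaction"),
    }
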
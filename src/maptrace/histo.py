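"""Binned laminar cell-distribution quantitation.

Cell positions (or pre-counted cells) are tallied over an ordered region
scheme — ten equally spaced cortical depth bins (bin 1 deepest, at the
ventricular side), hippocampal layers, cerebellar layers, or
electroporation zones — and group differences are tested with a two-way
mixed ANOVA (group x region, animal repeated over regions) on per-animal
region proportions, with Sidak or Tukey per-region post-hoc contrasts and a
normality-gated total-count comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core


@dataclass(frozen=True)
class RegionScheme:
    """An ordered, uniquely labelled set of spatial regions."""

    name: str
    regions: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.regions)) != len(self.regions) or not self.regions:
            raise ValueError("region labels must be unique and non-empty")


def cortex10() -> RegionScheme:
    """Ten equally spaced cortical depth bins, bin 1 deepest."""
    return RegionScheme("cortex10", tuple(f"bin{i}" for i in range(1, 11)))


def hippocampus() -> RegionScheme:
    return RegionScheme("hippocampus", ("OL", "PCL", "RL", "LM", "MDG", "DG", "H"))


def cerebellum() -> RegionScheme:
    return RegionScheme("cerebellum", ("IGL", "PCL", "ML", "EGL"))


def electroporation_zones() -> RegionScheme:
    return RegionScheme(
        "electroporation", ("VZ", "SVZ", "iIZ", "mIZ", "oIZ", "iCP", "mCP", "oCP")
    )


SCHEMES = {
    s().name: s() for s in (cortex10, hippocampus, cerebellum, electroporation_zones)
}


def bin_positions(
    positions: Sequence[float], n_bins: int = 10
) -> np.ndarray:
    """Tally normalised depth fractions into equally spaced bins.

    Bin ``i`` (1-based, deep to superficial) receives positions in
    ``[(i-1)/n, i/n)``; a position exactly at 1.0 falls in the last bin.
    """
    pos = np.asarray(positions, dtype=float)
    if ((pos < 0) | (pos > 1)).any():
        raise ValueError("positions must lie in [0, 1)")
    idx = np.minimum((pos * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def _pivot(table: pd.DataFrame, scheme: RegionScheme) -> pd.DataFrame:
    """Wide animal x region count matrix, validating completeness."""
    missing = set(scheme.regions) - set(table["region"])
    if missing:
        raise ValueError(f"regions missing from table: {sorted(missing)}")
    wide = table.pivot_table(
        index=["animal_id", "group"], columns="region", values="count", aggfunc="sum"
    )
    wide = wide.reindex(columns=list(scheme.regions))
    if wide.isna().any().any():
        raise ValueError("every animal needs a count for every region")
    if (wide < 0).any().any():
        raise ValueError("counts must be non-negative")
    return wide


def relative_distribution(
    table: pd.DataFrame, scheme: RegionScheme | None = None
) -> dict:
    """Per-animal region proportions with group mean +/- sem per region."""
    scheme = scheme or RegionScheme("adhoc", tuple(pd.unique(table["region"])))
    wide = _pivot(table, scheme)
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        bad = [a for (a, _), t in totals.items() if t == 0]
        raise ValueError(f"animal(s) with zero total count: {bad}")
    props = wide.div(totals, axis=0)
    groups = props.index.get_level_values("group")
    summary = {
        g: {
            "mean": props[groups == g].mean(axis=0).to_dict(),
            "sem": props[groups == g].sem(axis=0, ddof=1).to_dict(),
            "n_animals": int((groups == g).sum()),
        }
        for g in sorted(set(groups))
    }
    return {"proportions": props, "totals": totals, "group_summary": summary, "scheme": scheme}


def compare_distributions(
    table: pd.DataFrame,
    scheme: RegionScheme | None = None,
    posthoc: Literal["sidak", "tukey"] = "sidak",
    on: Literal["proportions", "counts"] = "proportions",
) -> dict:
    """Group-by-region comparison of laminar distributions.

    Runs the two-way mixed ANOVA on per-animal proportions (or raw counts),
    per-region group contrasts corrected across regions (Sidak) or across
    group pairs within regions (Tukey for > 2 groups), and a total-count
    comparison by t test or Mann-Whitney according to a Shapiro-Wilk gate.
    """
    rel = relative_distribution(table, scheme)
    scheme = rel["scheme"]
    props: pd.DataFrame = rel["proportions"]
    if on == "counts":
        props = _pivot(table, scheme).astype(float)
    long = props.stack().rename("value").reset_index()
    anova = stats_core.mixed_anova(
        long, dv="value", between="group", within="region", subject="animal_id"
    )
    groups = sorted(set(long["group"]))
    per_region = {}
    n_regions = len(scheme.regions)
    for region in scheme.regions:
        sub = long[long["region"] == region]
        vals = {g: sub[sub["group"] == g]["value"].to_numpy() for g in groups}
        if len(groups) == 2:
            a, b = (vals[g] for g in groups)
            t = sps.ttest_ind(a, b, equal_var=True)
            p_raw = float(t.pvalue) if np.isfinite(t.pvalue) else 1.0
            p_adj = float(
                stats_core.p_adjust([p_raw], "sidak" if posthoc == "sidak" else "bonferroni", m=n_regions)[0]
            )
            per_region[region] = {
                "t": float(t.statistic) if np.isfinite(t.statistic) else 0.0,
                "p_raw": p_raw,
                "p_adj": p_adj,
                "means": {g: float(vals[g].mean()) for g in groups},
            }
        else:
            res = sps.tukey_hsd(*(vals[g] for g in groups))
            per_region[region] = {
                "tukey_p": {
                    f"{groups[i]}|{groups[j]}": float(res.pvalue[i, j])
                    for i in range(len(groups))
                    for j in range(i + 1, len(groups))
                },
                "means": {g: float(vals[g].mean()) for g in groups},
            }
    totals = rel["totals"]
    tot_by_group = {
        g: totals[totals.index.get_level_values("group") == g].to_numpy(dtype=float)
        for g in groups
    }
    if len(groups) == 2:
        a, b = (tot_by_group[g] for g in groups)
        total_cmp = stats_core.welch_or_student_t(a, b, normality_gate=True).to_dict()
    else:
        total_cmp = stats_core.kruskal_dunn([tot_by_group[g] for g in groups]).to_dict()
    return {
        "scheme": scheme.name,
        "on": on,
        "anova": {k: v.to_dict() for k, v in anova.items()},
        "per_region": per_region,
        "posthoc": posthoc,
        "total_counts": total_cmp,
        "group_summary": rel["group_summary"],
    }
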
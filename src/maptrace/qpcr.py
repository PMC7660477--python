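"""Efficiency-corrected relative qPCR quantification.

Technical replicate Ct values are averaged per well; the reference value for
a sample is the geometric mean of its reference-gene Ct values (taken on the
cycle numbers themselves, the literal reading of the protocol; a
quantity-space variant is available); the relative level of a target is
``E_target ** (-dCt)`` with ``dCt = mean target Ct - reference value`` and
``E`` the per-gene amplification factor in (1, 2].

Note an intrinsic property of the cycle-space geometric mean: adding a
constant to every Ct does *not* cancel exactly unless the target efficiency
matches the implied reference efficiency, because the reference is averaged
in cycle space while the correction is exponential in E.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats as stats_core


def _replicate_means(ct: pd.DataFrame) -> pd.DataFrame:
    rep_cols = [c for c in ct.columns if c.startswith("ct_")]
    if not rep_cols:
        raise ValueError("no replicate columns ct_1..ct_k found")
    vals = ct[rep_cols].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite Ct value")
    out = ct[["sample_id", "group", "gene", "role"]].copy()
    out["ct"] = vals.mean(axis=1)
    return out


def check_efficiencies(eff: dict) -> dict:
    for gene, e in eff.items():
        if not (1.0 < float(e) <= 2.0):
            raise ValueError(f"efficiency for {gene!r} must lie in (1, 2], got {e}")
    return {g: float(e) for g, e in eff.items()}


def reference_geomean(
    ct: pd.DataFrame,
    sample: str,
    mode: Literal["cycles", "quantity"] = "cycles",
    efficiencies: dict | None = None,
) -> float:
    """Reference value for one sample from its reference-gene Cts.

    ``cycles`` (default): geometric mean of the replicate-averaged reference
    Ct values.  ``quantity``: geometric-mean in relative-quantity space,
    i.e. ``-log2 of geomean(E_ref ** -Ct)`` mapped back to an equivalent
    cycle number at E = 2.
    """
    means = _replicate_means(ct)
    refs = means[(means["sample_id"] == sample) & (means["role"] == "reference")]
    if refs.empty:
        raise ValueError(f"no reference genes for sample {sample!r}")
    cts = refs["ct"].to_numpy(dtype=float)
    if mode == "cycles":
        return float(np.exp(np.mean(np.log(cts))))
    if mode == "quantity":
        eff = check_efficiencies(efficiencies or {})
        logq = [
            -ct_i * np.log2(eff.get(g, 2.0))
            for g, ct_i in zip(refs["gene"], cts)
        ]
        return float(-np.mean(logq) / np.log2(2.0))
    raise ValueError("mode must be 'cycles' or 'quantity'")


def relative_level(
    ct: pd.DataFrame,
    efficiencies: dict,
    target: str,
    sample: str,
    mode: Literal["cycles", "quantity"] = "cycles",
) -> float:
    """Relative expression ``E_target ** (-dCt)`` for one sample."""
    eff = check_efficiencies(efficiencies)
    if target not in eff:
        raise ValueError(f"no efficiency for target {target!r}")
    means = _replicate_means(ct)
    row = means[(means["sample_id"] == sample) & (means["gene"] == target)]
    if row.empty:
        raise ValueError(f"target {target!r} not measured for sample {sample!r}")
    ref = reference_geomean(ct, sample, mode=mode, efficiencies=eff)
    dct = float(row["ct"].iloc[0]) - ref
    return float(eff[target] ** (-dct))


def quantify(
    ct: pd.DataFrame,
    efficiencies: dict,
    mode: Literal["cycles", "quantity"] = "cycles",
    pfaffl: bool = False,
) -> dict:
    """Per-sample relative levels for every target plus group comparisons.

    Group fold change is the ratio of mutant to control mean relative
    levels; group difference tested with a normality-gated t test.  With
    ``pfaffl`` the per-sample levels are additionally re-expressed relative
    to the control-group mean (a calibrator-ratio formulation); fold changes
    are identical, only the scale of reported levels differs.
    """
    eff = check_efficiencies(efficiencies)
    means = _replicate_means(ct)
    targets = sorted(means.loc[means["role"] == "target", "gene"].unique())
    samples = means[["sample_id", "group"]].drop_duplicates()
    levels = []
    for _, srow in samples.iterrows():
        for target in targets:
            levels.append(
                {
                    "sample_id": srow["sample_id"],
                    "group": srow["group"],
                    "gene": target,
                    "relative_level": relative_level(
                        ct, eff, target, srow["sample_id"], mode=mode
                    ),
                }
            )
    lv = pd.DataFrame(levels)
    groups = sorted(lv["group"].unique())
    report = {}
    for target in targets:
        sub = lv[lv["gene"] == target]
        vals = {g: sub[sub["group"] == g]["relative_level"].to_numpy() for g in groups}
        entry: dict = {
            "group_means": {g: float(v.mean()) for g, v in vals.items()},
            "n": {g: int(v.size) for g, v in vals.items()},
        }
        if len(groups) == 2 and all(v.size >= 2 for v in vals.values()):
            a, b = (vals[g] for g in groups)
            entry["fold_change"] = float(b.mean() / a.mean())  # second group / first
            entry["comparison"] = stats_core.welch_or_student_t(
                b, a, normality_gate=True
            ).to_dict()
        report[target] = entry
    if pfaffl and len(groups) == 2:
        cal = lv[lv["group"] == groups[0]].groupby("gene")["relative_level"].mean()
        lv["relative_level"] = lv.apply(
            lambda r: r["relative_level"] / cal[r["gene"]], axis=1
        )
    return {"levels": lv, "by_target": report, "mode": mode, "pfaffl": pfaffl}
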
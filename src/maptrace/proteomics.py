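"""Paired TMT co-sedimentation differential proteomics.

The pipeline mirrors a microtubule pull-down quantified on a single TMT
10-plex with littermate pairs split across conditions: filter to proteins
with >= 2 unique peptides, equalise channel medians, form per-pair
log2(mutant/control) reporter ratios, test each protein with an
empirical-Bayes moderated one-sample t on its pair ratios, adjust by
Benjamini-Hochberg, and intersect the FDR tier with a catalog of known
direct microtubule binders.

The moderated test shrinks each protein's sample variance toward a prior
estimated from the whole ensemble: with per-protein sample variance ``s^2``
on ``d = n_pairs - 1`` degrees of freedom, the posterior variance is

    s_tilde^2 = (d0 * s0^2 + d * s^2) / (d0 + d)

and ``t = mean / sqrt(s_tilde^2 / n)`` is referred to a t distribution with
``d0 + d`` degrees of freedom.  The prior parameters ``(d0, s0^2)`` are
estimated by moment matching on ``log s^2``, whose distribution under the
hierarchical model is a shifted log-F; the trigamma equation for ``d0`` is
solved by Newton iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

DEFAULT_MAP_CATALOG = frozenset(
    {"VAPA", "VAPB", "REEP1", "EZR", "PRNP", "KIF5C", "DYNC1I1"}
)
# aliases accepted when matching gene symbols against the catalog
SYMBOL_ALIASES = {"EZRIN": "EZR", "DYNC1L1": "DYNC1I1", "DYNC1I2": "DYNC1I1"}


def canonical_symbol(symbol: str) -> str:
    s = str(symbol).upper()
    return SYMBOL_ALIASES.get(s, s)


@dataclass
class QuantTable:
    """Protein x TMT-channel reporter matrix with paired design metadata.

    ``proteins``: DataFrame with columns accession, gene_symbol,
    unique_peptides (index aligned with ``intensities``).
    ``intensities``: DataFrame, rows = proteins, columns = channel ids,
    values = reporter signal/noise (>= 0).
    ``design``: DataFrame with columns channel, pair, condition
    (condition in {control, mutant}; each pair has exactly one of each).
    """

    proteins: pd.DataFrame
    intensities: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.proteins["accession"].duplicated().any():
            dupes = self.proteins["accession"][self.proteins["accession"].duplicated()]
            raise ValueError(f"duplicate accessions: {sorted(set(dupes))}")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("negative reporter intensity")
        if set(self.design["channel"]) != set(self.intensities.columns):
            raise ValueError("design channels do not match intensity columns")
        for pair, sub in self.design.groupby("pair"):
            conds = sorted(sub["condition"])
            if conds != ["control", "mutant"]:
                raise ValueError(
                    f"pair {pair!r} must have exactly one control and one mutant channel"
                )

    @property
    def n_pairs(self) -> int:
        return self.design["pair"].nunique()

    def channels_for(self, condition: str) -> list:
        """Channel ids for one condition, ordered by pair id."""
        sub = self.design[self.design["condition"] == condition]
        return list(sub.sort_values("pair")["channel"])


def read_quant_table(quant_file, design_file) -> QuantTable:
    """Read a quant TSV (accession, gene_symbol, unique_peptides, channels)
    and a design TSV (channel, pair, condition)."""
    sep_q = "\t" if str(quant_file).endswith((".tsv", ".txt")) else ","
    quant = pd.read_csv(quant_file, sep=sep_q)
    design = pd.read_csv(design_file, sep="\t" if str(design_file).endswith((".tsv", ".txt")) else ",")
    design["channel"] = design["channel"].astype(str)
    meta_cols = ["accession", "gene_symbol", "unique_peptides"]
    missing = [c for c in meta_cols if c not in quant.columns]
    if missing:
        raise ValueError(f"quant table missing columns: {missing}")
    quant.columns = [str(c) for c in quant.columns]
    channels = [c for c in quant.columns if c not in meta_cols]
    missing_ch = set(design["channel"]) - set(channels)
    if missing_ch:
        raise ValueError(f"channels in design but not in quant table: {sorted(missing_ch)}")
    return QuantTable(
        proteins=quant[meta_cols].reset_index(drop=True),
        intensities=quant[list(design["channel"])].reset_index(drop=True).astype(float),
        design=design,
    )


def write_quant_table(table: QuantTable, quant_file, design_file) -> None:
    out = pd.concat([table.proteins, table.intensities], axis=1)
    out.to_csv(quant_file, sep="\t", index=False)
    table.design.to_csv(design_file, sep="\t", index=False)


def filter_min_unique_peptides(table: QuantTable, k: int = 2) -> QuantTable:
    """Retain proteins with at least ``k`` unique peptides, order preserved."""
    if k < 1:
        raise ValueError("k must be >= 1")
    keep = table.proteins["unique_peptides"] >= k
    return QuantTable(
        proteins=table.proteins[keep].reset_index(drop=True),
        intensities=table.intensities[keep].reset_index(drop=True),
        design=table.design,
    )


def normalize_channels(table: QuantTable, zero_impute: bool = True) -> QuantTable:
    """Rescale each channel multiplicatively so all channel medians equal the
    grand median (the computational analogue of mixing labelled material to a
    1:1:...:1 median ratio).  Zeros are imputed to half the smallest positive
    value in their channel before scaling (configurable)."""
    values = table.intensities.to_numpy(dtype=float).copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        if (col <= 0).all():
            raise ValueError(f"channel {table.intensities.columns[j]!r} is all zero")
        if zero_impute and (col == 0).any():
            col[col == 0] = col[col > 0].min() * 0.5
            values[:, j] = col
    medians = np.median(values, axis=0)
    grand = float(np.median(values))
    values = values * (grand / medians)
    return QuantTable(
        proteins=table.proteins,
        intensities=pd.DataFrame(values, columns=table.intensities.columns),
        design=table.design,
    )


def paired_log_ratios(table: QuantTable) -> pd.DataFrame:
    """Per-protein log2(mutant/control) for each littermate pair.

    Rows indexed by accession, one column per pair id.  Zero intensities
    should have been imputed by :func:`normalize_channels` upstream; any
    remaining zeros are imputed the same way here.
    """
    table = QuantTable(  # impute any stray zeros without renormalising
        proteins=table.proteins,
        intensities=table.intensities.apply(
            lambda col: col.mask(col == 0, col[col > 0].min() * 0.5 if (col > 0).any() else np.nan)
        ),
        design=table.design,
    )
    pairs = sorted(table.design["pair"].unique())
    out = {}
    dsg = table.design.set_index(["pair", "condition"])["channel"]
    for pair in pairs:
        mut = table.intensities[dsg.loc[(pair, "mutant")]]
        ctl = table.intensities[dsg.loc[(pair, "control")]]
        out[pair] = np.log2(mut.to_numpy() / ctl.to_numpy())
    ratios = pd.DataFrame(out, index=table.proteins["accession"].to_numpy())
    ratios.index.name = "accession"
    return ratios


@dataclass
class ModeratedTestParams:
    """Empirical-Bayes prior for the moderated t: prior degrees of freedom
    ``d0``, prior variance ``s0^2`` and the per-protein posterior variances."""

    prior_df: float
    prior_var: float
    posterior_var: np.ndarray = field(repr=False, default=None)


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 80) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(sample_vars: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from the ensemble of sample variances.

    Under the hierarchical model ``log(s^2)`` is distributed as
    ``log s0^2 + log F(df, d0)``; its mean and variance involve digamma /
    trigamma terms, which are inverted here.  A non-positive excess variance
    yields ``d0 = inf`` (no ensemble over-dispersion; full shrinkage).
    """
    s2 = np.asarray(sample_vars, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValueError("ensemble variance is degenerate; use an ordinary t test")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    e_mean = float(e.mean())
    excess = float(np.mean((e - e_mean) ** 2) * positive.size / (positive.size - 1)) - float(
        special.polygamma(1, df / 2.0)
    )
    if excess <= 0:
        # no over-dispersion beyond the chi-square sampling spread: the prior
        # is a point mass and its scale is the plain average sample variance
        d0 = math.inf
        s0 = float(positive.mean())
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0 = math.exp(e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    return d0, s0


def moderated_paired_test(
    ratios: pd.DataFrame, prior_df: float | None = None
) -> tuple[pd.DataFrame, ModeratedTestParams]:
    """Empirical-Bayes moderated one-sample t on per-pair log ratios.

    Returns a DataFrame (mean_log2fc, t, df_total, p_value) indexed like
    ``ratios`` plus the fitted prior.  ``prior_df`` forces ``d0`` (0
    reproduces the ordinary paired t exactly).
    """
    arr = ratios.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 2:
        raise ValueError("need >= 2 pairs for a paired test")
    if arr.shape[0] < 10:
        raise ValueError("need >= 10 proteins to estimate the variance prior")
    mean = arr.mean(axis=1)
    s2 = arr.var(axis=1, ddof=1)
    d = n - 1
    if np.ptp(arr) == 0:
        raise ValueError(
            "all ratios identical across the table (zero ensemble variance); "
            "fall back to an ordinary t test"
        )
    if prior_df is None:
        d0, s0 = estimate_variance_prior(s2, d)
    else:
        d0 = float(prior_df)
        _, s0 = estimate_variance_prior(s2, d) if d0 > 0 else (None, float(np.median(s2)))
    pooled_df = arr.shape[0] * d  # cap: no more information than the ensemble holds
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = pooled_df
    else:
        s2_post = (d0 * s0 + d * s2) / (d0 + d)
        df_total = min(d0 + d, pooled_df)
    with np.errstate(divide="ignore"):
        t = mean / np.sqrt(s2_post / n)
    p = 2.0 * sps.t.sf(np.abs(t), df_total)
    res = pd.DataFrame(
        {"mean_log2fc": mean, "t": t, "df_total": df_total, "p_value": p},
        index=ratios.index,
    )
    return res, ModeratedTestParams(prior_df=d0, prior_var=s0, posterior_var=s2_post)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped
    at 1; monotone non-decreasing in rank.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_abundance(
    table: QuantTable,
    alpha: float = 0.01,
    fdr: float = 0.05,
    normalize: bool = True,
    fdr_within_alpha_subset: bool = False,
) -> pd.DataFrame:
    """Full per-protein differential result on a validated quant table.

    BH adjustment is applied to all tested proteins by default;
    ``fdr_within_alpha_subset`` restricts the adjustment to the ``p < alpha``
    tier (an alternative reading of a two-stage filter).
    """
    work = normalize_channels(table) if normalize else table
    ratios = paired_log_ratios(work)
    res, _ = moderated_paired_test(ratios)
    q = np.full(len(res), np.nan)
    if fdr_within_alpha_subset:
        mask = res["p_value"].to_numpy() < alpha
        q[mask] = bh_adjust(res["p_value"].to_numpy()[mask])
        q[~mask] = 1.0
    else:
        q = bh_adjust(res["p_value"].to_numpy())
    out = res.copy()
    out["q_value"] = q
    out["sig_p01"] = out["p_value"] < alpha
    out["sig_fdr05"] = out["q_value"] <= fdr
    out.insert(0, "gene_symbol", table.proteins.set_index("accession")["gene_symbol"].reindex(out.index).to_numpy())
    return out


def candidate_cascade(
    diff: pd.DataFrame, catalog: Sequence[str] | frozenset = DEFAULT_MAP_CATALOG
) -> dict:
    """Filter pyramid: quantified -> p < 0.01 -> FDR 5% -> known MAPs.

    Returns per-tier counts and the member symbols of the catalog
    intersection (matched case-insensitively with common aliases).
    """
    catalog = {canonical_symbol(s) for s in catalog}
    if not catalog:
        raise ValueError("MAP catalog is empty")
    tier_p = diff[diff["sig_p01"]]
    tier_q = diff[diff["sig_fdr05"]]
    symbols = {canonical_symbol(s) for s in tier_q["gene_symbol"].dropna()}
    hits = sorted(symbols & catalog)
    return {
        "n_quantified": int(len(diff)),
        "n_p_significant": int(len(tier_p)),
        "n_fdr_significant": int(len(tier_q)),
        "n_map_hits": len(hits),
        "map_hits": hits,
    }


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> members..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            members = {canonical_symbol(s) for s in parts[2:] if s}
            if not members:
                raise ValueError(f"empty gene set {parts[0]!r}")
            sets[parts[0]] = members
    if not sets:
        raise ValueError("no gene sets found")
    return sets


def enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Per-set upper-tail hypergeometric enrichment with BH adjustment.

    ``p = P(X >= k)`` for overlap ``k`` drawing ``|foreground|`` genes from a
    universe of ``|background|`` containing ``|set ∩ background|`` members.
    """
    fg = {canonical_symbol(s) for s in foreground}
    bg = {canonical_symbol(s) for s in background}
    stray = fg - bg
    if stray:
        raise ValueError(f"foreground genes missing from background: {sorted(stray)}")
    rows = []
    for name, members in sets.items():
        members_bg = {canonical_symbol(s) for s in members} & bg
        k = len(fg & members_bg)
        p = float(sps.hypergeom.sf(k - 1, len(bg), len(members_bg), len(fg)))
        rows.append({"set": name, "set_size": len(members_bg), "overlap": k, "p_value": p})
    out = pd.DataFrame(rows)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def volcano_table(diff: pd.DataFrame) -> pd.DataFrame:
    """Export (log2fc, -log10 p, tier flags), one row per protein."""
    out = pd.DataFrame(
        {
            "accession": diff.index,
            "gene_symbol": diff["gene_symbol"].to_numpy(),
            "log2fc": diff["mean_log2fc"].to_numpy(),
            "neg_log10_p": -np.log10(np.clip(diff["p_value"].to_numpy(), 1e-300, 1.0)),
            "sig_p01": diff["sig_p01"].to_numpy(),
            "sig_fdr05": diff["sig_fdr05"].to_numpy(),
        }
    )
    return out.reset_index(drop=True)
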
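"""Differential-abundance cascade: filters, normalisation, moderated test,
BH adjustment, enrichment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from maptrace import proteomics
from maptrace.proteomics import (
    QuantTable,
    bh_adjust,
    candidate_cascade,
    differential_abundance,
    enrichment,
    filter_min_unique_peptides,
    moderated_paired_test,
    normalize_channels,
    paired_log_ratios,
    read_quant_table,
    volcano_table,
    write_quant_table,
)
from maptrace.synthetic import ProteomeSimConfig, simulate_proteome


def toy_table(values, peptides=None):
    n = len(values)
    design = pd.DataFrame(
        {
            "channel": ["con_1", "mut_1", "con_2", "mut_2"],
            "pair": ["pair1", "pair1", "pair2", "pair2"],
            "condition": ["control", "mutant", "control", "mutant"],
        }
    )
    return QuantTable(
        proteins=pd.DataFrame(
            {
                "accession": [f"P{i}" for i in range(n)],
                "gene_symbol": [f"G{i}" for i in range(n)],
                "unique_peptides": peptides or [2] * n,
            }
        ),
        intensities=pd.DataFrame(values, columns=design["channel"]),
        design=design,
    )


class TestQuantTableIO:
    def test_round_trip_identity(self, tmp_path):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=20, seed=1))
        write_quant_table(table, tmp_path / "q.tsv", tmp_path / "d.tsv")
        back = read_quant_table(tmp_path / "q.tsv", tmp_path / "d.tsv")
        pd.testing.assert_frame_equal(table.proteins, back.proteins)
        np.testing.assert_allclose(table.intensities.to_numpy(),
                                   back.intensities.to_numpy())

    def test_toy_tsv(self, tmp_path):
        (tmp_path / "q.tsv").write_text(
            "accession\tgene_symbol\tunique_peptides\tc1\tc2\n"
            "P1\tVAPA\t3\t10\t12\nP2\tPRNP\t2\t8\t9\nP3\tKIF5C\t5\t7\t7\n"
        )
        (tmp_path / "d.tsv").write_text(
            "channel\tpair\tcondition\nc1\tpair1\tcontrol\nc2\tpair1\tmutant\n"
        )
        table = read_quant_table(tmp_path / "q.tsv", tmp_path / "d.tsv")
        assert len(table.proteins) == 3

    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            table = toy_table([[1, 2, 3, 4]] * 2)
            table.proteins.loc[1, "accession"] = "P0"
            QuantTable(table.proteins, table.intensities, table.design)

    def test_incomplete_pair_rejected(self):
        design = pd.DataFrame(
            {"channel": ["a", "b"], "pair": ["p1", "p2"],
             "condition": ["control", "mutant"]}
        )
        with pytest.raises(ValueError, match="pair"):
            QuantTable(
                proteins=pd.DataFrame({"accession": ["P1"], "gene_symbol": ["G"],
                                       "unique_peptides": [2]}),
                intensities=pd.DataFrame([[1.0, 2.0]], columns=["a", "b"]),
                design=design,
            )

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            toy_table([[1, 2, -3, 4]])


class TestPeptideFilter:
    def test_threshold(self):
        table = toy_table([[1, 1, 1, 1]] * 3, peptides=[1, 2, 3])
        assert len(filter_min_unique_peptides(table, 2).proteins) == 2

    def test_k1_identity(self):
        table = toy_table([[1, 1, 1, 1]] * 3, peptides=[0, 1, 5])
        assert len(filter_min_unique_peptides(table, 1).proteins) == 2

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            filter_min_unique_peptides(toy_table([[1, 1, 1, 1]]), 0)

    def test_retained_fraction_matches_tail_mass(self):
        # unique peptides ~ 1 + Poisson(3): P(count >= 2) = P(Poisson >= 1)
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=20000, seed=2))
        frac = len(filter_min_unique_peptides(table, 2).proteins) / 20000
        expected = 1.0 - np.exp(-3.0)
        assert frac == pytest.approx(expected, abs=0.01)


class TestNormalization:
    def test_equal_median_identity(self):
        table = toy_table([[1, 2, 3, 4], [4, 3, 2, 1], [2, 2, 2, 2]])
        normed = normalize_channels(table)
        np.testing.assert_allclose(normed.intensities.to_numpy(),
                                   table.intensities.to_numpy())

    def test_doubled_channel_recovered_up_to_scale(self, rng):
        base = rng.lognormal(2, 0.5, size=(50, 4))
        doubled = base.copy()
        doubled[:, 1] *= 2.0
        n1 = normalize_channels(toy_table(base)).intensities.to_numpy()
        n2 = normalize_channels(toy_table(doubled)).intensities.to_numpy()
        ratio = n2 / n1
        assert np.allclose(ratio, ratio[0, 0])

    def test_median_spread_vanishes(self, rng):
        values = rng.lognormal(3, 1, size=(200, 4)) * [1.0, 2.5, 0.5, 1.7]
        normed = normalize_channels(toy_table(values))
        med = np.median(normed.intensities.to_numpy(), axis=0)
        assert np.ptp(med) < 1e-9

    def test_all_zero_channel_rejected(self):
        values = np.ones((5, 4))
        values[:, 2] = 0.0
        with pytest.raises(ValueError, match="all zero"):
            normalize_channels(toy_table(values))


class TestPairedRatios:
    def test_equal_channels_zero(self):
        table = toy_table([[5, 5, 7, 7], [2, 2, 3, 3]])
        assert np.allclose(paired_log_ratios(table).to_numpy(), 0.0)

    def test_doubling_gives_unit_ratio(self):
        table = toy_table([[5, 10, 7, 14], [2, 4, 3, 6]])
        assert np.allclose(paired_log_ratios(table).to_numpy(), 1.0)


class TestModeratedTest:
    @staticmethod
    def _ratios(rng, n=200, pairs=4):
        scale = np.exp(rng.normal(0, 0.5, n))
        return pd.DataFrame(rng.normal(0, 0.3, (n, pairs)) * scale[:, None],
                            index=[f"P{i}" for i in range(n)])

    def test_zero_prior_df_is_ordinary_t(self, rng):
        ratios = self._ratios(rng)
        res, params = moderated_paired_test(ratios, prior_df=0.0)
        ref = sps.ttest_1samp(ratios.to_numpy(), 0.0, axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-10)

    def test_shrinkage_bounds(self, rng):
        ratios = self._ratios(rng)
        _, params = moderated_paired_test(ratios)
        s2 = ratios.to_numpy().var(axis=1, ddof=1)
        lo = np.minimum(s2, params.prior_var) - 1e-12
        hi = np.maximum(s2, params.prior_var) + 1e-12
        assert ((params.posterior_var >= lo) & (params.posterior_var <= hi)).all()

    def test_posterior_is_precision_weighted_blend(self, rng):
        ratios = self._ratios(rng)
        _, params = moderated_paired_test(ratios)
        d = ratios.shape[1] - 1
        s2 = ratios.to_numpy().var(axis=1, ddof=1)
        expected = (params.prior_df * params.prior_var + d * s2) / (params.prior_df + d)
        np.testing.assert_allclose(params.posterior_var, expected, rtol=1e-12)

    def test_scale_invariance(self, rng):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=100, seed=3))
        d1 = differential_abundance(table)
        scaled = QuantTable(table.proteins, table.intensities * 37.0, table.design)
        d2 = differential_abundance(scaled)
        np.testing.assert_allclose(d1["t"], d2["t"], rtol=1e-9)
        np.testing.assert_allclose(d1["q_value"], d2["q_value"], rtol=1e-9)

    def test_pair_swap_antisymmetry(self):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=100, seed=4))
        swapped_design = table.design.copy()
        swapped_design["condition"] = swapped_design["condition"].map(
            {"control": "mutant", "mutant": "control"}
        )
        d1 = differential_abundance(table)
        d2 = differential_abundance(QuantTable(table.proteins, table.intensities,
                                               swapped_design))
        np.testing.assert_allclose(d1["mean_log2fc"], -d2["mean_log2fc"], rtol=1e-9)
        np.testing.assert_allclose(d1["p_value"], d2["p_value"], rtol=1e-9)

    def test_degenerate_ensemble_rejected(self):
        ratios = pd.DataFrame(np.zeros((20, 4)))
        with pytest.raises(ValueError, match="ordinary t"):
            moderated_paired_test(ratios)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_reference_empirical_bayes(self, tmp_path, rng):
        # independent oracle: the reference empirical-Bayes implementation
        ratios = self._ratios(rng, n=150)
        ratios.to_csv(tmp_path / "ratios.csv")
        script = tmp_path / "check.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            'r <- read.csv("%s", row.names=1)\n'
            'fit <- eBayes(lmFit(as.matrix(r), design=matrix(1, ncol(r), 1)))\n'
            'write.csv(data.frame(t=fit$t[,1], p=fit$p.value[,1], d0=fit$df.prior,'
            ' s0=fit$s2.prior), "%s")\n'
            % (tmp_path / "ratios.csv", tmp_path / "out.csv")
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0)
        res, params = moderated_paired_test(ratios)
        assert params.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
        assert params.prior_var == pytest.approx(ref["s0"].iloc[0], rel=1e-6)
        np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-6)


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(5):
            p = rng.random(50)
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    def test_monotone_in_rank(self, rng):
        p = rng.random(100)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCascade:
    def test_counts_match_brute_force(self):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=800, seed=5))
        diff = differential_abundance(table)
        cascade = candidate_cascade(diff, {"GENE1", "GENE10", "NOPE"})
        # independent brute-force filtering
        p = diff["p_value"].to_numpy()
        q = diff["q_value"].to_numpy()
        assert cascade["n_quantified"] == 800
        assert cascade["n_p_significant"] == int((p < 0.01).sum())
        assert cascade["n_fdr_significant"] == int((q <= 0.05).sum())
        fdr_genes = {s.upper() for s in diff[q <= 0.05]["gene_symbol"]}
        assert set(cascade["map_hits"]) == fdr_genes & {"GENE1", "GENE10", "NOPE"}

    def test_disjoint_catalog_empty_final_tier(self):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=100, seed=6))
        diff = differential_abundance(table)
        cascade = candidate_cascade(diff, {"NOT_A_GENE"})
        assert cascade["n_map_hits"] == 0

    def test_empty_catalog_rejected(self):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=100, seed=6))
        diff = differential_abundance(table)
        with pytest.raises(ValueError, match="catalog"):
            candidate_cascade(diff, set())

    def test_alias_matching(self):
        assert proteomics.canonical_symbol("Ezrin") == "EZR"
        assert proteomics.canonical_symbol("DYNC1l1") == "DYNC1I1"
        assert proteomics.canonical_symbol("DYNC1I2") == "DYNC1I1"


class TestEnrichment:
    def test_forced_overlap_boundary(self):
        sets = {"s": {"A", "B", "C"}}
        res = enrichment(["A", "B", "C"], ["A", "B", "C"], sets)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_combinatorial_hand_case(self):
        # urn of 20, one set of 5, draw 5, all 5 in the set: p = 1/C(20,5)
        bg = [f"g{i}" for i in range(20)]
        sets = {"s": set(bg[:5])}
        res = enrichment(bg[:5], bg, sets)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 15504, rel=1e-9)

    def test_stray_foreground_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            enrichment(["X"], ["A"], {"s": {"A"}})

    def test_null_p_roughly_uniform(self, rng):
        bg = [f"g{i}" for i in range(500)]
        sets = {f"s{j}": set(rng.choice(bg, 50, replace=False)) for j in range(40)}
        ps = []
        for _ in range(10):
            fg = list(rng.choice(bg, 60, replace=False))
            ps.extend(enrichment(fg, bg, sets)["p_value"])
        # discrete p-values are conservative; check no inflation of small p
        assert np.mean(np.array(ps) < 0.05) < 0.10


class TestVolcano:
    def test_rows_flags_and_log_transform(self):
        table, _ = simulate_proteome(ProteomeSimConfig(n_proteins=60, seed=7))
        diff = differential_abundance(table)
        v = volcano_table(diff)
        assert len(v) == 60
        assert np.allclose(v["neg_log10_p"],
                           -np.log10(diff["p_value"].to_numpy()))
        both = v["sig_fdr05"] & v["sig_p01"]
        assert (both == (diff["sig_p01"] & diff["sig_fdr05"]).to_numpy()).all()
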
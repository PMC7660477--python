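# maptrace

Quantitative analysis pipelines for a mouse study of a tubulin missense
mutation that perturbs dynein-mediated transport and neuronal migration:

- **Kymograph trafficking** — segment lysosome tracks into directional runs,
  classify each lysosome (anterograde / retrograde / bidirectional /
  immobile), compute retrograde speed, run length and total retrograde
  distance, and compare genotypes (chi-square on class proportions,
  Mann-Whitney on run-level and track-level metrics).
- **Paired TMT differential proteomics** — for a microtubule
  co-sedimentation experiment quantified on one TMT 10-plex with littermate
  pairs: unique-peptide filtering, channel-median normalisation, per-pair
  log2(mutant/control) ratios, an empirical-Bayes **moderated paired t
  test**, Benjamini-Hochberg FDR, and a candidate cascade down to known
  microtubule-associated proteins (MAPs).
- **Laminar bin quantitation** — per-animal cell distributions over ordered
  region schemes (ten equal cortical depth bins, hippocampal / cerebellar
  layers, electroporation zones) with a two-way mixed ANOVA
  (group × region, animal repeated over regions) and Sidak/Tukey post hocs.
- **qPCR relative quantification** — reference-gene geometric mean,
  efficiency-corrected relative expression `E_target^(−ΔCt)`.
- **Synthetic data generators** — seeded generators with known ground truth
  for every stage (state-switching lysosome motion, paired reporter tables,
  multinomial bin counts, Ct tables), used by the test-suite and the
  acceptance script.

Intended for cell biologists and neurogenetics labs who want these
analyses as tested, scriptable building blocks rather than spreadsheet or
GUI workflows.

## The statistics at the core

A *run* is a maximal block of ≥ `min_run_frames` consecutive frames moving
in one direction with per-frame steps at or above a movement threshold
(default one pixel); it ends at the first change of state. Tracks traced
≥ 60 s with at least one retrograde run enter the retrograde metrics.

The moderated paired t shrinks each protein's sample variance s² (on
d = n_pairs − 1 df) toward a prior (d₀, s₀²) estimated from all proteins:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d),    t = mean(ratio) / √(s̃²/n),

with p from a t distribution on d₀ + d degrees of freedom; (d₀, s₀²) are
obtained by moment matching on log s² (digamma/trigamma inversion). The
implementation agrees with the reference empirical-Bayes implementation to
machine precision (cross-checked in the tests).

## Worked example

```python
from maptrace import synthetic, trafficking, proteomics

cfg = synthetic.TrackSimConfig(n_tracks_per_group=60, seed=42)
tracks, truth = synthetic.simulate_tracks(cfg)
report = trafficking.compare_trafficking(tracks)

report["chi_square"]          # statistic 3.13, df 3, p 0.3719
report["run_length"]          # n = 403 vs 327 runs, medians 3.11 vs 2.36 um, p 0.0002
report["total_retro_distance"]  # n = 36 vs 34 eligible lysosomes, p 0.0073
```

The class proportions do not differ between genotypes (chi-square p 0.37)
while the retrograde run lengths do (the generator is calibrated to
median retrograde run lengths of 2.52 μm in controls vs 1.91 μm in
mutants), mirroring the dissociation the assay is designed to detect; the
measured medians (3.11/2.36 μm) sit above the episode-level targets because
the ≥ 3-frame rule discards short runs and sub-frame pauses merge adjacent
episodes.

```python
pcfg = synthetic.ProteomeSimConfig(n_proteins=5283, frac_perturbed=0.05,
                                   unique_peptide_dist=(2, 3.0), seed=42)
table, ptruth = synthetic.simulate_proteome(pcfg)
diff = proteomics.differential_abundance(
    proteomics.filter_min_unique_peptides(table, 2))
proteomics.candidate_cascade(diff)
# {'n_quantified': 5283, 'n_p_significant': 278, 'n_fdr_significant': 186,
#  'n_map_hits': 0, 'map_hits': []}
```

The cascade reports each tier of the filter pyramid (all quantified →
p < 0.01 → FDR 5% → known-MAP intersection); simulated gene symbols do not
intersect the built-in MAP catalog, hence the empty final tier.

Every stage is also exposed on the command line:

```sh
maptrace simulate-tracks --n-tracks 60 --seed 42 --out sim/
maptrace kymo analyze --tracks sim/tracks.csv --pixel-um 0.1 --frame-s 0.5 --out kymo/
maptrace proteome diff --quant quant.tsv --design design.tsv --out diff/
maptrace bins compare --counts counts.tsv --scheme cortex10 --out bins/
maptrace qpcr --ct ct.tsv --eff efficiencies.tsv --out qpcr/
```

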
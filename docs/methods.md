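# Methods

## Lysosome motion model and trafficking analysis

Tracks are one-dimensional axial positions (μm from the soma, soma at 0,
retrograde = decreasing) sampled uniformly every `frame_interval_s`
(default 0.5 s) for `duration_s` (default 180 s → 361 samples).

The generator is a continuous-time Markov chain over three states —
anterograde run, retrograde run, pause — with exponential dwell times
(per-state exit rates) and a transition matrix applied on exit. Each run
episode draws a log-normal speed (default log-location ln 0.8 μm/s,
log-scale 0.35 for both directions) and moves the particle at constant
velocity; the trajectory is piecewise linear and sampled on the frame
grid. This is the simplest model producing runs, pauses and reversals of
tunable length. Measurement noise (Gaussian, `position_noise_um`) is added
to the sampled positions only, never to dwell times, so the ground-truth
episode list stays exact. Seeds are explicit; every generator is a pure
function of (config, seed).

Calibration. The retrograde dwell rate per group is set so that the median
episode length L = v·T (v log-normal, T exponential) hits a target median:
P(L ≤ m) = E_v[1 − e^(−λm/v)] is evaluated by Gauss-Hermite quadrature and
solved for m, and λ scales as 1/median. Defaults target 2.52 μm (control)
and 1.91 μm (mutant). The anterograde median (2.2 μm) and pause exit rate
(0.25 s⁻¹) are free parameters — the study this emulates reports no pause
statistics or anterograde summaries. Note a renewal-sampling effect shared
with the real assay: episodes completed inside a finite 3-min window are
length-biased against long dwells, so window-restricted medians fall a few
percent below the episode-distribution target; calibration checks measure
the median on long (30-min) recordings.

Heterogeneity. Real kymographs contain immobile, unidirectional and
bidirectional particles. Per track, the generator draws: immobility
(probability 0.35), a retrograde preference r ~ Beta(0.2, 0.2) used at
pause exits, and a pause-duration scale ~ LogNormal(0, 1.5). These affect
which classes occur and how many runs a track holds, not the calibrated
run-length distribution. Tracks that would dip below position 0 are
translated upward as a whole; every downstream quantity is
translation-invariant.

Run calling. Per-frame steps are classified anterograde (Δ ≥ threshold),
retrograde (Δ ≤ −threshold) or stationary; the threshold defaults to one
pixel (0.1 μm) per frame — sub-pixel movement is within tracing
resolution. A run is a maximal same-sign block spanning ≥ `min_run_frames`
frames (default 3); the frame that breaks the state is not part of the
run. With `min_run_frames = 3` a run's minimum *interval* span is 1.0 s
(two steps); the conventional field phrasing "3 frames = 1.5 s" counts
frames rather than intervals. "Paused" and "immobile" are one class.
Retrograde metrics (unweighted mean of per-run speeds by default — a
duration-weighted switch exists) are computed for tracks traced ≥ 60 s
with ≥ 1 retrograde run; an alternative eligibility mode requires 60 s of
cumulative retrograde time instead (rarely satisfiable in a 180 s
recording, hence not the default). Run-level comparisons pool runs from
eligible tracks by default (`run_pool="all"` uses every track).

Known artifact (by design): pauses shorter than one frame and the
≥ 3-frame rule make *measured* run lengths longer than the generating
episodes (merging and left-truncation), exactly as in kymograph tracing of
real recordings. The measured medians therefore sit ~20% above the episode
targets while preserving the between-group shift.

Statistical note. With run length = v·T (T exponential), the within-group
dispersion bounds the Mann-Whitney separation: for medians 2.52 vs 1.91 μm
the AUC is at most 2.52/(2.52+1.91) ≈ 0.57, which caps two-sided power at
~86% for pools of 343 vs 309 runs. Detection of this shift at those pool
sizes is therefore not guaranteed per replicate; at larger pools
(≳ 600/600) power exceeds 95%. The acceptance script reports the measured
rate.

## Kymograph rendering and tracing

`render_kymograph` rasterises tracks into rows = frames, columns = axial
pixels (column 0 at the soma). Returned per-track pixel paths stand in for
GUI path tracing; `path_to_track` resamples a traced polyline at every
frame row by linear interpolation (rows must strictly increase — a path
cannot revisit a time point) and converts columns to μm honouring the soma
side. Rasterisation rounds to the nearest pixel, so the round trip is
accurate to half a pixel.

## Paired TMT differential abundance

Input is a protein × channel reporter (S/N) matrix with a design mapping
each channel to a littermate pair and condition; each pair has exactly one
control and one mutant channel, all within one 10-plex (≤ 5 pairs;
multi-plex designs are out of scope). Processing:

1. keep proteins with ≥ 2 unique peptides;
2. rescale each channel so all channel medians equal the grand median
   (the computational analogue of mixing labelled material to a 1:1:…:1
   median ratio); zeros are imputed to half the channel's smallest
   positive value (configurable) rather than dropping proteins silently;
3. per-pair log2(mutant/control) ratios;
4. one-sample moderated t on each protein's ratios. With sample variance
   s² on d = n−1 df, the posterior variance is
   s̃² = (d₀s₀² + d·s²)/(d₀ + d) and t = mean/√(s̃²/n) is referred to a t
   distribution on min(d₀ + d, pooled df). The prior is fitted by moment
   matching on log s² (whose model distribution is a shifted log-F):
   the trigamma equation for d₀ is solved by Newton iteration and s₀²
   follows from the digamma relation; if the ensemble shows no
   over-dispersion beyond chi-square sampling noise, d₀ = ∞ and s₀² is the
   mean sample variance. Forcing d₀ = 0 reproduces the ordinary paired t.
   The implementation is cross-checked against the reference
   empirical-Bayes implementation (Bioconductor limma via Rscript) to
   machine precision in the test-suite.
5. Benjamini-Hochberg step-up q-values over all tested proteins (a flag
   restricts the adjustment to the p < α subset, an alternative two-stage
   reading);
6. candidate cascade: all quantified → p < 0.01 → q ≤ 0.05 → intersection
   with a catalog of direct microtubule binders (default VAPA, VAPB,
   REEP1, EZR, PRNP, KIF5C, DYNC1I1; matching is case-insensitive with
   EZRIN→EZR and DYNC1L1/DYNC1I2→DYNC1I1 aliases).

Gene-set enrichment is an upper-tail hypergeometric test per GMT set with
BH adjustment — a transparent replacement for web-service enrichment whose
term lists and correction are database-version dependent.

The proteome generator draws per-protein baselines, a shared within-pair
(litter) abundance term that cancels in ratios, heteroscedastic reporter
noise (per-protein log2 noise scale ~ LogNormal(0, 0.5) × 0.25 — the
heteroscedasticity is what gives the variance prior a finite d₀, as in
real reporter data), and for a `frac_perturbed` minority a signed log2
effect of magnitude ~ N(1.0, 0.25) plus a litter-level wobble
(`pair_effect_sd`). Unique-peptide counts are shift + Poisson.

## Laminar bin quantitation

Positions normalised to [0, 1) are tallied into equal half-open bins
(bin 1 deepest, at the ventricular side; a position exactly 1.0 joins the
last bin). Counts tables (animal, group, region) are converted to
per-animal proportions (default; raw counts by flag) and tested with a
two-way mixed (split-plot) ANOVA computed from sums of squares: the
between-groups effect is tested against subjects-within-groups, region and
group × region against the region × subject residual. No sphericity
correction is applied by default (a Greenhouse-Geisser flag is out of
scope here; the omnibus of interest is the interaction). On proportions
the group main effect is degenerate by construction (every animal's
proportions sum to 1) and reports F = 0. Per-region contrasts are t tests
Sidak-corrected across regions (Tukey across groups when > 2 groups);
total counts are compared by t test or Mann-Whitney according to a
Shapiro-Wilk gate on residuals (the gate's decision is reported).

Built-in region schemes: `cortex10` (bins 1–10 deep→superficial),
`hippocampus` (OL, PCL, RL, LM, MDG, DG, H), `cerebellum`
(IGL, PCL, ML, EGL), `electroporation` (VZ, SVZ, iIZ, mIZ, oIZ, iCP, mCP,
oCP). The generator draws independent multinomials per animal.

## qPCR relative quantification

Technical replicates are averaged per well (no outlier rejection — none is
described for the protocol emulated). The reference value of a sample is
the geometric mean of its reference-gene Ct values taken on the cycle
numbers themselves — the literal reading of the protocol; a quantity-space
variant (geometric mean of E^−Ct, re-expressed as an equivalent cycle
number) is available by flag, since field practice varies. Relative level
= E_target^(−ΔCt) with ΔCt = mean target Ct − reference value and E the
amplification factor in (1, 2] (percent efficiencies convert as
E = 1 + pct/100). Group fold change is the ratio of group means; a Pfaffl
style calibrator flag re-expresses levels relative to the control-group
mean (fold changes are unchanged). One intrinsic property of the
cycle-space geometric mean is documented and tested: adding a constant to
*every* Ct does not cancel exactly unless the reference Cts are equal (or
the target efficiency matches the implied reference efficiency) — this is
a property of the stated method, not a defect.

The Ct generator sets Ct = baseline − log_E(relative quantity) + noise,
with reference genes sharing quantity across groups, default noise 0.1
cycles, triplicates, 5 animals per group.

## Statistical core

Chi-square independence without continuity correction (four movement
classes, hundreds of lysosomes); Mann-Whitney from midranks with exact
enumeration when the pooled sample is ≤ 12 and tie-free, otherwise normal
approximation with tie and continuity correction; Kruskal-Wallis with tie
correction plus Dunn's z contrasts on mean ranks (Bonferroni-family
corrected); Bonferroni / Sidak / BH adjustments; Welch (default) or
Student t, paired t, with a reported Shapiro-Wilk gate. All p-values are
two-sided. Results serialise to JSON with sample sizes and options.

## Problem sizes and determinism

The test-suite and acceptance script regenerate all data from seeds at
desk scale: 5283-protein tables (the study's quantified-protein count),
4 littermate pairs, 20-seed null panels of 5000 proteins for type-I
calibration, 100 tracks per group for power replicates, exhaustive
enumeration for the segmentation (all 3^n step-sign sequences, n ≤ 8) and
Mann-Whitney (all achievable U, n ≤ 8 per group) oracles, and mixed-ANOVA
fixtures up to 4 groups × 4 animals × 4 regions. Identical seeds give
byte-identical outputs.

## What the synthetic data does and does not show

The generators reproduce the *statistical structure* the analyses assume —
state-switching motion with calibrated medians, paired log-normal reporter
noise with a perturbed minority, multinomial bin counts, Ct shifts with
stable references — but not photophysics, point-spread functions,
peptide-level identification, protein grouping, image segmentation or
melt-curve behaviour. Passing tests demonstrate that the estimators and
tests recover known ground truth under the assumed models at the stated
sizes; they do not validate upstream acquisition or identification steps,
and headline biological numbers from any particular real dataset (for
example, which proteins fall in an FDR tier) are functions of the raw data,
not of this code.
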
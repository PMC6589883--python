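# Methods

This note documents the models, conventions and numerical choices behind
`soilmfc`, and what the synthetic-data generators do and do not emulate.

## Experimental system being modelled

A single-chamber soil microbial fuel cell (MFC): 300 g of sieved farmland
soil between a buried carbon-fibre-cloth anode and an activated-carbon air
cathode (projected area A = 0.0036 m²), run for 58 days at 30 °C. Closed
circuits carry an external resistance R = 100 Ω; a data logger records the
voltage U every 1800 s. Treatments are the cross of antibiotic spike
(tetracycline T / sulfadiazine S / none C, 5 mg kg⁻¹) and circuit state
(closed C / open O / non-electrode N), labelled TC, TO, TN, SC, SO, SN, CC,
CO, CN. Soil is sampled near the cathode (layer C), anode (layer A) and
surface (layer S).

## Electrochemistry

All performance figures are normalised to the cathode's projected area:

- current density I′ = U/(R·A), reported in mA m⁻²;
- power density P′ = U²/(R·A) = I′·U, reported in mW m⁻²;
- accumulated charge Q = ∫ U/R dt, in coulombs.

Charge integration uses the left-rectangle rule over the logged intervals
(each sample contributes U·Δt/R), matching a per-cycle accumulator with
T = 1800 s and making Q exactly additive over trace concatenation;
trapezoidal integration is available behind a flag. Start-up time is the
first time the voltage exceeds 1 mV.

Polarization sweeps step the external resistance from 10 000 down to
100 Ω. Each point is converted to cell current I = U/R and the line
U = OCV − R_int·I is fitted by least squares over the ohmic region,
defined as all points except the highest-current 10 % (where activation
and mass-transport losses bend the curve); the fraction is configurable
because no universal convention exists. On data from the generator's
voltage-divider model the curve is globally linear, so the fit recovers
the generating (OCV, R_int) to machine precision regardless of the
exclusion window. The fitted power curve peaks at R ≈ R_int (matched-load
property), which the tests use as a consistency check.

## Antibiotic removal statistics

Removal efficiency is β = (C′ − C)/C′ × 100 with C′ the spiked
concentration and C the residual. A residual above the spike is allowed
(negative β with a warning) since extraction noise can produce it. The
per-treatment "average degradation rate" is β evaluated at the mean
residual across the three layers; per-layer β values are reported
alongside. Rounding to integer percent happens only at the reporting
boundary.

Group comparisons use classical one-way ANOVA (implemented directly
because Duncan's test needs the MSE and residual df from the same
decomposition; `scipy.stats.f_oneway` is the cross-check in the tests)
followed by Duncan's multiple range test. Critical values are
studentized-range quantiles at Duncan's protection levels
α_p = 1 − (1 − α)^(p−1), obtained by numeric inversion
(`scipy.stats.studentized_range.ppf`, cached — the inversion is costly and
can fail in the extreme upper tail, where an infinite range, i.e. "nothing
separates", is the correct limit). The sequential rule is standard: a span
of p ordered means is homogeneous when its range is below R_p, and
subranges of homogeneous spans are not tested. Maximal homogeneous spans
become the compact letter display; unbalanced designs use the harmonic
mean group size. A brute-force oracle that tests every contiguous span
directly, with containment handled by dynamic programming, verifies the
display on 1 000 random designs.

## qPCR quantification of ARGs and MGE genes

Well-level QC keeps wells with exactly one melt peak and amplification
efficiency in the closed interval [90 %, 110 %] ("beyond the range"
excludes only strictly outside values). Detection of a gene in a sample
requires at least two QC-surviving replicates (one well cannot define a
replicate deviation), mean CT below 31, and a replicate coefficient of
variation strictly below 20 %. "Deviation of three duplications" is read
as the CV of the replicate CTs — scale-free and standard for Smartchip
workflows; a per-replicate CT mode is available behind a flag. The
relative copy number is γ = 10^((31 − CT)/(10/3)) (one decade per 10/3
cycles; γ = 1 at the CT-31 detection boundary), and abundances are
normalised to the 16S rRNA gene as γ_gene/γ_16S, which makes them
invariant to plate-wide additive CT shifts. Undetected genes enter
aggregations as 0, not imputed at the detection limit; samples whose 16S
assay fails detection are flagged and carry undefined abundances.

## Diversity

Shannon entropy uses the natural log (a `base` switch exists since
conventions differ); Chao1 uses the bias-corrected form
S_obs + F₁(F₁−1)/(2(F₂+1)) by default because the classical F₁²/(2F₂)
divides by zero without doubletons; Good's coverage is 1 − F₁/N. Chao1 and
coverage refuse relative-abundance tables (the estimators are only defined
on counts). Genus-level aggregation keeps the top-N taxa per kingdom
(defaults 55 bacteria / 35 fungi / 15 archaea) and lumps the remainder
into an `other` bucket so per-sample totals are conserved exactly.
Indices are computed on the counts as given; an optional
rarefy-to-minimum-depth switch (multivariate hypergeometric subsampling)
exists but is off by default.

## Co-occurrence networks

Edges are Spearman rank correlations (mid-rank ties) across the samples
of the analysed group, kept when the two-sided p-value is below α = 0.05.
Following the source convention, no |rho| threshold and no multiplicity
correction are applied by default; both exist behind flags
(`rho_threshold`, `p_adjust="bh"`/`"bonferroni"`). p-values use the t
approximation except below 10 samples, where the exact tie-free
permutation null of rho is enumerated (cached per n). Zero-variance
features are dropped with a warning.

The keystone filter first removes all negative edges, then removes nodes
whose mean abundance under the treatment is not strictly above the
matched antibiotic-free control; isolated nodes are dropped by default.
Its output is always a subgraph of the positive-edge subgraph of its
input.

Topology reporting follows the usual network-analyzer conventions:
density 2E/(N(N−1)); average neighbours 2E/N; clustering coefficient =
mean local clustering over nodes of degree ≥ 2; "shortest paths" is
reported both as the count of connected ordered pairs (the
Cytoscape-style figure) and as the characteristic path length.

### MCODE

The submodule detector reimplements the Bader–Hogue algorithm with its
published default parameters (degree cutoff 2, node score cutoff 0.2,
k-core 2, max depth 100, haircut on, fluff off). The vertex weight is
(highest k-core level of the closed neighbourhood) × (density of that
highest-k-core subgraph) — the original core-clustering coefficient; note
the density factor applies to the core, not the whole neighbourhood,
which is what makes a clique member outrank its pendant-attached
neighbour. Seeds are processed in descending weight (ties broken by node
identifier); expansion admits unvisited neighbours whose weight reaches
(1 − cutoff) × seed weight; modules without a 2-core are discarded;
haircut removes singly-connected members once. The module score is
density × size. An exhaustive bitmask oracle (independent peeling for
core numbers, subset enumeration for the greedy closure) reproduces the
full module list on every connected graph with ≤ 7 nodes (graph atlas)
and on every connected 8-node graph generated as one-vertex extensions
of all 7-node graphs — every isomorphism class appears at least once.

## Synthetic data: what it emulates, and what it does not

The generators produce every input family the pipeline consumes, each
from an independent deterministic stream derived from the master seed, so
identical configurations give byte-identical outputs.

- **Voltage traces** follow a piecewise-linear current-density profile
  per treatment: zero until the start-up delay (9 h TC / 16 h SC / 17 h
  CC), an ignition step one logging cycle later (so the 1 mV start-up
  criterion fires at the programmed delay), a first peak within days 1–3
  (65/53/22 mA m⁻²), a trough, the maximum at day 27 (136/109 mA m⁻²; CC:
  47 at day 19) and a decline. Knot values were chosen so the noiseless
  traces also reproduce the observed 58-day charge outputs
  (≈1132/940/142 C within ~2 %). Additive Gaussian current noise (default
  2 mA m⁻²) applies only after start-up. Not emulated: feeding-cycle
  oscillations, temperature drift, electrode ageing.
- **Polarization sweeps** use the voltage-divider model
  U = OCV·R/(R + R_int) with per-treatment OCV/R_int (0.37 V/262 Ω,
  0.36/336, 0.18/1332) and optional multiplicative noise. No
  activation/mass-transport curvature (Butler–Volmer) is modelled, so
  recovery tests probe the fitting machinery, not kinetics.
- **Antibiotic residues** decay first-order, C(t) = C₀e^(−kt), with k
  pinned per treatment-layer so the day-58 residuals hit the observed
  endpoints (e.g. TC layers 1.4–1.65 mg kg⁻¹ ≈ 70 % average removal; SC
  0.23–0.27 ≈ 95 %). The true kinetics are unknown — only endpoints are
  observed — so first-order is the simplest curve through them.
  Replicate noise is 4 % multiplicative.
- **qPCR plates** invert the γ transform (CT = 31 − (10/3)log₁₀γ) with
  0.15-cycle replicate noise, plant QC failures (multi-peak and
  out-of-range efficiency, 3 % each by default) with exact bookkeeping,
  and build the true copy-number table with a planted circuit-group
  effect (closed 0.5× / open 0.75× / non-electrode 1×) for target genes.
  The 16S marker is nearly constant across samples (log₁₀ sd 0.05) so
  normalisation does not drown the planted effect — real 16S loads vary
  more, which would require more samples to resolve the same ordering.
- **Abundance tables** draw latent Gaussians with block correlation
  r = 2 sin(π·ρ_s/6) — the Gaussian-copula inverse of the target Spearman
  ρ_s — and push them through taxon-specific log-normal marginals
  (log-means shared between treatment and control draws). Planting on
  ranks guarantees the planted effect is exactly what the rank-based
  network stage measures. Defaults: 40 taxa (20 bacteria / 12 fungi / 8
  archaea), 30 samples, three planted modules of sizes 6/5/4 interleaved
  across kingdoms, within-module ρ_s = 0.9, and a 2× treatment
  fold-change on module members (so the keystone filter's enrichment
  criterion selects them). Not emulated: compositionality/depth
  variation, zero inflation, phylogenetic correlation — so passing
  recovery tests demonstrates correctness of the inference machinery
  under its own assumptions, not robustness to real microbiome artefacts.

## Recovery and calibration benchmarks

`benchmarks.null_calibration` draws module-free tables and reports the
fraction of raw p < 0.05 edges; across 200 replicates it must sit within
three Monte-Carlo standard errors of 0.05, which validates the t
approximation at n = 30.

`benchmarks.edge_recovery_experiment` scores edge calls against the
planted pairs over 10 independently seeded tables. Because this benchmark
evaluates ~780 simultaneous edge tests on individual merit, it uses the
Benjamini–Hochberg mode at q = 0.05: at raw α = 0.05 the ~37 expected
false edges among ~750 null pairs would cap precision near 0.45 no matter
how good the method, while Bonferroni is conservative enough to lose
genuine within-module edges (population ρ_s = 0.9 at n = 30 occasionally
yields sample correlations near 0.6 when the module's common factor draws
a compressed sample). With BH, mean precision ≈ 0.95 and recall ≈ 1.0.
Module recovery is a one-to-one coverage match: every planted member set
must be contained in a distinct top-scoring MCODE module. Occasionally a
background taxon chance-aligns with a module factor and rides into the
top module as an extra member; the planted module is still recovered.

## Problem sizes

Default analysis sizes were chosen to characterise behaviour well while
staying light: 10 replicates for recovery, 200 for null calibration, 100
for noisy polarization recovery, 1 000 random designs for the Duncan
oracle, and the exhaustive ≤ 8-node graph sweep for MCODE. The
reproduction script (`scripts/acceptance.py`) uses the same sizes except
null calibration, which drops to 50 replicates under `--quick`.

## Known limitations

- The pipeline starts at abundance tables; no read-level processing
  (OTU clustering, chimera removal) is included.
- Exact Spearman p-values require tie-free data; ties below 10 samples
  fall back to the t approximation.
- Duncan letters assume near-balanced designs (harmonic-mean n).
- The divider polarization model cannot probe concentration-loss regions;
  R_int estimates on real sweeps depend on the ohmic-window choice.
- MCODE's fluff option is implemented minimally (halo neighbours by
  neighbourhood density) and is off by default, as in the standard
  parameter set.
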
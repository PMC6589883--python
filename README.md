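# soilmfc

Analysis pipeline for soil microbial-fuel-cell (MFC) antibiotic-remediation
experiments. Soil MFCs bury an anode in contaminated soil under an air
cathode; exoelectrogenic micro-organisms oxidise substrates — including
spiked antibiotics such as tetracycline and sulfadiazine — and deliver
electrons through an external resistor, so remediation performance can be
read simultaneously from the electrical record, the chemical residues, the
resistome and the community structure. This package implements the full
downstream analysis for such experiments, for researchers who have the raw
tables (voltage logs, polarization sweeps, residue concentrations,
high-throughput qPCR well tables, multi-kingdom genus tables) and want the
derived quantities and statistics:

- **Electrochemistry** — current density I′ = U/(R·A), power density
  P′ = U²/(R·A), accumulated charge Q = ∫U/R dt, start-up time, and
  open-circuit voltage / internal resistance from the ohmic-region fit
  U = OCV − R_int·I of polarization sweeps.
- **Removal statistics** — removal efficiency β = (C′ − C)/C′ × 100 per
  treatment and soil layer, with one-way ANOVA and Duncan's multiple range
  test rendered as compact letter displays.
- **Resistance genes** — Smartchip-style qPCR post-processing: well QC
  (single melt peak, efficiency within 90–110 %), replicate detection calls
  (mean CT < 31, CV < 20 %), relative copy numbers
  γ = 10^((31−CT)/(10/3)), 16S-normalised abundances, detection rates and
  gene-class aggregates for tet/sul resistance genes and mobile genetic
  element (integron/transposase) genes.
- **Diversity** — Shannon, bias-corrected Chao1 and Good's coverage per
  sample; genus-level aggregation with per-kingdom top-N selection.
- **Networks** — Spearman co-occurrence networks over taxa and target
  genes (edges at p < 0.05), the keystone filter (drop negative links,
  keep taxa enriched over the antibiotic-free control), topology reports
  (clustering coefficient, density, average neighbours, shortest paths),
  a faithful reimplementation of the MCODE dense-submodule algorithm, and
  Cytoscape-compatible exports (edge-list TSV / SIF / GraphML).
- **Synthetic data** — generators for every input above with planted
  ground truth (decay calibrated to observed endpoint removals, qPCR
  plates with bookkept QC failures, Gaussian-copula abundance tables with
  planted rank-correlation modules), so the whole pipeline is testable
  end-to-end without any external data.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

Generate a study-like dataset and analyse the closed-circuit tetracycline
treatment (`TC`):

```python
from soilmfc import simulate, electrochem, chemistry, network

cfg = simulate.SimulationConfig(seed=1)

m = electrochem.trace_metrics(simulate.gen_voltage_trace(cfg, "TC"))
fit = electrochem.fit_polarization(simulate.gen_polarization(cfg, "TC"))
print(m.startup_time_h, m.first_peak_mA_m2, m.max_current_density_mA_m2,
      m.charge_C, fit.ocv_V, fit.internal_resistance_ohm)
```

prints (seed 1): start-up **9.5 h**, first current-density peak
**67.0 mA m⁻²** (within days 1–3), maximum **139.6 mA m⁻²**, 58-day charge
**1152 C**, OCV **0.370 V**, internal resistance **262 Ω** — a reactor that
ignites within hours, peaks early, and delivers roughly eight times the
charge of an antibiotic-free control (`trace_metrics` of `"CC"` gives
~140 C).

```python
table = chemistry.removal_table(simulate.gen_concentration_table(cfg), spike=5.0)
print(table[table.analyte == "tetracycline"]
      [["treatment", "layer", "mean_concentration", "removal_pct", "letters"]])
```

shows per-layer residues of 1.38–1.58 mg kg⁻¹ for TC (removal 68–72 %,
letter `c`) against 2.25–2.49 mg kg⁻¹ for the non-electrode control
(50–55 %, letter `a`): treatments sharing no letter differ at α = 0.05 by
Duncan's test, so the electrode effect is significant in every layer.

```python
tab, truth = simulate.gen_community(cfg)
g = network.co_occurrence_network(tab, alpha=0.05, p_adjust="bh")
for i, mod in enumerate(network.mcode(g), 1):
    print(i, mod.score, mod.members)
```

recovers the three planted cross-kingdom modules exactly — scores 6.0,
5.0 and 4.0 (density × size; all three are perfect cliques) over a
40-node, 32-edge network — mirroring how keystone guilds of bacteria,
fungi and archaea surface as top-scoring MCODE submodules.

The same stages are scriptable from the shell:

```sh
soilmfc simulate --outdir data --seed 1
soilmfc echem   --traces data/voltage_traces.csv --sweeps data/polarization.csv --out out/echem
soilmfc removal --conc data/concentrations.csv --out out/removal
soilmfc args    --wells data/qpcr_wells.tsv --out out/args
soilmfc network --table data/abundance_treatment.tsv --control data/abundance_control.tsv --out out/net
```

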
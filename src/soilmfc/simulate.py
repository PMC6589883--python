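"""Synthetic inputs for every pipeline stage.

Generates the five input families the analysis consumes — reactor voltage
traces, polarization sweeps, antibiotic concentration tables, qPCR well
plates and multi-kingdom abundance tables — with the statistical
structure the downstream stages assume, plus the ground truth needed for
recovery tests. Default parameters reproduce the study conditions of a
58-day soil-MFC run: 100 ohm external resistance, 0.0036 m^2 air
cathode, 5 mg kg^-1 antibiotic spikes, tetracycline/sulfadiazine/control
treatments in closed-circuit, open-circuit and non-electrode variants.

Current dynamics follow a piecewise-linear density profile (start-up
delay, early first peak, later maximum); polarization sweeps follow the
voltage-divider model U = OCV*R/(R + Rint); antibiotic residues follow
first-order decay calibrated to the endpoint removal levels; qPCR plates
invert the CT transform with planted QC failures; abundance tables are
log-normal with a Gaussian-copula rank-correlation structure so planted
module pairs have exactly the configured Spearman correlation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .electrochem import PolarizationSweep, VoltageTrace
from .qpcr import GENE_16S, WELL_COLUMNS, ct_from_gamma

__all__ = [
    "CurrentProfile",
    "CommunityDesign",
    "QPCRDesign",
    "SimulationConfig",
    "CommunityTruth",
    "QPCRPlate",
    "gen_voltage_trace",
    "gen_polarization",
    "gen_antibiotic_decay",
    "gen_concentration_table",
    "gen_qpcr_plate",
    "gen_community",
    "write_all",
]

LAYERS = ("C", "A", "S")  # cathode, anode, surface

#: circuit group of each treatment label
CIRCUIT_GROUP = {
    "TC": "closed", "SC": "closed", "CC": "closed",
    "TO": "open", "SO": "open", "CO": "open",
    "TN": "none", "SN": "none", "CN": "none",
}


@dataclass(frozen=True)
class CurrentProfile:
    """Piecewise-linear current-density dynamics of one closed-circuit MFC.

    ``knots_days`` lists (day, mA m^-2) way-points after start-up; the
    profile is zero before the start-up delay, jumps to a small ignition
    level one logging cycle later (so the 1 mV start-up criterion fires at
    the programmed delay), and is linearly interpolated through the knots.
    When no knots are given a generic shape is built: first peak at
    ``first_peak_day``, a trough at 25% of the first peak midway, the
    maximum at ``time_to_max_days``, then decline.
    """

    startup_h: float
    first_peak_mA_m2: float
    max_mA_m2: float
    time_to_max_days: float
    first_peak_day: float = 2.0
    dip_fraction: float = 0.25   # trough between first peak and maximum
    end_fraction: float = 0.1    # density at the end of the run, as frac of max
    knots_days: tuple | None = None


@dataclass(frozen=True)
class QPCRDesign:
    """Plate layout and noise/QC-failure model for the well-table generator."""

    genes: tuple = (
        "tetA", "tetG", "tetM", "tetO", "tetPA", "tetQ", "tetW", "tetX",
        "sul1", "sul2", "sul3",
        "intI1", "cIntI1", "Tn21", "Tn23", "Tn24", "Tn25", "TnpA",
        GENE_16S,
    )
    classes: dict = field(default_factory=lambda: {})
    replicates: int = 3
    ct_noise_sd: float = 0.15
    p_multi_peak: float = 0.03
    p_bad_efficiency: float = 0.03

    def gene_class(self, gene: str) -> str:
        if gene in self.classes:
            return self.classes[gene]
        if gene == GENE_16S:
            return "16S"
        if gene.startswith("tet"):
            return "tet"
        if gene.startswith("sul"):
            return "sul"
        return "MGE"


@dataclass(frozen=True)
class CommunityDesign:
    """Planted-structure design for the abundance-table generator."""

    taxa_per_kingdom: dict = field(default_factory=lambda: {
        "bacteria": 20, "fungi": 12, "archaea": 8})
    n_samples: int = 30
    module_sizes: tuple = (6, 5, 4)
    within_module_rho: float = 0.9
    treatment_fold_change: float = 2.0  # applied to planted-module taxa
    log_mean: float = 5.5               # log of the typical count (~245)
    log_mean_sd: float = 1.0            # taxon-to-taxon spread of log means
    abundance_sigma: float = 1.0        # within-taxon log-scale noise


@dataclass(frozen=True)
class SimulationConfig:
    """Every knob of the synthetic-data generators, with study defaults."""

    seed: int = 0
    n_reactors: int = 2
    duration_days: float = 58.0
    sample_interval_s: float = 1800.0
    external_resistance_ohm: float = 100.0
    cathode_area_m2: float = 0.0036
    #: knot placement calibrated so the noiseless traces land on the study's
    #: endpoint summaries (first peak, maximum, accumulated charge)
    current_profiles: dict = field(default_factory=lambda: {
        "TC": CurrentProfile(9.0, 65.0, 136.0, 27.0, knots_days=(
            (2.0, 65.0), (10.0, 10.0), (27.0, 136.0), (58.0, 0.0))),
        "SC": CurrentProfile(16.0, 53.0, 109.0, 27.0, knots_days=(
            (2.0, 53.0), (10.0, 15.0), (27.0, 109.0), (58.0, 0.0))),
        "CC": CurrentProfile(17.0, 22.0, 47.0, 19.0, knots_days=(
            (2.0, 22.0), (6.0, 4.0), (15.0, 4.0), (19.0, 47.0), (23.0, 4.0),
            (58.0, 4.0))),
    })
    current_noise_mA_m2: float = 2.0
    ocv_V: dict = field(default_factory=lambda: {
        "TC": 0.37, "SC": 0.36, "CC": 0.18})
    rint_ohm: dict = field(default_factory=lambda: {
        "TC": 262.0, "SC": 336.0, "CC": 1332.0})
    polarization_resistances: tuple = (
        10000.0, 7000.0, 5000.0, 4000.0, 3000.0, 2500.0, 2000.0, 1500.0,
        1200.0, 1000.0, 800.0, 600.0, 500.0, 400.0, 300.0, 250.0, 200.0,
        150.0, 120.0, 100.0)
    polarization_noise_frac: float = 0.0
    spike_mg_per_kg: float = 5.0
    #: endpoint residuals (mg kg^-1) that pin the first-order decay rates;
    #: layer C/A/S values per antibiotic-spiked treatment
    target_residuals: dict = field(default_factory=lambda: {
        ("TC", "C"): 1.5, ("TC", "A"): 1.4, ("TC", "S"): 1.65,
        ("TO", "C"): 1.65, ("TO", "A"): 1.60, ("TO", "S"): 1.85,
        ("TN", "C"): 2.35, ("TN", "A"): 2.30, ("TN", "S"): 2.55,
        ("SC", "C"): 0.23, ("SC", "A"): 0.26, ("SC", "S"): 0.27,
        ("SO", "C"): 0.33, ("SO", "A"): 0.35, ("SO", "S"): 0.37,
        ("SN", "C"): 0.62, ("SN", "A"): 0.65, ("SN", "S"): 0.68,
    })
    concentration_noise_frac: float = 0.04
    concentration_replicates: int = 3
    qpcr: QPCRDesign = field(default_factory=QPCRDesign)
    community: CommunityDesign = field(default_factory=CommunityDesign)

    def __post_init__(self):
        for name in ("duration_days", "sample_interval_s",
                     "external_resistance_ohm", "cathode_area_m2",
                     "spike_mg_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qpcr.replicates < 2:
            raise ValueError("qPCR replicate count must be >= 2")

    def decay_rate_per_day(self, treatment: str, layer: str) -> float:
        """First-order rate pinned so C(duration) hits the target residual."""
        key = (treatment, layer)
        if key not in self.target_residuals:
            raise KeyError(f"no decay calibration for {key}")
        c_end = self.target_residuals[key]
        return float(np.log(self.spike_mg_per_kg / c_end) / self.duration_days)


def _rng(seed: int, *key) -> np.random.Generator:
    """Deterministic per-product generator: same config seed + key, same stream."""
    tags = [zlib.crc32(str(k).encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31)] + tags))


# ---------------------------------------------------------------------------
# electrochemistry inputs
# ---------------------------------------------------------------------------

def _density_profile(profile: CurrentProfile, t_days: np.ndarray,
                     interval_s: float) -> np.ndarray:
    t0 = profile.startup_h / 24.0
    # ignition level one logging cycle after start-up, big enough that the
    # voltage clears the 1 mV start-up criterion immediately
    t_ign = t0 + interval_s / 86400.0
    ignition = max(0.15 * profile.first_peak_mA_m2, 3.0)
    if profile.knots_days is not None:
        knots = [k for k in profile.knots_days if k[0] > t_ign]
    else:
        t_dip = (profile.first_peak_day + profile.time_to_max_days) / 2.0
        knots = [(max(profile.first_peak_day, t_ign + 1e-6),
                  profile.first_peak_mA_m2)]
        if t_dip > knots[-1][0]:
            knots.append((t_dip, profile.dip_fraction * profile.first_peak_mA_m2))
        if profile.time_to_max_days > knots[-1][0]:
            knots.append((profile.time_to_max_days, profile.max_mA_m2))
        end = max(float(t_days.max()), knots[-1][0] + 1e-6)
        knots.append((end, profile.end_fraction * profile.max_mA_m2))
    knots_t = [0.0, t0, t_ign] + [k[0] for k in knots]
    knots_i = [0.0, 0.0, ignition] + [k[1] for k in knots]
    return np.interp(t_days, knots_t, knots_i)


def gen_voltage_trace(config: SimulationConfig, treatment: str,
                      reactor_id: str | None = None,
                      noise_mA_m2: float | None = None) -> VoltageTrace:
    """Voltage time series of one reactor under the configured profile.

    The trace is exactly zero before the start-up delay, reaches the
    configured first peak within days 1-3, dips, and climbs to the
    configured maximum; Gaussian current-density noise (only after
    start-up) is converted to voltage via U = I' * R * A.
    """
    if treatment not in config.current_profiles:
        raise KeyError(f"no current profile for treatment {treatment!r}")
    profile = config.current_profiles[treatment]
    noise = config.current_noise_mA_m2 if noise_mA_m2 is None else noise_mA_m2
    t = np.arange(0.0, config.duration_days * 86400.0 + 1.0,
                  config.sample_interval_s)
    i = _density_profile(profile, t / 86400.0, config.sample_interval_s)
    rng = _rng(config.seed, "voltage", treatment, reactor_id or "r1")
    eps = rng.normal(0.0, noise, size=i.size) if noise > 0 else 0.0
    i_noisy = np.where(i > 0, np.maximum(i + eps, 0.0), 0.0)
    u = i_noisy / 1e3 * config.external_resistance_ohm * config.cathode_area_m2
    return VoltageTrace(reactor_id or f"{treatment}-1", treatment, t, u,
                        config.external_resistance_ohm, config.cathode_area_m2)


def gen_polarization(config: SimulationConfig, treatment: str,
                     resistances=None,
                     noise_frac: float | None = None) -> PolarizationSweep:
    """Polarization sweep from the voltage-divider model U = OCV*R/(R+Rint)."""
    if treatment not in config.ocv_V or treatment not in config.rint_ohm:
        raise KeyError(f"no polarization parameters for treatment {treatment!r}")
    ocv = config.ocv_V[treatment]
    rint = config.rint_ohm[treatment]
    if ocv <= 0 or rint <= 0:
        raise ValueError("OCV and internal resistance must be positive")
    r = np.asarray(config.polarization_resistances if resistances is None
                   else resistances, dtype=float)
    if r.size == 0:
        raise ValueError("empty resistance ladder")
    u = ocv * r / (r + rint)
    frac = config.polarization_noise_frac if noise_frac is None else noise_frac
    if frac > 0:
        rng = _rng(config.seed, "polarization", treatment)
        u = u * (1.0 + rng.normal(0.0, frac, size=u.size))
    return PolarizationSweep(r, u, treatment, config.cathode_area_m2)


# ---------------------------------------------------------------------------
# antibiotic residues
# ---------------------------------------------------------------------------

def gen_antibiotic_decay(config: SimulationConfig, treatment: str, layer: str,
                         t_days: float) -> float:
    """Deterministic residual C(t) = C0 * exp(-k t) for one treatment layer."""
    if t_days < 0:
        raise ValueError("time cannot be negative")
    k = config.decay_rate_per_day(treatment, layer)
    return float(config.spike_mg_per_kg * np.exp(-k * t_days))


def gen_concentration_table(config: SimulationConfig,
                            t_days: float | None = None) -> pd.DataFrame:
    """Tidy endpoint concentration table with replicate noise.

    Columns: treatment, layer, replicate, analyte, concentration, spike.
    Multiplicative Gaussian noise emulates extraction/HPLC variability.
    """
    t = config.duration_days if t_days is None else t_days
    rng = _rng(config.seed, "concentration")
    rows = []
    for (treatment, layer) in sorted(config.target_residuals):
        analyte = "tetracycline" if treatment.startswith("T") else "sulfadiazine"
        c = gen_antibiotic_decay(config, treatment, layer, t)
        for rep in range(1, config.concentration_replicates + 1):
            noisy = c * (1.0 + rng.normal(0.0, config.concentration_noise_frac))
            rows.append({"treatment": treatment, "layer": layer,
                         "replicate": rep, "analyte": analyte,
                         "concentration": max(noisy, 0.0),
                         "spike": config.spike_mg_per_kg})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRPlate:
    """Generated well table plus the per-well generating truth."""

    wells: pd.DataFrame
    truth: pd.DataFrame  # sample, gene, replicate, gamma_true, qc_fail

    @property
    def n_planted_qc_failures(self) -> int:
        return int(self.truth["qc_fail"].sum())


def default_gamma_table(config: SimulationConfig) -> pd.DataFrame:
    """Samples x genes table of true relative copy numbers.

    Target-gene levels scale with the circuit group (closed < open <
    non-electrode), emulating the suppression of resistance genes by
    electrode introduction and biocurrent; 16S sits orders of magnitude
    higher, as a universal marker should.
    """
    rng = _rng(config.seed, "gamma_truth")
    samples = [f"{t}{l}" for t in sorted(CIRCUIT_GROUP) for l in LAYERS]
    mult = {"closed": 0.5, "open": 0.75, "none": 1.0}
    rows = {}
    # ubiquitous genes sit well above the detection limit; the rest spread
    # around it so the plate shows a realistic mix of detection rates
    ubiquitous = {"tetG", "tetPA", "sul2", "intI1", "Tn24", "Tn25"}
    base = {g: 10.0 ** (rng.uniform(0.8, 1.8) if g in ubiquitous
                        else rng.uniform(-1.0, 1.0))
            for g in config.qpcr.genes if g != GENE_16S}
    for s in samples:
        group = CIRCUIT_GROUP[s[:2]]
        vals = {}
        for g in config.qpcr.genes:
            if g == GENE_16S:
                # the universal marker is nearly constant across samples so
                # normalisation does not drown the planted group effect
                vals[g] = 10.0 ** rng.normal(4.0, 0.05)
            else:
                vals[g] = base[g] * mult[group] * np.exp(rng.normal(0.0, 0.2))
        rows[s] = vals
    return pd.DataFrame(rows).T[list(config.qpcr.genes)]


def gen_qpcr_plate(config: SimulationConfig,
                   true_gamma: pd.DataFrame | None = None) -> QPCRPlate:
    """Well table with CT = 31 - (10/3) log10(gamma) plus noise and QC faults.

    Each sample/gene pair gets ``replicates`` wells. A configured fraction
    of wells is planted with a second melt peak or an out-of-range
    amplification efficiency; the returned truth table records the planted
    faults so recovery tests can count them exactly.
    """
    if true_gamma is None:
        true_gamma = default_gamma_table(config)
    if (np.asarray(true_gamma.values, dtype=float) <= 0).any():
        raise ValueError("true relative copy numbers must be positive")
    design = config.qpcr
    rng = _rng(config.seed, "qpcr_plate")
    well_rows, truth_rows = [], []
    for s in true_gamma.index:
        for g in true_gamma.columns:
            gamma = float(true_gamma.loc[s, g])
            ct_clean = float(ct_from_gamma(gamma))
            for rep in range(1, design.replicates + 1):
                ct = ct_clean + (rng.normal(0.0, design.ct_noise_sd)
                                 if design.ct_noise_sd > 0 else 0.0)
                multi = rng.random() < design.p_multi_peak
                bad_eff = rng.random() < design.p_bad_efficiency
                if bad_eff:
                    eff = (rng.uniform(70.0, 88.0) if rng.random() < 0.5
                           else rng.uniform(112.0, 130.0))
                else:
                    eff = rng.uniform(92.0, 108.0)
                well_rows.append({
                    "sample": s, "gene": g,
                    "gene_class": design.gene_class(g), "replicate": rep,
                    "ct": ct, "n_melt_peaks": 2 if multi else 1,
                    "efficiency_pct": eff,
                })
                truth_rows.append({"sample": s, "gene": g, "replicate": rep,
                                   "gamma_true": gamma,
                                   "qc_fail": bool(multi or bad_eff)})
    return QPCRPlate(pd.DataFrame(well_rows, columns=list(WELL_COLUMNS)),
                     pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# community tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityTruth:
    """Planted structure behind a generated abundance table."""

    edges: pd.DataFrame            # taxon_a, taxon_b, rho_true
    modules: dict                  # module name -> tuple of taxa
    enriched: tuple                # taxa whose treatment abundance is boosted


def _taxon_names(design: CommunityDesign) -> pd.DataFrame:
    prefixes = {"bacteria": "B", "fungi": "F", "archaea": "A"}
    phyla = {"bacteria": ("Proteobacteria", "Firmicutes", "Bacteroidetes"),
             "fungi": ("Ascomycota", "Zygomycota"),
             "archaea": ("Thaumarchaeota", "Euryarchaeota")}
    rows = []
    for kingdom, n in design.taxa_per_kingdom.items():
        for i in range(n):
            name = f"{prefixes.get(kingdom, kingdom[:1].upper())}{i + 1:02d}"
            phylum = phyla.get(kingdom, ("Unknown",))[i % len(phyla.get(kingdom, ("x",)))]
            rows.append({"taxon": name, "kingdom": kingdom,
                         "lineage": f"{phylum};;;;{name}"})
    return pd.DataFrame(rows).set_index("taxon")


def _planted_modules(design: CommunityDesign, taxa: pd.DataFrame) -> dict:
    """Assign module members round-robin across kingdoms (disjoint sets)."""
    by_kingdom = {k: list(idx) for k, idx in
                  taxa.groupby("kingdom").groups.items()}
    order = sorted(by_kingdom)
    modules = {}
    cursors = {k: 0 for k in order}
    ki = 0
    for m, size in enumerate(design.module_sizes, start=1):
        members = []
        while len(members) < size:
            k = order[ki % len(order)]
            ki += 1
            if cursors[k] < len(by_kingdom[k]):
                members.append(by_kingdom[k][cursors[k]])
                cursors[k] += 1
        modules[f"module_{m}"] = tuple(members)
    total = sum(len(v) for v in modules.values())
    if total > taxa.shape[0]:
        raise ValueError("planted modules need more taxa than configured")
    return modules


def gen_community(config: SimulationConfig, group: str = "treatment"
                  ) -> tuple[AbundanceTable, CommunityTruth]:
    """Abundance table with planted rank-correlation modules + ground truth.

    Latent Gaussian samples with block correlation r = 2 sin(pi*rho_s/6)
    (the Gaussian-copula inverse of the target Spearman rho_s) are pushed
    through taxon-specific log-normal marginals, so the *population*
    Spearman correlation of within-module pairs equals the configured
    value and between-module pairs are independent. ``group="treatment"``
    multiplies planted-module taxa by the configured fold change;
    ``group="control"`` leaves them at baseline (an independent draw).
    """
    design = config.community
    rho_s = design.within_module_rho
    if not -1.0 < rho_s < 1.0:
        raise ValueError("within-module rho must be inside (-1, 1)")
    if design.n_samples < 2:
        raise ValueError("need at least 2 samples")
    taxa = _taxon_names(design)
    names = list(taxa.index)
    p = len(names)
    modules = _planted_modules(design, taxa)

    r_latent = 2.0 * np.sin(np.pi * rho_s / 6.0)
    sigma = np.eye(p)
    pos = {t: i for i, t in enumerate(names)}
    edge_rows = []
    for members in modules.values():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                sigma[pos[a], pos[b]] = sigma[pos[b], pos[a]] = r_latent
                edge_rows.append({"taxon_a": a, "taxon_b": b,
                                  "rho_true": rho_s})
    chol = np.linalg.cholesky(sigma)

    # taxon log-means are a property of the community, shared between the
    # treatment and control draws; only the per-sample noise is independent
    mu = _rng(config.seed, "community", "marginals").normal(
        design.log_mean, design.log_mean_sd, size=p)
    rng = _rng(config.seed, "community", group)
    z = rng.standard_normal((design.n_samples, p)) @ chol.T
    x = np.exp(mu + design.abundance_sigma * z)

    enriched = tuple(t for members in modules.values() for t in members)
    if group != "control":
        fold = np.array([design.treatment_fold_change if t in enriched else 1.0
                         for t in names])
        x = x * fold
    counts = np.rint(x).astype(int)

    sample_names = [f"{group[:2].upper()}{i + 1:02d}"
                    for i in range(design.n_samples)]
    samples = pd.DataFrame({
        "treatment": group,
        "layer": [LAYERS[i % 3] for i in range(design.n_samples)],
    }, index=pd.Index(sample_names, name="sample"))
    table = AbundanceTable(
        pd.DataFrame(counts.T, index=names, columns=sample_names),
        taxa, samples)
    truth = CommunityTruth(
        pd.DataFrame(edge_rows, columns=["taxon_a", "taxon_b", "rho_true"]),
        modules, enriched if group != "control" else tuple())
    return table, truth


# ---------------------------------------------------------------------------
# bulk writer
# ---------------------------------------------------------------------------

def write_all(config: SimulationConfig, outdir) -> dict:
    """Write every synthetic input plus the ground-truth sidecars.

    Returns a mapping of logical names to the file paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    trace_frames = []
    for treatment in sorted(config.current_profiles):
        for r in range(1, config.n_reactors + 1):
            tr = gen_voltage_trace(config, treatment, f"{treatment}-{r}")
            trace_frames.append(pd.DataFrame({
                "reactor": tr.reactor_id, "treatment": treatment,
                "time_s": tr.time_s, "voltage_V": tr.voltage_V,
                "resistance_ohm": tr.resistance_ohm,
                "cathode_area_m2": tr.cathode_area_m2,
            }))
    paths["traces"] = outdir / "voltage_traces.csv"
    pd.concat(trace_frames).to_csv(paths["traces"], index=False)

    sweep_frames = []
    for treatment in sorted(config.ocv_V):
        sw = gen_polarization(config, treatment)
        sweep_frames.append(pd.DataFrame({
            "treatment": treatment, "resistance_ohm": sw.resistance_ohm,
            "voltage_V": sw.voltage_V,
        }))
    paths["sweeps"] = outdir / "polarization.csv"
    pd.concat(sweep_frames).to_csv(paths["sweeps"], index=False)

    paths["concentrations"] = outdir / "concentrations.csv"
    gen_concentration_table(config).to_csv(paths["concentrations"], index=False)

    plate = gen_qpcr_plate(config)
    paths["qpcr_wells"] = outdir / "qpcr_wells.tsv"
    plate.wells.to_csv(paths["qpcr_wells"], sep="\t", index=False)
    paths["qpcr_truth"] = outdir / "qpcr_truth.tsv"
    plate.truth.to_csv(paths["qpcr_truth"], sep="\t", index=False)

    for group in ("treatment", "control"):
        table, truth = gen_community(config, group)
        paths[f"abundance_{group}"] = outdir / f"abundance_{group}.tsv"
        table.to_tsv(paths[f"abundance_{group}"])
        if group == "treatment":
            paths["true_edges"] = outdir / "ground_truth_edges.tsv"
            truth.edges.to_csv(paths["true_edges"], sep="\t", index=False)
            paths["true_modules"] = outdir / "ground_truth_modules.tsv"
            pd.DataFrame(
                [{"module": m, "taxon": t} for m, ts in truth.modules.items()
                 for t in ts]
            ).to_csv(paths["true_modules"], sep="\t", index=False)
    return paths
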
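"""High-throughput qPCR pipeline for antibiotic-resistance and MGE genes.

Implements the Smartchip-style post-processing chain: per-well QC
(single melt peak, amplification efficiency within 90-110%), replicate
detection calls (mean CT < 31 with replicate scatter < 20%), the CT to
relative-copy-number transform gamma = 10^((31 - CT)/(10/3)), and
normalisation to the 16S rRNA gene (copies of gene / copies of 16S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WELL_COLUMNS",
    "qc_filter",
    "DetectionCall",
    "call_detection",
    "relative_copy_number",
    "ct_from_gamma",
    "normalize_to_16S",
    "detection_rate",
    "aggregate_class",
    "GeneAbundanceTable",
    "build_gene_table",
    "read_wells",
]

#: expected columns of a well table
WELL_COLUMNS = ("sample", "gene", "gene_class", "replicate", "ct",
                "n_melt_peaks", "efficiency_pct")

#: CT at which the relative copy number is defined to be 1
CT_REFERENCE = 31.0
#: cycles per decade of template (10/3)
CYCLES_PER_DECADE = 10.0 / 3.0
#: name of the normalising gene
GENE_16S = "16S"


def qc_filter(wells: pd.DataFrame, efficiency_range=(90.0, 110.0),
              return_report: bool = False):
    """Drop wells with multiple melting peaks or out-of-range efficiency.

    A well survives when it has exactly one melt peak and an amplification
    efficiency inside the closed interval ``efficiency_range`` (boundary
    values are retained). With ``return_report=True`` the excluded wells
    are returned alongside, each annotated with its exclusion reason.
    """
    lo, hi = efficiency_range
    multi = wells["n_melt_peaks"] != 1
    bad_eff = (wells["efficiency_pct"] < lo) | (wells["efficiency_pct"] > hi)
    kept = wells.loc[~multi & ~bad_eff].copy()
    if not return_report:
        return kept
    excluded = wells.loc[multi | bad_eff].copy()
    reasons = []
    for is_multi, is_bad in zip(multi[multi | bad_eff], bad_eff[multi | bad_eff]):
        r = []
        if is_multi:
            r.append("multiple_melt_peaks")
        if is_bad:
            r.append("efficiency_out_of_range")
        reasons.append("+".join(r))
    excluded["exclusion_reason"] = reasons
    return kept, excluded


@dataclass(frozen=True)
class DetectionCall:
    detected: bool
    reason: str | None
    mean_ct: float
    cv_pct: float
    n_replicates: int


def call_detection(replicate_cts, ct_max: float = CT_REFERENCE,
                   cv_max_pct: float = 20.0, min_replicates: int = 2,
                   per_replicate: bool = False) -> DetectionCall:
    """Detection call from the surviving replicate CT values.

    Detected when (i) at least ``min_replicates`` wells survived QC,
    (ii) the mean CT is below ``ct_max`` (each replicate individually with
    ``per_replicate=True``), and (iii) the coefficient of variation of the
    replicate CTs is below ``cv_max_pct`` percent.
    """
    cts = np.asarray(list(replicate_cts), dtype=float)
    cts = cts[~np.isnan(cts)]
    n = cts.size
    if n == 0:
        return DetectionCall(False, "no_surviving_replicates", np.nan, np.nan, 0)
    mean_ct = float(cts.mean())
    cv = float(np.std(cts, ddof=1) / mean_ct * 100.0) if n > 1 else 0.0
    if n < min_replicates:
        return DetectionCall(False, "replicate_quorum", mean_ct, cv, n)
    ct_ok = (cts < ct_max).all() if per_replicate else mean_ct < ct_max
    if not ct_ok:
        return DetectionCall(False, "ct_above_threshold", mean_ct, cv, n)
    if not cv < cv_max_pct:
        return DetectionCall(False, "replicate_deviation", mean_ct, cv, n)
    return DetectionCall(True, None, mean_ct, cv, n)


def relative_copy_number(ct):
    """Relative copy number gamma = 10^((31 - CT)/(10/3))."""
    return np.power(10.0, (CT_REFERENCE - np.asarray(ct, dtype=float))
                    / CYCLES_PER_DECADE)


def ct_from_gamma(gamma):
    """Inverse transform: CT = 31 - (10/3) * log10(gamma)."""
    g = np.asarray(gamma, dtype=float)
    if (g <= 0).any():
        raise ValueError("relative copy numbers must be positive")
    return CT_REFERENCE - CYCLES_PER_DECADE * np.log10(g)


def normalize_to_16S(gamma_gene, gamma_16s):
    """Abundance relative to 16S: gamma_gene / gamma_16S."""
    g16 = np.asarray(gamma_16s, dtype=float)
    if (g16 <= 0).any():
        raise ValueError("16S relative copy number must be positive")
    return np.asarray(gamma_gene, dtype=float) / g16


def detection_rate(detected_flags) -> float:
    """Percent of samples in which a gene was called detected."""
    flags = np.asarray(list(detected_flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("detection rate needs at least one sample")
    return float(flags.mean() * 100.0)


def aggregate_class(abundance: pd.DataFrame, genes) -> pd.Series:
    """Per-sample summed relative abundance over a gene set.

    ``abundance`` is samples x genes with undetected genes already at 0.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in abundance.columns]
    if missing:
        raise KeyError(f"genes not in table: {missing}")
    return abundance[genes].sum(axis=1)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class GeneAbundanceTable:
    """Per-sample gene quantification after QC, detection and normalisation.

    ``gamma`` holds relative copy numbers for detected sample/gene pairs
    (NaN otherwise), ``detected`` the boolean calls, ``abundance`` the
    16S-normalised values with undetected genes at 0, and ``calls`` the
    per-pair diagnostic records. Samples whose 16S assay failed detection
    are listed in ``flagged_samples`` and carry NaN abundances.
    """

    gamma: pd.DataFrame
    detected: pd.DataFrame
    abundance: pd.DataFrame
    calls: pd.DataFrame
    qc_report: pd.DataFrame
    flagged_samples: tuple = ()

    def detection_rates(self) -> pd.Series:
        return self.detected.mean(axis=0) * 100.0


def build_gene_table(wells: pd.DataFrame, efficiency_range=(90.0, 110.0),
                     ct_max: float = CT_REFERENCE, cv_max_pct: float = 20.0,
                     min_replicates: int = 2) -> GeneAbundanceTable:
    """Run QC -> detection -> gamma -> 16S normalisation on a well table."""
    kept, excluded = qc_filter(wells, efficiency_range, return_report=True)
    samples = sorted(wells["sample"].unique())
    genes = sorted(wells["gene"].unique())

    call_rows = []
    gamma = pd.DataFrame(np.nan, index=samples, columns=genes)
    det = pd.DataFrame(False, index=samples, columns=genes)
    surviving = {k: v["ct"].values for k, v in kept.groupby(["sample", "gene"])}
    for s in samples:
        for g in genes:
            cts = surviving.get((s, g), np.array([]))
            call = call_detection(cts, ct_max, cv_max_pct, min_replicates)
            call_rows.append({"sample": s, "gene": g, **call.__dict__})
            det.loc[s, g] = call.detected
            if call.detected:
                gamma.loc[s, g] = relative_copy_number(call.mean_ct)

    flagged = tuple(s for s in samples if not det.loc[s, GENE_16S]) \
        if GENE_16S in genes else tuple(samples)
    if flagged:
        warnings.warn(f"16S undetected in samples {flagged}; "
                      "their normalised abundances are undefined", stacklevel=2)
    abundance = pd.DataFrame(0.0, index=samples, columns=[g for g in genes
                                                          if g != GENE_16S])
    for s in samples:
        if s in flagged:
            abundance.loc[s] = np.nan
            continue
        g16 = gamma.loc[s, GENE_16S]
        for g in abundance.columns:
            if det.loc[s, g]:
                abundance.loc[s, g] = normalize_to_16S(gamma.loc[s, g], g16)
    return GeneAbundanceTable(gamma, det, abundance,
                              pd.DataFrame(call_rows), excluded, flagged)


def read_wells(path) -> pd.DataFrame:
    """Read a well TSV with the columns in ``WELL_COLUMNS``."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"well table missing columns: {missing}")
    return df
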
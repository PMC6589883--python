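"""Community tables and alpha-diversity estimators.

Holds the taxon-by-sample abundance table shared by the diversity and
network stages, plus the three alpha-diversity estimators used to
summarise amplicon-derived genus tables: Shannon entropy, bias-corrected
Chao1 richness, and Good's coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "shannon",
    "chao1",
    "goods_coverage",
    "rarefy",
    "aggregate_taxonomy",
    "diversity_table",
    "DEFAULT_TOP_N",
]

#: taxonomic ranks encoded positionally in the lineage string
RANKS = ("phylum", "class", "order", "family", "genus")

#: default number of top taxa retained per kingdom when aggregating at genus
#: level (the rest is lumped into an "other" bucket)
DEFAULT_TOP_N = {"bacteria": 55, "fungi": 35, "archaea": 15}


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with taxon and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by taxon identifier with one column per sample.
        Cells are non-negative counts, or relative abundances when
        ``is_relative`` is set.
    taxa
        DataFrame indexed like ``counts`` with columns ``kingdom``
        (bacteria | fungi | archaea) and ``lineage`` (semicolon-separated
        phylum;class;order;family;genus).
    samples
        DataFrame indexed by sample name with columns ``treatment`` and
        ``layer``.
    is_relative
        True when cells are relative abundances rather than counts.
        Chao1 and Good's coverage refuse relative tables.
    """

    counts: pd.DataFrame
    taxa: pd.DataFrame
    samples: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("abundance table contains negative cells")
        if not self.counts.index.equals(self.taxa.index):
            raise ValueError("counts and taxa indexes differ")
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("counts columns and sample metadata differ")
        if self.counts.index.has_duplicates:
            raise ValueError("taxon identifiers must be unique")
        for df in (self.counts, self.taxa):
            df.index.name = "taxon"
        self.counts.columns.name = None
        self.samples.index.name = "sample"

    # -- convenience -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def relative(self) -> "AbundanceTable":
        """Return a copy normalised to per-sample relative abundances."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("cannot normalise a sample with zero total")
        return AbundanceTable(
            self.counts / totals, self.taxa.copy(), self.samples.copy(), True
        )

    def subset_samples(self, names) -> "AbundanceTable":
        names = list(names)
        return AbundanceTable(
            self.counts[names], self.taxa.copy(), self.samples.loc[names].copy(),
            self.is_relative,
        )

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path, samples_path=None) -> None:
        """Write taxon,kingdom,lineage + sample columns; metadata sidecar."""
        path = Path(path)
        out = pd.concat([self.taxa[["kingdom", "lineage"]], self.counts], axis=1)
        out.index.name = "taxon"
        out.to_csv(path, sep="\t")
        if samples_path is None:
            samples_path = path.with_suffix(".samples.tsv")
        meta = self.samples.copy()
        meta.index.name = "sample"
        meta.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, samples_path=None, is_relative: bool = False):
        path = Path(path)
        raw = pd.read_csv(path, sep="\t", index_col="taxon")
        taxa = raw[["kingdom", "lineage"]]
        counts = raw.drop(columns=["kingdom", "lineage"])
        if samples_path is None:
            samples_path = path.with_suffix(".samples.tsv")
        if Path(samples_path).exists():
            samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
            samples = samples.loc[list(counts.columns)]
        else:
            samples = pd.DataFrame(
                {"treatment": "", "layer": ""}, index=counts.columns
            )
        return cls(counts, taxa, samples, is_relative)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector of per-taxon counts")
    if (x < 0).any():
        raise ValueError("negative counts")
    return x


def _require_integers(x: np.ndarray, estimator: str) -> np.ndarray:
    if not np.allclose(x, np.round(x)):
        raise ValueError(
            f"{estimator} is defined on integer counts, not relative abundances"
        )
    return np.round(x).astype(int)


def shannon(counts, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over taxa with p_i > 0.

    Natural log by default; pass ``base=2`` for the bits convention.
    """
    x = _as_counts(counts)
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined Shannon index")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) by default; the
    classical F1^2/(2 F2) form divides by zero when no doubletons exist.
    """
    x = _require_integers(_as_counts(counts), "chao1")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 == 0:
        raise ZeroDivisionError("classical Chao1 undefined without doubletons")
    return s_obs + f1 * f1 / (2.0 * f2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: estimated fraction of reads from seen taxa."""
    x = _require_integers(_as_counts(counts), "goods_coverage")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has undefined coverage")
    f1 = int((x == 1).sum())
    return 1.0 - f1 / total


def rarefy(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample a count vector to ``depth`` reads without replacement."""
    x = _require_integers(_as_counts(counts), "rarefy")
    if depth > x.sum():
        raise ValueError("rarefaction depth exceeds sample total")
    return rng.multivariate_hypergeometric(x, depth)


def diversity_table(table: AbundanceTable, rarefy_to_min: bool = False,
                    seed: int = 0) -> pd.DataFrame:
    """Per-sample Shannon, Chao1, observed richness and Good's coverage."""
    if table.is_relative:
        raise ValueError("diversity estimators need integer counts")
    counts = table.counts
    if rarefy_to_min:
        depth = int(counts.sum(axis=0).min())
        rng = np.random.default_rng(seed)
        counts = counts.apply(lambda c: pd.Series(rarefy(c, depth, rng), c.index))
    rows = {}
    for s in counts.columns:
        c = counts[s].values
        rows[s] = {
            "shannon": shannon(c),
            "chao1": chao1(c),
            "observed": int((c > 0).sum()),
            "goods_coverage": goods_coverage(c),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    return out.join(table.samples)


# ---------------------------------------------------------------------------
# taxonomic aggregation
# ---------------------------------------------------------------------------

def _lineage_at(lineage: str, rank: str) -> str | None:
    parts = [p.strip() for p in str(lineage).split(";")]
    i = RANKS.index(rank)
    if i < len(parts) and parts[i]:
        return parts[i]
    return None


def aggregate_taxonomy(table: AbundanceTable, rank: str = "genus",
                       top_n: int | None = None) -> AbundanceTable:
    """Collapse the table to ``rank`` and keep the ``top_n`` most abundant taxa.

    Counts are summed per (kingdom, rank-name); taxa beyond ``top_n`` (ranked
    by mean relative abundance within their kingdom) are lumped into a single
    ``other`` bucket per kingdom, so per-sample totals are conserved exactly.
    ``top_n=None`` uses per-kingdom defaults (55 bacteria / 35 fungi /
    15 archaea); ``top_n`` >= the taxon count keeps everything.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    names = table.taxa["lineage"].map(lambda s: _lineage_at(s, rank))
    if names.isna().all():
        raise ValueError(f"no taxon has a lineage populated to rank {rank!r}")

    frames = []
    meta_rows = []
    rel = table.counts / table.counts.sum(axis=0).replace(0, np.nan)
    for kingdom, idx in table.taxa.groupby("kingdom").groups.items():
        sub = table.counts.loc[idx]
        sub_names = names.loc[idx].fillna("unclassified")
        grouped = sub.groupby(sub_names.values).sum()
        order = (
            rel.loc[idx].groupby(sub_names.values).sum().mean(axis=1)
            .sort_values(ascending=False)
        )
        n = DEFAULT_TOP_N.get(kingdom, len(order)) if top_n is None else top_n
        keep = list(order.index[:n])
        rest = [t for t in grouped.index if t not in keep]
        kept = grouped.loc[keep]
        if rest:
            other = grouped.loc[rest].sum(axis=0).to_frame("other").T
            kept = pd.concat([kept, other])
        plain = list(kept.index)
        kept.index = [f"{kingdom}:{t}" for t in plain]
        frames.append(kept)
        slot = RANKS.index(rank)
        for t, name in zip(kept.index, plain):
            lin = [""] * len(RANKS)
            lin[slot] = name
            meta_rows.append({"taxon": t, "kingdom": kingdom,
                              "lineage": ";".join(lin)})
    counts = pd.concat(frames)
    taxa = pd.DataFrame(meta_rows).set_index("taxon")
    return AbundanceTable(counts, taxa, table.samples.copy(), table.is_relative)
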
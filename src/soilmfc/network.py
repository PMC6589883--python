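"""Co-occurrence network inference, keystone filtering and MCODE modules.

Edges are Spearman rank correlations between taxa (and optionally target
genes) across samples, kept when the two-sided p-value clears the chosen
alpha (0.05 by convention, no multiplicity correction by default). The
keystone filter removes negative links and nodes not enriched over the
antibiotic-free control. Topology summaries mirror the usual network
analyzer output; dense submodules are found with a reimplementation of
the MCODE vertex-weighting/greedy-expansion algorithm of Bader & Hogue.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import AbundanceTable

__all__ = [
    "spearman_matrix",
    "build_network",
    "co_occurrence_network",
    "keystone_filter",
    "TopologyReport",
    "topology",
    "Module",
    "mcode",
    "export_network",
    "read_network",
]


# ---------------------------------------------------------------------------
# Spearman edge inference
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _exact_rho_null(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho for tie-free samples of n."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = [1.0 - 6.0 * float(((base - np.array(p)) ** 2).sum()) / denom
            for p in itertools.permutations(range(1, n + 1))]
    return np.sort(np.abs(np.array(rhos)))


def _exact_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for an observed tie-free Spearman rho."""
    null = _exact_rho_null(n)
    # P(|rho_null| >= |rho_obs|), counting ties as exceedances
    idx = np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float((null.size - idx) / null.size)


def spearman_matrix(table: AbundanceTable, gene_table: pd.DataFrame = None,
                    exact_below_n: int = 10):
    """All pairwise Spearman correlations among taxa (and genes).

    Rows of the abundance table and columns of the optional samples x genes
    table are stacked into one feature matrix over the shared samples.
    Mid-ranks handle ties; p-values use the t approximation, switching to
    the exact permutation null when fewer than ``exact_below_n`` samples
    are available (and the data are tie-free). Zero-variance features are
    dropped with a warning.

    Returns (rho, p) as square DataFrames over the feature names.
    """
    feats = table.counts.copy()
    feats.index = [str(i) for i in feats.index]
    if gene_table is not None:
        genes = gene_table.T  # genes x samples
        genes = genes[feats.columns]
        genes.index = [str(i) for i in genes.index]
        feats = pd.concat([feats, genes])
    n = feats.shape[1]
    if n < 4:
        raise ValueError("Spearman inference needs at least 4 samples")
    var = feats.var(axis=1)
    if (var == 0).any():
        dropped = list(feats.index[var == 0])
        warnings.warn(f"dropping zero-variance features: {dropped}",
                      stacklevel=2)
        feats = feats.loc[var > 0]
    names = list(feats.index)
    x = feats.values.astype(float)

    rho, p = stats.spearmanr(x, axis=1)
    if np.ndim(rho) == 0:  # scipy collapses the two-feature case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        p = np.array([[0.0, float(p)], [float(p), 0.0]])
    if n < exact_below_n:
        ranks = stats.rankdata(x, axis=1)
        tie_free = np.array([np.unique(r).size == n for r in ranks])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if tie_free[i] and tie_free[j]:
                    p[i, j] = p[j, i] = _exact_p(rho[i, j], n)
    return (pd.DataFrame(rho, index=names, columns=names),
            pd.DataFrame(p, index=names, columns=names))


def build_network(rho: pd.DataFrame, p: pd.DataFrame, alpha: float = 0.05,
                  rho_threshold: float | None = None,
                  p_adjust: str | None = None,
                  node_attrs: dict | None = None) -> nx.Graph:
    """Significance-filtered undirected co-occurrence graph.

    An edge joins every off-diagonal pair with p < ``alpha`` (after the
    optional Benjamini-Hochberg adjustment when ``p_adjust="bh"``, or
    Bonferroni with ``"bonferroni"``); ``rho_threshold`` additionally
    requires |rho| above it. Edge attributes: rho, p, sign, weight=|rho|.
    """
    if list(rho.index) != list(p.index):
        raise ValueError("rho and p matrices are not conformable")
    names = list(rho.index)
    iu = np.triu_indices(len(names), k=1)
    pvals = p.values[iu]
    if p_adjust == "bh":
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty(m)
        adj[order] = np.minimum.accumulate(
            (pvals[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        pvals = np.minimum(adj, 1.0)
    elif p_adjust == "bonferroni":
        pvals = np.minimum(pvals * pvals.size, 1.0)
    elif p_adjust is not None:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")

    g = nx.Graph()
    g.add_nodes_from(names)
    if node_attrs:
        nx.set_node_attributes(g, node_attrs)
    for (i, j), pv in zip(zip(*iu), pvals):
        if pv < alpha:
            r = float(rho.values[i, j])
            if rho_threshold is not None and abs(r) < rho_threshold:
                continue
            g.add_edge(names[i], names[j], rho=r, p=float(pv),
                       sign="positive" if r >= 0 else "negative",
                       weight=abs(r))
    return g


def co_occurrence_network(table: AbundanceTable, gene_table=None,
                          alpha: float = 0.05, rho_threshold=None,
                          p_adjust=None) -> nx.Graph:
    """Spearman matrix + significance filter, with node metadata attached."""
    rho, p = spearman_matrix(table, gene_table)
    attrs = {}
    mean_ab = table.counts.mean(axis=1)
    for t in table.counts.index:
        attrs[str(t)] = {"kind": "taxon",
                         "kingdom": str(table.taxa.loc[t, "kingdom"]),
                         "mean_abundance": float(mean_ab.loc[t])}
    if gene_table is not None:
        for gcol in gene_table.columns:
            attrs[str(gcol)] = {"kind": "gene",
                                "mean_abundance": float(gene_table[gcol].mean())}
    attrs = {k: v for k, v in attrs.items() if k in rho.index}
    return build_network(rho, p, alpha, rho_threshold, p_adjust, attrs)


# ---------------------------------------------------------------------------
# keystone filter
# ---------------------------------------------------------------------------

def keystone_filter(net: nx.Graph, treatment_abundance,
                    control_abundance, drop_isolated: bool = True) -> nx.Graph:
    """Keep positive links among taxa enriched over the antibiotic-free control.

    Step 1 removes every negative edge. Step 2 removes nodes whose mean
    abundance under the treatment is not strictly above the matched
    control (nodes missing from either mapping are dropped with a
    warning). Isolated nodes are dropped unless ``drop_isolated=False``.
    """
    g = net.copy()
    g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True)
                         if d.get("sign") == "negative" or d.get("rho", 0) < 0])
    treatment_abundance = dict(treatment_abundance)
    control_abundance = dict(control_abundance)
    missing = [v for v in g.nodes
               if v not in treatment_abundance or v not in control_abundance]
    if missing:
        warnings.warn(f"no control abundance for {missing}; nodes dropped",
                      stacklevel=2)
        g.remove_nodes_from(missing)
    g.remove_nodes_from([v for v in list(g.nodes)
                         if treatment_abundance[v] <= control_abundance[v]])
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyReport:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    network_density: float
    avg_neighbors: float
    shortest_path_count: int
    characteristic_path_length: float
    positive_edge_fraction: float


def topology(net: nx.Graph) -> TopologyReport:
    """Standard network-analyzer summary of an undirected graph.

    The clustering coefficient is the mean local clustering over nodes of
    degree >= 2; ``shortest_path_count`` is the number of connected ordered
    node pairs (the Cytoscape-style "shortest paths" figure) and the
    characteristic path length averages distances over those pairs.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    if n == 0:
        return TopologyReport(0, 0, float("nan"), float("nan"), float("nan"),
                              0, float("nan"), float("nan"))
    local = nx.clustering(net)
    eligible = [v for v in net if net.degree(v) >= 2]
    cc = float(np.mean([local[v] for v in eligible])) if eligible else 0.0
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_nb = 2.0 * e / n
    n_paths = 0
    total_len = 0
    for _, dists in nx.all_pairs_shortest_path_length(net):
        for target, d in dists.items():
            if d > 0:
                n_paths += 1
                total_len += d
    cpl = total_len / n_paths if n_paths else float("nan")
    signs = [d.get("sign", "positive") for _, _, d in net.edges(data=True)]
    pos_frac = signs.count("positive") / len(signs) if signs else float("nan")
    return TopologyReport(n, e, cc, density, avg_nb, n_paths, cpl, pos_frac)


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Module:
    members: tuple
    score: float
    density: float
    seed: str

    @property
    def size(self) -> int:
        return len(self.members)


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _mcode_weights(net: nx.Graph, degree_cutoff: int) -> dict:
    """Vertex weight = (highest k-core level of N[v]) x (density of that core).

    Nodes below the degree cutoff are given weight 0, as in the original
    vertex-scoring stage.
    """
    w = {}
    for v in net.nodes:
        if net.degree(v) < degree_cutoff:
            w[v] = 0.0
            continue
        nbhd = net.subgraph(set(net[v]) | {v})
        core = nx.core_number(nbhd)
        kmax = max(core.values())
        highest = nbhd.subgraph([u for u, k in core.items() if k == kmax])
        w[v] = kmax * _density(highest)
    return w


def mcode(net: nx.Graph, degree_cutoff: int = 2,
          node_score_cutoff: float = 0.2, k_core: int = 2,
          max_depth: int = 100, haircut: bool = True, fluff: bool = False,
          fluff_density: float = 0.1) -> list[Module]:
    """Dense-submodule detection (Bader-Hogue algorithm, standard parameters).

    Vertices are weighted by local core density, then greedily expanded
    from unvisited seeds in descending weight order, admitting neighbours
    whose weight reaches ``(1 - node_score_cutoff)`` times the seed weight
    within ``max_depth`` hops. Modules lacking a ``k_core``-core are
    discarded; ``haircut`` prunes singly-connected members; ``fluff``
    optionally adds halo neighbours with dense neighbourhoods. The module
    score is (density of the module subgraph) x (member count); modules are
    returned in descending score (ties: larger first, then by seed id).
    """
    if net.number_of_edges() == 0:
        return []
    w = _mcode_weights(net, degree_cutoff)
    visited = set()
    modules = []
    for seed in sorted(net.nodes, key=lambda v: (-w[v], str(v))):
        if seed in visited or w[seed] <= 0:
            continue
        threshold = w[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for u in net[v]:
                    if u in members or u in visited:
                        continue
                    if w[u] >= threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        visited |= members
        sub = net.subgraph(members).copy()
        core = nx.core_number(sub) if sub.number_of_nodes() else {}
        if not core or max(core.values()) < k_core:
            continue
        if haircut:
            sub.remove_nodes_from([v for v in list(sub.nodes)
                                   if sub.degree(v) < 2])
        if fluff:
            halo = set()
            for v in list(sub.nodes):
                for u in net[v]:
                    if u in sub or u in halo:
                        continue
                    nbhd = net.subgraph(set(net[u]) | {u})
                    if _density(nbhd) > fluff_density:
                        halo.add(u)
            sub = net.subgraph(set(sub.nodes) | halo).copy()
        if sub.number_of_nodes() == 0:
            continue
        modules.append(Module(tuple(sorted(sub.nodes, key=str)),
                              _density(sub) * sub.number_of_nodes(),
                              _density(sub), seed))
    modules.sort(key=lambda m: (-m.score, -m.size, str(m.seed)))
    return modules


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_network(net: nx.Graph, path, fmt: str = "edgelist") -> None:
    """Write the network as an edge-list TSV, SIF, or GraphML file.

    Edge rows are sorted by (source, target) for byte-stable output. The
    edge-list and GraphML formats round-trip all edge attributes; SIF keeps
    only the sign (as the interaction type) but preserves isolated nodes.
    """
    path = Path(path)
    edges = sorted(((min(str(u), str(v)), max(str(u), str(v)), d)
                    for u, v, d in net.edges(data=True)))
    if fmt == "edgelist":
        rows = [{"source": u, "target": v, "rho": d.get("rho", np.nan),
                 "p": d.get("p", np.nan), "sign": d.get("sign", "")}
                for u, v, d in edges]
        pd.DataFrame(rows, columns=["source", "target", "rho", "p", "sign"]) \
            .to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            linked = set()
            for u, v, d in edges:
                rel = "pp_neg" if d.get("sign") == "negative" else "pp_pos"
                fh.write(f"{u}\t{rel}\t{v}\n")
                linked.update((u, v))
            for v in sorted(str(v) for v in net.nodes):
                if v not in linked:
                    fh.write(f"{v}\n")
    elif fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_network(path, fmt: str = "edgelist") -> nx.Graph:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            g.add_edge(row["source"], row["target"], rho=float(row["rho"]),
                       p=float(row["p"]), sign=str(row["sign"]),
                       weight=abs(float(row["rho"])))
        return g
    if fmt == "sif":
        g = nx.Graph()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1 and parts[0]:
                    g.add_node(parts[0])
                elif len(parts) == 3:
                    sign = "negative" if parts[1] == "pp_neg" else "positive"
                    g.add_edge(parts[0], parts[2], sign=sign)
        return g
    if fmt == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown export format {fmt!r}")
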
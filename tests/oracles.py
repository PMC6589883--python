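"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity through different machinery than the
package (bitmask graph algebra, exhaustive subset enumeration, dynamic
programming over spans) so that agreement is informative.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from scipy.stats import studentized_range


@lru_cache(maxsize=4096)
def _q_quantile(prob: float, span: int, df: int) -> float:
    q = float(studentized_range.ppf(prob, span, df))
    return q if np.isfinite(q) else np.inf

# ---------------------------------------------------------------------------
# bitmask MCODE oracle
# ---------------------------------------------------------------------------

def graph_to_masks(graph) -> list[int]:
    """Adjacency as one bitmask per node; nodes must be 0..n-1 ints."""
    n = graph.number_of_nodes()
    masks = [0] * n
    for u, v in graph.edges():
        masks[u] |= 1 << v
        masks[v] |= 1 << u
    return masks


def _popcount(x: int) -> int:
    return bin(x).count("1")


def _members(mask: int) -> list[int]:
    return [i for i in range(mask.bit_length()) if mask >> i & 1]


def _connected(mask: int, masks: list[int]) -> bool:
    if mask == 0:
        return False
    start = 1 << (mask.bit_length() - 1)
    seen = start
    frontier = start
    while frontier:
        nxt = 0
        for v in _members(frontier):
            nxt |= masks[v] & mask & ~seen
        seen |= nxt
        frontier = nxt
    return seen == mask


def _degree_in(v: int, mask: int, masks: list[int]) -> int:
    return _popcount(masks[v] & mask)


def _core_numbers(mask: int, masks: list[int]) -> dict[int, int]:
    """Core decomposition of the induced subgraph by repeated peeling."""
    alive = mask
    core = {v: 0 for v in _members(mask)}
    k = 0
    while alive:
        while True:
            peel = [v for v in _members(alive)
                    if _degree_in(v, alive, masks) < k + 1]
            if not peel:
                break
            for v in peel:
                core[v] = k
                alive &= ~(1 << v)
        k += 1
    return core


def _subgraph_density(mask: int, masks: list[int]) -> float:
    vs = _members(mask)
    n = len(vs)
    if n < 2:
        return 0.0
    e = sum(_popcount(masks[v] & mask) for v in vs) // 2
    return 2.0 * e / (n * (n - 1))


def _vertex_weights(masks: list[int], degree_cutoff: int) -> list[float]:
    w = []
    for v in range(len(masks)):
        if _popcount(masks[v]) < degree_cutoff:
            w.append(0.0)
            continue
        nbhd = masks[v] | (1 << v)
        core = _core_numbers(nbhd, masks)
        kmax = max(core.values())
        top = 0
        for u, k in core.items():
            if k == kmax:
                top |= 1 << u
        w.append(kmax * _subgraph_density(top, masks))
    return w


def mcode_modules_oracle(masks: list[int], degree_cutoff: int = 2,
                         node_score_cutoff: float = 0.2, k_core: int = 2,
                         haircut: bool = True) -> list[tuple[float, tuple]]:
    """All modules by exhaustive closure search, as (score, members) sorted.

    For each seed (descending weight, ascending id) the candidate module is
    found by brute force: among all vertex subsets containing the seed,
    restricted to unvisited qualifying vertices, connected, and closed
    under admission, the (unique) maximal one is selected by enumeration.
    """
    n = len(masks)
    if not any(masks):
        return []
    w = _vertex_weights(masks, degree_cutoff)
    visited = 0
    modules = []
    for seed in sorted(range(n), key=lambda v: (-w[v], str(v))):
        if visited >> seed & 1 or w[seed] <= 0:
            continue
        threshold = w[seed] * (1.0 - node_score_cutoff)
        allowed = 1 << seed
        for u in range(n):
            if not (visited >> u & 1) and w[u] >= threshold:
                allowed |= 1 << u
        best = None
        for bits in range(1 << n):
            if not bits >> seed & 1 or bits & ~allowed:
                continue
            if not _connected(bits, masks):
                continue
            # closed: no admissible vertex outside is adjacent to the set
            reach = 0
            for v in _members(bits):
                reach |= masks[v]
            if reach & allowed & ~bits:
                continue
            if best is None or _popcount(bits) > _popcount(best):
                best = bits
        assert best is not None
        visited |= best
        core = _core_numbers(best, masks)
        if max(core.values()) < k_core:
            continue
        final = best
        if haircut:
            for v in _members(best):
                if _degree_in(v, best, masks) < 2:
                    final &= ~(1 << v)
        if final == 0:
            continue
        modules.append((_subgraph_density(final, masks) * _popcount(final),
                        tuple(_members(final))))
    modules.sort(key=lambda m: (-m[0], -len(m[1]), m[1]))
    return modules


# ---------------------------------------------------------------------------
# Duncan compact-letter-display oracle
# ---------------------------------------------------------------------------

def duncan_letters_oracle(groups, alpha: float = 0.05) -> list[str]:
    """Letters per group via exhaustive span testing with dynamic programming.

    Every contiguous span of the ordered means is tested directly against
    its least significant range, visiting spans from widest to narrowest;
    a span contained in an already-homogeneous span inherits homogeneity
    without testing. Letters follow from the maximal homogeneous spans.
    """
    arrs = [np.asarray(g, float) for g in groups]
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    df = int(ns.sum()) - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df
    n_h = k / np.sum(1.0 / ns)
    order = sorted(range(k), key=lambda i: (-means[i], i))
    m = means[order]

    declared = {}
    if mse == 0:
        for i in range(k):
            j = i
            while j + 1 < k and m[j + 1] == m[i]:
                j += 1
            if j > i:
                declared[(i, j)] = True
    else:
        for span in range(k, 1, -1):
            for i in range(0, k - span + 1):
                j = i + span - 1
                inside = any(a <= i and j <= b and declared[(a, b)]
                             for (a, b) in declared)
                if inside:
                    declared[(i, j)] = True
                    continue
                alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
                q = _q_quantile(1.0 - alpha_p, span, df)
                declared[(i, j)] = (m[i] - m[j]) <= q * np.sqrt(mse / n_h)

    homog = [s for s, ok in declared.items() if ok]
    maximal = [s for s in homog
               if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                          for o in homog)]
    covered = set()
    for a, b in maximal:
        covered.update(range(a, b + 1))
    maximal += [(i, i) for i in range(k) if i not in covered]
    maximal.sort()
    letters = [""] * k
    for idx, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + idx)
        for pos in range(a, b + 1):
            letters[order[pos]] += ch
    return letters


# ---------------------------------------------------------------------------
# misc small oracles
# ---------------------------------------------------------------------------

def spearman_p_montecarlo(x, y, n_draws: int, rng) -> float:
    """Two-sided permutation p for Spearman rho by Monte-Carlo sampling."""
    from scipy.stats import spearmanr

    obs = abs(spearmanr(x, y).statistic)
    y = np.asarray(y, float)
    hits = 0
    for _ in range(n_draws):
        hits += abs(spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12
    return hits / n_draws
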
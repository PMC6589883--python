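"""Antibiotic removal efficiency and group-comparison statistics.

Removal efficiency beta = (C' - C)/C' * 100 compares the residual
concentration C against the spiked level C'. Treatment/layer groups are
compared by one-way ANOVA followed by Duncan's multiple range test, whose
result is rendered as a compact letter display (groups sharing no letter
differ at the chosen alpha).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

__all__ = [
    "removal_efficiency",
    "AnovaResult",
    "anova_oneway",
    "DuncanResult",
    "duncan_letters",
    "removal_table",
]


def removal_efficiency(spike_c0: float, residual_c: float) -> float:
    """Removal efficiency beta = (C' - C)/C' * 100 (percent).

    ``spike_c0`` is the initial spiked concentration C' (mg kg^-1) and
    ``residual_c`` the residue C at the end of the run. A residue above the
    spike yields a negative efficiency and a warning, not an error.
    """
    if spike_c0 <= 0:
        raise ValueError("spike concentration must be positive")
    if residual_c < 0:
        raise ValueError("residual concentration cannot be negative")
    if residual_c > spike_c0:
        warnings.warn("residual exceeds spike; negative removal efficiency",
                      stacklevel=2)
    return (spike_c0 - residual_c) / spike_c0 * 100.0


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    mse: float
    group_means: np.ndarray
    group_ns: np.ndarray


def anova_oneway(groups) -> AnovaResult:
    """Classical one-way ANOVA between/within decomposition.

    ``groups`` is a sequence of 1-D arrays of replicate values, one per
    group. When the within-group variance is zero and all means are equal
    the F statistic is undefined and reported as ``nan``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("need at least two replicates per group")
    ns = np.array([a.size for a in arrs])
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b = len(arrs) - 1
    df_w = int(ns.sum()) - len(arrs)
    mse = ss_within / df_w
    if mse == 0:
        fval = np.nan if ss_between == 0 else np.inf
        p = np.nan if ss_between == 0 else 0.0
    else:
        fval = (ss_between / df_b) / mse
        p = float(f_dist.sf(fval, df_b, df_w))
    return AnovaResult(float(fval), float(p), df_b, df_w, mse, means, ns)


# ---------------------------------------------------------------------------
# Duncan's multiple range test + compact letter display
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuncanResult:
    letters: dict            # group label -> letter string
    means: dict              # group label -> mean
    alpha: float
    homogeneous_groups: tuple  # tuples of labels sharing a letter


from functools import lru_cache


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level for span p.

    alpha_p = 1 - (1 - alpha)^(p-1); the quantile is obtained by numeric
    inversion (cached: the inversion is expensive and the (p, df) grid
    small in practice).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = float(studentized_range.ppf(1.0 - alpha_p, p, df))
    # the numeric inversion can fail in the extreme upper tail; an infinite
    # critical range (nothing is significant) is the correct limit there
    return q if np.isfinite(q) else np.inf


def _least_significant_ranges(k: int, df: int, mse: float, n_h: float,
                              alpha: float) -> np.ndarray:
    """R_p for spans p = 2..k at Duncan's protection levels."""
    q = np.array([_duncan_q(alpha, p, df) for p in range(2, k + 1)])
    return q * np.sqrt(mse / n_h)


def duncan_letters(groups, alpha: float = 0.05, labels=None) -> DuncanResult:
    """Duncan's multiple range test rendered as a compact letter display.

    Means are ranked; a span of p consecutive ordered means is homogeneous
    when its range does not exceed the least significant range R_p, and the
    usual sequential rule applies (subranges of a non-significant range are
    not tested). Maximal homogeneous spans each receive one letter; groups
    sharing no letter differ at ``alpha``. Unbalanced designs use the
    harmonic mean of the group sizes.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(arrs))]
    labels = list(labels)
    if len(labels) != len(arrs):
        raise ValueError("labels and groups differ in length")
    k = len(arrs)
    means = {lab: float(a.mean()) for lab, a in zip(labels, arrs)}
    if k == 1:
        return DuncanResult({labels[0]: "a"}, means, alpha, (tuple(labels),))

    an = anova_oneway(arrs)
    n_h = k / float(np.sum(1.0 / an.group_ns))
    order = sorted(range(k), key=lambda i: (-an.group_means[i], labels[i]))
    m = np.array([an.group_means[i] for i in order])  # descending

    if an.mse == 0:
        # zero noise: distinct means are trivially separated
        spans = []
        i = 0
        while i < k:
            j = i
            while j + 1 < k and m[j + 1] == m[i]:
                j += 1
            spans.append((i, j))
            i = j + 1
    else:
        ranges = _least_significant_ranges(k, an.df_within, an.mse, n_h, alpha)

        homogeneous: set[tuple[int, int]] = set()

        def test(i: int, j: int) -> None:
            # span of p = j - i + 1 descending-ordered means; the same span
            # can be reached from both parents, hence the set
            if i >= j or (i, j) in homogeneous:
                return
            p = j - i + 1
            if m[i] - m[j] <= ranges[p - 2]:
                homogeneous.add((i, j))
                return
            test(i, j - 1)
            test(i + 1, j)

        test(0, k - 1)
        # keep maximal spans only; cover singletons not inside any span
        spans = [s for s in homogeneous
                 if not any(o != s and o[0] <= s[0] and s[1] <= o[1]
                            for o in homogeneous)]
        covered = set()
        for a, b in spans:
            covered.update(range(a, b + 1))
        spans += [(i, i) for i in range(k) if i not in covered]
        spans.sort()

    if len(spans) > len(string.ascii_lowercase):
        raise ValueError("too many distinct groups for a letter display")
    letters = {lab: "" for lab in labels}
    homogroups = []
    for letter, (a, b) in zip(string.ascii_lowercase, spans):
        members = [labels[order[i]] for i in range(a, b + 1)]
        homogroups.append(tuple(members))
        for lab in members:
            letters[lab] += letter
    return DuncanResult(letters, means, alpha, tuple(homogroups))


# ---------------------------------------------------------------------------
# tidy reporting
# ---------------------------------------------------------------------------

def removal_table(conc: pd.DataFrame, spike: float = 5.0,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-(treatment, layer) residuals and removal efficiencies with letters.

    ``conc`` is tidy with columns treatment, layer, replicate, analyte,
    concentration. Letters compare treatments within each (analyte, layer)
    stratum; the per-treatment average removal uses the mean residual
    across layers.
    """
    rows = []
    for (analyte, layer), sub in conc.groupby(["analyte", "layer"]):
        treatments = sorted(sub["treatment"].unique())
        groups = [sub.loc[sub["treatment"] == t, "concentration"].values
                  for t in treatments]
        if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
            letters = duncan_letters(groups, alpha, treatments).letters
        else:
            letters = {t: "a" for t in treatments}
        for t, g in zip(treatments, groups):
            rows.append({
                "analyte": analyte, "treatment": t, "layer": layer,
                "n": len(g), "mean_concentration": float(np.mean(g)),
                "sd": float(np.std(g, ddof=1)) if len(g) > 1 else 0.0,
                "removal_pct": removal_efficiency(spike, float(np.mean(g))),
                "letters": letters[t],
            })
    out = pd.DataFrame(rows)
    avg = (out.groupby(["analyte", "treatment"])["mean_concentration"]
           .mean().rename("mean_residual").reset_index())
    avg["average_removal_pct"] = [removal_efficiency(spike, c)
                                  for c in avg["mean_residual"]]
    return out.merge(avg, on=["analyte", "treatment"])
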
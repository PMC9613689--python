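"""Weighted coexpression networks and the venom-related module (VRM).

The network follows the weighted-coexpression construction: unsigned
adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with soft power ``beta = 4``,
topological overlap (TOM) similarity, average-linkage clustering of
``1 - TOM``, a static height cut, a minimum module size of 30, and
iterative merging of modules whose eigengenes correlate at >= 0.75
(merge threshold 0.25 on the dissimilarity scale).  A module eigengene
(ME) is the first principal component of the standardised module
submatrix; kME, a gene's Pearson correlation with an ME, measures its
connectivity to the module.

The VRM is the module capturing the most venom genes.  Cross-species
comparison of VRMs classifies each one-to-one ortholog as module-conserved
or module-shifted, tests whether shifts concentrate in non-venom genes
(chi-square), and compares |kME| between gene classes (rank-sum), probing
whether module turnover is confined to the network periphery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import Chi2Result, RankSumResult, chi2_2x2, wilcoxon_ranksum

__all__ = [
    "Network",
    "ModuleSet",
    "adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "kme",
    "identify_vrm",
    "vrm_absence_check",
    "module_shift_analysis",
]

SOFT_POWER = 4
MIN_MODULE_SIZE = 30
MERGE_THRESHOLD = 0.25
CUT_TAIL_FRACTION = 0.1
UNASSIGNED = "grey"


@dataclass
class Network:
    """Unsigned weighted network over genes; diagonal is zero by convention."""

    genes: list[str]
    adjacency: np.ndarray
    beta: float = SOFT_POWER

    @property
    def connectivity(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)


@dataclass
class ModuleSet:
    """Module labels plus per-module eigengenes and per-gene kME."""

    labels: pd.Series  # gene -> module label ('grey' = unassigned)
    eigengenes: pd.DataFrame  # samples x modules
    kme: pd.Series  # gene -> kME with its own module (nan for grey)

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def module_names(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


def adjacency(expr: pd.DataFrame, beta: float = SOFT_POWER) -> Network:
    """Unsigned adjacency |Pearson cor|^beta from a genes x samples matrix.

    Genes with zero expression everywhere are filtered out; genes constant
    across samples (correlation undefined) are dropped with a warning.
    """
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples to build a coexpression network")
    expr = expr.loc[(expr != 0).any(axis=1)]
    constant = expr.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s) from the network",
            stacklevel=2,
        )
        expr = expr.loc[~constant]
    mat = expr.to_numpy(dtype=float)
    corr = np.corrcoef(mat)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    return Network(genes=list(expr.index), adjacency=adj, beta=beta)


def tom(network: Network) -> np.ndarray:
    """Topological overlap matrix:
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    a = network.adjacency
    k = network.connectivity
    shared = a @ a  # diagonal of `a` is zero, so u != i, j contribute only
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    return t


def module_eigengene(expr: pd.DataFrame, module_genes: Sequence[str]) -> pd.Series:
    """Module eigengene: PC1 of the gene-standardised module submatrix.

    The sign is fixed so that the ME correlates non-negatively with the
    mean standardised module profile.  A single-gene module returns that
    gene's standardised profile.
    """
    if len(module_genes) == 0:
        raise ValueError("module is empty")
    sub = expr.loc[list(module_genes)].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    if z.shape[0] == 1:
        me = z[0]
    else:
        # PC1 over samples: leading right singular vector of genes x samples
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return pd.Series(me, index=expr.columns)


def kme(gene_profile: Sequence[float], me: Sequence[float]) -> float:
    """Module membership: Pearson correlation of a gene's profile with an ME."""
    g = np.asarray(gene_profile, dtype=float)
    m = np.asarray(me, dtype=float)
    if g.shape != m.shape:
        raise ValueError("profile and eigengene must have equal length")
    if g.std() == 0 or m.std() == 0:
        return float("nan")
    return float(np.corrcoef(g, m)[0, 1])


def detect_modules(
    expr: pd.DataFrame,
    beta: float = SOFT_POWER,
    min_size: int = MIN_MODULE_SIZE,
    merge_threshold: float = MERGE_THRESHOLD,
    cut_tail: float = CUT_TAIL_FRACTION,
) -> ModuleSet:
    """Detect coexpression modules from a genes x samples matrix.

    Average-linkage hierarchical clustering on 1 - TOM, cut at the largest
    gap between consecutive merge heights within the top ``cut_tail``
    fraction of merges (a static simplification of dynamic tree cutting:
    the gap separates between-module joins from within-module joins, and
    any over-splitting is repaired by the eigengene-merge step below).
    Clusters below ``min_size`` are unassigned ('grey'); modules with
    eigengene correlation >= 1 - merge_threshold are merged iteratively.
    Modules are labelled M1, M2, ... in decreasing size order.
    """
    net = adjacency(expr, beta=beta)
    expr = expr.loc[net.genes]
    n = len(net.genes)
    if n < min_size:
        warnings.warn(
            f"only {n} genes (< min module size {min_size}); all unassigned",
            stacklevel=2,
        )
        labels = pd.Series(UNASSIGNED, index=expr.index)
        return ModuleSet(
            labels=labels,
            eigengenes=pd.DataFrame(index=expr.columns),
            kme=pd.Series(np.nan, index=expr.index),
        )
    dissim = 1.0 - tom(net)
    np.fill_diagonal(dissim, 0.0)
    # guard tiny negative values from float round-off
    condensed = squareform(np.maximum(dissim, 0.0), checks=False)
    z = linkage(condensed, method="average")
    heights = np.sort(z[:, 2])
    m = heights.size
    tail = min(m - 1, max(10, int(np.ceil(cut_tail * m))))
    if tail < 1:
        cut_height = float(heights[-1])
    else:
        start = m - 1 - tail
        gaps = heights[start + 1 :] - heights[start:-1]
        i = start + int(np.argmax(gaps))
        cut_height = float((heights[i] + heights[i + 1]) / 2.0)
    raw = fcluster(z, t=cut_height, criterion="distance")

    labels = pd.Series(raw, index=expr.index).astype(object)
    sizes = labels.value_counts()
    for cluster, size in sizes.items():
        if size < min_size:
            labels[labels == cluster] = UNASSIGNED

    # rename surviving clusters by decreasing size
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    kept.sort(key=lambda c: (-sizes[c], c))
    rename = {c: f"M{i + 1}" for i, c in enumerate(kept)}
    labels = labels.map(lambda c: rename.get(c, UNASSIGNED))

    labels = _merge_similar_modules(expr, labels, merge_threshold)
    mes = _eigengene_table(expr, labels)
    kmes = _module_kme(expr, labels, mes)
    return ModuleSet(labels=labels, eigengenes=mes, kme=kmes)


def _eigengene_table(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    modules = sorted(set(labels) - {UNASSIGNED})
    data = {m: module_eigengene(expr, list(labels.index[labels == m])) for m in modules}
    return pd.DataFrame(data, index=expr.columns)


def _module_kme(
    expr: pd.DataFrame, labels: pd.Series, mes: pd.DataFrame
) -> pd.Series:
    out = pd.Series(np.nan, index=expr.index)
    for gene in expr.index:
        m = labels[gene]
        if m != UNASSIGNED and m in mes.columns:
            out[gene] = kme(expr.loc[gene], mes[m])
    return out


def _merge_similar_modules(
    expr: pd.DataFrame, labels: pd.Series, merge_threshold: float
) -> pd.Series:
    """Iteratively merge the most similar module pair while any eigengene
    correlation reaches 1 - merge_threshold."""
    labels = labels.copy()
    while True:
        mes = _eigengene_table(expr, labels)
        modules = list(mes.columns)
        if len(modules) < 2:
            break
        cors = np.corrcoef(mes.to_numpy().T)
        best, best_cor = None, 1.0 - merge_threshold
        for i in range(len(modules)):
            for j in range(i + 1, len(modules)):
                if cors[i, j] >= best_cor:
                    best, best_cor = (modules[i], modules[j]), cors[i, j]
        if best is None:
            break
        keep, absorb = sorted(best)
        labels[labels == absorb] = keep
    # renumber after merging so labels stay M1..Mk by size
    sizes = labels[labels != UNASSIGNED].value_counts()
    rename = {
        m: f"M{i + 1}"
        for i, m in enumerate(sorted(sizes.index, key=lambda m: (-sizes[m], m)))
    }
    return labels.map(lambda m: rename.get(m, UNASSIGNED))


def identify_vrm(modules: ModuleSet, venom_genes: Sequence[str]) -> tuple[str, float]:
    """The venom-related module: the module holding the most venom genes.

    Returns (module label, fraction of venom genes captured).  Ties break
    toward the lexicographically smaller label (logged).  Raises when no
    venom gene is assigned to any module.
    """
    venom = [g for g in venom_genes if g in modules.labels.index]
    if not venom:
        raise ValueError("no venom gene present in the module set")
    counts: dict[str, int] = {}
    for g in venom:
        m = modules.labels[g]
        if m != UNASSIGNED:
            counts[m] = counts.get(m, 0) + 1
    if not counts:
        raise ValueError("no venom gene assigned to any module")
    best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    winners = [m for m, c in counts.items() if c == best[1]]
    if len(winners) > 1:
        warnings.warn(
            f"VRM tie between modules {sorted(winners)}; "
            f"choosing {best[0]!r}",
            stacklevel=2,
        )
    return best[0], best[1] / len(venom)


def vrm_absence_check(
    expr: pd.DataFrame,
    sample_labels: Mapping[str, str],
    venom_genes: Sequence[str],
    vg_label: str = "venom_gland",
    dispersal_threshold: float = 0.5,
    **module_kwargs,
) -> dict[str, object]:
    """Rebuild the network without venom-gland samples and ask whether the
    venom genes still concentrate in one module.

    Reports the maximum venom-gene fraction captured by any module in the
    VG-free network and whether it falls below ``dispersal_threshold``
    (i.e. the VRM dispersed, evidencing venom-gland specificity).
    """
    vg_samples = [s for s in expr.columns if sample_labels.get(s) == vg_label]
    if not vg_samples:
        raise ValueError(f"no sample labelled {vg_label!r} to remove")
    reduced = expr.drop(columns=vg_samples)
    modules = detect_modules(reduced, **module_kwargs)
    venom = [g for g in venom_genes if g in modules.labels.index]
    assigned = [g for g in venom if modules.labels[g] != UNASSIGNED]
    counts: dict[str, int] = {}
    for g in assigned:
        m = modules.labels[g]
        counts[m] = counts.get(m, 0) + 1
    max_fraction = max(counts.values()) / len(venom) if counts and venom else 0.0
    return {
        "max_venom_fraction": max_fraction,
        "dispersed": max_fraction < dispersal_threshold,
        "modules": modules,
        "n_venom": len(venom),
    }


def module_shift_analysis(
    modules_a: ModuleSet,
    modules_b: ModuleSet,
    ortholog_map: Mapping[str, str],
    venom_genes_a: Sequence[str],
    vrm_a: str,
    vrm_b: str,
    shared_og_genes: set[str] | None = None,
) -> dict[str, object]:
    """Conservation vs shift of VRM members between two species.

    For each one-to-one ortholog whose species-A copy sits in the VRM of A:
    conserved iff its partner sits in the VRM of B (partners unassigned in B
    are excluded).  Returns the per-gene status, a chi-square test of shift
    counts in venom vs non-venom genes, |kME| rank lists of conserved vs
    shifted genes, and — when ``shared_og_genes`` is given — a rank-sum
    test of |kME| for shared-OG vs specific-OG non-venom VRM members.
    """
    vrm_members = modules_a.members(vrm_a)
    if not vrm_members:
        raise ValueError(f"VRM {vrm_a!r} of species A is empty")
    venom_set = set(venom_genes_a)

    status: dict[str, str] = {}
    for gene in vrm_members:
        partner = ortholog_map.get(gene)
        if partner is None or partner not in modules_b.labels.index:
            continue
        partner_module = modules_b.labels[partner]
        if partner_module == UNASSIGNED:
            continue
        status[gene] = "conserved" if partner_module == vrm_b else "shifted"

    table = np.zeros((2, 2), dtype=int)  # rows venom/non-venom, cols shifted/conserved
    for gene, st in status.items():
        row = 0 if gene in venom_set else 1
        col = 0 if st == "shifted" else 1
        table[row, col] += 1
    chi2: Chi2Result | None
    try:
        chi2 = chi2_2x2(table)
    except ValueError:
        chi2 = None

    abs_kme = modules_a.kme.abs()
    conserved_kme = sorted(
        (float(abs_kme[g]) for g, s in status.items() if s == "conserved"),
        reverse=True,
    )
    shifted_kme = sorted(
        (float(abs_kme[g]) for g, s in status.items() if s == "shifted"),
        reverse=True,
    )

    connectivity_test: RankSumResult | None = None
    if shared_og_genes is not None:
        nonvenom = [g for g in vrm_members if g not in venom_set]
        shared = [float(abs_kme[g]) for g in nonvenom if g in shared_og_genes]
        specific = [float(abs_kme[g]) for g in nonvenom if g not in shared_og_genes]
        if shared and specific:
            connectivity_test = wilcoxon_ranksum(shared, specific)

    n = len(status)
    n_shift = sum(s == "shifted" for s in status.values())
    return {
        "status": status,
        "shift_rate": n_shift / n if n else float("nan"),
        "shift_table": table,
        "shift_chi2": chi2,
        "conserved_kme": conserved_kme,
        "shifted_kme": shifted_kme,
        "connectivity_test": connectivity_test,
    }
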
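"""Comparative analysis of two condition-specific networks.

Covers differential node centrality (median of betweenness / closeness /
degree ranks, compared between conditions by absolute rank difference),
bridge-gene discovery (non-DE genes adjacent to >= 2 differentially
expressed genes), one-tailed Kolmogorov-Smirnov gene-set enrichment on a
ranked gene list, hypergeometric overrepresentation, and cross-network
module similarity by gene content.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from conet.inference import ModulePartition, WeightedNetwork


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="fdr_bh")[1]


@dataclasses.dataclass
class EnrichmentResult:
    """One gene-set enrichment test result."""

    set_id: str
    statistic: float
    pval: float
    adj_pval: float = np.nan
    direction: str = "top"


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

def _rank_desc(values: pd.Series) -> pd.Series:
    """Integer ranks 1..N, largest value first, ties broken by gene id."""
    order = sorted(values.index, key=lambda g: (-values[g], g))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(values.index)


def centrality_ranks(network: WeightedNetwork) -> pd.DataFrame:
    """Betweenness, closeness and degree centralities with per-measure ranks.

    Centralities are computed on the unweighted consensus topology;
    betweenness is the unnormalized shortest-path pair count and closeness
    is the harmonic variant (well defined on disconnected graphs). Ranks are
    1 = most central, ties broken by gene id; the median of the three
    integer ranks summarizes each gene.
    """
    if not network.genes:
        raise ValueError("empty network")
    g = network.to_networkx()
    btw = pd.Series(nx.betweenness_centrality(g, normalized=False))
    clo = pd.Series(nx.harmonic_centrality(g), dtype=float)
    deg = pd.Series(dict(g.degree()), dtype=float)
    table = pd.DataFrame(
        {"betweenness": btw, "closeness": clo, "degree": deg}
    ).reindex(network.genes)
    for measure in ("betweenness", "closeness", "degree"):
        table[f"rank_{measure}"] = _rank_desc(table[measure])
    table["median_rank"] = table[
        ["rank_betweenness", "rank_closeness", "rank_degree"]
    ].median(axis=1)
    return table.rename_axis("gene")


def differential_centrality(
    table_case: pd.DataFrame, table_ctrl: pd.DataFrame
) -> pd.DataFrame:
    """Absolute difference of per-gene median centrality ranks between two
    networks, sorted descending (ties by gene id)."""
    if set(table_case.index) != set(table_ctrl.index):
        raise ValueError("centrality tables cover different gene universes")
    out = pd.DataFrame(
        {
            "median_rank_case": table_case["median_rank"],
            "median_rank_ctrl": table_ctrl["median_rank"].reindex(table_case.index),
        }
    )
    out["difference"] = (out["median_rank_case"] - out["median_rank_ctrl"]).abs()
    out = out.rename_axis("gene").reset_index()
    out = out.sort_values(
        by=["difference", "gene"], ascending=[False, True], kind="stable"
    )
    return out.set_index("gene")


# ---------------------------------------------------------------------------
# bridge genes
# ---------------------------------------------------------------------------

def bridge_genes(
    network: WeightedNetwork, deg_set: Iterable[str], strict: bool = False
) -> pd.DataFrame:
    """Non-DE genes adjacent to >= 2 DEGs, with the number of DEG pairs they
    connect.

    ``pairs`` counts all C(k, 2) pairs of DEG neighbors by default; with
    ``strict`` only DEG pairs that are not themselves directly adjacent are
    counted. Sorted by pairs descending, gene id ascending.
    """
    deg_set = set(deg_set)
    unknown = deg_set - set(network.genes)
    if unknown:
        raise ValueError(f"DEG ids outside the network universe: {sorted(unknown)[:5]}")
    if not deg_set:
        return pd.DataFrame(
            columns=["n_deg_neighbors", "pairs"], index=pd.Index([], name="gene")
        )
    adj = network.weights > 0
    idx = {g: i for i, g in enumerate(network.genes)}
    deg_idx = {idx[g] for g in deg_set}
    rows = []
    for g in network.genes:
        if g in deg_set:
            continue
        i = idx[g]
        neigh = [j for j in np.nonzero(adj[i])[0] if j in deg_idx]
        k = len(neigh)
        if k < 2:
            continue
        if strict:
            pairs = sum(1 for a, b in combinations(neigh, 2) if not adj[a, b])
            if pairs == 0:
                continue
        else:
            pairs = k * (k - 1) // 2
        rows.append((g, k, pairs))
    out = pd.DataFrame(rows, columns=["gene", "n_deg_neighbors", "pairs"])
    out = out.sort_values(by=["pairs", "gene"], ascending=[False, True], kind="stable")
    return out.set_index("gene")


def condition_specific_bridges(
    bridge_case: pd.DataFrame, bridge_ctrl: pd.DataFrame
) -> set[str]:
    """Genes acting as bridges in the case network but not in the control one."""
    return set(bridge_case.index) - set(bridge_ctrl.index)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def ks_gsea(
    ranked_genes: Sequence[str], gene_set: Iterable[str], set_id: str = "set"
) -> EnrichmentResult:
    """One-tailed one-sample KS enrichment of a gene set toward the top of a
    ranked list.

    The normalized rank positions r/N of the set members are tested against
    the uniform distribution with the one-sided alternative "shifted toward
    the top" (empirical CDF above uniform, D+ statistic).
    """
    positions = [i + 1 for i, g in enumerate(ranked_genes) if g in set(gene_set)]
    if not positions:
        raise ValueError("gene set has no member in the ranked list")
    n = len(ranked_genes)
    x = np.asarray(positions, dtype=float) / n
    if len(positions) == n:
        return EnrichmentResult(set_id=set_id, statistic=0.0, pval=1.0)
    res = stats.ks_1samp(x, stats.uniform.cdf, alternative="greater")
    return EnrichmentResult(set_id=set_id, statistic=float(res.statistic), pval=float(res.pvalue))


def overrepresentation(
    module_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Sequence[str],
    set_id: str = "set",
) -> EnrichmentResult:
    """Upper-tail hypergeometric test of the module / gene-set overlap."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    module = set(module_genes) & uni
    members = set(gene_set) & uni
    k = len(module & members)
    p = stats.hypergeom.sf(k - 1, len(uni), len(members), len(module))
    return EnrichmentResult(set_id=set_id, statistic=float(k), pval=float(p))


def module_similarity(
    partition_a: ModulePartition, partition_b: ModulePartition
) -> pd.DataFrame:
    """Gene-content similarity of every module pair across two partitions.

    Each pair is scored by the upper-tail hypergeometric p of its gene
    overlap over the shared universe, BH-adjusted across all pairs.
    """
    uni_a = set(partition_a.assignments.index)
    uni_b = set(partition_b.assignments.index)
    if uni_a != uni_b:
        raise ValueError("partitions cover different gene universes")
    universe = sorted(uni_a)
    rows = []
    for ma in partition_a.modules:
        ga = set(partition_a.genes_of(ma))
        for mb in partition_b.modules:
            gb = set(partition_b.genes_of(mb))
            res = overrepresentation(ga, gb, universe)
            rows.append((ma, mb, len(ga), len(gb), int(res.statistic), res.pval))
    out = pd.DataFrame(
        rows, columns=["module_a", "module_b", "size_a", "size_b", "overlap", "pval"]
    )
    out["adj_pval"] = bh_adjust(out["pval"])
    return out.sort_values(by=["pval", "module_a", "module_b"]).reset_index(drop=True)


__all__ = [
    "EnrichmentResult",
    "bh_adjust",
    "centrality_ranks",
    "differential_centrality",
    "bridge_genes",
    "condition_specific_bridges",
    "ks_gsea",
    "overrepresentation",
    "module_similarity",
]
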
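"""Consensus co-expression network inference.

One condition's network is built from an ensemble of 3 inference algorithms
(CLR, ARACNE, MRNET) x 7 association estimators (Pearson, Spearman, Kendall
correlations as absolute values; mutual information under the empirical,
Miller-Madow, Schurmann-Grassberger and James-Stein shrinkage entropy
estimators) = 21 member networks, aggregated by Borda mean edge rank and
thresholded at a target edge density. Communities of the consensus network
are detected with the Walktrap random-walk algorithm.

Mutual information is computed on per-gene equal-frequency discretized data
as I(X;Y) = H(X) + H(Y) - H(X,Y), where each entropy term uses the chosen
estimator:

* empirical — plug-in on observed cell frequencies;
* Miller-Madow — plug-in plus the asymptotic bias correction
  (occupied_cells - 1) / (2 n);
* Schurmann-Grassberger — plug-in on Dirichlet-smoothed frequencies with
  pseudo-count 1/K per cell (K = number of cells of the table);
* shrinkage — plug-in on James-Stein-shrunk frequencies, shrinking the
  observed cell frequencies toward the uniform distribution with the
  analytic optimal intensity.

Entropies are in nats; only the relative order of scores matters to the
rank-based consensus.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.special import xlogy
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

CORRELATION_ESTIMATORS = ("pearson", "spearman", "kendall")
MI_ESTIMATORS = ("mi_empirical", "mi_millermadow", "mi_sg", "mi_shrink")
ESTIMATORS = CORRELATION_ESTIMATORS + MI_ESTIMATORS
ALGORITHMS = ("clr", "aracne", "mrnet")


@dataclasses.dataclass
class AssociationMatrix:
    """Symmetric gene x gene association scores with zero diagonal."""

    genes: list[str]
    values: np.ndarray
    estimator: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.genes), len(self.genes)):
            raise ValueError("association matrix shape does not match gene list")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("association matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v


@dataclasses.dataclass
class WeightedNetwork:
    """Undirected weighted gene network over a fixed node set.

    Edges are the strictly positive entries of the symmetric ``weights``
    matrix; zero means no edge. ``provenance`` records how the network was
    obtained (e.g. ``"clr:pearson"`` or ``"consensus"``).
    """

    genes: list[str]
    weights: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(w, w.T, atol=1e-8):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("edge weights must be positive")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_edges(self) -> int:
        return int((np.triu(self.weights, 1) > 0).sum())

    def edge_list(self) -> pd.DataFrame:
        """3-column edge list, gene_a < gene_b lexicographically."""
        iu, ju = np.triu_indices(len(self.genes), 1)
        mask = self.weights[iu, ju] > 0
        rows = []
        for i, j in zip(iu[mask], ju[mask]):
            a, b = sorted((self.genes[i], self.genes[j]))
            rows.append((a, b, self.weights[i, j]))
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    def write_tsv(self, path: str | Path) -> None:
        self.edge_list().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path: str | Path, genes: Sequence[str] | None = None) -> "WeightedNetwork":
        tab = pd.read_csv(path, sep="\t")
        if genes is None:
            genes = sorted(set(tab["gene_a"]) | set(tab["gene_b"]))
        genes = list(genes)
        idx = {g: i for i, g in enumerate(genes)}
        w = np.zeros((len(genes), len(genes)))
        for a, b, wt in tab.itertuples(index=False):
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = wt
        return cls(genes=genes, weights=w, provenance=str(path))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        iu, ju = np.triu_indices(len(self.genes), 1)
        mask = self.weights[iu, ju] > 0
        g.add_weighted_edges_from(
            (self.genes[i], self.genes[j], self.weights[i, j])
            for i, j in zip(iu[mask], ju[mask])
        )
        return g

    def to_igraph(self) -> ig.Graph:
        iu, ju = np.triu_indices(len(self.genes), 1)
        mask = self.weights[iu, ju] > 0
        g = ig.Graph(
            n=len(self.genes),
            edges=list(zip(iu[mask].tolist(), ju[mask].tolist())),
        )
        g.vs["name"] = self.genes
        g.es["weight"] = self.weights[iu[mask], ju[mask]].tolist()
        return g


@dataclasses.dataclass
class ModulePartition:
    """Assignment of network genes to modules (1-based ids, largest first).

    Modules smaller than ``min_size`` are kept in the partition but flagged
    excluded from downstream enrichment.
    """

    assignments: pd.Series  # gene -> module id
    min_size: int = 10

    @property
    def module_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()

    @property
    def modules(self) -> list[int]:
        return sorted(self.assignments.unique())

    @property
    def analysable_modules(self) -> list[int]:
        sizes = self.module_sizes
        return sorted(int(m) for m in sizes.index[sizes >= self.min_size])

    @property
    def excluded_modules(self) -> list[int]:
        sizes = self.module_sizes
        return sorted(int(m) for m in sizes.index[sizes < self.min_size])

    def genes_of(self, module: int) -> list[str]:
        return list(self.assignments.index[self.assignments == module])

    def write_tsv(self, path: str | Path) -> None:
        df = self.assignments.rename("module_id").rename_axis("gene").reset_index()
        df["excluded"] = df["module_id"].isin(self.excluded_modules)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, min_size: int = 10) -> "ModulePartition":
        df = pd.read_csv(path, sep="\t")
        return cls(df.set_index("gene")["module_id"], min_size=min_size)


# ---------------------------------------------------------------------------
# discretization and association estimation
# ---------------------------------------------------------------------------

def discretize(x: np.ndarray | pd.DataFrame, n_bins: int | None = None) -> np.ndarray:
    """Per-gene equal-frequency binning of a genes x samples matrix.

    Default number of bins is ceil(sqrt(n_samples)). Ties spanning a bin
    boundary are resolved by stable sample order; constant genes collapse to
    a single bin.
    """
    x = np.asarray(x, dtype=float)
    n_genes, n_samples = x.shape
    if n_bins is None:
        n_bins = math.ceil(math.sqrt(n_samples))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    out = np.zeros((n_genes, n_samples), dtype=np.int64)
    bin_of_pos = np.arange(n_samples) * n_bins // n_samples
    n_constant = 0
    for g in range(n_genes):
        row = x[g]
        if row.min() == row.max():
            n_constant += 1
            continue
        order = np.argsort(row, kind="stable")
        out[g, order] = bin_of_pos
    if n_constant:
        logger.info("discretize: %d constant gene(s) collapsed to one bin", n_constant)
    return out


def _abs_corr(x: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    if method in ("pearson", "spearman"):
        sd = x.std(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.corrcoef(x)
        c = np.nan_to_num(c, nan=0.0)
        c[sd == 0, :] = 0.0
        c[:, sd == 0] = 0.0
        return np.abs(c)
    # Kendall tau-b via pairwise sample-pair sign concordance
    n = x.shape[1]
    iu, ju = np.triu_indices(n, 1)
    s = np.sign(x[:, iu] - x[:, ju])
    num = s @ s.T
    n0 = iu.size
    non_tied = np.abs(s).sum(axis=1)  # n0 - (#tied sample pairs) per gene
    denom = np.sqrt(np.outer(non_tied, non_tied))
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom > 0, num / denom, 0.0)
    return np.abs(tau.astype(float))


def _mi_matrix(d: np.ndarray, n_bins: int, estimator: str) -> np.ndarray:
    """All-pairs mutual information from discretized data (genes x samples)."""
    n_genes, m = d.shape
    k = n_bins
    one_hot = np.zeros((k, n_genes, m), dtype=np.float32)
    for b in range(k):
        one_hot[b] = d == b
    counts_marg = one_hot.sum(axis=2).T.astype(np.float64)  # genes x bins

    def marginal_entropy(counts: np.ndarray, n_cells: int) -> np.ndarray:
        p = counts / m
        h = np.log(m) - xlogy(counts, counts).sum(axis=-1) / m
        if estimator == "mi_empirical":
            return h
        if estimator == "mi_millermadow":
            occupied = (counts > 0).sum(axis=-1)
            return h + (occupied - 1) / (2.0 * m)
        if estimator == "mi_sg":
            sm = counts + 1.0 / n_cells
            tot = m + 1.0
            return np.log(tot) - xlogy(sm, sm).sum(axis=-1) / tot
        if estimator == "mi_shrink":
            ss = (p**2).sum(axis=-1)
            lam = _shrink_lambda(ss, m, n_cells)
            q = lam[..., None] / n_cells + (1 - lam[..., None]) * p
            return -xlogy(q, q).sum(axis=-1)
        raise ValueError(f"unknown estimator {estimator!r}")

    def _shrink_lambda(ss: np.ndarray, m: int, n_cells: int) -> np.ndarray:
        denom = (m - 1) * (ss - 1.0 / n_cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = np.where(denom > 0, (1.0 - ss) / denom, 1.0)
        return np.clip(lam, 0.0, 1.0)

    h_marg = marginal_entropy(counts_marg, k)

    # pairwise joint entropies, accumulated over the k*k joint cells
    k2 = k * k
    if estimator in ("mi_empirical", "mi_millermadow"):
        s_emp = np.zeros((n_genes, n_genes))
        occ = np.zeros((n_genes, n_genes))
        for a in range(k):
            for b in range(k):
                c = (one_hot[a] @ one_hot[b].T).astype(float)
                s_emp += xlogy(c, c)
                if estimator == "mi_millermadow":
                    occ += c > 0
        h_joint = np.log(m) - s_emp / m
        if estimator == "mi_millermadow":
            h_joint += (occ - 1) / (2.0 * m)
    elif estimator == "mi_sg":
        s_sg = np.zeros((n_genes, n_genes))
        for a in range(k):
            for b in range(k):
                c = (one_hot[a] @ one_hot[b].T).astype(float) + 1.0 / k2
                s_sg += xlogy(c, c)
        tot = m + 1.0
        h_joint = np.log(tot) - s_sg / tot
    elif estimator == "mi_shrink":
        ss_joint = np.zeros((n_genes, n_genes))
        for a in range(k):
            for b in range(k):
                c = (one_hot[a] @ one_hot[b].T).astype(float)
                ss_joint += (c / m) ** 2
        lam = _shrink_lambda(ss_joint, m, k2)
        h_joint = np.zeros((n_genes, n_genes))
        for a in range(k):
            for b in range(k):
                c = (one_hot[a] @ one_hot[b].T).astype(float)
                q = lam / k2 + (1 - lam) * (c / m)
                h_joint -= xlogy(q, q)
        # zero cells outside the loop are covered: the loop visits every cell
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    mi = h_marg[:, None] + h_marg[None, :] - h_joint
    mi = np.maximum(0.5 * (mi + mi.T), 0.0)
    return mi


def association_matrix(
    expr: pd.DataFrame | np.ndarray,
    estimator: str,
    genes: Sequence[str] | None = None,
    n_bins: int | None = None,
) -> AssociationMatrix:
    """All-pairs association scores of a genes x samples expression slice.

    Correlation estimators return absolute values in [0, 1]; MI estimators
    operate on equal-frequency discretized data (default ceil(sqrt(n))
    bins). Constant genes get an all-zero association row.
    """
    if isinstance(expr, pd.DataFrame):
        genes = list(expr.index)
        x = expr.to_numpy(dtype=float)
    else:
        x = np.asarray(expr, dtype=float)
        genes = list(genes) if genes is not None else [f"g{i}" for i in range(x.shape[0])]
    if x.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    if estimator in CORRELATION_ESTIMATORS:
        values = _abs_corr(x, estimator)
    else:
        if n_bins is None:
            n_bins = math.ceil(math.sqrt(x.shape[1]))
        d = discretize(x, n_bins)
        values = _mi_matrix(d, n_bins, estimator)
        constant = x.min(axis=1) == x.max(axis=1)
        values[constant, :] = 0.0
        values[:, constant] = 0.0
    np.fill_diagonal(values, 0.0)
    return AssociationMatrix(genes=genes, values=values, estimator=estimator)


# ---------------------------------------------------------------------------
# inference algorithms
# ---------------------------------------------------------------------------

def _clr(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    mu = np.array([a[i, off[i]].mean() for i in range(n)])
    sd = np.array([a[i, off[i]].std() for i in range(n)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (a - mu[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    z = np.where(sd[:, None] > 0, z, 0.0)
    z = np.maximum(z, 0.0)
    w = np.sqrt(z**2 + z.T**2)
    np.fill_diagonal(w, 0.0)
    return w


def _aracne(a: np.ndarray, eps: float) -> np.ndarray:
    """Data Processing Inequality pruning: in every triangle of present
    edges, the strictly weakest edge is removed when it is more than ``eps``
    below both others. Marking uses the original weights."""
    w = a.copy()
    n = a.shape[0]
    remove = np.zeros_like(a, dtype=bool)
    present = a > 0
    for k in range(n):
        ik = a[:, k][:, None]  # a[i,k]
        jk = a[k, :][None, :]  # a[k,j]
        ok = present[:, k][:, None] & present[k, :][None, :]
        cond = ok & (a < ik - eps) & (a < jk - eps) & present
        remove |= cond
    remove[np.arange(n), np.arange(n)] = False
    w[remove | remove.T] = 0.0
    return w


def _mrnet(a: np.ndarray) -> np.ndarray:
    """Per-target forward max-relevance min-redundancy selection; the edge
    score of a selected variable is its MRMR criterion at selection time,
    symmetrized by the max over the two directions."""
    n = a.shape[0]
    scores = np.full((n, n), -np.inf)
    for t in range(n):
        rel = a[:, t].copy()
        rel[t] = -np.inf
        red_sum = np.zeros(n)
        selected: list[int] = []
        available = np.ones(n, dtype=bool)
        available[t] = False
        while available.any():
            if selected:
                crit = rel - red_sum / len(selected)
            else:
                crit = rel.copy()
            crit[~available] = -np.inf
            j = int(np.argmax(crit))
            if crit[j] <= 0:
                break
            scores[j, t] = crit[j]
            available[j] = False
            selected.append(j)
            red_sum += a[:, j]
    w = np.maximum(scores, scores.T)
    w[w < 0] = 0.0
    w[~np.isfinite(w)] = 0.0
    np.fill_diagonal(w, 0.0)
    return w


def infer_network(
    assoc: AssociationMatrix, algorithm: str, eps: float = 0.0
) -> WeightedNetwork:
    """Run one inference algorithm (clr / aracne / mrnet) on an association matrix."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    a = assoc.values
    if (a < 0).any():
        raise ValueError("association scores must be non-negative")
    if algorithm == "clr":
        w = _clr(a)
    elif algorithm == "aracne":
        w = _aracne(a, eps)
    else:
        w = _mrnet(a)
    return WeightedNetwork(
        genes=assoc.genes, weights=w, provenance=f"{algorithm}:{assoc.estimator}"
    )


def consensus_network(
    members: Sequence[WeightedNetwork], density: float
) -> WeightedNetwork:
    """Borda rank aggregation of member networks, thresholded at ``density``.

    Each member ranks all gene pairs by decreasing edge weight (average ranks
    for ties; absent edges share the worst, tied, rank). The consensus score
    of a pair is the mean rank across members; the top
    floor(density * n(n-1)/2) pairs become edges with weight
    1 - (mean_rank - 1)/M in (0, 1].
    """
    if not members:
        raise ValueError("empty member list")
    if not (0 < density <= 1):
        raise ValueError("density must be in (0, 1]")
    genes = members[0].genes
    for mbr in members[1:]:
        if mbr.genes != genes:
            raise ValueError("member networks must share the node set")
    n = len(genes)
    n_pairs = n * (n - 1) // 2
    mean_rank = np.zeros(n_pairs)
    for mbr in members:
        w = squareform(mbr.weights, checks=False)
        mean_rank += rankdata(-w, method="average")
    mean_rank /= len(members)
    n_edges = int(math.floor(density * n_pairs))
    # deterministic selection: best mean rank first, ties by pair order
    order = np.lexsort((np.arange(n_pairs), mean_rank))
    keep = order[:n_edges]
    wvec = np.zeros(n_pairs)
    wvec[keep] = 1.0 - (mean_rank[keep] - 1.0) / n_pairs
    return WeightedNetwork(
        genes=list(genes), weights=squareform(wvec), provenance="consensus"
    )


def ensemble_consensus(
    expr: pd.DataFrame,
    density: float,
    estimators: Sequence[str] = ESTIMATORS,
    algorithms: Sequence[str] = ALGORITHMS,
    eps: float = 0.0,
    n_bins: int | None = None,
) -> WeightedNetwork:
    """Full pipeline for one condition: estimators x algorithms -> consensus."""
    members = []
    for est in estimators:
        assoc = association_matrix(expr, est, n_bins=n_bins)
        for alg in algorithms:
            members.append(infer_network(assoc, alg, eps=eps))
    return consensus_network(members, density)


# ---------------------------------------------------------------------------
# community detection
# ---------------------------------------------------------------------------

def detect_communities(
    network: WeightedNetwork, steps: int = 4, min_size: int = 10
) -> ModulePartition:
    """Walktrap communities of the network at the maximum-modularity cut.

    Isolated nodes become singleton modules. Module ids are 1-based,
    assigned by decreasing module size (ties by smallest member gene id);
    modules below ``min_size`` are flagged excluded.
    """
    if not network.genes:
        raise ValueError("empty network")
    g = network.to_igraph()
    if g.ecount() == 0:
        membership = list(range(g.vcount()))
    else:
        dend = g.community_walktrap(weights="weight", steps=steps)
        membership = dend.as_clustering().membership
    ser = pd.Series(membership, index=network.genes)
    groups = sorted(
        ser.groupby(ser).groups.items(),
        key=lambda kv: (-len(kv[1]), min(kv[1])),
    )
    relabel = {old: i + 1 for i, (old, _) in enumerate(groups)}
    return ModulePartition(
        assignments=ser.map(relabel).rename_axis("gene"), min_size=min_size
    )


__all__ = [
    "ESTIMATORS",
    "ALGORITHMS",
    "AssociationMatrix",
    "WeightedNetwork",
    "ModulePartition",
    "discretize",
    "association_matrix",
    "infer_network",
    "consensus_network",
    "ensemble_consensus",
    "detect_communities",
]
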
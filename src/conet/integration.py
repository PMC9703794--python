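"""Per-dataset differential expression and cross-dataset integration statistics.

The integration layer mirrors a limma-style meta-analysis of many two-arm
studies: each dataset is tested gene-wise with a moderated two-group t-test
(empirical-Bayes variance shrinkage fitted by moments across genes), p values
are Benjamini-Hochberg adjusted within the dataset, and three cross-dataset
statistics are derived per gene:

* occurrence — the number of datasets in which the gene is differentially
  expressed (adjusted p <= alpha);
* consistency score Cg = \\|upDatasets - downDatasets\\|, with full
  consistency when every call shares one sign;
* significance score ss = \\|log2FC\\| * (-log10 adjusted p), a non-negative
  per-dataset magnitude of deregulation used for ranking.

Cross-platform merging uses simple batch mean-adjustment: per gene and batch,
subtract the batch mean and add back the grand mean.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from conet.datasets import LESIONAL, NON_LESIONAL, ExpressionDataset, GeneSetCollection

ADJP_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# moderated two-group t statistic (empirical-Bayes variance shrinkage)
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    # Newton iteration on y -> trigamma(y), as used for fitting the prior df
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of the scaled inverse-chi-square prior (d0, s0^2) to the
    distribution of log sample variances across genes."""
    ok = s2 > 0
    if not ok.any():
        return np.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if ok.sum() < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def moderated_ttest(
    x_case: np.ndarray, x_ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gene-wise moderated t-test of case vs control (rows = genes).

    Returns (logFC, t, p). The pooled per-gene variance is shrunk toward a
    prior fitted across genes: s2_post = (d0*s0^2 + dg*s2_g) / (d0 + dg),
    and the t statistic has d0 + dg degrees of freedom.
    """
    n1, n2 = x_case.shape[1], x_ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each arm needs >= 2 samples")
    dg = n1 + n2 - 2
    logfc = x_case.mean(axis=1) - x_ctrl.mean(axis=1)
    ss1 = ((x_case - x_case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x_ctrl - x_ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / dg
    d0, s02 = _fit_variance_prior(s2, dg)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02) if s02 > 0 else s2
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    # degenerate genes: zero residual variance in both arms
    zero_se = se == 0
    if zero_se.any():
        with np.errstate(invalid="ignore"):
            p = np.where(zero_se & (logfc == 0), 1.0, p)
            p = np.where(zero_se & (logfc != 0), 0.0, p)
            t = np.where(zero_se & (logfc != 0), np.sign(logfc) * np.inf, t)
    return logfc, t, p


def welch_ttest(
    x_case: np.ndarray, x_ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain Welch t-test fallback (rows = genes)."""
    if x_case.shape[1] < 2 or x_ctrl.shape[1] < 2:
        raise ValueError("each arm needs >= 2 samples")
    logfc = x_case.mean(axis=1) - x_ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(x_case, x_ctrl, axis=1, equal_var=False)
    bad = ~np.isfinite(p)
    if bad.any():
        p = np.where(bad & (logfc == 0), 1.0, p)
        p = np.where(bad & (logfc != 0), 0.0, p)
        t = np.where(bad, np.sign(logfc) * np.inf, t)
    return logfc, np.asarray(t), np.asarray(p)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def significance_score(logfc, adjpval):
    """ss = \\|log2FC\\| * (-log10 adjusted p); adjusted p floored at 1e-300.

    Scalar or vectorized. Raises for adjusted p outside (0, 1].
    """
    logfc = np.asarray(logfc, dtype=float)
    adjp = np.asarray(adjpval, dtype=float)
    if np.any(adjp <= 0) or np.any(adjp > 1):
        raise ValueError("adjusted p values must lie in (0, 1]")
    ss = np.abs(logfc) * (-np.log10(np.maximum(adjp, ADJP_FLOOR)))
    return float(ss) if ss.ndim == 0 else ss


def differential_expression(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    method: str = "moderated",
    case: str = LESIONAL,
    control: str = NON_LESIONAL,
) -> pd.DataFrame:
    """Per-gene two-group test of ``case`` vs ``control`` with BH adjustment.

    Returns a DataFrame indexed by gene with columns logFC, pval, adj_pval,
    direction (up/down/ns at adjusted p <= alpha) and ss.
    """
    conds = set(dataset.condition.unique())
    if not {case, control} <= conds:
        raise ValueError(
            f"dataset {dataset.dataset_id} lacks conditions {case!r}/{control!r}: {sorted(conds)}"
        )
    x1 = dataset.subset_condition(case).to_numpy(dtype=float)
    x2 = dataset.subset_condition(control).to_numpy(dtype=float)
    if method == "moderated":
        logfc, _, p = moderated_ttest(x1, x2)
    elif method == "welch":
        logfc, _, p = welch_ttest(x1, x2)
    else:
        raise ValueError(f"unknown method {method!r}")
    adj = multipletests(p, method="fdr_bh")[1]
    direction = np.where(
        adj <= alpha, np.where(logfc > 0, "up", np.where(logfc < 0, "down", "ns")), "ns"
    )
    adj_floor = np.maximum(adj, ADJP_FLOOR)
    table = pd.DataFrame(
        {
            "logFC": logfc,
            "pval": p,
            "adj_pval": adj,
            "direction": direction,
            "ss": significance_score(logfc, adj_floor),
        },
        index=pd.Index(dataset.genes, name="gene"),
    )
    return table


def occurrence_ranking(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cross-dataset occurrence and consistency of differential expression.

    Per gene: occurrence (datasets where DE), up/down dataset counts, the
    consistency score Cg = \\|up - down\\| and the full-consistency flag
    (min(up, down) == 0). Genes are ordered by occurrence (desc), median ss
    across datasets (desc), gene id (asc).
    """
    if not tables:
        raise ValueError("empty table list")
    genes = tables[0].index
    for t in tables[1:]:
        if not genes.equals(t.index):
            raise ValueError("all DE tables must share one gene universe")
    up = sum((t["direction"] == "up").astype(int) for t in tables)
    down = sum((t["direction"] == "down").astype(int) for t in tables)
    median_ss = pd.concat([t["ss"] for t in tables], axis=1).median(axis=1)
    out = pd.DataFrame(
        {
            "occurrence": up + down,
            "up_datasets": up,
            "down_datasets": down,
            "Cg": (up - down).abs(),
            "consistent": np.minimum(up, down) == 0,
            "median_ss": median_ss,
        },
        index=genes,
    )
    out = out.rename_axis("gene").reset_index()
    out = out.sort_values(
        by=["occurrence", "median_ss", "gene"],
        ascending=[False, False, True],
        kind="stable",
    )
    return out.set_index("gene")


def gene_set_frequency(
    tables: Sequence[pd.DataFrame],
    sets: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-set count of datasets in which the set is significantly
    overrepresented among that dataset's DEGs.

    Within each dataset, an upper-tail hypergeometric test is run per set and
    BH-adjusted across sets; the set counts as altered when adjusted
    p <= alpha.
    """
    if not tables:
        raise ValueError("empty table list")
    uni = set(universe)
    names, members = [], []
    for name in sets:
        m = sets.members(name) & uni
        if not m:
            warnings.warn(f"gene set {name!r} empty after universe intersection; skipped")
            continue
        names.append(name)
        members.append(m)
    freq = np.zeros(len(names), dtype=int)
    n_universe = len(uni)
    for table in tables:
        degs = set(table.index[table["direction"] != "ns"]) & uni
        pvals = np.array(
            [
                stats.hypergeom.sf(len(m & degs) - 1, n_universe, len(m), len(degs))
                for m in members
            ]
        )
        if len(pvals):
            adj = multipletests(pvals, method="fdr_bh")[1]
            freq += (adj <= alpha).astype(int)
    out = pd.DataFrame({"set": names, "frequency": freq}).sort_values(
        by=["frequency", "set"], ascending=[False, True], kind="stable"
    )
    return out.reset_index(drop=True)


@dataclasses.dataclass
class ScaledCompendium:
    """Merged gene x sample matrix (genes common to all datasets) after batch
    mean-adjustment, with batch and condition vectors."""

    expr: pd.DataFrame
    batch: pd.Series
    condition: pd.Series

    def condition_slice(self, condition: str) -> pd.DataFrame:
        cols = self.condition.index[self.condition == condition]
        return self.expr.loc[:, cols]


def scale_compendium(datasets: Sequence[ExpressionDataset]) -> ScaledCompendium:
    """Merge datasets on their common genes and mean-adjust by batch.

    Per gene and batch the batch mean is removed and the grand mean added
    back, so every batch has the same per-gene mean afterwards. Within-batch
    variances are untouched.
    """
    if not datasets:
        raise ValueError("no datasets")
    common = list(datasets[0].expr.index)
    common_set = set(common)
    for ds in datasets[1:]:
        common_set &= set(ds.expr.index)
    common = [g for g in common if g in common_set]
    if not common:
        raise ValueError("empty gene intersection across datasets")
    mats = [ds.expr.loc[common] for ds in datasets]
    merged = pd.concat(mats, axis=1)
    batch = pd.concat(
        [pd.Series(ds.dataset_id, index=ds.expr.columns) for ds in datasets]
    )
    condition = pd.concat([ds.condition for ds in datasets])
    x = merged.to_numpy(dtype=float)
    grand = x.mean(axis=1, keepdims=True)
    codes = batch.to_numpy()
    for b in pd.unique(codes):
        cols = codes == b
        x[:, cols] += grand - x[:, cols].mean(axis=1, keepdims=True)
    scaled = pd.DataFrame(x, index=merged.index, columns=merged.columns)
    return ScaledCompendium(expr=scaled, batch=batch, condition=condition)


__all__ = [
    "moderated_ttest",
    "welch_ttest",
    "significance_score",
    "differential_expression",
    "occurrence_ranking",
    "gene_set_frequency",
    "ScaledCompendium",
    "scale_compendium",
]
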
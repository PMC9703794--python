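"""Gene-centric knowledge base: membership matrix of curated gene sets,
grouped into categories (druggability, genetic association, immune modules,
...), and its enrichment over network modules.

The knowledge base is a boolean genes x sets matrix over the network
universe. Enrichment of every (module, set) pair uses either an upper-tail
hypergeometric overrepresentation test or a one-tailed KS GSEA of the set
over a module-membership ranking (module members first, each block ordered
by a supplied gene ranking such as the integrated-expression rank).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from conet.analysis import bh_adjust, ks_gsea, overrepresentation
from conet.datasets import GeneSetCollection
from conet.inference import ModulePartition


@dataclasses.dataclass
class KnowledgeBase:
    """Boolean membership matrix (one row per universe gene, one column per
    gene set) plus the category of each column."""

    membership: pd.DataFrame
    categories: dict[str, str]  # set name -> category

    @property
    def universe(self) -> list[str]:
        return list(self.membership.index)

    @property
    def sets(self) -> list[str]:
        return list(self.membership.columns)

    def members(self, set_name: str) -> set[str]:
        col = self.membership[set_name]
        return set(col.index[col])

    def write_tsv(self, path) -> None:
        out = self.membership.astype(int)
        out.columns = [f"{self.categories[c]}:{c}" for c in out.columns]
        out.rename_axis("gene").to_csv(path, sep="\t")


def build_knowledge_base(
    universe: Sequence[str], category_gmts: Mapping[str, GeneSetCollection]
) -> KnowledgeBase:
    """Assemble the membership matrix from per-category gene-set collections.

    Genes absent from every set carry an all-false row; a set name appearing
    in two categories is an error.
    """
    universe = list(universe)
    columns: dict[str, pd.Series] = {}
    categories: dict[str, str] = {}
    for category, coll in category_gmts.items():
        for name in coll:
            if name in categories:
                raise ValueError(f"duplicate gene set name across categories: {name!r}")
            categories[name] = category
            members = coll.members(name)
            columns[name] = pd.Series(
                [g in members for g in universe], index=universe, dtype=bool
            )
    if not columns:
        raise ValueError("no gene sets provided")
    membership = pd.DataFrame(columns, index=pd.Index(universe, name="gene"))
    return KnowledgeBase(membership=membership, categories=categories)


def enrich_knowledge_base(
    kb: KnowledgeBase,
    partition: ModulePartition,
    mode: str = "ora",
    ranked_genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Test every knowledge-base set against every analysable module.

    ``mode='ora'``: hypergeometric overrepresentation of the set in the
    module. ``mode='gsea'``: one-tailed KS test of the set over the
    module-membership ranking (module genes first); requires
    ``ranked_genes`` to order genes within the member / non-member blocks.
    BH adjustment across all (module, set) pairs. Modules below the
    partition's size threshold are skipped.
    """
    if set(kb.universe) != set(partition.assignments.index):
        raise ValueError("knowledge base and partition cover different universes")
    if mode not in ("ora", "gsea"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "gsea" and ranked_genes is None:
        raise ValueError("gsea mode requires ranked_genes")
    universe = kb.universe
    rows = []
    for module in partition.analysable_modules:
        module_genes = set(partition.genes_of(module))
        if mode == "gsea":
            members_first = [g for g in ranked_genes if g in module_genes]
            rest = [g for g in ranked_genes if g not in module_genes]
            ranking = members_first + rest
        for set_name in kb.sets:
            members = kb.members(set_name)
            if mode == "ora":
                res = overrepresentation(module_genes, members, universe, set_id=set_name)
            else:
                res = ks_gsea(ranking, members, set_id=set_name)
            rows.append(
                (module, set_name, kb.categories[set_name], res.statistic, res.pval)
            )
    out = pd.DataFrame(
        rows, columns=["module_id", "set", "category", "statistic", "pval"]
    )
    out["adj_pval"] = bh_adjust(out["pval"])
    return out


__all__ = ["KnowledgeBase", "build_knowledge_base", "enrich_knowledge_base"]
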
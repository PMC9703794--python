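"""Module-level druggability profiling.

Drug-target tables (drug id, target gene, ATC code) are joined onto a
network module partition; the analysis is then restricted to
"module-specific" drugs — drugs whose in-network targets all fall within a
single module — and each module is profiled by ATC level-2 therapeutic
class (the first three characters of the 7-character ATC code, e.g. D10
anti-acne preparations or L04 immunosuppressants) and by its drugs/genes
ratio (module-specific drugs over module size).
"""

from __future__ import annotations

import dataclasses
import logging
import re

import pandas as pd

from conet.inference import ModulePartition

logger = logging.getLogger(__name__)

_ATC_LEVEL2_RE = re.compile(r"^[A-Z]\d{2}")


@dataclasses.dataclass
class ModuleDrugMap:
    """Drug -> target gene -> module rows plus per-module aggregates."""

    table: pd.DataFrame  # columns: drug_id, target_gene, module_id, atc_code
    module_sizes: pd.Series  # module id -> number of genes
    dropped_per_drug: pd.Series  # drug id -> out-of-network target count

    def module_summary(self) -> pd.DataFrame:
        """Per module: n_genes, n_druggable_genes (distinct targets), n_drugs."""
        if self.table.empty:
            agg = pd.DataFrame(columns=["n_druggable_genes", "n_drugs"])
        else:
            agg = self.table.groupby("module_id").agg(
                n_druggable_genes=("target_gene", "nunique"),
                n_drugs=("drug_id", "nunique"),
            )
        out = pd.DataFrame({"n_genes": self.module_sizes})
        out = out.join(agg).fillna(0).astype(int)
        return out.rename_axis("module_id")


def map_drug_targets(
    partition: ModulePartition, drug_table: pd.DataFrame
) -> ModuleDrugMap:
    """Join a drug-target table onto the module partition.

    Rows whose target gene is outside the network universe are dropped (and
    counted per drug, for the strict module-specificity variant).
    """
    required = {"drug_id", "target_gene", "atc_code"}
    if not drug_table.empty and not required.issubset(drug_table.columns):
        raise ValueError(f"drug table must have columns {sorted(required)}")
    assignments = partition.assignments
    if drug_table.empty:
        table = pd.DataFrame(columns=["drug_id", "target_gene", "module_id", "atc_code"])
        dropped = pd.Series(dtype=int)
    else:
        in_net = drug_table["target_gene"].isin(assignments.index)
        n_dropped = int((~in_net).sum())
        if n_dropped:
            logger.info("map_drug_targets: %d target rows outside the network dropped", n_dropped)
        dropped = (
            drug_table.loc[~in_net].groupby("drug_id").size()
            .reindex(drug_table["drug_id"].unique(), fill_value=0)
        )
        table = drug_table.loc[in_net].copy()
        table["module_id"] = table["target_gene"].map(assignments).astype(int)
        table = table[["drug_id", "target_gene", "module_id", "atc_code"]].reset_index(drop=True)
    sizes = partition.module_sizes
    return ModuleDrugMap(table=table, module_sizes=sizes, dropped_per_drug=dropped)


def module_specific_drugs(drug_map: ModuleDrugMap, strict: bool = False) -> ModuleDrugMap:
    """Restrict to drugs whose in-network targets all lie in one module.

    With ``strict``, a drug is additionally disqualified if any of its
    targets fell outside the network universe. Idempotent.
    """
    if drug_map.table.empty:
        return ModuleDrugMap(
            table=drug_map.table.copy(),
            module_sizes=drug_map.module_sizes,
            dropped_per_drug=drug_map.dropped_per_drug,
        )
    modules_per_drug = drug_map.table.groupby("drug_id")["module_id"].nunique()
    keep = set(modules_per_drug.index[modules_per_drug == 1])
    if strict:
        lost = drug_map.dropped_per_drug
        keep -= set(lost.index[lost > 0])
    table = drug_map.table[drug_map.table["drug_id"].isin(keep)].reset_index(drop=True)
    return ModuleDrugMap(
        table=table,
        module_sizes=drug_map.module_sizes,
        dropped_per_drug=drug_map.dropped_per_drug,
    )


@dataclasses.dataclass
class ATCProfile:
    """Per-module ATC level-2 drug counts and drugs/genes ratios."""

    counts: pd.DataFrame  # columns: module_id, atc_level2, n_drugs
    ratios: pd.Series  # module id -> n_drugs / n_genes


def atc_profile(drug_map: ModuleDrugMap, level: int = 2) -> ATCProfile:
    """Profile modules by ATC therapeutic class.

    Level 2 classes are the first three characters of the ATC code
    (letter + two digits); malformed codes are skipped with a log message.
    A drug with several codes counts once per distinct class. The per-module
    ratio is distinct drugs over module size (n_genes).
    """
    if level != 2:
        raise ValueError("only ATC level 2 is supported")
    tab = drug_map.table.copy()
    if tab.empty:
        counts = pd.DataFrame(columns=["module_id", "atc_level2", "n_drugs"])
        ratios = pd.Series(0.0, index=drug_map.module_sizes.index)
        return ATCProfile(counts=counts, ratios=ratios)
    ok = tab["atc_code"].astype(str).str.match(_ATC_LEVEL2_RE)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("atc_profile: %d rows with malformed ATC codes skipped", n_bad)
    tab = tab[ok]
    tab["atc_level2"] = tab["atc_code"].str[:3]
    counts = (
        tab.groupby(["module_id", "atc_level2"])["drug_id"]
        .nunique()
        .rename("n_drugs")
        .reset_index()
    )
    drugs_per_module = tab.groupby("module_id")["drug_id"].nunique()
    ratios = (
        drugs_per_module.reindex(drug_map.module_sizes.index, fill_value=0)
        / drug_map.module_sizes
    ).rename("drugs_genes_ratio")
    return ATCProfile(counts=counts, ratios=ratios)


__all__ = ["ModuleDrugMap", "ATCProfile", "map_drug_targets", "module_specific_drugs", "atc_profile"]
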
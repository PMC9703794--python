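"""End-to-end pipeline: data -> per-dataset DE -> integration -> condition
networks -> communities -> differential centrality -> bridges -> enrichment
-> druggability, with every stage's outputs and parameters written to disk.

The pipeline is driven by a :class:`PipelineConfig`, which points either at
real inputs (per-dataset expression TSVs + sample annotation, optional GMT
gene sets and a drug-target table) or at a synthetic-compendium block. A
single top-level seed drives all randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from conet import analysis, druggability, integration
from conet.datasets import (
    LESIONAL,
    NON_LESIONAL,
    ExpressionDataset,
    GeneSetCollection,
    load_compendium,
    read_drug_target_tsv,
    read_gmt,
    write_gmt,
)
from conet.inference import (
    ALGORITHMS,
    ESTIMATORS,
    ModulePartition,
    ensemble_consensus,
    detect_communities,
)
from conet.synthetic import (
    CompendiumConfig,
    generate_compendium,
    generate_drug_target_table,
    generate_gene_sets,
    write_compendium,
)

logger = logging.getLogger(__name__)

DEFAULT_ATC_CODES = ("D10AX03", "L04AB01", "D05AX02", "L01XC05", "N02BA01", "J01CA04")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``synthetic`` (a :class:`CompendiumConfig`) or
    ``dataset_paths`` + ``annotation_path`` must be provided.
    ``deg_occurrence_threshold`` (K) selects the DEG set for the bridge
    analysis: genes DE in >= K datasets; when None, a majority rule
    ceil(n_datasets / 2) is used.
    """

    out_dir: str = "conet_run"
    seed: int = 0
    synthetic: CompendiumConfig | None = None
    dataset_paths: dict[str, str] | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    drug_table_path: str | None = None
    alpha: float = 0.05
    de_method: str = "moderated"
    deg_occurrence_threshold: int | None = None
    estimators: Sequence[str] = ESTIMATORS
    algorithms: Sequence[str] = ALGORITHMS
    consensus_density: float = 0.043
    aracne_eps: float = 0.0
    mi_bins: int | None = None  # None: ceil(sqrt(n_samples)) per-condition
    walktrap_steps: int = 4
    module_min_size: int = 10
    case_condition: str = LESIONAL
    control_condition: str = NON_LESIONAL

    def validate(self) -> None:
        has_synth = self.synthetic is not None
        has_real = self.dataset_paths is not None
        if has_synth == has_real:
            raise ValueError("provide exactly one of synthetic config or dataset paths")
        if has_real and not self.annotation_path:
            raise ValueError("real inputs require annotation_path")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.consensus_density <= 1):
            raise ValueError("consensus_density must be in (0, 1]")
        if self.walktrap_steps < 1 or self.module_min_size < 1:
            raise ValueError("walktrap_steps and module_min_size must be >= 1")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        synth = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = CompendiumConfig(**synth)
        return cfg


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


STAGE_ORDER = (
    "data",
    "differential_expression",
    "integration",
    "networks",
    "differential_centrality",
    "bridges",
    "enrichment",
    "druggability",
)


def run_pipeline(config: PipelineConfig, upto: str | None = None) -> dict:
    """Execute the pipeline (optionally only up to stage ``upto``) and return
    the run report (also written as ``report.json`` under the output
    directory)."""
    config.validate()
    if upto is not None and upto not in STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}; choose from {STAGE_ORDER}")
    limit = STAGE_ORDER.index(upto) if upto is not None else len(STAGE_ORDER)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            if STAGE_ORDER.index(name) > limit:
                return
            try:
                logger.info("stage %s", name)
                info = fn() or {}
                report["stages"][name] = info
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                _write_report(report, out)
                raise StageError(name, exc) from exc

        return wrap

    state: dict[str, Any] = {}

    @stage("data")
    def _data():
        if config.synthetic is not None:
            synth = dataclasses.replace(config.synthetic, seed=config.seed)
            datasets, truth = generate_compendium(synth)
            data_dir = out / "data"
            write_compendium(datasets, truth, data_dir)
            genes = datasets[0].genes
            sets = generate_gene_sets(
                genes,
                n_sets=10,
                size_range=(10, 50),
                seed=config.seed + 1,
                planted={"PLANTED_MODULE_1": [g for g, m in truth.modules[NON_LESIONAL].items() if m == 1]},
            )
            write_gmt(sets, data_dir / "gene_sets.gmt")
            module_map = truth.modules[LESIONAL]
            can_plant = len(set(module_map.values())) >= 2
            drug_table = generate_drug_target_table(
                genes,
                n_drugs=30,
                targets_per_drug=2,
                atc_codes=DEFAULT_ATC_CODES,
                seed=config.seed + 2,
                module_map=module_map if can_plant else None,
                single_module_fraction=0.5 if can_plant else 0.0,
            )
            drug_table.to_csv(data_dir / "drug_targets.tsv", sep="\t", index=False)
            state.update(datasets=datasets, truth=truth, sets=sets, drug_table=drug_table)
        else:
            datasets = load_compendium(config.dataset_paths, config.annotation_path)
            sets = read_gmt(config.gene_sets_path) if config.gene_sets_path else None
            drug_table = (
                read_drug_target_tsv(config.drug_table_path)
                if config.drug_table_path
                else None
            )
            state.update(datasets=datasets, truth=None, sets=sets, drug_table=drug_table)
        return {
            "n_datasets": len(state["datasets"]),
            "n_genes": len(state["datasets"][0].genes),
            "samples": int(sum(ds.expr.shape[1] for ds in state["datasets"])),
        }

    @stage("differential_expression")
    def _de():
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        tables = []
        for ds in state["datasets"]:
            tab = integration.differential_expression(
                ds,
                alpha=config.alpha,
                method=config.de_method,
                case=config.case_condition,
                control=config.control_condition,
            )
            tab.to_csv(de_dir / f"{ds.dataset_id}_de.tsv", sep="\t", float_format="%.6g")
            tables.append(tab)
        state["de_tables"] = tables
        return {
            "alpha": config.alpha,
            "method": config.de_method,
            "n_de_per_dataset": {
                ds.dataset_id: int((t["direction"] != "ns").sum())
                for ds, t in zip(state["datasets"], tables)
            },
        }

    @stage("integration")
    def _integrate():
        occ = integration.occurrence_ranking(state["de_tables"])
        occ.to_csv(out / "occurrence.tsv", sep="\t", float_format="%.6g")
        state["occurrence"] = occ
        info = {"n_genes": len(occ)}
        if state.get("sets"):
            genes = state["datasets"][0].genes
            freq = integration.gene_set_frequency(
                state["de_tables"], state["sets"], genes, alpha=config.alpha
            )
            freq.to_csv(out / "gene_set_frequency.tsv", sep="\t", index=False)
            info["n_sets"] = len(freq)
        scaled = integration.scale_compendium(state["datasets"])
        state["scaled"] = scaled
        k = config.deg_occurrence_threshold
        if k is None:
            k = math.ceil(len(state["datasets"]) / 2)
        state["deg_threshold"] = k
        state["deg_set"] = set(occ.index[occ["occurrence"] >= k])
        with open(out / "deg_list.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in sorted(state["deg_set"]))
        info.update(deg_occurrence_threshold=k, n_degs=len(state["deg_set"]))
        return info

    @stage("networks")
    def _networks():
        nets, parts = {}, {}
        for cond in (config.case_condition, config.control_condition):
            expr = state["scaled"].condition_slice(cond)
            net = ensemble_consensus(
                expr,
                density=config.consensus_density,
                estimators=config.estimators,
                algorithms=config.algorithms,
                eps=config.aracne_eps,
                n_bins=config.mi_bins,
            )
            net.write_tsv(out / f"network_{cond}.tsv")
            part = detect_communities(
                net, steps=config.walktrap_steps, min_size=config.module_min_size
            )
            part.write_tsv(out / f"modules_{cond}.tsv")
            nets[cond], parts[cond] = net, part
        state["networks"], state["partitions"] = nets, parts
        return {
            "estimators": list(config.estimators),
            "algorithms": list(config.algorithms),
            "density": config.consensus_density,
            "walktrap_steps": config.walktrap_steps,
            "edges": {c: n.n_edges for c, n in nets.items()},
            "modules": {c: len(p.modules) for c, p in parts.items()},
        }

    @stage("differential_centrality")
    def _centrality():
        case, ctrl = config.case_condition, config.control_condition
        tabs = {
            c: analysis.centrality_ranks(state["networks"][c]) for c in (case, ctrl)
        }
        for c, t in tabs.items():
            t.to_csv(out / f"centrality_{c}.tsv", sep="\t", float_format="%.6g")
        diff = analysis.differential_centrality(tabs[case], tabs[ctrl])
        diff = diff.join(state["occurrence"]["occurrence"])
        diff.to_csv(out / "differential_centrality.tsv", sep="\t", float_format="%.6g")
        state["diff_centrality"] = diff
        return {"n_genes": len(diff)}

    @stage("bridges")
    def _bridges():
        case, ctrl = config.case_condition, config.control_condition
        degs = state["deg_set"]
        b_case = analysis.bridge_genes(state["networks"][case], degs)
        b_ctrl = analysis.bridge_genes(state["networks"][ctrl], degs)
        b_case.to_csv(out / f"bridges_{case}.tsv", sep="\t")
        b_ctrl.to_csv(out / f"bridges_{ctrl}.tsv", sep="\t")
        specific = sorted(analysis.condition_specific_bridges(b_case, b_ctrl))
        with open(out / "bridges_case_specific.txt", "w") as fh:
            fh.writelines(f"{g}\n" for g in specific)
        state["bridges_specific"] = specific
        return {
            "n_bridges_case": len(b_case),
            "n_bridges_ctrl": len(b_ctrl),
            "n_case_specific": len(specific),
        }

    @stage("enrichment")
    def _enrichment():
        info: dict[str, Any] = {}
        part = state["partitions"][config.case_condition]
        sim = analysis.module_similarity(
            part, state["partitions"][config.control_condition]
        )
        sim.to_csv(out / "module_similarity.tsv", sep="\t", index=False, float_format="%.6g")
        info["n_module_pairs"] = len(sim)
        if state.get("sets"):
            universe = list(part.assignments.index)
            rows = []
            for module in part.analysable_modules:
                module_genes = part.genes_of(module)
                for name in state["sets"]:
                    res = analysis.overrepresentation(
                        module_genes, state["sets"].members(name), universe, set_id=name
                    )
                    rows.append((module, name, res.statistic, res.pval))
            enr = pd.DataFrame(rows, columns=["module_id", "set", "overlap", "pval"])
            enr["adj_pval"] = analysis.bh_adjust(enr["pval"])
            enr.to_csv(out / "module_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
            info["n_module_set_tests"] = len(enr)
        return info

    @stage("druggability")
    def _drugs():
        if state.get("drug_table") is None:
            return {"skipped": True}
        part = state["partitions"][config.case_condition]
        dmap = druggability.map_drug_targets(part, state["drug_table"])
        specific = druggability.module_specific_drugs(dmap)
        profile = druggability.atc_profile(specific)
        summary = specific.module_summary()
        summary["drugs_genes_ratio"] = profile.ratios
        summary.to_csv(out / "druggability_summary.tsv", sep="\t", float_format="%.6g")
        profile.counts.to_csv(out / "atc_profile.tsv", sep="\t", index=False)
        return {
            "n_drugs_total": int(state["drug_table"]["drug_id"].nunique()),
            "n_module_specific": int(specific.table["drug_id"].nunique()),
        }

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)


__all__ = ["PipelineConfig", "run_pipeline", "StageError"]
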
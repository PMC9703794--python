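"""Core data containers and plain-text I/O (expression TSV, GMT, drug-target TSV).

Expression matrices are genes x samples pandas DataFrames on the log2 scale,
with opaque string gene identifiers. Condition labels are the two arms of the
contrast; by convention the "case" arm is named ``lesional`` and the control
arm ``non_lesional``, but any two labels work as long as they are used
consistently.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

LESIONAL = "lesional"
NON_LESIONAL = "non_lesional"


@dataclasses.dataclass
class ExpressionDataset:
    """One study's gene x sample expression matrix with a two-level condition label.

    Parameters
    ----------
    expr:
        genes x samples matrix (log2 scale). Index: gene ids; columns: sample ids.
    condition:
        Series indexed by sample id with the condition label of each sample.
    dataset_id:
        Batch identifier of the study the matrix comes from.
    """

    expr: pd.DataFrame
    condition: pd.Series
    dataset_id: str

    def __post_init__(self) -> None:
        self.condition = self.condition.reindex(self.expr.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise ValueError(f"samples without condition label: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def conditions(self) -> list[str]:
        return sorted(self.condition.unique())

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset_condition(self, condition: str) -> pd.DataFrame:
        """Return the genes x samples block of one arm."""
        return self.expr.loc[:, self.samples_of(condition)]


class GeneSetCollection(dict):
    """Named gene sets: mapping set name -> (description, frozenset of gene ids).

    Stored as ``{name: (description, set)}``; behaves as a mapping from name
    to member set through :meth:`members`.
    """

    def __init__(self, sets: Mapping[str, tuple[str, Iterable[str]]] | None = None):
        super().__init__()
        if sets:
            for name, (desc, genes) in sets.items():
                self.add(name, genes, desc)

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self:
            raise ValueError(f"duplicate gene set name: {name!r}")
        self[name] = (description, frozenset(genes))

    def members(self, name: str) -> frozenset[str]:
        return self[name][1]

    def description(self, name: str) -> str:
        return self[name][0]


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene ids, header of sample ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample annotation TSV with columns sample_id, dataset_id, condition."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "dataset_id", "condition"}
    if not required.issubset(ann.columns):
        raise ValueError(f"sample annotation must have columns {sorted(required)}")
    return ann


def write_sample_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def load_compendium(
    expr_paths: Mapping[str, str | Path], annotation_path: str | Path
) -> list[ExpressionDataset]:
    """Assemble :class:`ExpressionDataset` objects from per-dataset TSVs + annotation."""
    ann = read_sample_annotation(annotation_path)
    datasets = []
    for dataset_id, path in expr_paths.items():
        expr = read_expression_tsv(path)
        sub = ann[ann["dataset_id"] == dataset_id].set_index("sample_id")
        datasets.append(
            ExpressionDataset(expr=expr, condition=sub["condition"], dataset_id=dataset_id)
        )
    return datasets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (set name, description, tab-separated member genes)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            coll.add(fields[0], fields[2:], fields[1])
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc, genes = collection[name]
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def read_drug_target_tsv(path: str | Path) -> pd.DataFrame:
    """Read a drug-target TSV with columns drug_id, target_gene, atc_code."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "target_gene", "atc_code"}
    if not required.issubset(tab.columns):
        raise ValueError(f"drug table must have columns {sorted(required)}")
    return tab
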
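"""Synthetic multi-dataset two-condition expression compendia with known ground truth.

The generator emulates a collection of independently collected case/control
microarray studies of one tissue contrast (e.g. lesional vs non-lesional
skin): log2-scale Gaussian expression, dataset-level additive batch shifts, a
shared panel of consistently up/down differentially expressed genes (DEGs),
planted co-expression modules, condition-specific hub genes, and planted
"bridge" genes co-expressed with several DEGs in the case condition only.

Expression follows a latent-factor model specified in *variance shares*: per
gene and condition, each factor is assigned a share of the gene's variance
and the residual noise always has standard deviation ``noise_sd``, so the
correlation of two genes sharing a factor equals the geometric mean of their
shares exactly — planted correlations are not diluted when further factors
are added. Factor draws are fresh per dataset; loadings are fixed across
datasets.

Gene universe layout (disjoint blocks, in index order):

    [module blocks][hub-switch genes][DEGs][bridge genes][background]

Planted structure, per condition:

* Module genes share a per-module factor in both conditions at the requested
  within-module correlation. In the non-lesional condition module *pairs*
  are additionally coupled through a shared factor
  (``module_coupling_rho``), keeping the within-module correlation intact:
  modules are co-regulated in healthy tissue and decoupled in the lesion.
* Hub-switch genes switch membership: in the lesional condition each loads
  the factors of two modules (total share ``hub_rho`` split over the two,
  with loading signs arranged so no two hubs are near-duplicates — duplicate
  profiles would prune each other's edges under DPI / redundancy-penalized
  inference); with the modules otherwise decoupled there, hubs are the only
  inter-module connectors — maximal betweenness, closeness and degree. In
  the non-lesional condition they only form one small peripheral block of
  their own. This is exactly the topology differential centrality ranks
  highest.
* DEGs get a mean shift of ``deg_effect`` (sign fixed per gene) in the
  lesional arm of every dataset. When bridges are planted, DEGs are grouped
  into small lesional-only co-expression cliques (share
  ``deg_clique_rho``), and in the non-lesional condition they form weak
  blocks among themselves (``deg_block_rho``) so their association rows are
  never empty — row-normalized inference (CLR) hands fully unstructured
  genes compensatory chance edges, which would manufacture spurious
  non-lesional bridges.
* Bridge genes are non-DE; each loads one DEG clique's factor in the
  lesional condition (share ``bridge_rho``) and is an ordinary member of one
  background block in the non-lesional condition.
* Background genes form condition-shared blocks of
  ``background_block_size`` genes (per-block correlation drawn once from
  ``background_rho_range``), and a condition-shared global backbone factor
  gives the network a giant component with a stable degree continuum, so
  closeness and betweenness vary smoothly instead of jumping when a chance
  edge joins two otherwise separate cliques. Background genes and bridges
  draw their backbone share from ``global_share_range``; DEGs sit at its
  floor and hubs carry none (their strong connectivity is
  lesional-specific by definition, and a shared positive loading would
  break the sign symmetry of the flipped hub attachments); module genes
  carry a fixed share with a random loading sign, anchoring them into the
  giant component while the signed contributions cancel on average and
  leave the mean within-module correlation at the requested level.

The non-lesional module couplings also keep the non-lesional structural edge
budget at least as large as the lesional one, so at a single consensus
density the non-lesional network fills with genuine structure and chance
edges concentrate in the lesional network, where they cannot contaminate the
condition-specific bridge and centrality statistics.
:meth:`CompendiumConfig.suggested_density` returns the density at which the
consensus holds the planted structure (default 10% allowance for the
backbone); a much sparser cut cannot represent the structure, a much denser
one admits noise edges.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from conet.datasets import (
    LESIONAL,
    NON_LESIONAL,
    ExpressionDataset,
    GeneSetCollection,
    write_expression_tsv,
    write_gmt,
    write_sample_annotation,
)

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

#: genes per lesional-only DEG co-expression clique (bridge attachment points)
DEG_CLIQUE_SIZE = 4

#: ceiling on the summed factor variance shares of one gene (residual >= 5%)
MAX_TOTAL_SHARE = 0.95


@dataclasses.dataclass
class CompendiumConfig:
    """Parameters of a synthetic compendium.

    Defaults describe a desk-scale study: 5 datasets of 30 + 30 samples,
    400 genes, 40 DEGs shifted by 2 log2 units, four 40-gene modules at
    within-module correlation 0.7, 10 hub-switch genes and 10 bridge genes,
    moderate batch shifts (sd 1.0) and residual noise sd 0.5.
    """

    n_datasets: int = 5
    n_genes: int = 400
    samples_per_arm: int = 30
    n_deg: int = 40
    deg_effect: float = 2.0
    module_spec: Sequence[tuple[int, float]] = ((40, 0.7), (40, 0.7), (40, 0.7), (40, 0.7))
    n_hub_switch: int = 10
    n_bridge: int = 10
    batch_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    # correlation architecture (variance shares)
    hub_rho: float = 0.9
    hub_nl_rho: float = 0.7
    deg_clique_rho: float = 0.8
    bridge_rho: float = 0.65
    deg_block_rho: float = 0.8
    module_coupling_rho: float = 0.5
    background_block_size: int = 20
    background_rho_range: tuple[float, float] = (0.45, 0.6)
    global_share_range: tuple[float, float] = (0.05, 0.5)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0

    def validate(self) -> None:
        for name in ("n_datasets", "n_genes", "samples_per_arm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_deg", "n_hub_switch", "n_bridge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for size, rho in self.module_spec:
            if size <= 0 or not (0.0 < rho < MAX_TOTAL_SHARE):
                raise ValueError(f"invalid module block ({size}, {rho})")
        reserved = (
            sum(s for s, _ in self.module_spec)
            + self.n_hub_switch
            + self.n_deg
            + self.n_bridge
        )
        if reserved > self.n_genes:
            raise ValueError(
                f"planted structure needs {reserved} genes but n_genes={self.n_genes}"
            )
        if self.n_deg + self.n_bridge > self.n_genes:
            raise ValueError("n_deg + n_bridge exceeds n_genes")
        if self.n_bridge > 0 and self.n_deg < DEG_CLIQUE_SIZE:
            raise ValueError("bridges require at least one DEG clique (n_deg >= 4)")
        if self.n_hub_switch > 0 and not self.module_spec:
            raise ValueError("hub-switch genes require at least one module block")
        for name in ("batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.background_rho_range
        g_lo, g_hi = self.global_share_range
        if not (0.0 <= lo <= hi < MAX_TOTAL_SHARE):
            raise ValueError("background_rho_range out of range")
        if not (0.0 <= g_lo <= g_hi < MAX_TOTAL_SHARE):
            raise ValueError("global_share_range out of range")
        for rho_name in ("hub_rho", "hub_nl_rho", "deg_clique_rho", "bridge_rho",
                         "deg_block_rho", "module_coupling_rho"):
            if not (0.0 < getattr(self, rho_name) < MAX_TOTAL_SHARE):
                raise ValueError(f"{rho_name} must lie in (0, {MAX_TOTAL_SHARE})")

    # -- planted-structure bookkeeping ----------------------------------

    def _n_cliques(self) -> int:
        if self.n_bridge == 0 or self.n_deg == 0:
            return 0
        return max(1, self.n_deg // DEG_CLIQUE_SIZE)

    def _blocks_of(self, count: int) -> list[int]:
        """Sizes of the weak blocks a group of ``count`` genes forms."""
        if self.background_block_size < 2 or count <= 0:
            return []
        sizes = []
        for start in range(0, count, self.background_block_size):
            size = min(self.background_block_size, count - start)
            if size >= 2:
                sizes.append(size)
        return sizes

    def _n_background(self) -> int:
        return (
            self.n_genes
            - sum(s for s, _ in self.module_spec)
            - self.n_hub_switch
            - self.n_deg
            - self.n_bridge
        )

    def _lesional_only_pairs(self) -> int:
        """Planted pairs present in the lesional condition only."""
        c2 = lambda k: k * (k - 1) // 2  # noqa: E731
        nq = self._n_cliques()
        clique_pairs = 0
        bridge_attach = 0
        if nq:
            sizes = [
                self.n_deg // nq + (1 if r < self.n_deg % nq else 0) for r in range(nq)
            ]
            clique_pairs = sum(c2(s) for s in sizes)
            bridge_attach = sum(sizes[j % nq] for j in range(self.n_bridge))
        module_sizes = [s for s, _ in self.module_spec]
        hub_pairs = 0
        m = len(module_sizes)
        for j in range(self.n_hub_switch):
            if m >= 2:
                hub_pairs += module_sizes[j % m] + module_sizes[(j + 1) % m]
            elif m == 1:
                hub_pairs += module_sizes[0]
        hub_pairs += c2(self.n_hub_switch)  # hubs sharing a module correlate too
        return hub_pairs + clique_pairs + bridge_attach

    def _nl_only_pairs(self) -> int:
        """Planted pairs present in the non-lesional condition only."""
        c2 = lambda k: k * (k - 1) // 2  # noqa: E731
        module_sizes = [s for s, _ in self.module_spec]
        nl = c2(self.n_hub_switch)  # hub island
        nl += sum(c2(s) for s in self._blocks_of(self.n_deg))  # DEG weak blocks
        if self._blocks_of(self._n_background()):
            nl += self.n_bridge * self.background_block_size  # bridge block riders
        for k in range(self.n_nl_couplings()):
            nl += module_sizes[2 * k] * module_sizes[2 * k + 1]
        return nl

    def n_nl_couplings(self) -> int:
        """Number of non-lesional module-pair couplings planted.

        All module pairs are coupled whenever any lesional-specific
        structure exists (coupling only some modules would demote the
        others in the non-lesional centrality ranking); none otherwise.
        """
        has_lesional_specific = self.n_hub_switch > 0 or self._n_cliques() > 0
        if not has_lesional_specific or len(self.module_spec) < 2:
            return 0
        return len(self.module_spec) // 2

    def structural_pairs(self) -> dict[str, int]:
        """Expected number of planted (above-noise) gene pairs per condition."""
        c2 = lambda k: k * (k - 1) // 2  # noqa: E731
        shared = sum(c2(s) for s, _ in self.module_spec)
        shared += sum(c2(s) for s in self._blocks_of(self._n_background()))
        return {
            LESIONAL: shared + self._lesional_only_pairs(),
            NON_LESIONAL: shared + self._nl_only_pairs(),
        }

    def suggested_density(self, margin: float = 1.1) -> float:
        """Edge density at which a consensus network holds the planted
        structure; the default 10% allowance covers the strongest global
        backbone pairs."""
        total = self.n_genes * (self.n_genes - 1) // 2
        return min(1.0, margin * max(self.structural_pairs().values()) / total)


@dataclasses.dataclass
class GroundTruth:
    """Planted structure of a synthetic compendium."""

    genes: list[str]
    deg_direction: dict[str, str]  # gene -> "up" | "down"
    modules: dict[str, dict[str, int]]  # condition -> gene -> module id (1-based)
    hub_switch: list[str]
    bridges: list[str]
    bridge_partners: dict[str, list[str]]  # bridge gene -> DEG clique members

    @property
    def deg_ids(self) -> list[str]:
        return list(self.deg_direction)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["modules"] = {
            cond: {g: int(m) for g, m in assign.items()}
            for cond, assign in payload["modules"].items()
        }
        return cls(**payload)


class _ShareLedger:
    """Per-gene, per-condition factor variance shares.

    ``add(factor, gene, share_lesional, share_non_lesional, sign)`` registers
    a loading; :meth:`loadings` converts shares into additive loadings such
    that the residual noise sd equals ``noise_sd`` in both conditions and
    the correlation of two genes sharing a factor is the geometric mean of
    their shares.
    """

    def __init__(self, n_genes: int, noise_sd: float):
        self.n = n_genes
        self.noise_sd = noise_sd
        self.entries: list[tuple[str, int, float, float, float]] = []
        self.total_l = np.zeros(n_genes)
        self.total_nl = np.zeros(n_genes)

    def add(self, factor: str, gene: int, s_l: float, s_nl: float, sign: float = 1.0) -> None:
        if s_l == 0 and s_nl == 0:
            return
        self.entries.append((factor, gene, s_l, s_nl, sign))
        self.total_l[gene] += s_l
        self.total_nl[gene] += s_nl

    def validate(self) -> None:
        worst = max(self.total_l.max(initial=0), self.total_nl.max(initial=0))
        if worst > MAX_TOTAL_SHARE + 1e-9:
            raise ValueError(
                f"factor variance shares exceed {MAX_TOTAL_SHARE} (got {worst:.3f})"
            )

    def loadings(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """factor -> (lesional loading vector, non-lesional loading vector)."""
        noise_l = 1.0 - self.total_l  # residual share per gene
        noise_nl = 1.0 - self.total_nl
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for factor, gene, s_l, s_nl, sign in self.entries:
            if factor not in out:
                out[factor] = (np.zeros(self.n), np.zeros(self.n))
            lam_l, lam_nl = out[factor]
            if s_l > 0:
                lam_l[gene] = sign * self.noise_sd * np.sqrt(s_l / noise_l[gene])
            if s_nl > 0:
                lam_nl[gene] = sign * self.noise_sd * np.sqrt(s_nl / noise_nl[gene])
        return out


def generate_compendium(
    config: CompendiumConfig,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Generate ``config.n_datasets`` two-arm expression datasets plus ground truth.

    Every dataset shares the gene universe, the planted DEG panel (same sign
    everywhere), factor memberships and loadings; batch shifts, factor
    realisations and residual noise are drawn independently per dataset from
    one RNG stream seeded by ``config.seed``. Identical config (including
    seed) gives bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]

    # --- gene universe layout -------------------------------------------
    cursor = 0
    module_blocks: list[tuple[list[int], float]] = []
    for size, rho in config.module_spec:
        module_blocks.append((list(range(cursor, cursor + size)), rho))
        cursor += size
    hub_idx = list(range(cursor, cursor + config.n_hub_switch))
    cursor += config.n_hub_switch
    deg_idx = list(range(cursor, cursor + config.n_deg))
    cursor += config.n_deg
    bridge_idx = list(range(cursor, cursor + config.n_bridge))
    cursor += config.n_bridge
    bg_idx = list(range(cursor, n))
    background_blocks: list[list[int]] = []
    for start in range(0, len(bg_idx), max(config.background_block_size, 1)):
        block = bg_idx[start : start + config.background_block_size]
        if len(block) >= 2 and config.background_block_size >= 2:
            background_blocks.append(block)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    deg_sign = rng.choice([-1.0, 1.0], size=config.n_deg)
    bg_rho = rng.uniform(*config.background_rho_range, size=len(background_blocks))
    g_lo, _ = config.global_share_range
    backbone = rng.uniform(*config.global_share_range, size=n)
    backbone[np.asarray(deg_idx, dtype=int)] = g_lo
    # hubs carry no backbone at all: a shared positive backbone loading
    # would break the sign symmetry of their flipped module attachments
    backbone[np.asarray(hub_idx, dtype=int)] = 0.0
    # Module genes carry a fixed backbone share with a random loading sign:
    # every module gene is anchored into the network's giant component
    # (anchoring only needs the association magnitude), while the signed
    # contributions average out within the module, keeping the mean
    # within-module correlation at the requested level (pairs spread
    # symmetrically around it).
    module_backbone = 0.2
    backbone_sign = np.ones(n)
    for block, _ in module_blocks:
        idx = np.asarray(block, dtype=int)
        backbone[idx] = module_backbone
        backbone_sign[idx] = rng.choice([-1.0, 1.0], size=len(block))

    ledger = _ShareLedger(n, config.noise_sd)
    m = len(module_blocks)

    # modules: full within-module correlation in both conditions; in the
    # non-lesional condition part of it flows through the pair coupling
    n_couplings = config.n_nl_couplings()
    coupled_of_module = {}
    for k in range(n_couplings):
        coupled_of_module[2 * k] = k
        coupled_of_module[2 * k + 1] = k
    for b, (block, rho) in enumerate(module_blocks):
        k = coupled_of_module.get(b)
        coupling = min(config.module_coupling_rho, rho) if k is not None else 0.0
        for g in block:
            ledger.add(f"mod{b}", g, rho, rho - coupling)
            if coupling > 0:
                ledger.add(f"coupling{k}", g, 0.0, coupling)

    # hub-switch genes: two modules in lesional (sign-flipped repeats),
    # one small island in non-lesional
    module_pairs = [(a, b) for a in range(m) for b in range(a + 1, m)]
    hub_modules: list[list[int]] = []
    for j, h in enumerate(hub_idx):
        if m >= 2:
            a, b = module_pairs[j % len(module_pairs)]
            flip = -1.0 if (j // len(module_pairs)) % 2 else 1.0
            ledger.add(f"mod{a}", h, config.hub_rho / 2, 0.0)
            ledger.add(f"mod{b}", h, config.hub_rho / 2, 0.0, sign=flip)
            hub_modules.append([a, b])
        elif m == 1:
            ledger.add("mod0", h, config.hub_rho, 0.0)
            hub_modules.append([0])
        if len(hub_idx) >= 2:
            ledger.add("hub_island", h, 0.0, config.hub_nl_rho)

    # DEGs: lesional-only cliques (when bridges are planted), non-lesional
    # weak blocks among themselves
    n_cliques = config._n_cliques()
    deg_clique_of = np.arange(config.n_deg) % n_cliques if n_cliques else None
    if n_cliques:
        for i, g in enumerate(deg_idx):
            ledger.add(f"clique{deg_clique_of[i]}", g, config.deg_clique_rho, 0.0)
    deg_blocks = [
        deg_idx[s : s + config.background_block_size]
        for s in range(0, config.n_deg, max(config.background_block_size, 1))
    ]
    for b, block in enumerate(deg_blocks):
        if len(block) >= 2 and config.background_block_size >= 2:
            for g in block:
                ledger.add(f"degblock{b}", g, 0.0, config.deg_block_rho)

    # bridges: one DEG clique in lesional, one background block otherwise
    for j, g in enumerate(bridge_idx):
        if n_cliques:
            ledger.add(f"clique{j % n_cliques}", g, config.bridge_rho, 0.0)
        if background_blocks:
            b = j % len(background_blocks)
            ledger.add(f"bgblock{b}", g, 0.0, bg_rho[b])

    # background blocks (condition-shared)
    for b, block in enumerate(background_blocks):
        for g in block:
            ledger.add(f"bgblock{b}", g, bg_rho[b], bg_rho[b])

    # global backbone, capped so total shares stay below the ceiling
    for g in range(n):
        cap_l = MAX_TOTAL_SHARE - ledger.total_l[g]
        cap_nl = MAX_TOTAL_SHARE - ledger.total_nl[g]
        ledger.add(
            "backbone",
            g,
            min(backbone[g], cap_l),
            min(backbone[g], cap_nl),
            sign=backbone_sign[g],
        )
    ledger.validate()
    loadings = ledger.loadings()

    # --- sample the datasets --------------------------------------------
    n_arm = config.samples_per_arm
    n_samples = 2 * n_arm
    is_lesional = np.zeros(n_samples, dtype=bool)
    is_lesional[:n_arm] = True
    les_mask = is_lesional.astype(float)
    nl_mask = 1.0 - les_mask

    datasets: list[ExpressionDataset] = []
    for d in range(config.n_datasets):
        dataset_id = f"DS{d + 1:02d}"
        batch = rng.normal(0.0, config.batch_sd, size=n)
        x = baseline[:, None] + batch[:, None] + np.zeros((n, n_samples))
        if config.n_deg:
            x[np.asarray(deg_idx), :] += (
                config.deg_effect * deg_sign[:, None] * les_mask[None, :]
            )
        for factor in loadings:
            lam_l, lam_nl = loadings[factor]
            z = rng.standard_normal(n_samples)
            lam = lam_l[:, None] * les_mask[None, :] + lam_nl[:, None] * nl_mask[None, :]
            x += lam * z[None, :]
        x += rng.normal(0.0, config.noise_sd, size=(n, n_samples))

        sample_ids = [
            f"{dataset_id}_{'L' if les else 'N'}{i:03d}"
            for i, les in enumerate(is_lesional)
        ]
        expr = pd.DataFrame(x, index=genes, columns=sample_ids)
        condition = pd.Series(
            np.where(is_lesional, LESIONAL, NON_LESIONAL), index=sample_ids
        )
        datasets.append(
            ExpressionDataset(expr=expr, condition=condition, dataset_id=dataset_id)
        )

    # --- ground truth ----------------------------------------------------
    deg_direction = {
        genes[g]: ("up" if s > 0 else "down") for g, s in zip(deg_idx, deg_sign)
    }
    modules_shared = {
        genes[g]: b + 1 for b, (block, _) in enumerate(module_blocks) for g in block
    }
    modules_lesional = dict(modules_shared)
    for j, h in enumerate(hub_idx):
        modules_lesional[genes[h]] = hub_modules[j][0] + 1 if module_blocks else 0
    truth = GroundTruth(
        genes=genes,
        deg_direction=deg_direction,
        modules={LESIONAL: modules_lesional, NON_LESIONAL: modules_shared},
        hub_switch=[genes[h] for h in hub_idx],
        bridges=[genes[b] for b in bridge_idx],
        bridge_partners={
            genes[b]: [genes[g] for g in np.asarray(deg_idx)[deg_clique_of == (j % n_cliques)]]
            for j, b in enumerate(bridge_idx)
            if n_cliques
        },
    )
    return datasets, truth


def generate_gene_sets(
    universe: Sequence[str],
    n_sets: int,
    size_range: tuple[int, int],
    seed: int,
    planted: dict[str, Sequence[str]] | None = None,
) -> GeneSetCollection:
    """Random gene sets over ``universe``; ``planted`` entries are kept verbatim.

    Stands in for curated pathway collections (e.g. Reactome) at desk scale.
    """
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError(f"size_range {size_range} incompatible with universe")
    rng = np.random.default_rng(seed)
    coll = GeneSetCollection()
    if planted:
        for name, members in planted.items():
            coll.add(name, members, "planted")
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        coll.add(f"SET{i + 1:03d}", [universe[j] for j in members], "random")
    return coll


def generate_drug_target_table(
    universe: Sequence[str],
    n_drugs: int,
    targets_per_drug: int,
    atc_codes: Sequence[str],
    seed: int,
    module_map: dict[str, int] | None = None,
    single_module_fraction: float = 0.0,
) -> pd.DataFrame:
    """Synthetic drug-target rows (drug_id, target_gene, atc_code).

    When ``module_map`` is given, exactly
    ``round(single_module_fraction * n_drugs)`` drugs have all their targets
    inside one planted module; the remaining drugs are guaranteed to span at
    least two modules.
    """
    if not universe:
        raise ValueError("empty gene universe")
    for code in atc_codes:
        if not _ATC_RE.match(code):
            raise ValueError(f"malformed ATC code: {code!r}")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    rows = []
    n_single = int(round(single_module_fraction * n_drugs)) if module_map else 0
    modules: dict[int, list[str]] = {}
    if module_map:
        in_universe = set(universe)
        for g, mod in module_map.items():
            if g in in_universe:
                modules.setdefault(mod, []).append(g)
        modules = {k: v for k, v in modules.items() if len(v) >= targets_per_drug}
        if n_single and not modules:
            raise ValueError("no module large enough to host a single-module drug")
        if n_single < n_drugs and len(modules) < 2:
            raise ValueError("need >= 2 modules to plant multi-module drugs")
    for i in range(n_drugs):
        drug = f"DRUG{i + 1:04d}"
        atc = atc_codes[int(rng.integers(len(atc_codes)))]
        if module_map and i < n_single:
            mod = sorted(modules)[int(rng.integers(len(modules)))]
            targets = rng.choice(modules[mod], size=targets_per_drug, replace=False)
        elif module_map:
            m1, m2 = rng.choice(sorted(modules), size=2, replace=False)
            k1 = max(1, targets_per_drug // 2)
            t1 = rng.choice(modules[m1], size=k1, replace=False)
            t2 = rng.choice(modules[m2], size=targets_per_drug - k1, replace=False)
            targets = np.concatenate([t1, t2])
        else:
            targets = rng.choice(universe, size=targets_per_drug, replace=False)
        rows.extend({"drug_id": drug, "target_gene": t, "atc_code": atc} for t in targets)
    return pd.DataFrame(rows, columns=["drug_id", "target_gene", "atc_code"])


def write_compendium(
    datasets: Sequence[ExpressionDataset], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Serialize a compendium: per-dataset TSVs, sample annotation, ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_rows = []
    for ds in datasets:
        write_expression_tsv(ds.expr, out / f"{ds.dataset_id}.tsv")
        for sample, cond in ds.condition.items():
            ann_rows.append(
                {"sample_id": sample, "dataset_id": ds.dataset_id, "condition": cond}
            )
    write_sample_annotation(pd.DataFrame(ann_rows), out / "samples.tsv")
    truth.to_json(out / "ground_truth.json")


__all__ = [
    "CompendiumConfig",
    "GroundTruth",
    "generate_compendium",
    "generate_gene_sets",
    "generate_drug_target_table",
    "write_compendium",
    "write_gmt",
]
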
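"""Seeded generators for every input the pipeline consumes.

The generative model emulates the structure that substructure-driven network
inference exploits: drugs come in structural clusters that share a block of
substructures, and drugs within a cluster share targets with a configurable
probability (``signal_strength``).  An SMG catalog is drawn over the same
gene namespace, and a drug-cancer enrichment signal can be planted so that
parameter-recovery tests need no external data.

Everything is driven by a single :class:`numpy.random.Generator` seeded from
``SynthConfig.seed``: the same config produces byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_io import DTICatalog, DTIRecord, SMGCatalog
from .errors import ParameterError
from .substructures import SubstructureMatrix

__all__ = ["SynthConfig", "WorldTruth", "gen_world", "load_indication_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic world.

    Sizes mirror a small curated study: tens of drugs, a few hundred
    fingerprint bits, tens of cancer types with 20-100 SMGs each, a gene
    namespace at the few-thousand scale so enrichment overlaps stay sparse.

    ``signal_strength`` is the probability that a drug carries each of its
    cluster's pool targets — 0 leaves only background interactions.
    ``planted = (drug_id, cancer_code, overlap_fraction)`` rebuilds that
    drug's target set to overlap that cancer's SMG set at the stated
    fraction of the SMG set size.
    """

    n_drugs: int = 60
    n_substructures: int = 120
    n_targets: int = 80
    n_cancers: int = 24
    n_genes: int = 2000
    fp_density: float = 0.08
    dti_density: float = 0.03
    signal_strength: float = 0.8
    smg_size_range: tuple[int, int] = (20, 60)
    cluster_size: int = 5
    block_size: int = 8
    pool_size: int = 6
    planted: tuple[str, str, float] | None = None
    planted_target_count: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fp_density", "dti_density"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ParameterError("signal_strength must be in [0, 1]")
        lo, hi = self.smg_size_range
        if not (0 < lo <= hi):
            raise ParameterError(f"bad smg_size_range {self.smg_size_range}")
        if hi > self.n_genes:
            raise ParameterError("smg sets cannot exceed the gene namespace")
        n_clusters = -(-self.n_drugs // self.cluster_size)
        if n_clusters * self.block_size > self.n_substructures:
            raise ParameterError(
                "not enough substructures for one block per cluster: need "
                f"{n_clusters * self.block_size}, have {self.n_substructures}"
            )
        if self.planted is not None:
            _, _, frac = self.planted
            if not (0.0 <= frac <= 1.0):
                raise ParameterError("planted overlap fraction must be in [0, 1]")


@dataclass(frozen=True)
class WorldTruth:
    """Every planted fact of a generated world, for recovery tests."""

    config: SynthConfig
    clusters: dict[str, int]
    cluster_targets: dict[int, tuple[str, ...]]
    drug_targets: dict[str, tuple[str, ...]]
    planted_drug: str | None = None
    planted_cancer: str | None = None
    planted_overlap_genes: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "clusters": self.clusters,
            "cluster_targets": {str(k): list(v) for k, v in self.cluster_targets.items()},
            "drug_targets": {k: list(v) for k, v in self.drug_targets.items()},
            "planted_drug": self.planted_drug,
            "planted_cancer": self.planted_cancer,
            "planted_overlap_genes": list(self.planted_overlap_genes),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def gen_world(
    config: SynthConfig,
) -> tuple[DTICatalog, SubstructureMatrix, SMGCatalog, WorldTruth]:
    """Generate a coupled (DTI catalog, substructure matrix, SMG catalog).

    Drugs are partitioned into consecutive clusters of ``cluster_size``.
    Each cluster owns a dedicated substructure block and a pool of targets;
    a drug carries its block bits (plus background bits at ``fp_density``)
    and links each pool target with probability ``signal_strength`` (plus
    background interactions at ``dti_density``).  SMG sets are drawn from
    the gene namespace with sizes in ``smg_size_range``; an optional planted
    drug-cancer pair gets a constructed target-set overlap.
    """
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    target_pool = [genes[i] for i in sorted(
        rng.choice(config.n_genes, size=config.n_targets, replace=False)
    )]
    drugs = [f"D{i:03d}" for i in range(config.n_drugs)]
    subs = [f"SYNTH:{j:04d}" for j in range(config.n_substructures)]

    n_clusters = -(-config.n_drugs // config.cluster_size)
    clusters = {d: i // config.cluster_size for i, d in enumerate(drugs)}

    # substructure matrix: cluster block bits (dense) + background bits
    inc = (rng.random((config.n_drugs, config.n_substructures)) < config.fp_density)
    inc = inc.astype(np.uint8)
    for i, d in enumerate(drugs):
        c = clusters[d]
        block = slice(c * config.block_size, (c + 1) * config.block_size)
        inc[i, block] = (rng.random(config.block_size) < 0.9).astype(np.uint8)
        if inc[i].sum() == 0:
            inc[i, c * config.block_size] = 1

    # cluster target pools and interactions
    cluster_targets: dict[int, tuple[str, ...]] = {}
    for c in range(n_clusters):
        chosen = rng.choice(config.n_targets, size=min(config.pool_size, config.n_targets), replace=False)
        cluster_targets[c] = tuple(sorted(target_pool[j] for j in chosen))

    drug_targets: dict[str, set[str]] = {d: set() for d in drugs}
    for d in drugs:
        for t in cluster_targets[clusters[d]]:
            if rng.random() < config.signal_strength:
                drug_targets[d].add(t)
        background = rng.random(config.n_targets) < config.dti_density
        drug_targets[d].update(t for t, b in zip(target_pool, background) if b)

    # SMG catalog over the gene namespace
    lo, hi = config.smg_size_range
    smg_sets: dict[str, frozenset[str]] = {}
    for c_idx in range(config.n_cancers):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        smg_sets[f"CAN{c_idx:02d}"] = frozenset(genes[i] for i in sorted(members))

    planted_drug = planted_cancer = None
    planted_overlap: tuple[str, ...] = ()
    if config.planted is not None:
        planted_drug, planted_cancer, frac = config.planted
        if planted_drug not in drug_targets:
            raise ParameterError(f"planted drug {planted_drug!r} not generated")
        if planted_cancer not in smg_sets:
            raise ParameterError(f"planted cancer {planted_cancer!r} not generated")
        smg_genes = sorted(smg_sets[planted_cancer])
        n_overlap = int(round(frac * len(smg_genes)))
        if n_overlap > config.planted_target_count:
            raise ParameterError(
                f"planted overlap ({n_overlap}) exceeds the planted target "
                f"set size ({config.planted_target_count})"
            )
        overlap_idx = rng.choice(len(smg_genes), size=n_overlap, replace=False)
        overlap = [smg_genes[i] for i in sorted(overlap_idx)]
        outside = sorted(set(genes) - smg_sets[planted_cancer])
        fill_idx = rng.choice(len(outside), size=config.planted_target_count - n_overlap, replace=False)
        fill = [outside[i] for i in sorted(fill_idx)]
        drug_targets[planted_drug] = set(overlap) | set(fill)
        planted_overlap = tuple(overlap)

    records = tuple(
        DTIRecord(drug_id=d, target_gene=t, source="SYNTH")
        for d in drugs
        for t in sorted(drug_targets[d])
    )
    catalog = DTICatalog(records)
    matrix = SubstructureMatrix(
        drug_ids=tuple(drugs), substructure_ids=tuple(subs), incidence=inc
    )
    smg = SMGCatalog(sets=smg_sets)
    truth = WorldTruth(
        config=config,
        clusters=clusters,
        cluster_targets=cluster_targets,
        drug_targets={d: tuple(sorted(ts)) for d, ts in drug_targets.items()},
        planted_drug=planted_drug,
        planted_cancer=planted_cancer,
        planted_overlap_genes=planted_overlap,
    )
    return catalog, matrix, smg, truth


def load_indication_fixture() -> pd.DataFrame:
    """Published berberine indication screen: raw Fisher P-values per cancer
    type, the printed adjusted values, and literature-validation PMIDs.

    Columns: ``cancer_type``, ``p_raw``, ``adj_p_printed``,
    ``neglog_printed``, ``pmids`` (``"N/A"`` when unvalidated).
    """
    from importlib.resources import files

    path = files("netpharm.data").joinpath("berberine_indications.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", keep_default_na=False)
    df["p_raw"] = df["p_raw"].astype(float)
    df["adj_p_printed"] = df["adj_p_printed"].astype(float)
    df["neglog_printed"] = df["neglog_printed"].astype(float)
    return df
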
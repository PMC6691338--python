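"""Drug-target interaction (DTI) catalogs and significantly-mutated-gene (SMG) sets.

The inference network is trained on evidence-tagged drug->target links merged
from heterogeneous sources (curated databases, text mining, literature).  This
module normalizes those tables into a single deduplicated :class:`DTICatalog`
and reads per-cancer SMG gene sets from GMT files into an :class:`SMGCatalog`.

Conventions
-----------
* Gene identity is the uppercased HGNC-style symbol everywhere; Entrez ids,
  when present, ride along as annotation only.
* Source-specific evidence filtering: rows from a score-bearing interaction
  database (STITCH) are kept only when their experimental evidence score is
  strictly greater than the configured minimum (default 0.7).  Other sources
  need no score.
* Species filtering is exact match after trimming and case-folding; the
  default keeps human interactions only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ParseError

__all__ = [
    "DTIRecord",
    "DTICatalog",
    "SMGCatalog",
    "merge_dti_sources",
    "read_dti_table",
    "load_dti_catalog",
    "write_dti_catalog",
    "load_smg_catalog",
    "write_smg_catalog",
]

logger = logging.getLogger(__name__)

DEFAULT_SPECIES = "Homo sapiens"
DEFAULT_STITCH_MIN_SCORE = 0.7
#: sources whose rows must carry an evidence score subject to the cutoff
SCORE_FILTERED_SOURCES = frozenset({"STITCH"})

_DTI_COLUMNS = ("drug_id", "target_gene", "source", "evidence_score", "species")


@dataclass(frozen=True, order=True)
class DTIRecord:
    """One drug->target link with its provenance.

    ``source`` may be a ``";"``-joined union after merging.  ``evidence_score``
    is the maximum score observed across merged rows, or ``None`` when no
    source reported one.
    """

    drug_id: str
    target_gene: str
    source: str = "unknown"
    evidence_score: float | None = None
    species: str = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise FormatError("DTIRecord requires a non-empty drug_id")
        if not self.target_gene:
            raise FormatError("DTIRecord requires a non-empty target_gene")
        if self.evidence_score is not None and not (0.0 <= self.evidence_score <= 1.0):
            raise FormatError(
                f"evidence_score {self.evidence_score!r} outside [0, 1] "
                f"for ({self.drug_id}, {self.target_gene})"
            )


@dataclass(frozen=True)
class DTICatalog:
    """Deduplicated, deterministically ordered collection of DTI records."""

    records: tuple[DTIRecord, ...] = ()

    def __post_init__(self) -> None:
        pairs = [(r.drug_id, r.target_gene) for r in self.records]
        if len(pairs) != len(set(pairs)):
            raise FormatError("duplicate (drug_id, target_gene) pair in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(sorted({r.drug_id for r in self.records}))

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(sorted({r.target_gene for r in self.records}))

    @property
    def pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset((r.drug_id, r.target_gene) for r in self.records)

    def targets_of(self, drug_id: str) -> tuple[str, ...]:
        return tuple(sorted(r.target_gene for r in self.records if r.drug_id == drug_id))

    def restrict_drugs(self, keep: Iterable[str]) -> "DTICatalog":
        keep = set(keep)
        return DTICatalog(tuple(r for r in self.records if r.drug_id in keep))

    def drop_pairs(self, pairs: Iterable[tuple[str, str]]) -> "DTICatalog":
        drop = set(pairs)
        return DTICatalog(
            tuple(r for r in self.records if (r.drug_id, r.target_gene) not in drop)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "drug_id": r.drug_id,
                    "target_gene": r.target_gene,
                    "source": r.source,
                    "evidence_score": r.evidence_score,
                    "species": r.species,
                }
                for r in self.records
            ],
            columns=list(_DTI_COLUMNS),
        )


def _normalize_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


def _species_key(species: str) -> str:
    return str(species).strip().casefold()


def read_dti_table(path: str | Path) -> pd.DataFrame:
    """Read a raw DTI table (TSV with header) without filtering or merging."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return df


def merge_dti_sources(
    tables: Sequence[pd.DataFrame],
    stitch_min_score: float = DEFAULT_STITCH_MIN_SCORE,
    species_filter: str = DEFAULT_SPECIES,
) -> DTICatalog:
    """Merge raw DTI tables into one filtered, deduplicated catalog.

    Rules, applied in order:

    1. rows from score-filtered sources (STITCH) are kept only when their
       evidence score is strictly greater than ``stitch_min_score``;
    2. rows whose species differs from ``species_filter`` (exact match after
       trimming/case-folding; a missing species column passes) are dropped;
    3. duplicate (drug, gene) pairs collapse into one record carrying the
       union of sources and the maximum evidence score.

    The result is sorted by ``(drug_id, target_gene)``, which makes merging
    order-insensitive and idempotent.
    """
    species_key = _species_key(species_filter)
    kept: dict[tuple[str, str], dict] = {}

    for t_idx, table in enumerate(tables):
        for col in ("drug_id", "target_gene", "source"):
            if col not in table.columns:
                raise FormatError(f"table {t_idx}: missing mandatory column {col!r}")
        has_score = "evidence_score" in table.columns
        has_species = "species" in table.columns

        for r_idx, row in table.iterrows():
            drug = str(row["drug_id"]).strip()
            gene = _normalize_gene(row["target_gene"])
            source = str(row["source"]).strip()
            if not drug or not gene:
                raise FormatError(
                    f"table {t_idx} row {r_idx}: empty drug_id or target_gene"
                )

            score: float | None = None
            raw_score = row["evidence_score"] if has_score else None
            if raw_score is not None and not pd.isna(raw_score) and str(raw_score).strip():
                try:
                    score = float(raw_score)
                except (TypeError, ValueError) as exc:
                    raise ParseError(
                        f"table {t_idx} row {r_idx}: non-numeric evidence_score "
                        f"{raw_score!r}"
                    ) from exc

            if source.upper() in SCORE_FILTERED_SOURCES:
                if score is None:
                    raise FormatError(
                        f"table {t_idx} row {r_idx}: {source} row lacks evidence_score"
                    )
                if not score > stitch_min_score:
                    continue

            species = str(row["species"]).strip() if has_species and not pd.isna(row.get("species")) else species_filter
            if _species_key(species) != species_key:
                continue

            key = (drug, gene)
            entry = kept.setdefault(
                key, {"sources": set(), "score": None, "species": species_filter}
            )
            entry["sources"].add(source)
            if score is not None:
                entry["score"] = score if entry["score"] is None else max(entry["score"], score)

    records = tuple(
        DTIRecord(
            drug_id=drug,
            target_gene=gene,
            source=";".join(sorted(entry["sources"])),
            evidence_score=entry["score"],
            species=entry["species"],
        )
        for (drug, gene), entry in sorted(kept.items())
    )
    return DTICatalog(records)


def write_dti_catalog(
    catalog: DTICatalog, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    """Write a catalog as TSV with a provenance comment line."""
    from . import __version__

    path = Path(path)
    param_str = " ".join(f"{k}={v}" for k, v in (params or {}).items())
    with path.open("w") as fh:
        fh.write(f"# netpharm {__version__} dti_catalog {param_str}".rstrip() + "\n")
        catalog.to_dataframe().to_csv(fh, sep="\t", index=False)


def load_dti_catalog(path: str | Path) -> DTICatalog:
    """Load a catalog previously written by :func:`write_dti_catalog`."""
    df = read_dti_table(path)
    for col in ("drug_id", "target_gene", "source"):
        if col not in df.columns:
            raise FormatError(f"catalog file missing column {col!r}")
    records = []
    for r_idx, row in df.iterrows():
        score = None
        raw = row.get("evidence_score")
        if raw is not None and not pd.isna(raw) and str(raw).strip():
            try:
                score = float(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"row {r_idx}: non-numeric evidence_score {raw!r}") from exc
        records.append(
            DTIRecord(
                drug_id=str(row["drug_id"]),
                target_gene=_normalize_gene(row["target_gene"]),
                source=str(row["source"]),
                evidence_score=score,
                species=str(row.get("species", DEFAULT_SPECIES)),
            )
        )
    records.sort()
    return DTICatalog(tuple(records))


# ---------------------------------------------------------------------------
# SMG catalogs


@dataclass(frozen=True)
class SMGCatalog:
    """Per-cancer-type sets of significantly mutated genes.

    ``sets`` maps a cancer type code (e.g. ``"HCC"``) to its gene set;
    ``descriptions`` keeps the free-text second GMT field.  ``dropped``
    records (code, size) pairs removed by the minimum-size filter, so a run
    log can report them.
    """

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    dropped: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        for code, genes in self.sets.items():
            if not genes:
                raise FormatError(f"SMG set {code!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, code: str) -> bool:
        return code in self.sets

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(sorted(self.sets))

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)

    def __getitem__(self, code: str) -> frozenset[str]:
        return self.sets[code]

    @classmethod
    def from_dict(cls, sets: Mapping[str, Iterable[str]], **kw) -> "SMGCatalog":
        return cls(
            sets={c: frozenset(_normalize_gene(g) for g in gs) for c, gs in sets.items()},
            **kw,
        )


def load_smg_catalog(path: str | Path, min_smg: int = 20) -> SMGCatalog:
    """Read a GMT file of per-cancer SMG sets, dropping underpowered types.

    Each GMT row is ``code<TAB>description<TAB>gene...``.  Cancer types with
    fewer than ``min_smg`` distinct genes are excluded (too little statistical
    power for enrichment) and reported in the log and in ``dropped``.
    """
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    dropped: list[tuple[str, int]] = []

    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: GMT row with no genes")
            code, desc, *genes = fields
            code = code.strip()
            if code in sets or code in dict(dropped):
                raise FormatError(f"{path}:{line_no}: duplicate cancer code {code!r}")
            gene_set = frozenset(_normalize_gene(g) for g in genes if g.strip())
            if not gene_set:
                raise FormatError(f"{path}:{line_no}: GMT row with no genes")
            if len(gene_set) < min_smg:
                dropped.append((code, len(gene_set)))
                continue
            sets[code] = gene_set
            descriptions[code] = desc

    if dropped:
        logger.info(
            "load_smg_catalog: dropped %d cancer types below min_smg=%d: %s",
            len(dropped),
            min_smg,
            ", ".join(f"{c}({n})" for c, n in dropped),
        )
    return SMGCatalog(sets=sets, descriptions=descriptions, dropped=tuple(dropped))


def write_smg_catalog(catalog: SMGCatalog, path: str | Path) -> None:
    """Write an SMG catalog as GMT (sorted codes, sorted genes)."""
    path = Path(path)
    with path.open("w") as fh:
        for code in catalog.codes:
            desc = catalog.descriptions.get(code, "")
            genes = "\t".join(sorted(catalog.sets[code]))
            fh.write(f"{code}\t{desc}\t{genes}\n")


def load_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a generic GMT file (e.g. pathway sets) into name -> gene set."""
    out: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{line_no}: GMT row with no genes")
            name, _desc, *genes = fields
            if name in out:
                raise FormatError(f"{path}:{line_no}: duplicate set name {name!r}")
            out[name] = frozenset(_normalize_gene(g) for g in genes if g.strip())
    return out
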
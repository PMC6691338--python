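"""Binary drug x substructure incidence matrices from pluggable providers.

The diffusion engine is chemistry-agnostic: all it ever sees is a binary
incidence matrix saying which predefined fragments (fingerprint bits) occur
in which molecule.  Fingerprint families differ only in which external tool
defines the bits, so providers are pluggable:

* ``MACCS`` — computed from SMILES with RDKit (166 public MACCS keys);
* ``FILE`` — any precomputed binary matrix saved as TSV, covering families
  (FP4, Klekota-Roth, PubChem) whose bit definitions live in external tools;
* ``SYNTH`` — a seeded random matrix for simulation studies.

Any provider output is binarized (``> 0``) before use, and all-zero
substructure columns are pruned: an unused fragment is an isolated node and
cannot carry diffusion resource.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .catalog_io import DTICatalog
from .errors import CapabilityError, ConfigurationError, FormatError, ParseError

__all__ = [
    "SubstructureMatrix",
    "FINGERPRINT_FAMILIES",
    "compute_substructures",
    "synthetic_matrix",
    "load_matrix",
    "write_matrix",
    "restrict_to_common",
    "CommonSubset",
]

logger = logging.getLogger(__name__)

#: families the pipeline knows about; only some have an in-process provider
FINGERPRINT_FAMILIES = ("FP4", "KR", "MACCS", "PubChem", "FILE", "SYNTH")

#: the family used by default throughout the pipeline (best-performing in
#: benchmark comparisons of substructure-driven network inference)
DEFAULT_FAMILY = "KR"


@dataclass(frozen=True)
class SubstructureMatrix:
    """Binary drug x substructure incidence.

    ``incidence[i, j] == 1`` iff drug ``drug_ids[i]`` contains substructure
    ``substructure_ids[j]``.  Ids are unique; entries are 0/1 (uint8).
    """

    drug_ids: tuple[str, ...]
    substructure_ids: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.shape != (len(self.drug_ids), len(self.substructure_ids)):
            raise FormatError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.substructure_ids)} substructures"
            )
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise FormatError("duplicate drug ids in substructure matrix")
        if len(set(self.substructure_ids)) != len(self.substructure_ids):
            raise FormatError("duplicate substructure ids in substructure matrix")
        binarized = (inc > 0).astype(np.uint8)
        object.__setattr__(self, "incidence", binarized)
        self.incidence.setflags(write=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstructureMatrix):
            return NotImplemented
        return (
            self.drug_ids == other.drug_ids
            and self.substructure_ids == other.substructure_ids
            and np.array_equal(self.incidence, other.incidence)
        )

    def __hash__(self) -> int:
        return hash((self.drug_ids, self.substructure_ids))

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_substructures(self) -> int:
        return len(self.substructure_ids)

    def row(self, drug_id: str) -> np.ndarray:
        return self.incidence[self.drug_ids.index(drug_id)]

    def substructures_of(self, drug_id: str) -> tuple[str, ...]:
        mask = self.row(drug_id) > 0
        return tuple(s for s, m in zip(self.substructure_ids, mask) if m)

    def prune_empty_columns(self) -> "SubstructureMatrix":
        """Drop substructures present in no drug (isolated nodes)."""
        keep = self.incidence.sum(axis=0) > 0
        if keep.all():
            return self
        dropped = [s for s, k in zip(self.substructure_ids, keep) if not k]
        logger.info("pruned %d all-zero substructure columns: %s",
                    len(dropped), ", ".join(dropped[:10]))
        return SubstructureMatrix(
            drug_ids=self.drug_ids,
            substructure_ids=tuple(
                s for s, k in zip(self.substructure_ids, keep) if k
            ),
            incidence=self.incidence[:, keep],
        )

    def restrict_drugs(self, keep: tuple[str, ...]) -> "SubstructureMatrix":
        index = {d: i for i, d in enumerate(self.drug_ids)}
        rows = [index[d] for d in keep]
        return SubstructureMatrix(
            drug_ids=tuple(keep),
            substructure_ids=self.substructure_ids,
            incidence=self.incidence[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence,
            index=pd.Index(self.drug_ids, name="drug_id"),
            columns=list(self.substructure_ids),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SubstructureMatrix":
        return cls(
            drug_ids=tuple(str(d) for d in df.index),
            substructure_ids=tuple(str(c) for c in df.columns),
            incidence=df.to_numpy(),
        )


def load_matrix(path: str | Path) -> SubstructureMatrix:
    """Load a TSV matrix: first column drug_id, remaining columns 0/1 cells."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in substructure matrix") from exc
    return SubstructureMatrix(
        drug_ids=tuple(str(d) for d in df.index),
        substructure_ids=tuple(str(c) for c in df.columns),
        incidence=values,
    )


def write_matrix(matrix: SubstructureMatrix, path: str | Path) -> None:
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# netpharm {__version__} substructure_matrix\n")
        matrix.to_dataframe().to_csv(fh, sep="\t")


def synthetic_matrix(
    n_drugs: int,
    n_substructures: int,
    density: float = 0.25,
    seed: int = 0,
    drug_prefix: str = "D",
) -> SubstructureMatrix:
    """Seeded pseudorandom binary matrix (the ``SYNTH`` provider).

    Deterministic in ``seed``; every drug is guaranteed at least one set bit
    so it can seed a diffusion.
    """
    rng = np.random.default_rng(seed)
    inc = (rng.random((n_drugs, n_substructures)) < density).astype(np.uint8)
    for i in range(n_drugs):
        if inc[i].sum() == 0:
            inc[i, rng.integers(n_substructures)] = 1
    return SubstructureMatrix(
        drug_ids=tuple(f"{drug_prefix}{i:03d}" for i in range(n_drugs)),
        substructure_ids=tuple(f"SYNTH:{j:04d}" for j in range(n_substructures)),
        incidence=inc,
    )


def _maccs_provider(smiles_table: pd.DataFrame) -> SubstructureMatrix:
    try:
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise CapabilityError(
            "MACCS provider requires rdkit; install the 'chem' extra or use the "
            "FILE provider with a precomputed matrix"
        ) from exc

    drug_ids: list[str] = []
    rows: list[np.ndarray] = []
    for _, row in smiles_table.iterrows():
        drug = str(row["drug_id"])
        mol = Chem.MolFromSmiles(str(row["smiles"]))
        if mol is None:
            raise ParseError(f"unparseable SMILES for drug {drug!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)
        rows.append(np.array([fp.GetBit(i) for i in range(fp.GetNumBits())], dtype=np.uint8))
        drug_ids.append(drug)
    inc = np.vstack(rows) if rows else np.zeros((0, 167), dtype=np.uint8)
    return SubstructureMatrix(
        drug_ids=tuple(drug_ids),
        substructure_ids=tuple(f"MACCS:{i:04d}" for i in range(inc.shape[1])),
        incidence=inc,
    )


def _unavailable_provider(family: str) -> Callable[[pd.DataFrame], SubstructureMatrix]:
    def provider(smiles_table: pd.DataFrame) -> SubstructureMatrix:
        raise CapabilityError(
            f"no in-process provider computes {family} fingerprints; "
            "precompute the matrix externally and load it with the FILE provider"
        )

    return provider


_PROVIDERS: dict[str, Callable[[pd.DataFrame], SubstructureMatrix]] = {
    "MACCS": _maccs_provider,
    "FP4": _unavailable_provider("FP4"),
    "KR": _unavailable_provider("Klekota-Roth"),
    "PubChem": _unavailable_provider("PubChem"),
}


def register_provider(
    family: str, provider: Callable[[pd.DataFrame], SubstructureMatrix]
) -> None:
    """Register (or override) the provider backing a fingerprint family."""
    _PROVIDERS[family] = provider


def compute_substructures(
    smiles_table: pd.DataFrame,
    family: str = "MACCS",
    min_support: int = 1,
) -> SubstructureMatrix:
    """Compute a binary substructure matrix for the drugs in ``smiles_table``.

    Parameters
    ----------
    smiles_table
        Two columns, ``drug_id`` and ``smiles``.
    family
        Fingerprint family name; must have a registered provider
        (``FILE``/``SYNTH`` inputs go through :func:`load_matrix` /
        :func:`synthetic_matrix` instead).
    min_support
        Substructures present in fewer than this many drugs are dropped
        (default 1, i.e. only the mandatory all-zero-column pruning).

    Columns are ordered lexicographically by substructure id; rows follow the
    input drug order.
    """
    for col in ("drug_id", "smiles"):
        if col not in smiles_table.columns:
            raise FormatError(f"smiles table missing column {col!r}")
    if family not in _PROVIDERS:
        raise CapabilityError(
            f"unknown fingerprint family {family!r}; known: {sorted(_PROVIDERS)}"
        )
    matrix = _PROVIDERS[family](smiles_table)

    order = np.argsort(np.array(matrix.substructure_ids))
    matrix = SubstructureMatrix(
        drug_ids=matrix.drug_ids,
        substructure_ids=tuple(matrix.substructure_ids[i] for i in order),
        incidence=matrix.incidence[:, order],
    )
    support = matrix.incidence.sum(axis=0)
    keep = support >= max(min_support, 1)
    return SubstructureMatrix(
        drug_ids=matrix.drug_ids,
        substructure_ids=tuple(
            s for s, k in zip(matrix.substructure_ids, keep) if k
        ),
        incidence=matrix.incidence[:, keep],
    )


class CommonSubset(NamedTuple):
    """Result of aligning a substructure matrix with a DTI catalog."""

    matrix: SubstructureMatrix
    catalog: DTICatalog
    training_drugs: tuple[str, ...]
    query_drugs: tuple[str, ...]
    dropped_from_catalog: tuple[str, ...]


def restrict_to_common(
    matrix: SubstructureMatrix, catalog: DTICatalog
) -> CommonSubset:
    """Align fingerprints and interactions on a common drug set.

    Training drugs are those present in both inputs; drugs present only in
    the matrix are retained as *query* drugs ("new chemicals" with structure
    but no known targets); catalog drugs without structure are dropped from
    the catalog (they cannot join the substructure layer).
    """
    matrix_drugs = set(matrix.drug_ids)
    catalog_drugs = set(catalog.drugs)
    training = tuple(sorted(matrix_drugs & catalog_drugs))
    query = tuple(sorted(matrix_drugs - catalog_drugs))
    dropped = tuple(sorted(catalog_drugs - matrix_drugs))

    if not training:
        # without shared drugs there are no training edges, hence no target
        # layer to rank, regardless of how many query drugs remain
        raise ConfigurationError(
            "no drug appears in both the substructure matrix and the catalog"
        )
    if dropped:
        logger.info(
            "restrict_to_common: dropped %d catalog drugs without structure: %s",
            len(dropped), ", ".join(dropped[:10]),
        )
    if query:
        logger.info("restrict_to_common: %d new chemicals (matrix only)", len(query))

    kept_order = tuple(d for d in matrix.drug_ids if d in matrix_drugs)
    return CommonSubset(
        matrix=matrix.restrict_drugs(kept_order),
        catalog=catalog.restrict_drugs(training),
        training_drugs=training,
        query_drugs=query,
        dropped_from_catalog=dropped,
    )
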
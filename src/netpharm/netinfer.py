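"""Balanced substructure-drug-target network-based inference (bSDTNBI).

Candidate targets for a (possibly new) chemical are scored by resource
diffusion on a tripartite network with three node layers — drugs,
substructures (fingerprint bits) and protein targets — and two edge layers:
drug-substructure incidence and known drug-target interactions.  There are
no within-layer or substructure-target edges.

The diffusion is a proper stochastic flow controlled by four parameters:

``alpha``
    split of the unit seed mass between the query's known targets
    (share ``1 - alpha``) and its substructures (share ``alpha``).  A new
    chemical with no known targets puts all mass on its substructures.
``beta``
    edge-type weight during drug-outward redistribution: drug-substructure
    edges carry raw weight ``beta``, drug-target edges ``1 - beta``.
``gamma``
    hub-penalty exponent applied to the *receiving* node's degree during
    drug-outward redistribution (``gamma < 0`` down-weights hubs).
``k``
    number of diffusion rounds.

One round is phase A then phase B.  In phase A every substructure/target
node splits its resource equally among its drug neighbours.  In phase B
every drug sends its resource to its neighbours with per-edge weight
``w(edge type) * deg(receiver)^gamma``, renormalized per drug so outflow
equals the drug's resource.  Total mass is therefore exactly 1 after every
phase (asserted to 1e-12).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np

from .catalog_io import DTICatalog
from .errors import CapabilityError, ConfigurationError, ParameterError
from .substructures import SubstructureMatrix

__all__ = [
    "DiffusionParams",
    "TripartiteNetwork",
    "NodeResources",
    "TargetScoreList",
    "build_network",
    "diffuse",
    "rank_targets",
    "predict_targets",
]

logger = logging.getLogger(__name__)

#: mass-conservation tolerance after every diffusion phase
CONSERVATION_TOL = 1e-12


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the balanced diffusion (defaults from benchmark tuning)."""

    alpha: float = 0.1
    beta: float = 0.1
    gamma: float = -0.5
    k: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.beta <= 1.0):
            raise ParameterError(f"beta must be in [0, 1], got {self.beta}")
        if self.k < 1 or int(self.k) != self.k:
            raise ParameterError(f"k must be a positive integer, got {self.k}")


@dataclass(frozen=True)
class TripartiteNetwork:
    """Drug / substructure / target layers with bipartite incidence blocks.

    ``b_ds[i, j] == 1`` iff drug i contains substructure j;
    ``b_dt[i, j] == 1`` iff drug i has a known interaction with target j.
    """

    drug_ids: tuple[str, ...]
    substructure_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    b_ds: np.ndarray
    b_dt: np.ndarray

    def __post_init__(self) -> None:
        b_ds = (np.asarray(self.b_ds) > 0).astype(np.float64)
        b_dt = (np.asarray(self.b_dt) > 0).astype(np.float64)
        if b_ds.shape != (len(self.drug_ids), len(self.substructure_ids)):
            raise ConfigurationError("b_ds shape does not match node lists")
        if b_dt.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ConfigurationError("b_dt shape does not match node lists")
        object.__setattr__(self, "b_ds", b_ds)
        object.__setattr__(self, "b_dt", b_dt)
        b_ds.setflags(write=False)
        b_dt.setflags(write=False)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_substructures(self) -> int:
        return len(self.substructure_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_edges(self) -> int:
        return int(self.b_ds.sum() + self.b_dt.sum())

    @property
    def substructure_degrees(self) -> np.ndarray:
        """Degree of each substructure node (its drug neighbours)."""
        return self.b_ds.sum(axis=0)

    @property
    def target_degrees(self) -> np.ndarray:
        return self.b_dt.sum(axis=0)

    @property
    def drug_degrees(self) -> np.ndarray:
        return self.b_ds.sum(axis=1) + self.b_dt.sum(axis=1)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise ConfigurationError(f"drug {drug_id!r} not in network") from None

    def known_targets_of(self, drug_id: str) -> frozenset[str]:
        row = self.b_dt[self.drug_index(drug_id)]
        return frozenset(t for t, x in zip(self.target_ids, row) if x > 0)

    def checksum(self) -> str:
        """Stable digest of the node lists and edge sets (provenance stamp)."""
        h = hashlib.sha256()
        for part in (self.drug_ids, self.substructure_ids, self.target_ids):
            h.update("\x1f".join(part).encode())
            h.update(b"\x1e")
        h.update(np.ascontiguousarray(self.b_ds, dtype=np.uint8).tobytes())
        h.update(np.ascontiguousarray(self.b_dt, dtype=np.uint8).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class NodeResources:
    """Resource vector over all nodes, split by layer."""

    drugs: np.ndarray
    substructures: np.ndarray
    targets: np.ndarray

    def total(self) -> float:
        return float(self.drugs.sum() + self.substructures.sum() + self.targets.sum())


@dataclass(frozen=True)
class TargetScoreList:
    """Ranked candidate targets for one query drug, with provenance."""

    query_drug: str
    entries: tuple[tuple[str, float], ...]
    params: DiffusionParams = field(default_factory=DiffusionParams)
    network_checksum: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)

    @property
    def scores(self) -> tuple[float, ...]:
        return tuple(s for _, s in self.entries)


def build_network(
    catalog: DTICatalog, matrix: SubstructureMatrix
) -> TripartiteNetwork:
    """Assemble the tripartite network from interactions and fingerprints.

    Drug layer = the matrix's drugs (training drugs plus query drugs);
    catalog edges attach known targets to training drugs.  All-zero
    substructure columns are pruned (isolated nodes).  Duplicate edges in
    the inputs collapse: the network is simple.
    """
    if matrix.n_drugs == 0:
        raise ConfigurationError("substructure matrix has no drugs")
    if len(catalog) == 0:
        raise ConfigurationError("DTI catalog has no edges: no targets to rank")

    matrix = matrix.prune_empty_columns()
    drug_ids = matrix.drug_ids
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    target_ids = tuple(sorted({r.target_gene for r in catalog}))
    target_index = {t: j for j, t in enumerate(target_ids)}

    b_dt = np.zeros((len(drug_ids), len(target_ids)), dtype=np.float64)
    skipped = 0
    for r in catalog:
        i = drug_index.get(r.drug_id)
        if i is None:
            skipped += 1
            continue
        b_dt[i, target_index[r.target_gene]] = 1.0
    if skipped:
        logger.warning(
            "build_network: %d catalog edges reference drugs without structure "
            "(run restrict_to_common first)", skipped,
        )
    if b_dt.sum() == 0:
        raise ConfigurationError("no catalog edge matches a drug in the matrix")

    return TripartiteNetwork(
        drug_ids=drug_ids,
        substructure_ids=matrix.substructure_ids,
        target_ids=target_ids,
        b_ds=matrix.incidence,
        b_dt=b_dt,
    )


def _initial_resources(
    network: TripartiteNetwork, query_drug: str, alpha: float
) -> NodeResources:
    qi = network.drug_index(query_drug)
    s_mask = network.b_ds[qi] > 0
    t_mask = network.b_dt[qi] > 0
    n_s, n_t = int(s_mask.sum()), int(t_mask.sum())

    f_s = np.zeros(network.n_substructures)
    f_t = np.zeros(network.n_targets)
    if n_s == 0 and n_t == 0:
        raise CapabilityError(
            f"query drug {query_drug!r} has neither substructure nor known "
            "target edges: no seed resource can be allocated"
        )
    if n_t == 0:
        # new chemical: all mass on its substructures
        f_s[s_mask] = 1.0 / n_s
    elif n_s == 0:
        # structureless known drug: all mass on its targets
        f_t[t_mask] = 1.0 / n_t
    else:
        f_t[t_mask] = (1.0 - alpha) / n_t
        f_s[s_mask] = alpha / n_s
    return NodeResources(
        drugs=np.zeros(network.n_drugs), substructures=f_s, targets=f_t
    )


def _assert_conserved(f: NodeResources, phase: str) -> None:
    total = f.total()
    assert abs(total - 1.0) < CONSERVATION_TOL, (
        f"mass not conserved after {phase}: total={total!r}"
    )


def diffuse(
    network: TripartiteNetwork,
    query_drug: str,
    params: DiffusionParams | None = None,
) -> NodeResources:
    """Run ``k`` rounds of two-phase diffusion seeded at ``query_drug``.

    Returns the final resource vector (after phase B of the last round, so
    all mass sits on substructure and target nodes).  Total mass is checked
    to equal 1 after every phase.
    """
    params = params or DiffusionParams()
    f = _initial_resources(network, query_drug, params.alpha)

    deg_s = network.substructure_degrees  # >= 1 after pruning
    deg_t = network.target_degrees
    if (deg_t == 0).any():
        raise ConfigurationError("target node with no drug neighbour")

    # phase-B per-edge raw weights: edge-type weight times receiver-degree^gamma
    w_s = params.beta * deg_s ** params.gamma
    w_t = (1.0 - params.beta) * deg_t ** params.gamma
    z = network.b_ds @ w_s + network.b_dt @ w_t  # per-drug normalizer
    deg_d = network.drug_degrees
    # a drug whose weighted outflow vanishes (beta exactly 0 or 1 with edges
    # of a single type) splits its resource uniformly over its neighbours
    # instead, so the flow stays stochastic for every parameter choice
    degenerate = (z <= 0) & (deg_d > 0)
    z_safe = np.where(z > 0, z, 1.0)
    deg_d_safe = np.where(deg_d > 0, deg_d, 1.0)

    for _ in range(params.k):
        # phase A: substructures/targets split equally among drug neighbours
        gain = network.b_ds @ (f.substructures / deg_s) + network.b_dt @ (
            f.targets / deg_t
        )
        f = NodeResources(
            drugs=f.drugs + gain,
            substructures=np.zeros_like(f.substructures),
            targets=np.zeros_like(f.targets),
        )
        _assert_conserved(f, "phase A")

        # phase B: drugs redistribute with weighted, hub-penalized edges
        share = np.where(~degenerate, f.drugs, 0.0) / z_safe
        uniform = np.where(degenerate, f.drugs, 0.0) / deg_d_safe
        f = NodeResources(
            drugs=np.zeros_like(f.drugs),
            substructures=(share @ network.b_ds) * w_s + uniform @ network.b_ds,
            targets=(share @ network.b_dt) * w_t + uniform @ network.b_dt,
        )
        _assert_conserved(f, "phase B")

    return f


def rank_targets(
    resources: NodeResources,
    network: TripartiteNetwork,
    query_drug: str,
    L: int = 20,
    exclude_known: bool = True,
) -> TargetScoreList:
    """Rank target-layer nodes by final resource, truncated to the top ``L``.

    Known targets of the query are removed before truncation when
    ``exclude_known`` (the evaluation setting); ties break lexicographically
    by gene symbol, making the order fully deterministic.
    """
    if L < 1:
        raise ParameterError(f"L must be >= 1, got {L}")
    known = network.known_targets_of(query_drug) if exclude_known else frozenset()
    scored = [
        (gene, float(score))
        for gene, score in zip(network.target_ids, resources.targets)
        if gene not in known
    ]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    return TargetScoreList(
        query_drug=query_drug,
        entries=tuple(scored[:L]),
        network_checksum=network.checksum(),
    )


def predict_targets(
    catalog: DTICatalog,
    matrix: SubstructureMatrix,
    query_drug: str,
    params: DiffusionParams | None = None,
    L: int = 20,
    exclude_known: bool = True,
) -> TargetScoreList:
    """Convenience wrapper: build the network, diffuse, rank."""
    params = params or DiffusionParams()
    network = build_network(catalog, matrix)
    resources = diffuse(network, query_drug, params)
    ranked = rank_targets(resources, network, query_drug, L=L, exclude_known=exclude_known)
    return TargetScoreList(
        query_drug=ranked.query_drug,
        entries=ranked.entries,
        params=params,
        network_checksum=ranked.network_checksum,
    )
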
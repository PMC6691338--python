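"""Construction and export of the polypharmacology summary networks.

Three annotated graphs summarize a compound's target profile:

* **D-T** — the drug-target network: known interactions plus top-ranked
  predicted targets, each edge tagged with its provenance.
* **T-F** — the target-function network: targets linked to the functional
  modules (hallmark processes) they participate in.
* **D-T-D** — the drug-target-disease network: the drug's targets linked to
  every cancer type whose significantly-mutated-gene set contains them.

Graphs are :class:`networkx.Graph` objects with a node attribute ``ntype``
(``drug`` / ``target`` / ``cancer`` / ``function_module``) and an edge
attribute ``etag`` (``known`` / ``predicted`` / ``smg_membership`` /
``function_link``).  Exports: SIF (interaction label = ``etag``) and
GraphML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .catalog_io import DTICatalog, SMGCatalog
from .errors import FormatError
from .netinfer import TargetScoreList

__all__ = [
    "build_dt",
    "build_tf",
    "build_dtd",
    "degree_summary",
    "write_sif",
    "read_sif",
    "write_graphml",
    "read_graphml",
]

NODE_TYPES = ("drug", "target", "cancer", "function_module")
EDGE_TAGS = ("known", "predicted", "smg_membership", "function_link")


def build_dt(
    catalog: DTICatalog, predictions: TargetScoreList | None = None
) -> nx.Graph:
    """Drug-target graph: union of known interactions and top predictions.

    A predicted edge that duplicates a known one keeps the ``known`` tag
    (experimental evidence outranks inference); distinct edges are counted
    once each, so the edge total is |known| + |predicted| - |shared|.
    """
    g = nx.Graph()
    for r in catalog:
        g.add_node(r.drug_id, ntype="drug")
        g.add_node(r.target_gene, ntype="target")
        g.add_edge(r.drug_id, r.target_gene, etag="known", source=r.source)
    if predictions is not None:
        drug = predictions.query_drug
        g.add_node(drug, ntype="drug")
        for gene, score in predictions.entries:
            if g.has_edge(drug, gene):
                continue
            g.add_node(gene, ntype="target")
            g.add_edge(drug, gene, etag="predicted", score=score)
    return g


def build_tf(
    target_genes: Iterable[str],
    annotation: pd.DataFrame,
    modules: Sequence[str] | None = None,
) -> nx.Graph:
    """Target-function graph from a (gene, module) annotation table.

    ``modules``, when given, is the declared module vocabulary; an
    annotation row referencing an undeclared module is an error.
    """
    for col in ("gene", "module"):
        if col not in annotation.columns:
            raise FormatError(f"annotation table missing column {col!r}")
    declared = set(modules) if modules is not None else None

    g = nx.Graph()
    for gene in target_genes:
        g.add_node(str(gene).upper(), ntype="target")
    for _, row in annotation.iterrows():
        gene = str(row["gene"]).upper()
        module = str(row["module"])
        if declared is not None and module not in declared:
            raise FormatError(f"module {module!r} not in the declared module list")
        g.add_node(gene, ntype="target")
        g.add_node(module, ntype="function_module")
        g.add_edge(gene, module, etag="function_link")
    return g


def build_dtd(
    drug: str, target_genes: Iterable[str], smg: SMGCatalog
) -> nx.Graph:
    """Drug-target-disease graph: targets wired to the cancers that mutate them.

    Every target gets a ``known`` drug edge; a target-cancer
    ``smg_membership`` edge is added whenever the target belongs to that
    cancer's SMG set.  Targets in no SMG set stay as flagged isolated
    (drug-only) nodes.
    """
    g = nx.Graph()
    g.add_node(drug, ntype="drug")
    targets = [str(t).upper() for t in target_genes]
    for gene in targets:
        in_any = False
        g.add_node(gene, ntype="target")
        g.add_edge(drug, gene, etag="known")
        for code in smg.codes:
            if gene in smg[code]:
                g.add_node(code, ntype="cancer")
                g.add_edge(gene, code, etag="smg_membership")
                in_any = True
        g.nodes[gene]["in_smg"] = in_any
    return g


def degree_summary(graph: nx.Graph, top_k: int = 10) -> dict[str, pd.DataFrame]:
    """Min/mean/max degree per node type plus the top-k hubs per type.

    Hubs are ordered by degree descending, name ascending — a deterministic
    tie-break so summaries are reproducible across runs.
    """
    rows = []
    hub_rows = []
    by_type: dict[str, list[tuple[str, int]]] = {}
    for node, data in graph.nodes(data=True):
        by_type.setdefault(data.get("ntype", "unknown"), []).append(
            (node, graph.degree(node))
        )
    for ntype in sorted(by_type):
        degrees = [d for _, d in by_type[ntype]]
        rows.append(
            {
                "ntype": ntype,
                "n_nodes": len(degrees),
                "min_degree": min(degrees),
                "mean_degree": sum(degrees) / len(degrees),
                "max_degree": max(degrees),
            }
        )
        hubs = sorted(by_type[ntype], key=lambda nd: (-nd[1], nd[0]))[:top_k]
        for rank, (node, deg) in enumerate(hubs, start=1):
            hub_rows.append({"ntype": ntype, "rank": rank, "node": node, "degree": deg})
    return {
        "by_type": pd.DataFrame(rows),
        "hubs": pd.DataFrame(hub_rows),
    }


def write_sif(graph: nx.Graph, path: str | Path) -> None:
    """Write ``source<TAB>etag<TAB>target`` rows (deterministic order)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get('etag', 'link')}\t{v}\n")


def read_sif(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{line_no}: SIF row needs 3 fields")
            u, etag, v = fields
            g.add_edge(u, v, etag=etag)
    return g


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
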
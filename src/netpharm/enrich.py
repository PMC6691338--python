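"""Statistical prioritization of cancer indications by target-set enrichment.

A compound is a candidate therapy for a cancer type when its protein targets
overlap that cancer's significantly mutated genes (SMGs) more than chance.
For every cancer type a 2x2 table is built —

=====================  ===========  ===============
                       in SMG set   not in SMG set
=====================  ===========  ===============
drug target            a            b
not a drug target      c            d
=====================  ===========  ===============

— and tested with a one-sided (enrichment, "greater") Fisher exact test.
P-values are corrected for the number of cancer types tested, either by the
Benjamini-Hochberg step-up procedure or by a single-step multiplicative
(Bonferroni-style) correction ``q = min(1, p * m)``; a configurable ``m``
allows correcting against more tests than p-values supplied.

The same machinery drives generic gene-set over-representation analysis
(ORA) against arbitrary GMT collections, e.g. pathway sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import SMGCatalog
from .errors import ConfigurationError, ParameterError

__all__ = [
    "UniverseSpec",
    "CorrectionConfig",
    "EnrichmentResult",
    "fisher_one_sided",
    "correct_pvalues",
    "prioritize_indications",
    "geneset_ora",
    "export_indication_report",
    "results_to_frame",
]


@dataclass(frozen=True)
class UniverseSpec:
    """Background gene universe for the 2x2 tables.

    ``fixed_n``: an abstract universe of ``n`` genes (protein-coding genome
    scale by default); ``union_smg``: the union of all tested gene sets plus
    the query set; ``explicit_list``: a caller-supplied gene list.
    """

    mode: str = "fixed_n"
    n: int = 20000
    genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_n", "union_smg", "explicit_list"):
            raise ParameterError(f"unknown universe mode {self.mode!r}")
        if self.mode == "fixed_n" and self.n < 1:
            raise ParameterError("fixed_n universe needs n >= 1")
        if self.mode == "explicit_list" and not self.genes:
            raise ParameterError("explicit_list universe needs a gene list")

    def size_and_membership(
        self, target_genes: frozenset[str], gene_sets: Mapping[str, frozenset[str]]
    ) -> tuple[int, frozenset[str] | None]:
        """Resolve the universe size; returns (N, membership or None)."""
        everything = set(target_genes)
        for genes in gene_sets.values():
            everything |= genes
        if self.mode == "fixed_n":
            if self.n < len(everything):
                raise ConfigurationError(
                    f"fixed universe n={self.n} smaller than the union of the "
                    f"tested sets ({len(everything)} genes)"
                )
            return self.n, None
        if self.mode == "union_smg":
            return len(everything), frozenset(everything)
        assert self.genes is not None
        outside = everything - self.genes
        if outside:
            raise ConfigurationError(
                "genes outside the explicit universe: "
                + ", ".join(sorted(outside)[:10])
            )
        return len(self.genes), self.genes


@dataclass(frozen=True)
class CorrectionConfig:
    """Multiple-testing correction: method, test count basis, threshold."""

    method: str = "multiplicative"
    m: int | None = None  # defaults to the number of p-values supplied
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("bh_stepup", "multiplicative"):
            raise ParameterError(f"unknown correction method {self.method!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise ParameterError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    """One cancer type's row of the indication screen."""

    cancer_type: str
    overlap: int
    target_count: int
    set_count: int
    universe_n: int
    p_raw: float
    q: float
    neglog_q: float
    significant: bool


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Returns the hypergeometric upper tail ``P(X >= a)`` at fixed margins —
    the probability, drawing ``a + c`` genes from a universe of
    ``a + b + c + d`` containing ``a + b`` marked ones, of an overlap at
    least as large as observed.  Computed with the survival function of the
    hypergeometric distribution, which works in log-space internally.
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ParameterError(f"count {name}={v!r} must be a non-negative integer")
    n_total = a + b + c + d
    if n_total == 0:
        raise ParameterError("all four counts are zero")
    return float(np.clip(stats.hypergeom.sf(a - 1, n_total, a + b, a + c), 0.0, 1.0))


def correct_pvalues(
    p_list: Sequence[float], config: CorrectionConfig = CorrectionConfig()
) -> list[float]:
    """Adjust p-values for ``m`` tests; output order matches input order.

    ``multiplicative``: single-step ``q_i = min(1, p_i * m)``.
    ``bh_stepup``: Benjamini-Hochberg step-up with monotonicity enforcement,
    with ``m`` (not ``len(p_list)``) as the denominator basis, so a subset of
    a larger screen can be corrected against the full test count.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = config.m if config.m is not None else p.size
    if m < p.size:
        raise ParameterError(f"m={m} smaller than the {p.size} p-values supplied")

    if config.method == "multiplicative":
        return [float(min(1.0, pi * m)) for pi in p]

    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return [float(v) for v in q]


def _enrichment_rows(
    query_genes: frozenset[str],
    gene_sets: Mapping[str, frozenset[str]],
    universe: UniverseSpec,
    correction: CorrectionConfig,
) -> list[EnrichmentResult]:
    if not query_genes:
        raise ConfigurationError("query gene set is empty")
    if not gene_sets:
        raise ConfigurationError("no gene sets to test against")

    n_universe, membership = universe.size_and_membership(query_genes, gene_sets)
    if membership is not None:
        query = query_genes & membership
    else:
        query = query_genes

    names = sorted(gene_sets)
    p_raw: list[float] = []
    overlaps: list[int] = []
    for name in names:
        genes = gene_sets[name]
        a = len(query & genes)
        b = len(query) - a
        c = len(genes) - a
        d = n_universe - a - b - c
        p_raw.append(fisher_one_sided(a, b, c, d))
        overlaps.append(a)

    m = correction.m if correction.m is not None else len(names)
    qs = correct_pvalues(p_raw, CorrectionConfig(correction.method, m, correction.threshold))

    results = [
        EnrichmentResult(
            cancer_type=name,
            overlap=a,
            target_count=len(query),
            set_count=len(gene_sets[name]),
            universe_n=n_universe,
            p_raw=p,
            q=q,
            neglog_q=-math.log10(q),
            significant=q < correction.threshold,
        )
        for name, a, p, q in zip(names, overlaps, p_raw, qs)
    ]
    results.sort(key=lambda r: (r.q, r.cancer_type))
    return results


def prioritize_indications(
    target_genes: Iterable[str],
    smg: SMGCatalog,
    universe: UniverseSpec = UniverseSpec(),
    correction: CorrectionConfig = CorrectionConfig(),
) -> list[EnrichmentResult]:
    """Rank cancer types by enrichment of the drug's targets in their SMG sets.

    One Fisher test per cancer type; ``m`` defaults to the number of cancer
    types tested.  Results are sorted by adjusted p ascending (ties broken by
    cancer code) and flagged significant at the configured threshold.
    """
    query = frozenset(str(g).strip().upper() for g in target_genes)
    return _enrichment_rows(query, smg.sets, universe, correction)


def geneset_ora(
    gene_list: Iterable[str],
    gmt_sets: Mapping[str, Iterable[str]],
    universe: UniverseSpec = UniverseSpec(),
    correction: CorrectionConfig = CorrectionConfig(),
    enriched_only: bool = False,
) -> pd.DataFrame:
    """Generic over-representation analysis of a gene list against GMT sets.

    Returns the full table (one row per set); with ``enriched_only`` the view
    is restricted to sets passing the significance threshold.
    """
    query = frozenset(str(g).strip().upper() for g in gene_list)
    sets = {name: frozenset(str(g).strip().upper() for g in genes)
            for name, genes in gmt_sets.items()}
    results = _enrichment_rows(query, sets, universe, correction)
    df = results_to_frame(results).rename(columns={"cancer_type": "gene_set"})
    if enriched_only:
        df = df[df["significant"]].reset_index(drop=True)
    return df


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cancer_type": r.cancer_type,
                "overlap": r.overlap,
                "target_count": r.target_count,
                "set_count": r.set_count,
                "universe_n": r.universe_n,
                "p_raw": r.p_raw,
                "q": r.q,
                "neglog_q": r.neglog_q,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def export_indication_report(
    results: Sequence[EnrichmentResult],
    validated_annotations: Mapping[str, Sequence[str] | str] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Tabulate an indication screen with literature-validation annotations.

    ``validated_annotations`` maps cancer code to supporting PMIDs (a list,
    or a ``"|"``-joined string; empty or ``"N/A"`` means unvalidated).  The
    summary reports how many significant indications exist, how many of them
    are literature-validated, and the resulting success rate in percent
    (1 decimal).  ``neglog_q`` is computed from the unrounded adjusted p and
    printed to 2 decimals in the table.
    """
    annotations = validated_annotations or {}

    def _pmids(code: str) -> list[str]:
        raw = annotations.get(code, "")
        if isinstance(raw, str):
            parts = [p.strip() for p in raw.split("|")]
        else:
            parts = [str(p).strip() for p in raw]
        return [p for p in parts if p and p.upper() != "N/A"]

    rows = []
    for r in results:
        pmids = _pmids(r.cancer_type)
        rows.append(
            {
                "cancer_type": r.cancer_type,
                "overlap": r.overlap,
                "p_raw": r.p_raw,
                "q": r.q,
                "neglog_q": round(r.neglog_q, 2),
                "significant": r.significant,
                "validated": bool(pmids),
                "pmids": "|".join(pmids) if pmids else "N/A",
            }
        )
    table = pd.DataFrame(rows)

    n_significant = int(sum(r.significant for r in results))
    n_validated = int(
        sum(bool(_pmids(r.cancer_type)) for r in results if r.significant)
    )
    success_rate = (
        round(100.0 * n_validated / n_significant, 1) if n_significant else 0.0
    )
    summary = {
        "n_significant": n_significant,
        "n_validated": n_validated,
        "success_rate": success_rate,
    }
    return table, summary
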
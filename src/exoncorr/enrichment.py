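"""Functional-term enrichment of genes containing associated exons.

For a term annotating K of the N universe genes, a foreground of f genes with
k term members gets the upper-tail hypergeometric p-value — the same log-space
overlap kernel used by the correspondence tests.  Term depth in the ontology
DAG (minimum edge count from a root) supports the reporting filter used for
developmental analyses (depth == 3, p < 1e-30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .correspondence import AssociatedExonSet, hypergeom_tail
from .errors import AnnotationLookupError, DomainError

__all__ = [
    "TermAnnotation",
    "TermDag",
    "EnrichmentResult",
    "foreground_genes",
    "term_enrichment",
    "min_depth",
    "report_top_terms",
    "load_gene_terms",
    "load_dag",
]


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    gene_ids: frozenset
    namespace: str = "biological_process"


@dataclass
class TermDag:
    """Parent->child term DAG with roots at depth 0."""

    graph: nx.DiGraph

    @classmethod
    def from_edges(cls, edges) -> "TermDag":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise DomainError("term graph contains a cycle")
        return cls(graph=g)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.in_degree(n) == 0}


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # foreground genes with the term
    f: int  # foreground size
    big_k: int  # universe genes with the term
    big_n: int  # universe size
    log10_p: float
    min_depth: int | None = None

    @property
    def p_value(self) -> float:
        return 10.0 ** self.log10_p


def foreground_genes(
    assoc: AssociatedExonSet, status: str, exon_to_gene: dict[str, str]
) -> set[str]:
    """Parent genes of the sample's associated exons with the given status."""
    genes = set()
    for exon_id, st in assoc.members:
        if st != status:
            continue
        if exon_id not in exon_to_gene:
            raise AnnotationLookupError(f"exon '{exon_id}' has no gene mapping")
        genes.add(exon_to_gene[exon_id])
    return genes


def term_enrichment(
    foreground: set[str], terms: list[TermAnnotation], universe: set[str]
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of each term in the foreground."""
    if not foreground <= universe:
        raise DomainError(
            f"foreground genes outside the universe: {sorted(foreground - universe)[:3]}"
        )
    n = len(universe)
    f = len(foreground)
    out = []
    for term in terms:
        genes = term.gene_ids & universe
        k = len(foreground & genes)
        log10_p = hypergeom_tail(k, f, len(genes), n)
        out.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                k=k,
                f=f,
                big_k=len(genes),
                big_n=n,
                log10_p=log10_p,
            )
        )
    return out


def _root_depths(dag: TermDag) -> dict[str, int]:
    depths: dict[str, int] = {}
    for root in dag.roots:
        for node, d in nx.single_source_shortest_path_length(dag.graph, root).items():
            if node not in depths or d < depths[node]:
                depths[node] = d
    return depths


def min_depth(dag: TermDag, term_id: str) -> int:
    """Shortest root->term path length (roots have depth 0), by BFS."""
    if term_id not in dag.graph:
        raise AnnotationLookupError(f"term '{term_id}' not in DAG")
    depths = _root_depths(dag)
    if term_id not in depths:
        raise DomainError(f"term '{term_id}' unreachable from any root")
    return int(depths[term_id])


def annotate_depths(results: list[EnrichmentResult], dag: TermDag) -> list[EnrichmentResult]:
    """Attach DAG min-depths to enrichment results (terms absent from the DAG get None)."""
    depths = _root_depths(dag)
    return [
        EnrichmentResult(
            r.term_id, r.term_name, r.k, r.f, r.big_k, r.big_n, r.log10_p,
            min_depth=int(depths[r.term_id]) if r.term_id in depths else None,
        )
        for r in results
    ]


def report_top_terms(
    results: list[EnrichmentResult],
    p_max: float = 1e-30,
    depth_eq: int | None = None,
    top_n: int = 5,
) -> pd.DataFrame:
    """Top enriched terms: p < p_max, optional exact-depth filter, sorted by p.

    Ties in p are broken by term_id for determinism.
    """
    import math

    log10_pmax = math.log10(p_max)
    kept = [r for r in results if r.log10_p < log10_pmax]
    if depth_eq is not None:
        kept = [r for r in kept if r.min_depth == depth_eq]
    kept.sort(key=lambda r: (r.log10_p, r.term_id))
    rows = [
        (r.term_id, r.term_name, r.k, r.f, r.big_k, r.big_n, r.p_value, r.log10_p, r.min_depth)
        for r in kept[:top_n]
    ]
    return pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "k", "f", "K", "N", "p_value", "log10_p", "min_depth"],
    )


def load_gene_terms(path: str | Path) -> list[TermAnnotation]:
    """Read a gene->term TSV (gene_id, term_id[, term_name, namespace]) into terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "term_name" not in df.columns:
        df["term_name"] = df["term_id"]
    if "namespace" not in df.columns:
        df["namespace"] = "biological_process"
    out = []
    for term_id, grp in df.groupby("term_id"):
        out.append(
            TermAnnotation(
                term_id=str(term_id),
                term_name=str(grp["term_name"].iloc[0]),
                gene_ids=frozenset(grp["gene_id"]),
                namespace=str(grp["namespace"].iloc[0]),
            )
        )
    return sorted(out, key=lambda t: t.term_id)


def load_dag(path: str | Path) -> TermDag:
    """Read a parent-child edge TSV (parent, child) into a TermDag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return TermDag.from_edges(list(zip(df[cols[0]], df[cols[1]])))
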
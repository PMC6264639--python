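"""Gene retrieval for significant windows and GO over-representation testing.

Genes overlapping detected windows by at least one base (strand-agnostic,
half-open coordinates) are collected, together with the number of windows
hitting each gene — long genes accumulating many informative windows are
themselves of interest. The resulting gene set is then tested per GO term
for over-representation against a genome background (all genes of the
supplied annotation) with a one-sided Fisher exact test, BH-corrected per
namespace. Annotations are propagated to ancestor terms through the
ontology's is_a graph before testing, as GO enrichment tools do implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import hypergeom

from .mi import bh_adjust
from .windowing import Window

__all__ = [
    "GeneAnnotation", "TermAnnotation", "EnrichmentResult", "OverlapResult",
    "read_gff3_genes", "read_gtf_genes", "read_bed_genes",
    "overlap_genes", "fisher_enrichment", "propagate_terms",
    "load_gene2term", "load_obo", "enrichment_to_frame",
]


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    symbol: str
    chrom: str
    start: int  # 0-based
    end: int    # exclusive
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    namespace: str  # BP / CC / MF
    genes: set[str] = field(default_factory=set)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int          # study genes in term
    K: int          # study size
    n: int          # background genes in term
    N: int          # background size
    p_fisher: float
    p_adj: float = float("nan")
    genes: tuple[str, ...] = ()


@dataclass
class OverlapResult:
    """Genes hit by the window set, plus both directions of the overlap map."""

    gene_ids: set[str]
    windows_per_gene: dict[str, int]
    genes_per_window: dict[Window, list[str]]

    @property
    def n_windows_without_gene(self) -> int:
        return sum(1 for g in self.genes_per_window.values() if not g)


# ---------------------------------------------------------------------------
# annotation readers (pyranges does the 1-based -> 0-based GFF/GTF shift)
# ---------------------------------------------------------------------------

def _frame_to_genes(df: pd.DataFrame, id_cols: Sequence[str],
                    name_cols: Sequence[str]) -> list[GeneAnnotation]:
    def first(row, cols, default):
        for c in cols:
            v = row.get(c)
            if isinstance(v, str) and v:
                return v
        return default

    genes = []
    for i, row in df.iterrows():
        gid = first(row, id_cols, f"gene_{i}")
        genes.append(GeneAnnotation(
            gene_id=gid,
            symbol=first(row, name_cols, gid),
            chrom=str(row["Chromosome"]),
            start=int(row["Start"]),
            end=int(row["End"]),
            strand=str(row.get("Strand", ".")),
        ))
    return genes


def read_gff3_genes(path: str | Path) -> list[GeneAnnotation]:
    """Gene rows of a GFF3 file, converted to 0-based half-open coordinates."""
    import pyranges as pr

    df = pr.read_gff3(str(path)).df
    df = df[df["Feature"] == "gene"].reset_index(drop=True)
    return _frame_to_genes(df, ["gene_id", "ID"], ["Name", "gene_name", "gene"])


def read_gtf_genes(path: str | Path) -> list[GeneAnnotation]:
    """Gene rows of a GTF file, converted to 0-based half-open coordinates."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df = df[df["Feature"] == "gene"].reset_index(drop=True)
    return _frame_to_genes(df, ["gene_id", "ID"], ["gene_name", "Name"])


def read_bed_genes(path: str | Path) -> list[GeneAnnotation]:
    """BED4+ gene annotation (chrom, start, end, name[, score, strand])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    genes = []
    for i, row in df.iterrows():
        name = str(row[3]) if len(row) > 3 else f"gene_{i}"
        strand = str(row[5]) if len(row) > 5 else "."
        genes.append(GeneAnnotation(name, name, str(row[0]), int(row[1]),
                                    int(row[2]), strand))
    return genes


# ---------------------------------------------------------------------------
# window–gene overlap
# ---------------------------------------------------------------------------

def overlap_genes(windows: Sequence[Window],
                  annotation: Sequence[GeneAnnotation]) -> OverlapResult:
    """Retrieve every gene intersecting a window by >= 1 bp (strand-agnostic).

    Also counts, per gene, how many of the windows hit it (the window
    "concentration" per gene) and lists, per window, its overlapping genes.
    """
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.gene_id)

    gene_ids: set[str] = set()
    per_gene: dict[str, int] = {}
    per_window: dict[Window, list[str]] = {}
    for w in windows:
        hits = sorted({iv.data for iv in trees.get(w.chrom, IntervalTree())
                       .overlap(w.start, w.end)})
        per_window[w] = hits
        gene_ids.update(hits)
        for gid in hits:
            per_gene[gid] = per_gene.get(gid, 0) + 1
    return OverlapResult(gene_ids, per_gene, per_window)


# ---------------------------------------------------------------------------
# GO term handling and Fisher enrichment
# ---------------------------------------------------------------------------

def load_gene2term(path: str | Path,
                   term_names: Mapping[str, str] | None = None,
                   namespaces: Mapping[str, str] | None = None,
                   ) -> list[TermAnnotation]:
    """Read a gene -> term table.

    Accepts either a plain two-column ``gene<TAB>term`` file (an optional
    third column supplies the term name, a fourth the namespace) or the NCBI
    gene2go dialect (header line starting with '#'; tax_id, GeneID, GO_ID,
    Evidence, Qualifier, GO_term, PubMed, Category).
    """
    terms: dict[str, TermAnnotation] = {}
    ns_map = {"Process": "BP", "Function": "MF", "Component": "CC"}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 8 and parts[2].startswith("GO:"):
                # gene2go dialect
                gene, tid, name, ns = parts[1], parts[2], parts[5], \
                    ns_map.get(parts[7], parts[7])
            else:
                gene, tid = parts[0], parts[1]
                name = parts[2] if len(parts) > 2 else tid
                ns = parts[3] if len(parts) > 3 else "BP"
            t = terms.setdefault(tid, TermAnnotation(tid, name, ns))
            t.genes.add(gene)
    if term_names:
        for t in terms.values():
            t.term_name = term_names.get(t.term_id, t.term_name)
    if namespaces:
        for t in terms.values():
            t.namespace = namespaces.get(t.term_id, t.namespace)
    return sorted(terms.values(), key=lambda t: t.term_id)


def load_obo(path: str | Path) -> tuple[dict[str, list[str]], dict[str, str],
                                        dict[str, str]]:
    """Parse an OBO ontology (is_a edges only) with obonet.

    Returns (child -> parents adjacency, term -> name, term -> namespace);
    namespaces are abbreviated to BP/CC/MF.
    """
    import obonet

    graph = obonet.read_obo(str(path))
    ns_abbrev = {"biological_process": "BP", "cellular_component": "CC",
                 "molecular_function": "MF"}
    parents: dict[str, list[str]] = {}
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        names[node] = data.get("name", node)
        namespaces[node] = ns_abbrev.get(data.get("namespace", ""), "BP")
        parents[node] = sorted(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
    return parents, names, namespaces


def propagate_terms(terms: Sequence[TermAnnotation],
                    parents: Mapping[str, Sequence[str]],
                    term_names: Mapping[str, str] | None = None,
                    namespaces: Mapping[str, str] | None = None,
                    ) -> list[TermAnnotation]:
    """Annotate every gene to all is_a ancestors of its direct terms
    (within the ancestor's own namespace). Raises on a cyclic graph."""
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("ontology parent graph contains a cycle")

    out: dict[str, TermAnnotation] = {}

    def ensure(tid: str, like: TermAnnotation | None) -> TermAnnotation:
        if tid not in out:
            name = (term_names or {}).get(tid, like.term_name if like else tid)
            ns = (namespaces or {}).get(tid, like.namespace if like else "BP")
            out[tid] = TermAnnotation(tid, name, ns)
        return out[tid]

    for t in terms:
        ensure(t.term_id, t).genes.update(t.genes)
        if t.term_id in g:
            for anc in nx.descendants(g, t.term_id):  # edges point child->parent
                a = ensure(anc, t)
                if a.namespace == ensure(t.term_id, t).namespace:
                    a.genes.update(t.genes)
    return sorted(out.values(), key=lambda t: t.term_id)


def fisher_enrichment(study_genes: set[str],
                      background_genes: set[str],
                      terms: Sequence[TermAnnotation],
                      min_term_size: int = 1) -> list[EnrichmentResult]:
    """One-sided over-representation Fisher test per term, BH per namespace.

    The per-term p-value is the hypergeometric upper tail P(X >= k) of the
    2x2 table (study∩term, study∖term, background-only∩term, rest). Terms
    with fewer than ``min_term_size`` background genes are not tested.
    Results are sorted by raw p ascending.
    """
    if not study_genes <= background_genes:
        extra = sorted(study_genes - background_genes)[:5]
        raise ValueError(f"study genes not in background: {', '.join(extra)} ...")
    N = len(background_genes)
    K = len(study_genes)
    results: list[EnrichmentResult] = []
    for t in terms:
        term_bg = t.genes & background_genes
        n = len(term_bg)
        if n < min_term_size:
            continue
        in_term = sorted(study_genes & term_bg)
        k = len(in_term)
        # upper tail P(X >= k), drawing K from N with n successes
        p = float(hypergeom.sf(k - 1, N, n, K)) if k > 0 else 1.0
        results.append(EnrichmentResult(t.term_id, t.term_name, t.namespace,
                                        k, K, n, N, min(p, 1.0),
                                        genes=tuple(in_term)))
    for ns in {r.namespace for r in results}:
        idx = [i for i, r in enumerate(results) if r.namespace == ns]
        adj = bh_adjust([results[i].p_fisher for i in idx])
        for i, q in zip(idx, adj):
            results[i].p_adj = float(q)
    results.sort(key=lambda r: (r.p_fisher, r.term_id))
    return results


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"term_id": r.term_id, "term_name": r.term_name, "namespace": r.namespace,
         "k": r.k, "K": r.K, "n": r.n, "N": r.N,
         "p_fisher": r.p_fisher, "p_adj": r.p_adj,
         "genes": ",".join(r.genes)}
        for r in results
    ])
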
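"""GO/KEGG-style enrichment and the term-gene-miRNA tripartite network.

Enrichment is the plain upper-tail hypergeometric test: drawing n genes
(the study set) from a universe of N, of which K carry the term, the
p-value for observing >= k carriers is P(X >= k), X ~ Hypergeom(N, K, n).
Benjamini-Hochberg correction is applied within each namespace (BP, CC,
MF, pathway) separately; a term is enriched when adjusted p < alpha
(default 0.05).

The regulatory network joins three node layers — enriched terms, their
annotated genes, and the miRNAs targeting those genes — with typed edges
(miRNA->gene targeting, gene->term annotation).  There are never
term-miRNA edges.  GraphML export round-trips node and edge attributes;
SIF export preserves topology only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .degradome_targets import TargetInteraction
from .differential_expression import bh_adjust

__all__ = [
    "AnnotationMap",
    "hypergeom_enrich",
    "build_network",
    "export_network",
    "import_network",
    "summarize_run",
]


@dataclass
class AnnotationMap:
    """Gene -> term annotation over an explicit gene universe."""

    term_info: dict[str, tuple[str, str]]      # term -> (namespace, label)
    gene2terms: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        missing = {g for g in self.gene2terms if g not in self.universe}
        if missing:
            raise ValueError(f"annotated genes outside universe: {sorted(missing)[:5]}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, universe: Iterable[str]) -> "AnnotationMap":
        """Build from a (gene, term, namespace, label) table."""
        term_info: dict[str, tuple[str, str]] = {}
        gene2terms: dict[str, set[str]] = {}
        for row in df.itertuples(index=False):
            term_info[row.term] = (row.namespace, row.label)
            gene2terms.setdefault(row.gene, set()).add(row.term)
        return cls(term_info, gene2terms, set(universe))

    def genes_of(self, term: str) -> set[str]:
        return {g for g, ts in self.gene2terms.items() if term in ts}


def hypergeom_enrich(gene_set: Iterable[str], annotation: AnnotationMap,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-term hypergeometric enrichment of ``gene_set`` with BH correction.

    Returns one row per term: k (carriers in the set), K (carriers in the
    universe), n (set size), N (universe size), p, p_adjusted (BH within
    namespace) and the enriched flag.
    """
    genes = set(gene_set)
    if not annotation.universe:
        raise ValueError("empty annotation universe")
    outside = genes - annotation.universe
    if outside:
        raise ValueError(f"gene set outside universe: {sorted(outside)[:5]}")
    N = len(annotation.universe)
    n = len(genes)
    rows = []
    for term in sorted(annotation.term_info):
        namespace, label = annotation.term_info[term]
        carriers = annotation.genes_of(term)
        K = len(carriers)
        k = len(carriers & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, namespace, label, k, K, n, N, p))
    df = pd.DataFrame(rows, columns=["term", "namespace", "label",
                                     "k", "K", "n", "N", "p"])
    df["p_adjusted"] = float("nan")
    for ns, idx in df.groupby("namespace").groups.items():
        df.loc[idx, "p_adjusted"] = bh_adjust(df.loc[idx, "p"].to_numpy())
    df["enriched"] = df["p_adjusted"] < alpha
    return df


# --------------------------------------------------------------------------
# network construction

def build_network(enriched: pd.DataFrame, annotation: AnnotationMap,
                  interactions: Sequence[TargetInteraction],
                  de_flags: Mapping[str, str] | None = None) -> nx.DiGraph:
    """Tripartite network restricted to enriched terms.

    Nodes carry ``kind`` in {term, gene, miRNA}; genes carry their DE flag,
    miRNA->gene edges carry the degradome alignment score and category.
    Only genes annotated to an enriched term — and the miRNAs targeting
    them — enter the network.
    """
    de_flags = de_flags or {}
    g = nx.DiGraph()
    terms = enriched.loc[enriched["enriched"], "term"].tolist()
    term_genes: dict[str, set[str]] = {t: annotation.genes_of(t) for t in terms}
    kept_genes = set().union(*term_genes.values()) if term_genes else set()
    for t in sorted(terms):
        ns, label = annotation.term_info[t]
        g.add_node(t, kind="term", namespace=ns, label=label)
    for gene in sorted(kept_genes):
        g.add_node(gene, kind="gene", de_flag=de_flags.get(gene, "ns"))
        for t in sorted(term_genes):
            if gene in term_genes[t]:
                g.add_edge(gene, t, kind="annotation")
    for it in sorted(interactions, key=lambda x: (x.mirna, x.gene, x.site)):
        if it.gene in kept_genes:
            if not g.has_node(it.mirna):
                g.add_node(it.mirna, kind="miRNA")
            if not g.has_edge(it.mirna, it.gene):
                g.add_edge(it.mirna, it.gene, kind="targeting",
                           score=float(it.alignment_score),
                           category=int(it.category))
    return g


def export_network(network: nx.DiGraph, path, fmt: str = "GraphML") -> None:
    """Write the network as GraphML (attributes kept) or SIF (topology only)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    f = fmt.lower()
    if f == "graphml":
        nx.write_graphml(network, str(path))
    elif f == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(network.edges(data=True)):
                fh.write(f"{u}\t{data.get('kind', 'edge')}\t{v}\n")
            for node in sorted(network.nodes):
                if network.degree(node) == 0:
                    fh.write(f"{node}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def import_network(path, fmt: str = "GraphML") -> nx.DiGraph:
    if fmt.lower() != "graphml":
        raise ValueError("only GraphML import is supported")
    return nx.read_graphml(str(path))


# --------------------------------------------------------------------------
# run summary

def summarize_run(length_table: pd.DataFrame | None = None,
                  group_counts: Mapping[str, int] | None = None,
                  family_table: pd.DataFrame | None = None,
                  category_counts: Mapping[str, Mapping[int, int]] | None = None,
                  venn: Mapping[str, object] | None = None,
                  de_counts: Mapping[str, int] | None = None,
                  top_terms: pd.DataFrame | None = None) -> dict:
    """Assemble the per-stage headline numbers into one report dict.

    Missing stages yield explicit ``None`` gaps rather than being dropped,
    so a partial run is visible as such.  ``to_markdown_report`` renders
    the same structure for humans.
    """
    return {
        "length_table": length_table,
        "group_counts": dict(group_counts) if group_counts else None,
        "family_table": family_table,
        "category_counts": {k: dict(v) for k, v in category_counts.items()}
        if category_counts else None,
        "venn": dict(venn) if venn else None,
        "de_counts": dict(de_counts) if de_counts else None,
        "top_terms": top_terms,
    }


def to_markdown_report(summary: Mapping[str, object]) -> str:
    lines = ["# Run summary", ""]
    def section(title: str, body: str) -> None:
        lines.extend([f"## {title}", "", body, ""])

    lt = summary.get("length_table")
    section("Read length distribution",
            lt.to_string() if lt is not None else "_stage missing_")
    gc = summary.get("group_counts")
    section("Evidence groups",
            "\n".join(f"- {k}: {v}" for k, v in sorted(gc.items()))
            if gc else "_stage missing_")
    ft = summary.get("family_table")
    section("Largest families",
            ft.head(10).to_string(index=False) if ft is not None else "_stage missing_")
    cc = summary.get("category_counts")
    if cc:
        body = "\n".join(
            f"- {lib}: " + ", ".join(f"cat{c}={n}" for c, n in sorted(v.items()))
            for lib, v in sorted(cc.items()))
    else:
        body = "_stage missing_"
    section("Degradome categories", body)
    venn = summary.get("venn")
    section("Target overlap",
            (f"unique A: {venn['n_unique_a']}, unique B: {venn['n_unique_b']}, "
             f"common: {venn['n_common']}") if venn else "_stage missing_")
    de = summary.get("de_counts")
    section("Differential expression",
            "\n".join(f"- {k}: {v}" for k, v in sorted(de.items()))
            if de else "_stage missing_")
    tt = summary.get("top_terms")
    section("Top enriched terms",
            tt.to_string(index=False) if tt is not None else "_stage missing_")
    return "\n".join(lines)
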
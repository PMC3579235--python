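"""GO-term over-representation of gene sets and second-order GO profiles.

The Gene Ontology is held as a directed acyclic graph with edges pointing
from child term to parent term.  Annotations follow the true-path rule: a
gene annotated to a term is implicitly annotated to every ancestor, so
annotation sets are closed upward before testing.  Over-representation of
a study set against an annotated universe uses the one-sided (upper-tail)
hypergeometric test, i.e. the classic per-term Fisher exact test without
any DAG decorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

#: Relationship types that define the hierarchy.
HIERARCHY_EDGES = ("is_a", "part_of")


@dataclass
class GODag:
    """Acyclic, single-root ontology; edges run child -> parent."""

    graph: nx.DiGraph
    root: str = field(init=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"ontology graph contains a cycle: {cycle}")
        roots = [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.root = roots[0]

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` by parent links (term excluded)."""
        if term not in self.graph:
            raise KeyError(term)
        return frozenset(nx.descendants(self.graph, term))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self.graph.predecessors(term))

    def level2_terms(self) -> frozenset[str]:
        """Direct children of the root (the "second-order" terms)."""
        return self.children(self.root)

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"child": c, "parent": p, "child_name": self.name(c)}
            for c, p in sorted(self.graph.edges)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def to_obo(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: synthetic\n")
            for term in sorted(self.graph.nodes):
                fh.write(f"\n[Term]\nid: {term}\nname: {self.name(term)}\n")
                for parent in sorted(self.graph.successors(term)):
                    fh.write(f"is_a: {parent} ! {self.name(parent)}\n")


def load_dag(path: str | Path) -> GODag:
    """Read an ontology from an OBO file or a child/parent TSV.

    Only hierarchy relationships (``is_a``/``part_of``) are kept.  The
    result is validated: it must be acyclic and have a single root.
    """
    path = Path(path)
    graph = nx.DiGraph()
    if path.suffix == ".obo":
        multi = obonet.read_obo(path)
        for node, data in multi.nodes(data=True):
            graph.add_node(node, name=data.get("name", node))
        for child, parent, key in multi.edges(keys=True):
            if key in HIERARCHY_EDGES:
                graph.add_edge(child, parent)
    else:
        frame = pd.read_csv(path, sep="\t")
        if not {"child", "parent"}.issubset(frame.columns):
            raise ValueError(f"{path}: expected columns 'child' and 'parent'")
        for _, row in frame.iterrows():
            name = row.get("child_name", row["child"])
            graph.add_node(row["child"], name=name)
            graph.add_edge(row["child"], row["parent"])
    return GODag(graph)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Gene -> GO term sets, direct and ancestor-closed."""

    direct: dict[str, frozenset[str]]
    closed: dict[str, frozenset[str]] | None = None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationMap":
        """Build from a two-column (gene_id, term_id) table."""
        direct: dict[str, set[str]] = {}
        for _, row in frame.iterrows():
            direct.setdefault(str(row["gene_id"]), set()).add(str(row["term_id"]))
        return cls({g: frozenset(t) for g, t in direct.items()})

    def to_frame(self, which: str = "direct") -> pd.DataFrame:
        source = self.direct if which == "direct" else self.closed
        if source is None:
            raise ValueError("closed annotations not computed yet")
        rows = [
            {"gene_id": g, "term_id": t}
            for g in sorted(source)
            for t in sorted(source[g])
        ]
        return pd.DataFrame(rows, columns=["gene_id", "term_id"])

    def genes_for_term(self, term: str) -> frozenset[str]:
        if self.closed is None:
            raise ValueError("closed annotations not computed yet")
        return frozenset(g for g, terms in self.closed.items() if term in terms)


def propagate_annotations(dag: GODag, annotations: AnnotationMap) -> AnnotationMap:
    """Close every gene's annotation set upward (true-path rule)."""
    cache: dict[str, frozenset[str]] = {}
    closed: dict[str, frozenset[str]] = {}
    for gene, terms in annotations.direct.items():
        full: set[str] = set()
        for term in terms:
            if term not in dag:
                raise KeyError(f"gene {gene!r} annotated to unknown term {term!r}")
            if term not in cache:
                cache[term] = dag.ancestors(term) | {term}
            full |= cache[term]
        closed[gene] = frozenset(full)
    return AnnotationMap(direct=dict(annotations.direct), closed=closed)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(study: Iterable[str],
                      universe: Iterable[str],
                      annotations: AnnotationMap,
                      min_genes: int = 5,
                      bh: bool = True) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per GO term.

    Parameters
    ----------
    study, universe
        Gene sets; ``study`` must be a subset of ``universe``.  The
        universe is the set of genes with at least one annotation (genes
        without annotation carry no information for the test).
    annotations
        Ancestor-closed annotation map.
    min_genes
        Terms annotated to fewer than this many universe genes are
        dropped entirely (not just marked insignificant).
    bh
        Add a Benjamini-Hochberg adjusted column alongside the raw p.

    Returns a frame with columns term, name-free ``annotated``, ``observed``,
    ``expected`` and ``p_value`` (plus ``fdr``), sorted by p.
    """
    study_set = frozenset(study)
    universe_set = frozenset(universe)
    if not study_set <= universe_set:
        extra = sorted(study_set - universe_set)[:5]
        raise ValueError(f"study genes outside the universe, e.g. {extra}")
    if annotations.closed is None:
        raise ValueError("annotations must be propagated before testing")

    term_genes: dict[str, set[str]] = {}
    for gene in universe_set:
        for term in annotations.closed.get(gene, frozenset()):
            term_genes.setdefault(term, set()).add(gene)

    m_univ = len(universe_set)
    n_study = len(study_set)
    rows = []
    for term, genes in term_genes.items():
        annotated = len(genes)
        if annotated < min_genes:
            continue
        observed = len(genes & study_set)
        expected = n_study * annotated / m_univ
        p = float(stats.hypergeom.sf(observed - 1, m_univ, annotated, n_study))
        rows.append({"term": term, "annotated": annotated,
                     "observed": observed, "expected": expected,
                     "p_value": min(p, 1.0)})
    table = pd.DataFrame(
        rows, columns=["term", "annotated", "observed", "expected", "p_value"]
    ).sort_values(["p_value", "term"]).reset_index(drop=True)
    if bh and len(table):
        # local import: avoids a cycle with differential_expression
        from .differential_expression import bh_adjust
        table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    elif bh:
        table["fdr"] = pd.Series(dtype=float)
    return table


def second_order_profile(gene_set: Iterable[str],
                         dag: GODag,
                         annotations: AnnotationMap) -> pd.Series:
    """Proportion of ``gene_set`` annotated (via closure) to each
    second-order term (direct child of the root).

    Proportions need not sum to one: a gene annotated under several
    branches counts toward each of them.
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("gene_set is empty")
    if annotations.closed is None:
        raise ValueError("annotations must be propagated first")
    level2 = sorted(dag.level2_terms())
    values = {}
    for term in level2:
        hit = sum(1 for g in genes
                  if term in annotations.closed.get(g, frozenset()))
        values[term] = hit / len(genes)
    return pd.Series(values, name="proportion")
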
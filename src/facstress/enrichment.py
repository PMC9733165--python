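"""Ontology-aware over-representation analysis.

Annotations are propagated up a term DAG under the true-path rule (a gene
annotated to a term is annotated to all its ancestors), terms are scored
with one-sided Fisher exact (hypergeometric upper-tail) tests against a
gene universe, and the elim procedure decorrelates the DAG: terms are
processed leaves-first, and the study genes of any term already found
significant are removed from its ancestors before those are tested.
Enrichment is typically run separately for up- and down-regulated sets,
with the universe being all genes tested for differential expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class OntologyDAG:
    """Term DAG (directed child -> parent edges) with term -> gene annotations."""

    graph: nx.DiGraph
    annotations: dict[str, set[str]] = field(default_factory=dict)
    propagated: bool = False

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], annotations: dict[str, set[str]]
    ) -> "OntologyDAG":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for term in annotations:
            g.add_node(term)
        return cls(g, {t: set(gs) for t, gs in annotations.items()})

    def genes(self, term: str) -> set[str]:
        return self.annotations.get(term, set())


def _require_acyclic(g: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology graph contains a cycle: {cycle}")


def propagate_annotations(dag: OntologyDAG) -> OntologyDAG:
    """True-path closure: annotate every gene to all ancestors of its terms.

    Set semantics — a gene reached through multiple paths (diamonds) is
    counted once per term.
    """
    _require_acyclic(dag.graph)
    ann = {t: set(g) for t, g in dag.annotations.items()}
    # children before parents: child -> parent edges point forward in
    # topological order, so one forward sweep suffices
    for term in nx.lexicographical_topological_sort(dag.graph):
        if term not in ann:
            ann[term] = set()
        for parent in dag.graph.successors(term):
            ann.setdefault(parent, set()).update(ann[term])
    return OntologyDAG(dag.graph.copy(), ann, propagated=True)


def fisher_term(study: set, universe: set, term_genes: set) -> float:
    """One-sided over-representation p-value.

    With N = |universe|, K = |term in universe|, n = |study|,
    k = |study in term|: p = P(X >= k) for X hypergeometric(N, K, n).
    """
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    K = len(set(term_genes) & universe)
    k = len(set(term_genes) & study)
    return float(hypergeom.sf(k - 1, len(universe), K, len(study)))


def elim_enrichment(
    dag: OntologyDAG,
    study: set,
    universe: set,
    alpha_elim: float = 0.01,
) -> pd.DataFrame:
    """Fisher tests per term with elim decorrelation.

    Terms are processed in reverse topological order (leaves first).  When
    a term's current (elim) p falls below ``alpha_elim``, its study genes
    are removed from the annotation sets of all its ancestors before those
    are tested.  Both the raw and the elim-adjusted p-value are reported.
    """
    if not dag.propagated:
        raise ValueError("annotations must be propagated before enrichment")
    _require_acyclic(dag.graph)
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    # sanity: propagation means every child gene appears in each parent
    for child, parent in dag.graph.edges:
        if not dag.genes(child) <= dag.genes(parent):
            raise ValueError(
                f"term {child!r} has genes missing from parent {parent!r}; "
                "run propagate_annotations first"
            )

    eliminated: dict[str, set] = {t: set() for t in dag.graph.nodes}
    for t in dag.annotations:
        eliminated.setdefault(t, set())
    N, n = len(universe), len(study)
    rows = []
    terms = list(nx.lexicographical_topological_sort(dag.graph)) or list(dag.annotations)
    for term in terms:
        genes = dag.genes(term)
        K_raw = len(genes & universe)
        k_raw = len(genes & study)
        p_raw = float(hypergeom.sf(k_raw - 1, N, K_raw, n))
        eff = genes - eliminated.get(term, set())
        K = len(eff & universe)
        k = len(eff & study)
        p_elim = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, p_raw, p_elim))
        if p_elim < alpha_elim and term in dag.graph:
            marked = genes & study
            for anc in nx.descendants(dag.graph, term):  # ancestors (child->parent)
                eliminated.setdefault(anc, set()).update(marked)
    out = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_raw", "p_elim"]
    ).sort_values(["p_elim", "term"], kind="stable").reset_index(drop=True)
    return out
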
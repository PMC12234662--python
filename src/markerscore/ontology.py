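"""Cell-type ontology DAG: information content, Lin similarity, subtrees.

Terms form a directed acyclic graph with child → parent ``is_a`` edges.
Information content is corpus-free, derived from the topology alone:

    IC(t) = −ln( |descendants(t) ∪ {t}| / |terms| )

so the root of a connected graph carries no information (IC = 0) and leaves
are maximally informative.  Semantic similarity between two terms is the Lin
ratio on a 0–100 percentage scale,

    sim(a, b) = 100 · 2·IC(MICA) / (IC(a) + IC(b))

where MICA is the common ancestor with maximal IC; 0 means maximal distance
(e.g. only the root in common, or disconnected components) and 100 a perfect
match.  The log base cancels in the ratio.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Mapping, Optional

import networkx as nx

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    """Malformed ontology input."""


class CyclicOntologyError(OntologyError):
    """The term graph contains a cycle."""


class UnknownTermError(KeyError):
    """A queried term is not in the graph."""


class OntologyGraph:
    """DAG of cell-type terms with child → parent edges."""

    def __init__(self, graph: nx.DiGraph):
        if graph.number_of_nodes() == 0:
            raise OntologyError("empty ontology graph")
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            pass
        else:
            raise CyclicOntologyError(f"cyclic ontology: {cycle}")
        self._g = graph
        self._ic_cache: dict = {}

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        labels: Optional[Mapping[str, str]] = None,
    ) -> "OntologyGraph":
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        for node in g.nodes:
            g.nodes[node]["label"] = (labels or {}).get(node, node)
        if g.number_of_nodes() == 0:
            raise OntologyError("no edges supplied")
        return cls(g)

    # -- basic queries ---------------------------------------------------
    @property
    def terms(self) -> set:
        return set(self._g.nodes)

    def __contains__(self, term) -> bool:
        return term in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def label(self, term: str) -> str:
        self._check(term)
        return self._g.nodes[term].get("label", term)

    @property
    def roots(self) -> list:
        return sorted(n for n in self._g.nodes if self._g.out_degree(n) == 0)

    def _check(self, term) -> None:
        if term not in self._g:
            raise UnknownTermError(f"unknown ontology term: {term!r}")

    def ancestors(self, term: str, include_self: bool = True) -> set:
        """Terms reachable by following parent edges (plus the term itself)."""
        self._check(term)
        anc = nx.descendants(self._g, term)  # edges run child -> parent
        if include_self:
            anc = anc | {term}
        return anc

    def descendants(self, term: str, include_self: bool = True) -> set:
        self._check(term)
        desc = nx.ancestors(self._g, term)
        if include_self:
            desc = desc | {term}
        return desc

    # -- information content & similarity --------------------------------
    def information_content(self, term: str) -> float:
        self._check(term)
        if term not in self._ic_cache:
            closure = len(self.descendants(term))
            self._ic_cache[term] = -math.log(closure / len(self))
        return self._ic_cache[term]

    def most_informative_common_ancestor(
        self, t1: str, t2: str
    ) -> Optional[str]:
        """Common ancestor maximizing IC; ties broken by lexicographic id.

        Returns None when the terms share no ancestor (disconnected
        components).
        """
        common = self.ancestors(t1) & self.ancestors(t2)
        if not common:
            return None
        return min(common, key=lambda t: (-self.information_content(t), t))

    def term_similarity(self, t1: str, t2: str) -> float:
        """Lin similarity on a 0–100 scale; identical terms score 100."""
        self._check(t1)
        self._check(t2)
        if t1 == t2:
            return 100.0
        denom = self.information_content(t1) + self.information_content(t2)
        if denom == 0.0:
            return 0.0
        mica = self.most_informative_common_ancestor(t1, t2)
        if mica is None:
            return 0.0
        sim = 100.0 * 2.0 * self.information_content(mica) / denom
        return float(min(100.0, max(0.0, sim)))

    # -- subtrees ---------------------------------------------------------
    def minimal_subgraph(self, terms: Iterable[str]) -> "OntologyGraph":
        """Induced subgraph on the input terms plus all their ancestors."""
        nodes: set = set()
        for t in terms:
            nodes |= self.ancestors(t)
        if not nodes:
            raise OntologyError("no terms supplied")
        return OntologyGraph(self._g.subgraph(nodes).copy())


def _load_edge_tsv(path: str) -> OntologyGraph:
    edges = []
    labels: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise OntologyError(
                    f"{path}: line {lineno}: expected "
                    "child<TAB>parent[<TAB>label]"
                )
            child, parent = parts[0].strip(), parts[1].strip()
            edges.append((child, parent))
            if len(parts) >= 3 and parts[2].strip():
                labels[child] = parts[2].strip()
    if not edges:
        raise OntologyError(f"{path}: no edges found (empty ontology)")
    return OntologyGraph.from_edges(edges, labels)


def _load_obo(path: str, strict: bool) -> OntologyGraph:
    import obonet

    multigraph = obonet.read_obo(path, ignore_obsolete=True)
    if multigraph.number_of_nodes() == 0:
        raise OntologyError(f"{path}: no terms found (empty ontology)")
    declared = {
        n for n, d in multigraph.nodes(data=True) if "name" in d or d
    }
    g = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        g.add_node(node, label=data.get("name", node))
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if strict and parent not in declared:
            raise OntologyError(
                f"{path}: is_a edge references undeclared term {parent!r}"
            )
        if parent not in g:
            g.add_node(parent, label=parent)
        g.add_edge(child, parent)
    return OntologyGraph(g)


def load_ontology(
    path: str, fmt: Optional[str] = None, strict: bool = False
) -> OntologyGraph:
    """Load a term DAG from an edge TSV or an OBO-flat file.

    The format is inferred from the extension (``.obo``) unless ``fmt`` is
    given (``"obo"`` or ``"tsv"``).  Only ``is_a`` relationships are honored
    in OBO input; labels default to term ids when absent.  With
    ``strict=True`` an ``is_a`` edge pointing at a term with no stanza is an
    error; otherwise the term is materialized with its id as label.
    """
    if not os.path.exists(path):
        raise OntologyError(f"ontology file not found: {path}")
    if os.path.getsize(path) == 0:
        raise OntologyError(f"{path}: empty file (empty ontology)")
    if fmt is None:
        fmt = "obo" if str(path).endswith(".obo") else "tsv"
    if fmt == "obo":
        return _load_obo(path, strict)
    if fmt == "tsv":
        return _load_edge_tsv(path)
    raise ValueError(f"unknown ontology format: {fmt!r}")
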
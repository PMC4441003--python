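"""Gene Ontology graph: parsing, true-path expansion, depth and information content.

The ontology is modelled as a rooted DAG per namespace (molecular_function,
biological_process, cellular_component).  The parent relation is the union of
``is_a`` and ``part_of`` edges; the true-path rule states that annotation to a
term implies annotation to every ancestor reached through that relation, so
both gold annotations and predictions are expanded through it before any
comparison.  Other relationship types are ignored.

Depth is the length of the shortest parent-edge path from the namespace root
(root = 0).  Information content is annotation-based in the Resnik sense:
``ic(t) = -log p(t)`` where ``p(t)`` is the fraction of annotated proteins
whose true-path-expanded gold set contains ``t``.
"""

from __future__ import annotations

import math
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

NAMESPACES = ("molecular_function", "biological_process", "cellular_component")

#: OBO relationship types traversed by the true-path expansion.
PARENT_RELATIONS = ("is_a", "part_of")

_SYNONYM_RE = re.compile(r'^"(?P<surface>.*)"\s*(?P<scope>EXACT|BROAD|NARROW|RELATED)?')


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies (cycles, missing fields)."""


@dataclass
class OntologyTerm:
    """A single ontology term.

    ``synonyms`` maps each synonym surface string to its OBO scope
    (EXACT/BROAD/NARROW/RELATED); all scopes are kept as plain surfaces.
    ``parents`` holds the ids reached via is_a or part_of.
    """

    id: str
    name: str
    namespace: str
    synonyms: dict[str, str] = field(default_factory=dict)
    parents: set[str] = field(default_factory=set)
    obsolete: bool = False

    @property
    def surfaces(self) -> set[str]:
        """Name plus all synonym surfaces."""
        return {self.name, *self.synonyms}


class OntologyGraph:
    """A DAG of ontology terms with one root per namespace.

    Parameters
    ----------
    terms:
        Terms keyed by accession.  Non-obsolete, non-root terms must have at
        least one parent present in the graph.
    """

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        # child -> parent edges over non-obsolete terms only
        self._dag = nx.DiGraph()
        for term in self.terms.values():
            if term.obsolete:
                continue
            self._dag.add_node(term.id)
            for parent in term.parents:
                if parent not in self.terms:
                    raise OntologyError(f"{term.id} lists unknown parent {parent}")
                self._dag.add_edge(term.id, parent)
        if not nx.is_directed_acyclic_graph(self._dag):
            member = nx.find_cycle(self._dag)[0][0]
            raise OntologyError(f"parent relation contains a cycle through {member}")
        self.roots: dict[str, str] = {}
        for term in self.terms.values():
            if term.obsolete or term.parents:
                continue
            if term.namespace in self.roots:
                raise OntologyError(
                    f"namespace {term.namespace} has multiple roots: "
                    f"{self.roots[term.namespace]}, {term.id}"
                )
            self.roots[term.namespace] = term.id

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown term id {term_id!r}") from None

    def active_terms(self) -> Iterable[OntologyTerm]:
        """Non-obsolete terms, the only ones dictionaries and evaluation use."""
        return (t for t in self.terms.values() if not t.obsolete)

    def ancestors(self, term_id: str) -> set[str]:
        """All proper ancestors of ``term_id`` via is_a/part_of closure."""
        self._require(term_id)
        return set(nx.descendants(self._dag, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All proper descendants of ``term_id`` (inverse of :meth:`ancestors`)."""
        self._require(term_id)
        return set(nx.ancestors(self._dag, term_id))

    def expand_true_path(self, term_ids: Iterable[str]) -> set[str]:
        """Close a term set under the parent relation (terms plus ancestors)."""
        out: set[str] = set()
        for t in term_ids:
            self._require(t)
            out.add(t)
            out |= set(nx.descendants(self._dag, t))
        return out

    def topological_order(self) -> list[str]:
        """Non-obsolete term ids, every child before its parents."""
        return list(nx.topological_sort(self._dag))


# ---------------------------------------------------------------------------
# operations


def parse_obo(path) -> OntologyGraph:
    """Read an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    Obsolete terms are retained but flagged; they take no part in
    dictionaries, depth, IC or evaluation.  A cycle in the is_a/part_of
    relation or a term without a namespace is a hard error.
    """
    raw = obonet.read_obo(path, ignore_obsolete=False)
    terms: dict[str, OntologyTerm] = {}
    for node, data in raw.nodes(data=True):
        namespace = data.get("namespace")
        obsolete = data.get("is_obsolete", "false") == "true"
        if namespace is None:
            raise OntologyError(f"term {node} has no namespace")
        synonyms: dict[str, str] = {}
        for line in data.get("synonym", []):
            m = _SYNONYM_RE.match(line)
            if m:
                synonyms[m.group("surface")] = m.group("scope") or "RELATED"
        parents: set[str] = set()
        if not obsolete:
            for _, parent, rel in raw.out_edges(node, keys=True):
                if rel in PARENT_RELATIONS:
                    parents.add(parent)
        terms[node] = OntologyTerm(
            id=node,
            name=data.get("name", node),
            namespace=namespace,
            synonyms=synonyms,
            parents=parents,
            obsolete=obsolete,
        )
    return OntologyGraph(terms)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize a graph back to OBO text (inverse of :func:`parse_obo`)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for term_id in sorted(graph.terms):
            term = graph.terms[term_id]
            fh.write("\n[Term]\n")
            fh.write(f"id: {term.id}\n")
            fh.write(f"name: {term.name}\n")
            fh.write(f"namespace: {term.namespace}\n")
            for surface in sorted(term.synonyms):
                scope = term.synonyms[surface]
                fh.write(f'synonym: "{surface}" {scope} []\n')
            for parent in sorted(term.parents):
                fh.write(f"is_a: {parent} ! {graph.terms[parent].name}\n")
            if term.obsolete:
                fh.write("is_obsolete: true\n")


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Proper ancestors of ``term_id`` (excludes the term itself)."""
    return graph.ancestors(term_id)


def expand_true_path(graph: OntologyGraph, term_ids: Iterable[str]) -> set[str]:
    """Terms plus all their ancestors; idempotent and parent-closed."""
    return graph.expand_true_path(term_ids)


def term_depth(graph: OntologyGraph) -> dict[str, int]:
    """Shortest-path depth from each namespace root (root = 0) by BFS.

    Raises :class:`OntologyError` listing any non-obsolete term that cannot
    reach its namespace root.
    """
    depth: dict[str, int] = {}
    for root in graph.roots.values():
        queue = deque([(root, 0)])
        while queue:
            node, d = queue.popleft()
            if node in depth:
                continue
            depth[node] = d
            for child, _ in graph._dag.in_edges(node):
                if child not in depth:
                    queue.append((child, d + 1))
    missing = [t.id for t in graph.active_terms() if t.id not in depth]
    if missing:
        raise OntologyError(f"terms unreachable from any namespace root: {sorted(missing)}")
    return depth


def compute_ic(
    graph: OntologyGraph,
    gold,
    base: float | None = None,
    namespace: str | None = None,
) -> dict[str, float]:
    """Annotation-based information content, ``ic(t) = -log p(t)``.

    ``p(t)`` is the fraction of proteins, among those with at least one
    annotation in ``t``'s namespace, whose true-path-expanded gold set
    contains ``t``.  Terms never seen in the expanded gold get no entry
    (p = 0 would give infinite IC).  Natural log by default; pass ``base=2``
    for bits.

    ``gold`` is a mapping protein -> set of term ids, or any object with a
    ``by_protein`` attribute holding one.
    """
    by_protein: Mapping[str, set[str]] = getattr(gold, "by_protein", gold)
    if not by_protein:
        raise ValueError("gold annotation set is empty")
    expanded = {p: graph.expand_true_path(ts) for p, ts in by_protein.items() if ts}
    namespaces = [namespace] if namespace else list(graph.roots)
    log = math.log if base is None else (lambda x: math.log(x, base))
    ic: dict[str, float] = {}
    for ns in namespaces:
        ns_terms = {t.id for t in graph.active_terms() if t.namespace == ns}
        annotated = [p for p, ts in expanded.items() if ts & ns_terms]
        if not annotated:
            if namespace is not None:
                raise ValueError(f"no gold annotations in namespace {ns}")
            continue
        n = len(annotated)
        for term_id in ns_terms:
            k = sum(1 for p in annotated if term_id in expanded[p])
            if k:
                ic[term_id] = -log(k / n)
    if not ic:
        raise ValueError("no gold annotations in any namespace")
    return ic
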
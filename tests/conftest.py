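"""Shared fixtures: small hand-built ontologies and random-structure helpers."""

from __future__ import annotations

import random

import pytest

from litgo.ontology import OntologyGraph, OntologyTerm


def graph_from(parents: dict[str, set[str]], names: dict[str, str] | None = None,
               namespace: str = "biological_process") -> OntologyGraph:
    """Build a graph from a {term: parent set} mapping (single namespace)."""
    names = names or {}
    terms = {
        tid: OntologyTerm(
            id=tid,
            name=names.get(tid, f"term {tid}"),
            namespace=namespace,
            parents=set(ps),
        )
        for tid, ps in parents.items()
    }
    return OntologyGraph(terms)


def random_dag(rng: random.Random, n_terms: int = 12) -> OntologyGraph:
    """A random rooted DAG: each term's parents are sampled among earlier terms."""
    ids = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n_terms):
        k = 1 + (rng.random() < 0.4)
        parents[ids[i]] = set(rng.sample(ids[:i], min(k, i)))
    return graph_from(parents)


def brute_force_ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """Transitive closure of the parent relation by naive iteration."""
    out: set[str] = set()
    frontier = set(graph.terms[term_id].parents)
    while frontier:
        out |= frontier
        frontier = {p for t in frontier for p in graph.terms[t].parents} - out
    return out


@pytest.fixture
def diamond() -> OntologyGraph:
    """a -> {b, c} -> d, with d the root."""
    return graph_from({"d": set(), "b": {"d"}, "c": {"d"}, "a": {"b", "c"}})
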
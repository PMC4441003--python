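"""Synthetic ontologies, lexicons, gold annotations and corpora.

The generator emulates the inputs of the literature-mining pipeline at toy
scale so every stage can be exercised without external downloads: a rooted
DAG ontology whose term names partly follow the rewrite-rule patterns
("X metabolic process", "positive regulation of X"), a protein lexicon, gold
protein-term annotations emitted as GAF, and documents whose sentences embed
protein and GO surfaces among distractor words.

Planted (protein, term) pairs come from the gold standard: at
``planted_rate`` each pair yields one document in which the two surfaces
co-occur, within one sentence (probability ``sentence_ratio``) or in
adjacent sentences.  ``noise_rate`` injects spurious co-mentions with terms
outside the protein's expanded gold set, so precision degrades while recall
of true pairs is untouched.  ``synonym_use_prob`` plants rule-generated
surfaces instead of term names; a corpus planted exclusively with generated
synonyms is invisible to the original dictionary by construction, which is
what makes original-vs-enhanced contrasts testable.

Everything is a pure function of the config; the same seed gives a
byte-identical corpus.  Distractor tokens use a dedicated ``filler`` prefix
that never collides with dictionary surfaces.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .lexicon import (
    ConceptDictionary,
    ProteinLexicon,
    build_enhanced_dictionary,
    build_original_dictionary,
    write_protein_lexicon,
)
from .ontology import OntologyGraph, OntologyTerm, write_obo
from .predict import EXPERIMENTAL_EVIDENCE, GoldAnnotations
from .textpipe import Document, write_corpus

_ASPECT = {"molecular_function": "F", "biological_process": "P", "cellular_component": "C"}


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset.  All rates in [0, 1]."""

    seed: int
    n_terms: int = 30
    n_proteins: int = 50
    annotations_per_protein: int = 2
    rule_pattern_fraction: float = 0.2
    topology: str = "random"  # "random" | "chain"
    namespace: str = "biological_process"
    sentences_per_doc: int = 5
    planted_rate: float = 1.0
    sentence_ratio: float = 0.7
    noise_rate: float = 0.0
    synonym_use_prob: float = 0.0
    distractor_vocab: int = 200
    gold_from_pattern_terms: bool = False

    def __post_init__(self):
        for name in ("rule_pattern_fraction", "planted_rate", "sentence_ratio",
                     "noise_rate", "synonym_use_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_terms < 3:
            raise ValueError("need at least 3 terms (root plus two children)")


@dataclass(frozen=True)
class PlantedEvent:
    """One planted or spurious co-occurrence, recoverable from the corpus text."""

    protein: str
    go_id: str
    doc_id: str
    protein_sentence: int
    go_sentence: int
    go_surface: str
    spurious: bool = False

    @property
    def span(self) -> str:
        return "sentence" if self.protein_sentence == self.go_sentence else "non_sentence"


@dataclass
class SynthTruth:
    """Everything the generator knows: inputs plus the exact planted events."""

    config: SynthConfig
    graph: OntologyGraph
    protein_lexicon: ProteinLexicon
    gold: GoldAnnotations
    original_dictionary: ConceptDictionary
    enhanced_dictionary: ConceptDictionary
    documents: list[Document] = field(default_factory=list)
    planted: list[PlantedEvent] = field(default_factory=list)

    def planted_pairs(self, include_spurious: bool = False) -> set[tuple[str, str]]:
        return {
            (e.protein, e.go_id)
            for e in self.planted
            if include_spurious or not e.spurious
        }

    def events_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([asdict(e) for e in self.planted], fh, indent=2)


# ---------------------------------------------------------------------------
# ontology / lexicon / gold


def make_toy_ontology(config: SynthConfig, obo_path=None) -> OntologyGraph:
    """A rooted single-namespace DAG with partly rule-patterned names.

    ``round(rule_pattern_fraction * n_terms)`` non-root terms get names
    matching the metabolic or positive-regulation rewrite patterns
    (alternating); the rest are plain "<noun> pathway" nominals.  Every
    third term carries a curated synonym.  ``topology="chain"`` links each
    term to its predecessor, giving depths 0..n-1.
    """
    rng = random.Random(config.seed)
    ids = [f"GO:{i + 1:07d}" for i in range(config.n_terms)]
    terms: dict[str, OntologyTerm] = {}
    root = ids[0]
    terms[root] = OntologyTerm(id=root, name="biological process",
                               namespace=config.namespace)
    n_pattern = round(config.rule_pattern_fraction * config.n_terms)
    pattern_idx = set(rng.sample(range(1, config.n_terms), min(n_pattern,
                                                               config.n_terms - 1)))
    for i in range(1, config.n_terms):
        noun = f"funword{i}"
        if i in pattern_idx:
            name = (f"{noun} metabolic process" if i % 2 == 0
                    else f"positive regulation of {noun}")
        else:
            name = f"{noun} pathway"
        synonyms = {f"synword{i}": "EXACT"} if i % 3 == 0 else {}
        if config.topology == "chain":
            parents = {ids[i - 1]}
        else:
            n_parents = 1 + (rng.random() < 0.3)
            parents = set(rng.sample(ids[:i], min(n_parents, i)))
        terms[ids[i]] = OntologyTerm(
            id=ids[i], name=name, namespace=config.namespace,
            synonyms=synonyms, parents=parents,
        )
    graph = OntologyGraph(terms)
    if obo_path is not None:
        write_obo(graph, obo_path)
    return graph


def pattern_terms(graph: OntologyGraph) -> list[str]:
    """Term ids whose names match an enhancement-rule pattern."""
    from .lexicon import apply_enhancement_rules

    return sorted(
        t.id for t in graph.active_terms() if apply_enhancement_rules(t)
    )


def make_protein_lexicon(config: SynthConfig, tsv_path=None) -> ProteinLexicon:
    """One unambiguous surface per synthetic protein accession."""
    lex = ProteinLexicon()
    for i in range(config.n_proteins):
        lex.add(f"protword{i}", f"P{10000 + i}")
    if tsv_path is not None:
        write_protein_lexicon(lex, tsv_path)
    return lex


def make_gold(config: SynthConfig, graph: OntologyGraph, gaf_path=None) -> GoldAnnotations:
    """Gold annotations: each protein gets k distinct leaf-ish terms.

    Candidates are leaves (terms without children), padded with other
    non-root terms when too few; ``gold_from_pattern_terms`` restricts
    candidates to rule-patterned terms instead.  Evidence codes are drawn
    from the experimental allow-list.
    """
    rng = random.Random(config.seed + 1)
    root = graph.roots[config.namespace]
    if config.gold_from_pattern_terms:
        candidates = [t for t in pattern_terms(graph) if t != root]
    else:
        with_children = {p for t in graph.active_terms() for p in t.parents}
        candidates = sorted(
            t.id for t in graph.active_terms()
            if t.id != root and t.id not in with_children
        )
        if len(candidates) < config.annotations_per_protein:
            candidates = sorted(t.id for t in graph.active_terms() if t.id != root)
    if len(candidates) < config.annotations_per_protein:
        raise ValueError("not enough candidate terms for the requested annotations")
    gold = GoldAnnotations()
    evidence_codes = sorted(EXPERIMENTAL_EVIDENCE)
    for i in range(config.n_proteins):
        acc = f"P{10000 + i}"
        for term in rng.sample(candidates, config.annotations_per_protein):
            gold.add(acc, term, rng.choice(evidence_codes))
    if gaf_path is not None:
        write_gaf(gold, graph, gaf_path)
    return gold


def write_gaf(gold: GoldAnnotations, graph: OntologyGraph, path) -> None:
    """Emit the gold standard as a GAF 2.2 file."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for acc in sorted(gold.by_protein):
            for go_id in sorted(gold.by_protein[acc]):
                evidence = gold.evidence[(acc, go_id)]
                aspect = _ASPECT[graph.terms[go_id].namespace]
                cols = [
                    "SYNTH", acc, acc.lower(), "enables", go_id, "SYNTH_REF:1",
                    evidence, "", aspect, "", "", "protein", "taxon:9606",
                    "20260101", "litgo", "", "",
                ]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# corpus


def _term_surface_pools(
    graph: OntologyGraph, enhanced: ConceptDictionary
) -> dict[str, tuple[list[str], list[str]]]:
    """Per term: (name/synonym surfaces, rule-generated surfaces), unambiguous only."""
    pools: dict[str, tuple[list[str], list[str]]] = {}
    by_term: dict[str, dict[str, set[str]]] = {}
    for surface, values in enhanced.entries.items():
        if len({tid for tid, _ in values}) > 1:
            continue  # ambiguous surfaces are never planted deliberately
        for tid, prov in values:
            by_term.setdefault(tid, {}).setdefault(surface, set()).add(prov)
    for tid, surfaces in by_term.items():
        base = sorted(s for s, provs in surfaces.items()
                      if provs & {"name", "synonym", "activity_stripped"})
        generated = sorted(s for s, provs in surfaces.items()
                           if any(p.startswith("rule:") for p in provs))
        pools[tid] = (base, generated)
    return pools


def make_corpus(
    config: SynthConfig,
    graph: OntologyGraph,
    gold: GoldAnnotations,
    protein_lexicon: ProteinLexicon,
    enhanced_dictionary: ConceptDictionary,
    corpus_path=None,
) -> tuple[list[Document], list[PlantedEvent]]:
    """One document per planted (protein, term) pair, plus noise.

    Returns the unsegmented documents and the exact planted events
    (including spurious noise events, flagged).
    """
    rng = random.Random(config.seed + 2)
    pools = _term_surface_pools(graph, enhanced_dictionary)
    surface_of = {}
    for surface in protein_lexicon.surfaces():
        for acc in protein_lexicon.lookup(surface):
            surface_of.setdefault(acc, surface)
    all_terms = sorted(t.id for t in graph.active_terms())
    docs: list[Document] = []
    events: list[PlantedEvent] = []

    def distractors(k: int) -> list[str]:
        return [f"filler{rng.randrange(config.distractor_vocab)}" for _ in range(k)]

    def pick_surface(term: str) -> str | None:
        base, generated = pools.get(term, ([], []))
        if not base and not generated:
            return None
        if generated and (not base or rng.random() < config.synonym_use_prob):
            return rng.choice(generated)
        return rng.choice(base) if base else rng.choice(generated)

    counter = 0
    for acc in sorted(gold.by_protein):
        expanded_gold = graph.expand_true_path(gold.by_protein[acc])
        for term in sorted(gold.by_protein[acc]):
            if rng.random() >= config.planted_rate:
                continue
            go_surface = pick_surface(term)
            if go_surface is None:
                continue
            doc_id = f"doc{counter:05d}"
            counter += 1
            n_sent = max(config.sentences_per_doc, 2)
            sentences = [distractors(rng.randint(4, 8)) for _ in range(n_sent)]
            if rng.random() < config.sentence_ratio:
                s_p = s_g = rng.randrange(n_sent)
            else:
                s_p = rng.randrange(n_sent - 1)
                s_g = s_p + 1
            prot_surface = surface_of[acc]
            sentences[s_p].insert(rng.randrange(len(sentences[s_p]) + 1), prot_surface)
            sentences[s_g].insert(rng.randrange(len(sentences[s_g]) + 1), go_surface)
            events.append(PlantedEvent(acc, term, doc_id, s_p, s_g, go_surface))
            if rng.random() < config.noise_rate:
                off_gold = [t for t in all_terms if t not in expanded_gold]
                if off_gold:
                    noise_term = rng.choice(off_gold)
                    noise_surface = pick_surface(noise_term)
                    if noise_surface is not None:
                        sentences[s_p].insert(
                            rng.randrange(len(sentences[s_p]) + 1), noise_surface
                        )
                        events.append(
                            PlantedEvent(acc, noise_term, doc_id, s_p, s_p,
                                         noise_surface, spurious=True)
                        )
            text = ". ".join(
                " ".join(words).capitalize() for words in sentences
            ) + "."
            kind = "abstract" if counter % 2 else "paragraph"
            docs.append(Document(doc_id=doc_id, unit_kind=kind, text=text))
    if corpus_path is not None:
        write_corpus(docs, corpus_path)
    return docs, events


def generate(config: SynthConfig, outdir=None) -> SynthTruth:
    """Build the full synthetic workspace (optionally written to ``outdir``)."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    graph = make_toy_ontology(config, obo_path=out / "ontology.obo" if out else None)
    lex = make_protein_lexicon(config, tsv_path=out / "proteins.tsv" if out else None)
    gold = make_gold(config, graph, gaf_path=out / "gold.gaf" if out else None)
    original = build_original_dictionary(graph)
    enhanced = build_enhanced_dictionary(graph)
    docs, events = make_corpus(
        config, graph, gold, lex, enhanced,
        corpus_path=out / "corpus.tsv" if out else None,
    )
    truth = SynthTruth(
        config=config, graph=graph, protein_lexicon=lex, gold=gold,
        original_dictionary=original, enhanced_dictionary=enhanced,
        documents=docs, planted=events,
    )
    if out is not None:
        truth.events_json(out / "planted.json")
    return truth
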
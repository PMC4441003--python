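"""Concept dictionaries for GO term recognition, plus the protein lexicon.

Two dictionary flavors are built from the ontology:

* **original** — every non-obsolete term's name and synonyms, lowercased;
  any surface ending in " activity" additionally contributes the form with
  that trailing word stripped (molecular-function names almost always carry
  it, but it rarely appears in running text).
* **enhanced** — the original plus rule-generated synonym variants.  The
  rule engine captures systematic mismatches between ontology nominals and
  how authors actually write them:

  - Rule M (metabolic family): "X metabolic process" -> "X metabolism",
    "metabolism of X".  Optional extensions cover the biosynthetic and
    catabolic siblings.
  - Rule P (positive regulation): "positive regulation of X" ->
    "stimulation of X", "X stimulation", "pro-X"; if a derivational variant
    of X is known (e.g. apoptosis -> apoptotic) each form is also emitted
    with the variant substituted, yielding e.g. "apoptotic stimulation" and
    "pro-apoptotic".
  - Rule N (negative analog, off by default): "negative regulation of X" ->
    "inhibition of X", "anti-X".

Every variant records its provenance (name / synonym / activity_stripped /
rule:<id>), so the rule-generated subset is exactly recoverable as
enhanced minus original.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .ontology import OntologyGraph, OntologyTerm

#: Default derivational variants for Rule P substitution; user-extensible.
DEFAULT_VARIANTS: dict[str, set[str]] = {
    "apoptosis": {"apoptotic"},
    "proliferation": {"proliferative"},
    "inflammation": {"inflammatory"},
}

VariantTable = Mapping[str, set[str]]


@dataclass(frozen=True)
class LexicalVariant:
    """One surface form for one term, with how it was derived."""

    surface: str
    term_id: str
    provenance: str

    def __post_init__(self):
        if not self.surface:
            raise ValueError("empty surface string")


@dataclass
class RuleConfig:
    """Which enhancement rules are active.

    Rule M on the literal "metabolic process" pattern and Rule P are the
    anchored defaults; the biosynthetic/catabolic extensions of Rule M and
    the negative-regulation analog (Rule N) are off by default.
    """

    metabolic: bool = True
    biosynthetic: bool = False
    catabolic: bool = False
    positive_regulation: bool = True
    negative_regulation: bool = False


class ConceptDictionary:
    """Map from lowercased surface string to the terms it may denote.

    ``entries[surface]`` is a set of ``(term_id, provenance)`` pairs; one
    surface may be ambiguous between several terms.
    """

    def __init__(self, flavor: str):
        self.flavor = flavor
        self.entries: dict[str, set[tuple[str, str]]] = {}

    def add(self, variant: LexicalVariant) -> None:
        surface = _normalize(variant.surface)
        if not surface:
            return
        self.entries.setdefault(surface, set()).add((variant.term_id, variant.provenance))

    def lookup(self, surface: str) -> set[str]:
        """Term ids for a surface (case/whitespace-insensitive); empty if absent."""
        return {tid for tid, _ in self.entries.get(_normalize(surface), ())}

    def surfaces(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return _normalize(surface) in self.entries

    def pairs(self) -> set[tuple[str, str, str]]:
        """All (surface, term_id, provenance) triples."""
        return {
            (s, tid, prov) for s, vs in self.entries.items() for tid, prov in vs
        }

    def write_tsv(self, path) -> None:
        """Dump as surface<TAB>term_id<TAB>provenance for inspection."""
        with open(path, "w", encoding="utf-8") as fh:
            for surface, term_id, prov in sorted(self.pairs()):
                fh.write(f"{surface}\t{term_id}\t{prov}\n")


class ProteinLexicon:
    """Case-insensitive map from protein surface name to UniProt-style accessions."""

    def __init__(self):
        self.entries: dict[str, set[tuple[str, str]]] = {}

    def add(self, surface: str, accession: str) -> None:
        if not surface or not accession:
            raise ValueError("surface and accession must be non-empty")
        self.entries.setdefault(_normalize(surface), set()).add((accession, "lexicon"))

    def lookup(self, surface: str) -> set[str]:
        return {acc for acc, _ in self.entries.get(_normalize(surface), ())}

    def surfaces(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, surface: str) -> bool:
        return _normalize(surface) in self.entries


def _normalize(surface: str) -> str:
    return " ".join(surface.lower().split())


# ---------------------------------------------------------------------------
# dictionary construction


def term_variants(term: OntologyTerm) -> list[LexicalVariant]:
    """Name, synonyms, and activity-stripped forms for one term."""
    out: list[LexicalVariant] = []
    seen: list[tuple[str, str]] = [(term.name, "name")]
    seen += [(s, "synonym") for s in sorted(term.synonyms)]
    for surface, prov in seen:
        out.append(LexicalVariant(surface.lower(), term.id, prov))
        stripped = _strip_activity(surface.lower())
        if stripped:
            out.append(LexicalVariant(stripped, term.id, "activity_stripped"))
    return out


def _strip_activity(surface: str) -> str | None:
    if surface.endswith(" activity") and len(surface) > len(" activity"):
        return surface[: -len(" activity")]
    return None


def build_original_dictionary(graph: OntologyGraph) -> ConceptDictionary:
    """Names + synonyms of all non-obsolete terms, with " activity" stripping."""
    d = ConceptDictionary(flavor="original")
    for term in graph.active_terms():
        for variant in term_variants(term):
            d.add(variant)
    return d


_RULE_M_PATTERNS = {
    "metabolic": (re.compile(r"^(?P<x>.+) metabolic process$"), "metabolism"),
    "biosynthetic": (re.compile(r"^(?P<x>.+) biosynthetic process$"), "biosynthesis"),
    "catabolic": (re.compile(r"^(?P<x>.+) catabolic process$"), "catabolism"),
}
_RULE_P_RE = re.compile(r"^positive regulation of (?P<x>.+)$")
_RULE_N_RE = re.compile(r"^negative regulation of (?P<x>.+)$")


def apply_enhancement_rules(
    term: OntologyTerm,
    variants: VariantTable | None = None,
    config: RuleConfig | None = None,
) -> set[LexicalVariant]:
    """Rule-generated synonym variants for one term (empty if no rule matches)."""
    if term.obsolete:
        return set()
    variants = DEFAULT_VARIANTS if variants is None else variants
    config = config or RuleConfig()
    name = _normalize(term.name)
    out: set[LexicalVariant] = set()

    for key, (pattern, noun) in _RULE_M_PATTERNS.items():
        if not getattr(config, key):
            continue
        m = pattern.match(name)
        if m:
            x = m.group("x")
            for form in (f"{x} {noun}", f"{noun} of {x}"):
                out.add(LexicalVariant(form, term.id, "rule:M"))

    m = _RULE_P_RE.match(name)
    if m and config.positive_regulation:
        for x in _with_variants(m.group("x"), variants):
            for form in (f"stimulation of {x}", f"{x} stimulation", f"pro-{x}"):
                out.add(LexicalVariant(form, term.id, "rule:P"))

    m = _RULE_N_RE.match(name)
    if m and config.negative_regulation:
        for x in _with_variants(m.group("x"), variants):
            for form in (f"inhibition of {x}", f"anti-{x}"):
                out.add(LexicalVariant(form, term.id, "rule:N"))

    return out


def _with_variants(x: str, variants: VariantTable) -> set[str]:
    return {x, *variants.get(x, ())}


def build_enhanced_dictionary(
    graph: OntologyGraph,
    variants: VariantTable | None = None,
    config: RuleConfig | None = None,
) -> ConceptDictionary:
    """Original dictionary plus all rule-generated variants (a strict superset)."""
    original = build_original_dictionary(graph)
    d = ConceptDictionary(flavor="enhanced")
    d.entries = {s: set(v) for s, v in original.entries.items()}
    for term in graph.active_terms():
        for variant in apply_enhancement_rules(term, variants, config):
            d.add(variant)
    assert original.pairs() <= d.pairs()
    return d


# ---------------------------------------------------------------------------
# protein lexicon I/O


def load_protein_lexicon(path) -> ProteinLexicon:
    """Read a two-column TSV (surface<TAB>accession) into a :class:`ProteinLexicon`.

    One surface may map to several accessions; ambiguity is preserved.
    """
    lex = ProteinLexicon()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"malformed protein lexicon line {lineno}: {line!r}")
            lex.add(parts[0].strip(), parts[1].strip())
    return lex


def write_protein_lexicon(lex: ProteinLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for surface in sorted(lex.entries):
            for acc in sorted(lex.lookup(surface)):
                fh.write(f"{surface}\t{acc}\n")
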
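"""Document segmentation and dictionary-based concept recognition.

Documents arrive as whole abstracts or single full-text paragraphs.  A
rule-based splitter finds sentence boundaries (terminal punctuation followed
by whitespace and an upper-case/digit start, guarded against common
abbreviations and single-initial patterns); tokens are maximal runs of word
characters with internal hyphens kept.

Concept matching is ConceptMapper-style dictionary lookup: case-insensitive,
token-boundary aligned, contiguous, longest match wins, overlapping shorter
matches are suppressed, ties broken leftmost.  A surface that is ambiguous
between several concepts yields a single mention carrying all candidate ids.
All offsets are 0-based half-open character positions into the raw text.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Span = tuple[int, int]

#: Abbreviations that must not terminate a sentence.
ABBREVIATIONS = {
    "e.g", "i.e", "etc", "cf", "vs", "al", "fig", "figs", "no", "dr",
    "prof", "mr", "mrs", "ms", "st", "approx", "ca", "resp",
}

_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+(?:[-'][A-Za-z0-9_]+)*")
_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+)(?=[A-Z0-9])")


@dataclass
class Document:
    """A corpus record (abstract or paragraph) with optional segmentation."""

    doc_id: str
    unit_kind: str  # "abstract" | "paragraph"
    text: str
    sentences: list[Span] = field(default_factory=list)
    tokens: list[list[Span]] = field(default_factory=list)  # per sentence

    @property
    def segmented(self) -> bool:
        return bool(self.sentences) or not self.text.strip()

    def sentence_text(self, index: int) -> str:
        s, e = self.sentences[index]
        return self.text[s:e]


@dataclass(frozen=True)
class Mention:
    """A located concept occurrence; ``concept_ids`` may hold several candidates."""

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    kind: str  # "protein" | "go_term"
    concept_ids: frozenset[str]
    provenance: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("empty mention span")
        if not self.concept_ids:
            raise ValueError("mention without concept ids")


def read_corpus(path) -> list[Document]:
    """Read a corpus TSV (columns doc_id, unit_kind, text) into Documents.

    Duplicate doc_ids are a hard error; rows with empty text are skipped
    with a warning.  Standard TSV quoting applies, so quoted fields may
    contain tabs.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "unit_kind", "text"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"corpus file must have columns {sorted(required)}")
        for row in reader:
            doc_id = row["doc_id"]
            if doc_id in seen:
                raise ValueError(f"duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            if not (row["text"] or "").strip():
                warnings.warn(f"skipping empty document {doc_id!r}", stacklevel=2)
                continue
            docs.append(Document(doc_id=doc_id, unit_kind=row["unit_kind"], text=row["text"]))
    return docs


def write_corpus(docs: Iterable[Document], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["doc_id", "unit_kind", "text"])
        for doc in docs:
            writer.writerow([doc.doc_id, doc.unit_kind, doc.text])


# ---------------------------------------------------------------------------
# segmentation


def _is_abbreviation(text: str, punct_start: int) -> bool:
    """Whether the token ending at ``punct_start`` blocks a sentence break."""
    head = text[:punct_start]
    m = re.search(r"([A-Za-z][A-Za-z.]*)$", head)
    if not m:
        return False
    word = m.group(1)
    if word.strip(".").lower() in ABBREVIATIONS:
        return True
    # single capital initial, as in "A. Smith" or "E. coli"
    if len(word.strip(".")) == 1 and word.strip(".").isupper():
        return True
    return False


def segment(doc: Document) -> Document:
    """Fill in sentence and token spans (idempotent; returns the same object)."""
    text = doc.text
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        if _is_abbreviation(text, m.start(1)):
            continue
        boundaries.append(m.end(1))  # sentence ends after the punctuation
    spans: list[Span] = []
    start = 0
    for b in boundaries:
        chunk = text[start:b]
        if chunk.strip():
            spans.append(_trim(text, start, b))
        start = b
    if text[start:].strip():
        spans.append(_trim(text, start, len(text)))
    doc.sentences = spans
    doc.tokens = [
        [(start + m.start(), start + m.end()) for m in _TOKEN_RE.finditer(text[start:end])]
        for start, end in spans
    ]
    return doc


def _trim(text: str, start: int, end: int) -> Span:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    return start, end


# ---------------------------------------------------------------------------
# concept matching


def _normalize(s: str) -> str:
    return " ".join(s.lower().split())


def match_concepts(doc: Document, dictionary, kind: str) -> list[Mention]:
    """Longest-match dictionary scan over each sentence of a segmented document.

    ``dictionary`` is any object with ``entries`` mapping normalized surface
    to a set of ``(concept_id, provenance)`` pairs (ConceptDictionary or
    ProteinLexicon).  The scan walks token positions left to right; at each
    position the longest dictionary hit starting there is emitted and the
    scan resumes after it, which suppresses overlapping shorter matches.
    """
    if not doc.segmented:
        raise ValueError(f"document {doc.doc_id!r} is not segmented")
    entries = dictionary.entries
    max_tokens = 1
    for surface in entries:
        max_tokens = max(max_tokens, surface.count(" ") + 1)
    mentions: list[Mention] = []
    for s_idx, token_spans in enumerate(doc.tokens):
        i = 0
        n = len(token_spans)
        while i < n:
            hit = None
            for j in range(min(n, i + max_tokens) - 1, i - 1, -1):
                start, end = token_spans[i][0], token_spans[j][1]
                key = _normalize(doc.text[start:end])
                if key in entries:
                    hit = (start, end, key, j)
                    break
            if hit is None:
                i += 1
                continue
            start, end, key, j = hit
            values = entries[key]
            mentions.append(
                Mention(
                    doc_id=doc.doc_id,
                    sentence_index=s_idx,
                    start=start,
                    end=end,
                    surface=doc.text[start:end],
                    kind=kind,
                    concept_ids=frozenset(cid for cid, _ in values),
                    provenance=";".join(sorted({prov for _, prov in values})),
                )
            )
            i = j + 1
    return mentions


def write_mentions(mentions: Sequence[Mention], path) -> None:
    """Dump mentions as TSV (doc_id, sentence_index, start, end, kind, ids, surface)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["doc_id", "sentence_index", "start", "end", "kind", "concept_ids", "surface"]
        )
        for m in mentions:
            writer.writerow(
                [m.doc_id, m.sentence_index, m.start, m.end, m.kind,
                 ",".join(sorted(m.concept_ids)), m.surface]
            )
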
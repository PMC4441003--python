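"""Co-mention and bag-of-words feature extraction over recognized mentions.

A *co-mention* is a protein mention and a GO concept mention co-occurring in
a defined span of one document unit (abstract or paragraph):

* **sentence** span — both appear in the same sentence; counted once per
  sentence per (protein, term) pair, regardless of how many times each is
  mentioned in it (presence-based).
* **non_sentence** span — the two appear in distinct sentences of the same
  unit; counted once per unordered sentence pair per (protein, term) pair.

Bag-of-words associates each protein with the lowercased, stopword-filtered
tokens of every sentence that mentions it; no stemming or lemmatization.

Features are sparse per-protein counts under namespaced keys: ``co_<GO id>``
(sentence), ``nco_<GO id>`` (non-sentence), ``w_<word>``.  The on-disk
format is one record per protein, ``ACC, key=value, key=value, ...`` with
only non-zero features written.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .stopwords import STOPWORDS
from .textpipe import Document, Mention

MODES = (
    "sentence_only",
    "nonsentence_only",
    "combined",
    "separate",
    "bow_only",
    "comentions_plus_bow",
)


@dataclass(frozen=True)
class CoMention:
    """One co-occurrence event of a protein and a GO term within a unit."""

    protein: str
    go_id: str
    span: str  # "sentence" | "non_sentence"
    doc_id: str
    protein_sentence: int
    go_sentence: int

    def __post_init__(self):
        if self.span == "sentence" and self.protein_sentence != self.go_sentence:
            raise ValueError("sentence co-mention with differing sentence indices")
        if self.span == "non_sentence" and self.protein_sentence == self.go_sentence:
            raise ValueError("non-sentence co-mention within a single sentence")


#: protein accession -> {feature key -> positive count}
FeatureTable = dict[str, Counter]


def extract_comentions(
    doc: Document,
    protein_mentions: Sequence[Mention],
    go_mentions: Sequence[Mention],
    multiplicity: str = "presence",
) -> list[CoMention]:
    """All sentence and non-sentence co-mention events in one document unit.

    Ambiguous mentions contribute once per candidate concept.  With the
    default presence-based counting there is one event per sentence
    (sentence span) or per unordered sentence pair (non-sentence span) for
    each (protein, term) combination; ``multiplicity="mention_pairs"``
    instead emits one event per (protein mention, GO mention) pair, which
    inflates counts quadratically when entities repeat.
    """
    if multiplicity not in ("presence", "mention_pairs"):
        raise ValueError(f"unknown multiplicity {multiplicity!r}")
    for m in itertools.chain(protein_mentions, go_mentions):
        if m.doc_id != doc.doc_id:
            raise ValueError(f"mention for {m.doc_id!r} passed with document {doc.doc_id!r}")
    if multiplicity == "mention_pairs":
        out: list[CoMention] = []
        for pm in protein_mentions:
            for gm in go_mentions:
                for acc in sorted(pm.concept_ids):
                    for gid in sorted(gm.concept_ids):
                        span = ("sentence" if pm.sentence_index == gm.sentence_index
                                else "non_sentence")
                        out.append(CoMention(acc, gid, span, doc.doc_id,
                                             pm.sentence_index, gm.sentence_index))
        return out
    prot_sentences: dict[str, set[int]] = defaultdict(set)
    go_sentences: dict[str, set[int]] = defaultdict(set)
    for m in protein_mentions:
        for acc in m.concept_ids:
            prot_sentences[acc].add(m.sentence_index)
    for m in go_mentions:
        for gid in m.concept_ids:
            go_sentences[gid].add(m.sentence_index)

    out: list[CoMention] = []
    for acc in sorted(prot_sentences):
        for gid in sorted(go_sentences):
            ps, gs = prot_sentences[acc], go_sentences[gid]
            for s in sorted(ps & gs):
                out.append(CoMention(acc, gid, "sentence", doc.doc_id, s, s))
            seen_pairs: set[frozenset[int]] = set()
            for sp in sorted(ps):
                for sg in sorted(gs):
                    if sp == sg:
                        continue
                    pair = frozenset((sp, sg))
                    if pair in seen_pairs:
                        continue
                    seen_pairs.add(pair)
                    out.append(CoMention(acc, gid, "non_sentence", doc.doc_id, sp, sg))
    return out


def extract_bow(
    doc: Document,
    protein_mentions: Sequence[Mention],
    stopwords: Iterable[str] = STOPWORDS,
    include_protein_tokens: bool = True,
) -> FeatureTable:
    """Per-protein word counts from sentences mentioning the protein."""
    stop = set(stopwords)
    table: FeatureTable = defaultdict(Counter)
    by_sentence: dict[int, list[Mention]] = defaultdict(list)
    for m in protein_mentions:
        by_sentence[m.sentence_index].append(m)
    for s_idx, mentions in by_sentence.items():
        token_spans = doc.tokens[s_idx]
        words = [doc.text[a:b].lower() for a, b in token_spans]
        accs = {acc for m in mentions for acc in m.concept_ids}
        mention_spans = [(m.start, m.end) for m in mentions]
        for acc in accs:
            for (a, b), w in zip(token_spans, words):
                if w in stop:
                    continue
                if not include_protein_tokens and any(
                    a >= ms and b <= me for ms, me in mention_spans
                ):
                    continue
                table[acc][w] += 1
    return dict(table)


def assemble_features(
    comentions: Iterable[CoMention],
    bow: FeatureTable | None = None,
    mode: str = "separate",
) -> FeatureTable:
    """Aggregate event streams into a sparse per-protein feature table.

    Modes mirror the co-mention usage strategies: ``sentence_only``,
    ``nonsentence_only``, ``combined`` (sentence + non-sentence summed under
    ``co_``), ``separate`` (``co_`` and ``nco_`` keys), ``bow_only``, and
    ``comentions_plus_bow`` (separate co-mentions plus ``w_`` words).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    table: FeatureTable = defaultdict(Counter)
    if mode != "bow_only":
        for cm in comentions:
            if cm.span == "sentence":
                key = None if mode == "nonsentence_only" else f"co_{cm.go_id}"
            else:
                if mode in ("sentence_only",):
                    key = None
                elif mode == "combined":
                    key = f"co_{cm.go_id}"
                elif mode == "nonsentence_only":
                    key = f"nco_{cm.go_id}"
                else:  # separate / comentions_plus_bow
                    key = f"nco_{cm.go_id}"
            if key:
                table[cm.protein][key] += 1
    if mode in ("bow_only", "comentions_plus_bow") and bow:
        for acc, words in bow.items():
            for w, c in words.items():
                table[acc][f"w_{w}"] += c
    return dict(table)


def merge_bow(tables: Iterable[FeatureTable]) -> FeatureTable:
    """Sum per-document bag-of-words tables across a corpus."""
    out: FeatureTable = defaultdict(Counter)
    for t in tables:
        for acc, words in t.items():
            out[acc].update(words)
    return dict(out)


# ---------------------------------------------------------------------------
# serialization


def write_features(table: FeatureTable, path) -> None:
    """One record per protein: ``ACC, key=value, ...``, non-zero features only."""
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(table):
            feats = table[acc]
            pairs = ", ".join(f"{k}={feats[k]}" for k in sorted(feats) if feats[k])
            if pairs:
                fh.write(f"{acc}, {pairs}\n")
            else:
                fh.write(f"{acc}\n")


def read_features(path) -> FeatureTable:
    """Inverse of :func:`write_features`."""
    table: FeatureTable = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            acc, pairs = parts[0], parts[1:]
            feats: Counter = Counter()
            for pair in pairs:
                if "=" not in pair:
                    raise ValueError(f"malformed feature pair {pair!r} in record {acc!r}")
                key, value = pair.rsplit("=", 1)
                try:
                    feats[key] = int(value)
                except ValueError:
                    raise ValueError(
                        f"non-integer count {value!r} in record {acc!r}"
                    ) from None
            table[acc] = feats
    return table


# ---------------------------------------------------------------------------
# statistics


def comention_stats(comentions: Iterable[CoMention]) -> dict[str, dict[str, int]]:
    """Summary counts per span and combined.

    For each of ``sentence``, ``non_sentence`` and ``combined``: the number
    of unique proteins, unique GO terms, unique (protein, GO) pairs, and
    total co-mention events.  ``combined`` deduplicates uniques across spans
    and sums the totals; ``combined_total_summed`` in each row records the
    plain sentence + non-sentence sum for comparison.
    """
    rows = {
        span: {"proteins": set(), "go_terms": set(), "pairs": set(), "total": 0}
        for span in ("sentence", "non_sentence", "combined")
    }
    for cm in comentions:
        for span in (cm.span, "combined"):
            row = rows[span]
            row["proteins"].add(cm.protein)
            row["go_terms"].add(cm.go_id)
            row["pairs"].add((cm.protein, cm.go_id))
            row["total"] += 1
    out = {
        span: {
            "unique_proteins": len(row["proteins"]),
            "unique_go_terms": len(row["go_terms"]),
            "unique_pairs": len(row["pairs"]),
            "total_comentions": row["total"],
        }
        for span, row in rows.items()
    }
    out["combined"]["total_summed"] = (
        out["sentence"]["total_comentions"] + out["non_sentence"]["total_comentions"]
    )
    return out


def write_stats(stats: dict[str, dict[str, int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("span\tunique_proteins\tunique_go_terms\tunique_pairs\ttotal_comentions\n")
        for span in ("sentence", "non_sentence", "combined"):
            row = stats[span]
            fh.write(
                f"{span}\t{row['unique_proteins']}\t{row['unique_go_terms']}"
                f"\t{row['unique_pairs']}\t{row['total_comentions']}\n"
            )
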
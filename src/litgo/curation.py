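"""Medium-throughput manual review of sentence co-mentions via brat standoff.

Sampled sentence co-mentions are exported one sentence per brat document:
the ``.txt`` file holds the sentence, the ``.ann`` file two entity lines
(T1 = the protein mention, T2 = the GO concept mention) plus AnnotatorNotes
lines carrying the co-mention identity.  The annotator connects the two
entities with a single relation, ``Good-Comention`` when the sentence really
relates the protein to the function and ``Bad-Comention`` otherwise; import
reads those relations back.  Per-class precision is then simple exact
arithmetic: good / total.
"""

from __future__ import annotations

import json
import random
import warnings
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .comention import CoMention
from .textpipe import Document, Mention

LABELS = ("Good", "Bad", "unlabeled")
RELATION_TYPES = {"Good-Comention": "Good", "Bad-Comention": "Bad"}


@dataclass(frozen=True)
class CurationRecord:
    """One sentence co-mention prepared for (or returned from) human labeling.

    Spans are character offsets relative to the sentence text.
    """

    protein: str
    go_id: str
    doc_id: str
    sentence_index: int
    sentence_text: str
    protein_span: tuple[int, int]
    go_span: tuple[int, int]
    label: str = "unlabeled"

    def __post_init__(self):
        for a, b in (self.protein_span, self.go_span):
            if not (0 <= a < b <= len(self.sentence_text)):
                raise ValueError("span outside sentence text")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def protein_surface(self) -> str:
        return self.sentence_text[slice(*self.protein_span)]

    @property
    def go_surface(self) -> str:
        return self.sentence_text[slice(*self.go_span)]


def build_curation_records(
    comentions: Iterable[CoMention],
    documents: Mapping[str, Document],
    protein_mentions: Sequence[Mention],
    go_mentions: Sequence[Mention],
) -> list[CurationRecord]:
    """Attach sentence text and spans to sentence-span co-mentions.

    For each sentence co-mention the first mention of the protein and of the
    GO term within that sentence provides the highlighted spans.
    """
    prot_index: dict[tuple[str, int, str], Mention] = {}
    for m in protein_mentions:
        for acc in m.concept_ids:
            prot_index.setdefault((m.doc_id, m.sentence_index, acc), m)
    go_index: dict[tuple[str, int, str], Mention] = {}
    for m in go_mentions:
        for gid in m.concept_ids:
            go_index.setdefault((m.doc_id, m.sentence_index, gid), m)

    records: list[CurationRecord] = []
    for cm in comentions:
        if cm.span != "sentence":
            continue
        doc = documents[cm.doc_id]
        pm = prot_index[(cm.doc_id, cm.protein_sentence, cm.protein)]
        gm = go_index[(cm.doc_id, cm.go_sentence, cm.go_id)]
        s_start, _ = doc.sentences[cm.protein_sentence]
        records.append(
            CurationRecord(
                protein=cm.protein,
                go_id=cm.go_id,
                doc_id=cm.doc_id,
                sentence_index=cm.protein_sentence,
                sentence_text=doc.sentence_text(cm.protein_sentence),
                protein_span=(pm.start - s_start, pm.end - s_start),
                go_span=(gm.start - s_start, gm.end - s_start),
            )
        )
    return records


def sample_comentions(
    records: Sequence[CurationRecord],
    n: int,
    seed: int,
    go_filter: str | None = None,
) -> list[CurationRecord]:
    """Seeded uniform sample without replacement, optionally one functional class."""
    pool = [r for r in records if go_filter is None or r.go_id == go_filter]
    if n >= len(pool):
        if n > len(pool):
            warnings.warn(
                f"requested {n} records but only {len(pool)} available; returning all",
                stacklevel=2,
            )
        return list(pool)
    return random.Random(seed).sample(pool, n)


# ---------------------------------------------------------------------------
# brat standoff I/O


def export_brat(records: Sequence[CurationRecord], outdir, prefix: str = "comention") -> list[str]:
    """Write one .txt/.ann pair per record; returns the document stems.

    Entity lines T1 (protein) and T2 (GO concept) always appear; a relation
    line is written only for records that already carry a label, so fresh
    exports leave the relation for the annotator.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stems: list[str] = []
    for i, rec in enumerate(records):
        stem = f"{prefix}-{i:05d}"
        stems.append(stem)
        (outdir / f"{stem}.txt").write_text(rec.sentence_text, encoding="utf-8")
        lines = [
            f"T1\tProtein {rec.protein_span[0]} {rec.protein_span[1]}\t{rec.protein_surface}",
            f"T2\tGO_concept {rec.go_span[0]} {rec.go_span[1]}\t{rec.go_surface}",
            "#1\tAnnotatorNotes T1\t" + json.dumps({"protein": rec.protein}),
            "#2\tAnnotatorNotes T2\t"
            + json.dumps(
                {"go_id": rec.go_id, "doc_id": rec.doc_id,
                 "sentence_index": rec.sentence_index}
            ),
        ]
        if rec.label != "unlabeled":
            lines.append(f"R1\t{rec.label}-Comention Arg1:T1 Arg2:T2")
        (outdir / f"{stem}.ann").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return stems


def import_brat(indir, prefix: str = "comention") -> list[CurationRecord]:
    """Read .txt/.ann pairs back into records, applying Good/Bad relation labels.

    Records whose .ann has entities but no relation stay unlabeled; an
    unrecognized relation type is an error naming it.
    """
    indir = Path(indir)
    records: list[CurationRecord] = []
    for ann_path in sorted(indir.glob(f"{prefix}-*.ann")):
        txt_path = ann_path.with_suffix(".txt")
        text = txt_path.read_text(encoding="utf-8")
        spans: dict[str, tuple[int, int]] = {}
        notes: dict[str, dict] = {}
        label = "unlabeled"
        for line in ann_path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            fields = line.split("\t")
            tag = fields[0]
            if tag.startswith("T"):
                _, start, end = fields[1].rsplit(" ", 2)
                spans[tag] = (int(start), int(end))
            elif tag.startswith("#"):
                _, target = fields[1].split(" ", 1)
                notes[target] = json.loads(fields[2])
            elif tag.startswith("R"):
                rel_type = fields[1].split(" ", 1)[0]
                if rel_type not in RELATION_TYPES:
                    raise ValueError(f"unknown relation type {rel_type!r} in {ann_path.name}")
                label = RELATION_TYPES[rel_type]
        meta1, meta2 = notes.get("T1", {}), notes.get("T2", {})
        records.append(
            CurationRecord(
                protein=meta1.get("protein", ""),
                go_id=meta2.get("go_id", ""),
                doc_id=meta2.get("doc_id", ""),
                sentence_index=int(meta2.get("sentence_index", -1)),
                sentence_text=text,
                protein_span=spans["T1"],
                go_span=spans["T2"],
                label=label,
            )
        )
    return records


def label_records(
    records: Sequence[CurationRecord], labels: Mapping[int, str]
) -> list[CurationRecord]:
    """Return records with labels applied by position (testing/scripting aid)."""
    return [
        replace(r, label=labels.get(i, r.label)) for i, r in enumerate(records)
    ]


def class_precision(
    records: Sequence[CurationRecord],
    go_id: str,
    include_descendants: bool = False,
    graph=None,
) -> tuple[int, int, Fraction]:
    """Good / total over the labeled records of one functional class.

    With ``include_descendants`` the class covers co-mentions of descendant
    terms too (requires ``graph``).  Exact rational arithmetic; an empty
    class is an error.
    """
    wanted = {go_id}
    if include_descendants:
        if graph is None:
            raise ValueError("include_descendants requires the ontology graph")
        wanted |= graph.descendants(go_id)
    pool = [r for r in records if r.go_id in wanted]
    if not pool:
        raise ValueError(f"no curation records for class {go_id}")
    unlabeled = sum(1 for r in pool if r.label == "unlabeled")
    if unlabeled:
        raise ValueError(f"{unlabeled} records for {go_id} are unlabeled")
    n_good = sum(1 for r in pool if r.label == "Good")
    return n_good, len(pool), Fraction(n_good, len(pool))
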
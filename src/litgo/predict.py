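"""Gold-standard loading, the co-mention baseline, and a flat supervised model.

The gold standard comes from GAF 2.x files filtered to experimental evidence
codes (EXP, IDA, IPI, IMP, IGI, IEP, TAS); protein binding (GO:0005515) is
dropped for its broadness, as are NOT-qualified rows and terms missing or
obsolete in the ontology.

Two predictors are provided:

* :func:`baseline_predict` — the co-mentions themselves as a classifier: the
  score for (protein, term) is its co-mention count, max-normalized to
  [0, 1].  No learning; a floor on what literature co-occurrence alone buys.
* :func:`train_predict_flat` — per-term one-vs-rest linear classifiers on the
  sparse feature table with out-of-fold predictions from k-fold
  cross-validation.  This is a deliberately simple flat stand-in for a
  structured hierarchical learner, sufficient to compare feature sets
  end-to-end.

:func:`enforce_hierarchy` makes any score set consistent with the true-path
rule by propagating each score to all ancestors (parent score = max over
descendants), so thresholding commutes with expansion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold

from .comention import FeatureTable
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

#: Experimental evidence codes admitted to the gold standard.
EXPERIMENTAL_EVIDENCE = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS"})

#: Removed from the gold standard regardless of evidence.
PROTEIN_BINDING = "GO:0005515"

#: protein -> {GO id -> score in [0, 1]}
PredictionSet = dict[str, dict[str, float]]


@dataclass
class GoldAnnotations:
    """Protein -> GO term annotations with per-pair evidence provenance."""

    by_protein: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, protein: str, go_id: str, evidence: str) -> None:
        self.by_protein.setdefault(protein, set()).add(go_id)
        self.evidence[(protein, go_id)] = evidence

    @property
    def n_annotations(self) -> int:
        return sum(len(v) for v in self.by_protein.values())

    def proteins(self) -> set[str]:
        return set(self.by_protein)


def load_gold_gaf(
    path,
    graph: OntologyGraph,
    evidence_codes: Iterable[str] = EXPERIMENTAL_EVIDENCE,
) -> GoldAnnotations:
    """Read a GAF 2.x file, keeping only experimentally supported annotations.

    Rows are dropped when the evidence code is outside ``evidence_codes``,
    the qualifier contains NOT, the term is GO:0005515, or the term is
    absent/obsolete in ``graph`` (logged).  A row with fewer than 15 columns
    is a hard error naming the line.
    """
    allowed = set(evidence_codes)
    gold = GoldAnnotations()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                raise ValueError(f"malformed GAF row at line {lineno}: {len(cols)} columns")
            _, protein, _, qualifier, go_id, _, evidence = cols[:7]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence not in allowed:
                continue
            if go_id == PROTEIN_BINDING:
                continue
            term = graph.terms.get(go_id)
            if term is None or term.obsolete:
                logger.info("dropping annotation to missing/obsolete term %s (line %d)",
                            go_id, lineno)
                continue
            gold.add(protein, go_id, evidence)
    return gold


# ---------------------------------------------------------------------------
# predictors


def baseline_predict(
    features: FeatureTable,
    graph: OntologyGraph,
    mode: str = "combined",
    normalize: bool = True,
) -> PredictionSet:
    """Use co-mention counts directly as prediction scores.

    ``mode`` selects which counts feed the score: ``sentence`` (``co_``
    keys), ``non_sentence`` (``nco_``), or ``combined`` (their sum).  Scores
    are divided by the corpus-wide maximum count so they land in (0, 1]
    (counts are implicitly 0 for absent pairs, so the minimum of the
    normalization range is 0).
    """
    prefixes = {"sentence": ("co_",), "non_sentence": ("nco_",), "combined": ("co_", "nco_")}
    if mode not in prefixes:
        raise ValueError(f"unknown baseline mode {mode!r}")
    counts: PredictionSet = {}
    any_key = False
    for acc, feats in features.items():
        row: dict[str, float] = {}
        for key, c in feats.items():
            for prefix in prefixes[mode]:
                if key.startswith(prefix):
                    go_id = key[len(prefix):]
                    if go_id in graph.terms:
                        row[go_id] = row.get(go_id, 0.0) + c
        if any(k.startswith(("co_", "nco_")) for k in feats):
            any_key = True
        if row:
            counts[acc] = row
    if not any_key:
        raise ValueError("feature table contains no co-mention (co_/nco_) keys")
    if normalize and counts:
        top = max(max(row.values()) for row in counts.values())
        if top > 0:
            counts = {a: {g: c / top for g, c in row.items()} for a, row in counts.items()}
    return counts


def train_predict_flat(
    features: FeatureTable,
    gold: GoldAnnotations,
    graph: OntologyGraph,
    folds: int = 5,
    seed: int = 0,
    min_annotations: int = 10,
    expand_labels: bool = True,
) -> PredictionSet:
    """Per-term one-vs-rest logistic models with out-of-fold predictions.

    Targets are the terms with at least ``min_annotations`` annotated
    proteins after true-path expansion of the gold labels.  Each protein's
    score for a term is the probability predicted by the model trained on
    the other folds; single-class folds fall back to the training-fold
    positive rate.  Deterministic for a fixed seed.
    """
    proteins = sorted(set(features) | gold.proteins())
    if len(proteins) < 2 * folds:
        raise ValueError(f"need at least {2 * folds} proteins for {folds}-fold CV")
    feat_keys = sorted({k for feats in features.values() for k in feats})
    key_index = {k: i for i, k in enumerate(feat_keys)}
    rows, cols, vals = [], [], []
    for i, acc in enumerate(proteins):
        for k, c in features.get(acc, {}).items():
            rows.append(i)
            cols.append(key_index[k])
            vals.append(float(c))
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(len(proteins), max(len(feat_keys), 1)))

    expanded = {
        p: (graph.expand_true_path(ts) if expand_labels else set(ts))
        for p, ts in gold.by_protein.items()
    }
    term_counts: dict[str, int] = {}
    for ts in expanded.values():
        for t in ts:
            term_counts[t] = term_counts.get(t, 0) + 1
    targets = sorted(t for t, c in term_counts.items() if c >= min_annotations)

    rng_splits = list(
        KFold(n_splits=folds, shuffle=True, random_state=seed).split(np.arange(len(proteins)))
    )
    predictions: PredictionSet = {p: {} for p in proteins}
    for term in targets:
        y = np.array([1 if term in expanded.get(p, ()) else 0 for p in proteins])
        if y.min() == y.max():
            warnings.warn(f"term {term} is single-class in the gold standard; skipped",
                          stacklevel=2)
            continue
        scores = np.zeros(len(proteins))
        for train_idx, test_idx in rng_splits:
            y_train = y[train_idx]
            if y_train.min() == y_train.max():
                scores[test_idx] = float(y_train.mean())
                continue
            model = LogisticRegression(max_iter=1000, C=10.0)
            model.fit(X[train_idx], y_train)
            scores[test_idx] = model.predict_proba(X[test_idx])[:, 1]
        for i, p in enumerate(proteins):
            if scores[i] > 0:
                predictions[p][term] = float(scores[i])
    return {p: row for p, row in predictions.items() if row}


def enforce_hierarchy(predictions: PredictionSet, graph: OntologyGraph) -> PredictionSet:
    """Propagate scores upward so score(parent) >= score(child) everywhere.

    Each term's new score is the maximum over itself and its scored
    descendants; ancestors of scored terms gain entries.  Idempotent.
    """
    out: PredictionSet = {}
    for acc, row in predictions.items():
        new_row = dict(row)
        for term in graph.topological_order():
            score = new_row.get(term)
            if score is None:
                continue
            t = graph.terms[term]
            for parent in t.parents:
                if new_row.get(parent, -1.0) < score:
                    new_row[parent] = score
        out[acc] = new_row
    return out


def write_predictions(predictions: PredictionSet, path) -> None:
    """TSV dump: protein<TAB>GO id<TAB>score."""
    with open(path, "w", encoding="utf-8") as fh:
        for acc in sorted(predictions):
            for go_id in sorted(predictions[acc]):
                fh.write(f"{acc}\t{go_id}\t{predictions[acc][go_id]:.6g}\n")


def read_predictions(path) -> PredictionSet:
    out: PredictionSet = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            acc, go_id, score = line.rstrip("\n").split("\t")
            out.setdefault(acc, {})[go_id] = float(score)
    return out
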
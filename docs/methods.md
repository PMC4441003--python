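# Methods

## The problem

Given a collection of abstracts and full-text paragraphs, a protein name
lexicon, and the Gene Ontology, `litgo` derives per-protein literature
features — concept co-mentions and bag-of-words counts — and measures how
well they support prediction of GO annotations under hierarchy-aware
evaluation. The package treats dictionary construction, concept matching,
feature extraction, prediction and evaluation as separable, individually
testable stages.

## Ontology model

The ontology is a DAG with one root per namespace (molecular_function,
biological_process, cellular_component). The parent relation is the union
of `is_a` and `part_of`; the true-path rule — annotation to a term implies
annotation to every ancestor — is taken to traverse both, since GO states
the rule for both relations. Other relationship types are ignored.
Obsolete terms are parsed and flagged but excluded from dictionaries,
depth, IC and evaluation.

**Depth** is the shortest parent-edge path from the namespace root
(root = 0), computed by BFS; with multiple inheritance the shortest path is
the only unambiguous choice. **Information content** is annotation-based:
`ic(t) = −log p(t)` where `p(t)` is the fraction of annotated proteins (in
t's namespace) whose true-path-expanded gold set contains `t`. Natural log
by default with a `base` flag (base 2 gives bits); published IC figures do
not pin the base down, so it stays configurable. Terms never seen in the
expanded gold get no IC entry rather than an infinite one, and therefore
fall outside IC-binned reports.

## Dictionaries

The *original* dictionary contains every non-obsolete term's name and all
synonyms, lowercased; any surface ending in " activity" also contributes
the stripped form, because molecular-function names carry that suffix far
more often than running text does. The *enhanced* dictionary adds
rule-generated variants:

* **Rule M**: "X metabolic process" → "X metabolism", "metabolism of X".
  The biosynthetic and catabolic siblings are implemented behind flags
  that default off — they are the obvious extension of the same pattern,
  but only the metabolic family is anchored by a worked example, so the
  default configuration generates nothing it cannot justify.
* **Rule P**: "positive regulation of X" → "stimulation of X",
  "X stimulation", "pro-X"; when a derivational variant of X is known
  (packaged defaults: apoptosis→apoptotic, proliferation→proliferative,
  inflammation→inflammatory; user-extensible), every form is also emitted
  with the variant substituted. This over-generates slightly
  ("stimulation of apoptotic"), which is harmless for a lookup dictionary:
  unattested forms simply never match.
* **Rule N** (default off): "negative regulation of X" → "inhibition of
  X", "anti-X".

Every entry records provenance (name / synonym / activity_stripped /
rule:\<id\>), so the enhanced-minus-original delta is exactly the
rule-generated set. Dictionaries are deterministic functions of the graph,
the variant table and the rule config.

## Segmentation and matching

Sentence splitting is rule-based: split after terminal punctuation followed
by whitespace and an upper-case/digit start, guarded by an abbreviation
list and a single-capital-initial check ("E. coli"). Tokens are maximal
word-character runs with internal hyphens/apostrophes kept. Offsets are
0-based half-open character positions everywhere, including brat export.

Matching is dictionary lookup in the ConceptMapper style: within each
sentence the scanner walks token positions left to right and takes the
longest dictionary hit starting at the current position (case-insensitive,
whitespace-normalized, contiguous tokens, no stemming), then resumes after
it; overlapping shorter matches are thereby suppressed and ties resolve
leftmost. Cross-sentence and discontiguous matches are not attempted. An
ambiguous surface yields one mention carrying all candidate concept ids;
no disambiguation is attempted, and ambiguity flows through to features
(each candidate accession/term counts once). Protein recognition uses the
same matcher over the protein lexicon rather than a statistical NER model;
this keeps the mention → accession normalization step explicit and
deterministic.

## Co-mentions and bag of words

Within one document unit (abstract or paragraph), for each (protein p,
term g): one **sentence** co-mention per sentence containing both, and one
**non-sentence** co-mention per unordered pair of distinct sentences with
p in one and g in the other. Counting is presence-based — repeated
mentions inside a sentence do not multiply events — because per-mention
counting inflates quadratically in entity-dense sentences; a
`multiplicity="mention_pairs"` flag provides the per-mention-pair variant.
A pair co-occurring both within and across sentences in one unit counts in
both feature namespaces.

Bag-of-words associates each protein with the lowercased tokens of every
sentence mentioning it, minus a packaged English stopword list
(overridable), with no stemming or lemmatization. The protein's own tokens
are included by default (a flag excludes them).

Feature tables are sparse per-protein counters with namespaced keys
(`co_`, `nco_`, `w_`), assembled in six modes: sentence_only,
nonsentence_only, combined (sentence + non-sentence summed under `co_`),
separate, bow_only, comentions_plus_bow. Serialization is one record per
protein, `ACC, key=value, ...`, non-zero features only; read∘write is the
identity. Co-mention statistics report unique proteins/terms/pairs and
total events per span; the "combined" row deduplicates uniques across
spans and sums totals, with the plain sum also exposed (`total_summed`)
since either convention is defensible.

## Gold standard

GAF 2.x rows are kept only with experimental evidence codes (EXP, IDA,
IPI, IMP, IGI, IEP, TAS); NOT-qualified rows, protein binding (GO:0005515
— too broad and over-annotated to be informative), and terms missing or
obsolete in the loaded ontology are dropped (the latter logged).

## Predictors

**Baseline**: the co-mention counts themselves are the classifier.
score(p, g) = count (sentence, non-sentence, or their sum, per mode)
divided by the corpus-wide maximum count. The natural minimum of the
count range is 0 (absent pair), so max-scaling is the min-max map onto
(0, 1]; taking the minimum over *observed* counts instead would send the
weakest genuine pair to score 0. No learning; predictions for a protein
depend only on its own feature row.

**Flat classifier**: per-term one-vs-rest logistic regression (C = 10,
sparse input) over terms with ≥ `min_annotations` (default 10) proteins in
the expanded gold, scored by out-of-fold predicted probability under
seeded 5-fold CV; single-class folds fall back to the training-fold
positive rate. This is a deliberately simple flat stand-in for structured
hierarchical learners — the quantity of interest here is the relative
value of feature sets, not classifier sophistication.

**Hierarchy consistency**: `enforce_hierarchy` sets each term's score to
the max over itself and its scored descendants (one pass in topological
order), so thresholding commutes with true-path expansion. It is
idempotent.

## Evaluation

Both gold and predictions are expanded via the true-path rule before
comparison; exact-match evaluation penalizes near-miss predictions that
share most of their ancestry with the gold term. Micro P/R pool TP/FP/FN
over proteins: pooled precision is equivalent to restricting to proteins
with ≥ 1 prediction at the threshold; recall is over all gold proteins by
default, with a flag to restrict to predicted proteins (both conventions
appear in the literature). F-max sweeps τ over the distinct observed
scores plus 0 — the F curve is a step function of τ, so this sweep attains
the exact maximum (verified against a dense-grid oracle). Macro-AUC
averages per-term ROC AUC over terms with ≥ 10 expanded-gold positives and
at least one negative, with scores taken from hierarchy-consistent
predictions (absent = 0). Branches should be evaluated separately via the
`namespace` argument. Binned reports macro-average per-term F by depth
value or unit-width half-open IC interval `[k, k+1)`; terms missing from
the axis table are listed and excluded.

## Curation

Sentence co-mentions are sampled (seeded, uniform, optionally restricted
to one functional class) and exported one sentence per brat document: T1
(protein span) and T2 (GO concept span) entity lines plus AnnotatorNotes
lines carrying the co-mention identity, so import reconstructs records
exactly. The annotator adds a single `Good-Comention` / `Bad-Comention`
relation; unknown relation types are errors, missing relations leave the
record unlabeled. Per-class precision is exact rational arithmetic
(`Fraction(n_good, n_total)`); a flag widens a class to descendant terms.
One sentence per brat document keeps annotator context switches and offset
bookkeeping minimal.

## Synthetic data

The generator emulates the pipeline's inputs: a single-namespace rooted
DAG (default 30 terms; each term's parents sampled among earlier terms, or
a chain topology for depth tests) in which a configurable fraction
(default 20%) of names follow the rewrite-rule patterns; a one-surface-
per-accession protein lexicon (default 50 proteins); gold annotations of
k = 2 leaf-ish terms per protein with experimental evidence codes; and one
document per planted gold pair (default planted rate 1.0) of 5 sentences
of `filler*` distractor words, with the protein and GO surfaces placed in
one sentence (probability 0.7) or adjacent sentences. Noise injects, per
document with the given probability, a surface of a term outside the
protein's *expanded* gold set into the protein's sentence — guaranteeing
it is a false positive even after true-path expansion. `synonym_use_prob`
plants rule-generated surfaces instead of names; combined with
pattern-only gold terms this yields corpora that the original dictionary
cannot see at all. Only unambiguous surfaces are planted deliberately.

What this emulates — and what it does not: mentions are exact dictionary
surfaces in synthetic prose, so there is no morphological variation,
misspelling, genuine lexical ambiguity, coreference, or realistic word
statistics. Passing end-to-end tests therefore demonstrates the pipeline's
mechanics (recovery of planted signal, correct propagation, monotone
degradation under noise), not recognition performance on real text.

Default sizes (30 terms, 50 proteins, ~100 documents; acceptance runs use
3 seeds per noise condition) keep a full end-to-end run in seconds while
leaving every stage non-trivial: multi-parent terms, ambiguous modes
exercised in dedicated tests, and enough annotated terms to clear the
macro-AUC inclusion threshold.

## Numerical and degenerate-input choices

* Precision with no predictions at τ is reported as 0 with a flag rather
  than NaN; recall with empty gold likewise.
* F(τ) = 0 whenever P + R = 0.
* IC uses exact counts; `-log(1)` is normalized to 0.
* Macro-AUC skips terms with no negatives (AUC undefined) and errors only
  when no term qualifies at all.
* Ties in the matcher resolve leftmost by construction of the scan; equal
  scores in the F-max sweep are visited once each.
* Duplicate corpus doc_ids and GAF rows with fewer than 15 columns are
  hard errors naming the offender; empty documents are skipped with a
  warning.

## Known limitations

* No statistical NER: proteins not in the lexicon are invisible; species
  are not normalized.
* Matcher semantics are fixed to contiguous, non-stemmed, longest-match
  lookup; systems with fuzzier matching will recognize more (and noisier)
  mentions.
* The flat classifier ignores label structure during training (hierarchy
  is only enforced post hoc) and is not a substitute for structured
  hierarchical learning.
* The rule inventory is small and anchored to well-attested patterns;
  part-of-speech variant generation beyond the regulation rule is an
  extension hook (supply a richer `VariantTable`), not implemented logic.
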
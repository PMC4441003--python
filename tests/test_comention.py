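"""Co-mention extraction, bag-of-words, feature assembly and serialization."""

import random
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from litgo.comention import (
    CoMention,
    assemble_features,
    comention_stats,
    extract_bow,
    extract_comentions,
    read_features,
    write_features,
)
from litgo.textpipe import Document, Mention, segment


def doc_with_sentences(n, doc_id="d1"):
    text = " ".join(f"Sentence number {i} filler words." for i in range(n))
    doc = segment(Document(doc_id=doc_id, unit_kind="paragraph", text=text))
    assert len(doc.sentences) == n
    return doc


def mention(doc, sentence, concept, kind):
    s, e = doc.sentences[sentence]
    return Mention(doc_id=doc.doc_id, sentence_index=sentence, start=s, end=s + 1,
                   surface=doc.text[s:s + 1], kind=kind,
                   concept_ids=frozenset([concept]))


class TestExtractComentions:
    def test_no_go_mentions_empty(self):
        doc = doc_with_sentences(2)
        assert extract_comentions(doc, [mention(doc, 0, "P1", "protein")], []) == []

    def test_sentence_and_nonsentence_enumeration(self):
        # p in sentences {0, 2}, g in sentences {0, 1}
        doc = doc_with_sentences(3)
        pms = [mention(doc, 0, "P1", "protein"), mention(doc, 2, "P1", "protein")]
        gms = [mention(doc, 0, "G1", "go_term"), mention(doc, 1, "G1", "go_term")]
        cms = extract_comentions(doc, pms, gms)
        sent = [c for c in cms if c.span == "sentence"]
        nons = [c for c in cms if c.span == "non_sentence"]
        assert len(sent) == 1 and sent[0].protein_sentence == 0
        assert {frozenset((c.protein_sentence, c.go_sentence)) for c in nons} == {
            frozenset((0, 1)), frozenset((2, 0)), frozenset((2, 1))}
        assert len(nons) == 3

    def test_presence_based_within_sentence(self):
        doc = doc_with_sentences(1)
        pms = [mention(doc, 0, "P1", "protein")] * 2
        gms = [mention(doc, 0, "G1", "go_term")] * 2
        cms = extract_comentions(doc, pms, gms)
        assert len(cms) == 1 and cms[0].span == "sentence"

    def test_mention_pair_multiplicity_counts_quadratically(self):
        doc = doc_with_sentences(1)
        pms = [mention(doc, 0, "P1", "protein")] * 2
        gms = [mention(doc, 0, "G1", "go_term")] * 2
        cms = extract_comentions(doc, pms, gms, multiplicity="mention_pairs")
        assert len(cms) == 4
        with pytest.raises(ValueError, match="multiplicity"):
            extract_comentions(doc, pms, gms, multiplicity="per_token")

    def test_ambiguous_protein_counts_per_accession(self):
        doc = doc_with_sentences(1)
        s, _ = doc.sentences[0]
        pm = Mention(doc_id="d1", sentence_index=0, start=s, end=s + 1, surface="S",
                     kind="protein", concept_ids=frozenset(["P1", "P2"]))
        cms = extract_comentions(doc, [pm], [mention(doc, 0, "G1", "go_term")])
        assert {c.protein for c in cms} == {"P1", "P2"}

    def test_foreign_mention_is_error(self):
        doc = doc_with_sentences(1)
        other = doc_with_sentences(1, doc_id="d2")
        with pytest.raises(ValueError, match="d2"):
            extract_comentions(doc, [mention(other, 0, "P1", "protein")], [])

    def test_matches_bruteforce_pair_enumeration(self):
        rng = random.Random(3)
        for _ in range(60):
            n = rng.randint(1, 5)
            doc = doc_with_sentences(n)
            pms = [mention(doc, rng.randrange(n), f"P{rng.randint(1, 2)}", "protein")
                   for _ in range(rng.randint(0, 4))]
            gms = [mention(doc, rng.randrange(n), f"G{rng.randint(1, 2)}", "go_term")
                   for _ in range(rng.randint(0, 4))]
            cms = extract_comentions(doc, pms, gms)
            # oracle: presence sets per concept, then all sentence / pair events
            ps = {}
            gs = {}
            for m in pms:
                for a in m.concept_ids:
                    ps.setdefault(a, set()).add(m.sentence_index)
            for m in gms:
                for g in m.concept_ids:
                    gs.setdefault(g, set()).add(m.sentence_index)
            expect_sent = {(p, g, s) for p in ps for g in gs for s in ps[p] & gs[g]}
            expect_non = {
                (p, g, frozenset((sp, sg)))
                for p in ps for g in gs
                for sp in ps[p] for sg in gs[g] if sp != sg
            }
            got_sent = {(c.protein, c.go_id, c.protein_sentence)
                        for c in cms if c.span == "sentence"}
            got_non = {(c.protein, c.go_id,
                        frozenset((c.protein_sentence, c.go_sentence)))
                       for c in cms if c.span == "non_sentence"}
            assert got_sent == expect_sent
            assert got_non == expect_non
            assert len(cms) == len(expect_sent) + len(expect_non)


class TestExtractBow:
    def test_sentence_without_protein_contributes_nothing(self):
        doc = doc_with_sentences(2)
        bow = extract_bow(doc, [mention(doc, 0, "P1", "protein")], stopwords=set())
        # only sentence 0 words counted
        assert sum(bow["P1"].values()) == len(doc.tokens[0])

    def test_hand_counted_example(self):
        doc = segment(Document(doc_id="d1", unit_kind="abstract",
                               text="P53 inhibits the growth."))
        pm = Mention(doc_id="d1", sentence_index=0, start=0, end=3, surface="P53",
                     kind="protein", concept_ids=frozenset(["P04637"]))
        bow = extract_bow(doc, [pm], stopwords={"the"})
        assert bow["P04637"] == Counter({"p53": 1, "inhibits": 1, "growth": 1})

    def test_lowercasing_merges_counts_across_sentences(self):
        doc = segment(Document(doc_id="d1", unit_kind="abstract",
                               text="P53 alters Growth. P53 alters growth."))
        pms = [
            Mention(doc_id="d1", sentence_index=i, start=doc.sentences[i][0],
                    end=doc.sentences[i][0] + 3, surface="P53", kind="protein",
                    concept_ids=frozenset(["P04637"]))
            for i in range(2)
        ]
        bow = extract_bow(doc, pms, stopwords=set())
        assert bow["P04637"]["growth"] == 2

    def test_protein_tokens_excludable(self):
        doc = segment(Document(doc_id="d1", unit_kind="abstract",
                               text="P53 inhibits growth."))
        pm = Mention(doc_id="d1", sentence_index=0, start=0, end=3, surface="P53",
                     kind="protein", concept_ids=frozenset(["P04637"]))
        bow = extract_bow(doc, [pm], stopwords=set(), include_protein_tokens=False)
        assert "p53" not in bow["P04637"]


def cm(protein, go, span, doc="d1", sp=0, sg=0):
    if span == "non_sentence" and sp == sg:
        sg = sp + 1
    if span == "sentence":
        sg = sp
    return CoMention(protein, go, span, doc, sp, sg)


class TestAssembleFeatures:
    def events(self):
        return ([cm("P1", "G1", "sentence")] * 2
                + [cm("P1", "G1", "non_sentence", sp=i) for i in range(3)])

    def test_separate_mode(self):
        table = assemble_features(self.events(), mode="separate")
        assert table["P1"] == Counter({"co_G1": 2, "nco_G1": 3})

    def test_combined_mode_sums(self):
        table = assemble_features(self.events(), mode="combined")
        assert table["P1"] == Counter({"co_G1": 5})

    def test_single_span_modes(self):
        assert assemble_features(self.events(), mode="sentence_only")["P1"] == Counter(
            {"co_G1": 2})
        assert assemble_features(self.events(), mode="nonsentence_only")["P1"] == Counter(
            {"nco_G1": 3})

    def test_bow_modes(self):
        bow = {"P1": Counter({"growth": 4})}
        t = assemble_features(self.events(), bow=bow, mode="comentions_plus_bow")
        assert t["P1"] == Counter({"co_G1": 2, "nco_G1": 3, "w_growth": 4})
        assert assemble_features([], bow=bow, mode="bow_only")["P1"] == Counter(
            {"w_growth": 4})

    def test_unknown_mode_is_error(self):
        with pytest.raises(ValueError, match="unknown mode"):
            assemble_features([], mode="everything")

    def test_totals_conserved_between_combined_and_separate(self):
        rng = random.Random(11)
        events = [cm(f"P{rng.randint(1, 4)}", f"G{rng.randint(1, 4)}",
                     rng.choice(["sentence", "non_sentence"]), sp=rng.randrange(4),
                     sg=rng.randrange(4)) for _ in range(200)]
        events = [e for e in events if e.span == "sentence" or True]
        combined = assemble_features(events, mode="combined")
        separate = assemble_features(events, mode="separate")
        total = lambda t: sum(sum(c.values()) for c in t.values())
        assert total(combined) == total(separate) == len(events)


class TestSerialization:
    def test_paper_style_line_format(self, tmp_path):
        table = {"Q9ZPY7": Counter({"co_GO:0003675": 6, "co_GO:0005623": 2})}
        path = tmp_path / "features.txt"
        write_features(table, path)
        assert path.read_text() == "Q9ZPY7, co_GO:0003675=6, co_GO:0005623=2\n"

    def test_empty_table_empty_file(self, tmp_path):
        path = tmp_path / "features.txt"
        write_features({}, path)
        assert path.read_text() == ""

    def test_malformed_pair_is_error(self, tmp_path):
        path = tmp_path / "features.txt"
        path.write_text("P1, co_G1=2, broken\n")
        with pytest.raises(ValueError, match="P1"):
            read_features(path)

    @settings(max_examples=50, derandomize=True)
    @given(raw=st.dictionaries(
        st.text(alphabet="ABCDEFG0123456789", min_size=1, max_size=6),
        st.dictionaries(
            st.sampled_from([f"co_GO:{i:07d}" for i in range(5)]
                            + [f"nco_GO:{i:07d}" for i in range(5)]
                            + ["w_growth", "w_kinase"]),
            st.integers(min_value=1, max_value=99),
            max_size=6),
        max_size=5))
    def test_write_read_roundtrip(self, raw):
        import tempfile
        from pathlib import Path

        table = {acc: Counter(feats) for acc, feats in raw.items()}
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "features.txt"
            write_features(table, path)
            assert read_features(path) == {a: Counter(f) for a, f in table.items()}


class TestComentionStats:
    def test_empty_stream_all_zero(self):
        stats = comention_stats([])
        for span in ("sentence", "non_sentence", "combined"):
            assert stats[span]["total_comentions"] == 0
            assert stats[span]["unique_pairs"] == 0

    def test_hand_counted_fixture(self):
        events = [
            cm("P1", "G1", "sentence"),
            cm("P1", "G1", "sentence"),
            cm("P1", "G2", "non_sentence"),
            cm("P2", "G1", "non_sentence"),
            cm("P2", "G1", "sentence"),
        ]
        stats = comention_stats(events)
        assert stats["sentence"] == {"unique_proteins": 2, "unique_go_terms": 1,
                                     "unique_pairs": 2, "total_comentions": 3}
        assert stats["non_sentence"] == {"unique_proteins": 2, "unique_go_terms": 2,
                                         "unique_pairs": 2, "total_comentions": 2}
        assert stats["combined"]["unique_pairs"] == 3
        assert stats["combined"]["total_comentions"] == 5
        assert stats["combined"]["total_summed"] == 5

    def test_combined_uniques_bounded_by_span_sum(self):
        rng = random.Random(2)
        events = [cm(f"P{rng.randint(1, 5)}", f"G{rng.randint(1, 5)}",
                     rng.choice(["sentence", "non_sentence"]),
                     sp=rng.randrange(3), sg=rng.randrange(3)) for _ in range(100)]
        stats = comention_stats(events)
        assert (stats["combined"]["unique_pairs"]
                <= stats["sentence"]["unique_pairs"]
                + stats["non_sentence"]["unique_pairs"])
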
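"""GAF loading, the co-mention baseline, hierarchy enforcement, flat classifier."""

import random
from collections import Counter

import pytest

from litgo.evaluate import fmax, macro_auc
from litgo.predict import (
    GoldAnnotations,
    baseline_predict,
    enforce_hierarchy,
    load_gold_gaf,
    train_predict_flat,
)

from conftest import graph_from, random_dag


def gaf_row(protein, go_id, evidence, qualifier="enables"):
    cols = ["SYNTH", protein, protein.lower(), qualifier, go_id, "REF:1", evidence,
            "", "P", "", "", "protein", "taxon:9606", "20260101", "src"]
    return "\t".join(cols)


@pytest.fixture
def small_graph():
    g = graph_from({"GO:0008150": set(),
                    "GO:0005515": {"GO:0008150"},
                    "GO:0001000": {"GO:0008150"},
                    "GO:0002000": {"GO:0001000"}})
    return g


class TestLoadGoldGaf:
    def test_evidence_filter_and_binding_removal(self, small_graph, tmp_path):
        rows = [
            gaf_row("P1", "GO:0001000", "IDA"),        # kept
            gaf_row("P1", "GO:0002000", "IEA"),        # non-experimental
            gaf_row("P2", "GO:0005515", "IDA"),        # protein binding, dropped
            gaf_row("P2", "GO:0002000", "TAS"),        # kept
            gaf_row("P3", "GO:0001000", "IMP", qualifier="NOT|enables"),  # negated
            gaf_row("P3", "GO:9999999", "EXP"),        # unknown term, dropped
        ]
        path = tmp_path / "gold.gaf"
        path.write_text("!gaf-version: 2.2\n" + "\n".join(rows) + "\n")
        gold = load_gold_gaf(path, small_graph)
        assert gold.by_protein == {"P1": {"GO:0001000"}, "P2": {"GO:0002000"}}
        assert gold.evidence[("P2", "GO:0002000")] == "TAS"

    def test_twenty_row_fixture_keeps_hand_counted_seven(self, small_graph, tmp_path):
        allowed = ["EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "TAS"]
        rows = [gaf_row(f"P{i}", "GO:0001000", allowed[i]) for i in range(7)]
        rows += [gaf_row(f"P{i + 7}", "GO:0002000", ev)
                 for i, ev in enumerate(["IEA", "ISS", "ISO", "IBA", "RCA",
                                         "ND", "IC", "HDA", "HEP", "IGC"])]
        rows += [gaf_row("P90", "GO:0005515", "IDA"),
                 gaf_row("P91", "GO:0005515", "EXP"),
                 gaf_row("P92", "GO:0005515", "IEA")]
        assert len(rows) == 20
        path = tmp_path / "gold.gaf"
        path.write_text("\n".join(rows) + "\n")
        gold = load_gold_gaf(path, small_graph)
        assert gold.n_annotations == 7
        assert all("GO:0005515" not in ts for ts in gold.by_protein.values())

    def test_malformed_row_reports_line(self, small_graph, tmp_path):
        path = tmp_path / "gold.gaf"
        path.write_text(gaf_row("P1", "GO:0001000", "IDA") + "\nP2\tshort\n")
        with pytest.raises(ValueError, match="line 2"):
            load_gold_gaf(path, small_graph)


class TestBaselinePredict:
    def test_single_feature_gets_maximal_score(self, small_graph):
        table = {"P1": Counter({"co_GO:0002000": 5})}
        preds = baseline_predict(table, small_graph)
        assert preds == {"P1": {"GO:0002000": 1.0}}

    def test_protein_without_comentions_absent(self, small_graph):
        table = {"P1": Counter({"co_GO:0002000": 5}), "P2": Counter({"w_growth": 3})}
        preds = baseline_predict(table, small_graph)
        assert "P2" not in preds

    def test_mode_selects_span(self, small_graph):
        table = {"P1": Counter({"co_GO:0001000": 2, "nco_GO:0001000": 6})}
        sent = baseline_predict(table, small_graph, mode="sentence", normalize=False)
        both = baseline_predict(table, small_graph, mode="combined", normalize=False)
        assert sent["P1"]["GO:0001000"] == 2
        assert both["P1"]["GO:0001000"] == 8

    def test_scores_scaled_to_unit_interval(self, small_graph):
        table = {"P1": Counter({"co_GO:0001000": 2}),
                 "P2": Counter({"co_GO:0002000": 8})}
        preds = baseline_predict(table, small_graph)
        assert preds["P2"]["GO:0002000"] == 1.0
        assert preds["P1"]["GO:0001000"] == pytest.approx(0.25)

    def test_no_comention_keys_is_error(self, small_graph):
        with pytest.raises(ValueError, match="co-mention"):
            baseline_predict({"P1": Counter({"w_growth": 1})}, small_graph)

    def test_depends_only_on_own_feature_row(self, small_graph):
        t1 = {"P1": Counter({"co_GO:0002000": 4}), "P2": Counter({"co_GO:0001000": 4})}
        t2 = {"P1": Counter({"co_GO:0002000": 4}), "P3": Counter({"co_GO:0001000": 4})}
        assert (baseline_predict(t1, small_graph)["P1"]
                == baseline_predict(t2, small_graph)["P1"])


class TestEnforceHierarchy:
    def test_leaf_score_propagates_to_ancestors(self, diamond):
        out = enforce_hierarchy({"P1": {"a": 0.8}}, diamond)
        assert out["P1"] == {"a": 0.8, "b": 0.8, "c": 0.8, "d": 0.8}

    def test_idempotent_on_consistent_input(self, diamond):
        consistent = {"P1": {"a": 0.2, "b": 0.5, "c": 0.3, "d": 0.5}}
        assert enforce_hierarchy(consistent, diamond) == consistent

    def test_matches_bruteforce_descendant_max(self):
        rng = random.Random(21)
        for _ in range(20):
            graph = random_dag(rng, n_terms=10)
            scores = {t: rng.random() for t in rng.sample(sorted(graph.terms), 5)}
            out = enforce_hierarchy({"P1": scores}, graph)["P1"]
            for term in graph.terms:
                below = {term} | graph.descendants(term)
                expect = max((scores[d] for d in below if d in scores), default=None)
                if expect is None:
                    assert term not in out
                else:
                    assert out[term] == pytest.approx(expect)


class TestTrainPredictFlat:
    def separable_setup(self, n=40):
        graph = graph_from({"GO:0008150": set(),
                            "GO:0001000": {"GO:0008150"},
                            "GO:0002000": {"GO:0008150"}})
        gold = GoldAnnotations()
        features = {}
        for i in range(n):
            acc = f"P{i}"
            term = "GO:0001000" if i % 2 == 0 else "GO:0002000"
            gold.add(acc, term, "IDA")
            features[acc] = Counter({f"w_{term}": 5})
        return graph, gold, features

    def test_separable_features_reach_perfect_fmax(self):
        graph, gold, features = self.separable_setup()
        preds = train_predict_flat(features, gold, graph, seed=0, min_annotations=5)
        result = fmax(enforce_hierarchy(preds, graph), gold, graph)
        assert result.fmax == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        graph, gold, features = self.separable_setup()
        a = train_predict_flat(features, gold, graph, seed=3, min_annotations=5)
        b = train_predict_flat(features, gold, graph, seed=3, min_annotations=5)
        assert a == b

    def test_shuffled_labels_give_chance_auc(self):
        graph, gold, features = self.separable_setup(n=120)
        aucs = []
        for seed in (1, 2, 3):
            rng = random.Random(seed)
            accs = sorted(gold.by_protein)
            terms = [sorted(gold.by_protein[a])[0] for a in accs]
            rng.shuffle(terms)
            shuffled = GoldAnnotations()
            for acc, term in zip(accs, terms):
                shuffled.add(acc, term, "IDA")
            preds = train_predict_flat(features, shuffled, graph, seed=seed,
                                       min_annotations=5)
            aucs.append(macro_auc(enforce_hierarchy(preds, graph), shuffled, graph,
                                  min_annotations=5))
        assert abs(sum(aucs) / len(aucs) - 0.5) < 0.1

    def test_too_few_proteins_is_error(self):
        graph, gold, features = self.separable_setup(n=6)
        gold.by_protein = {k: v for k, v in list(gold.by_protein.items())[:6]}
        with pytest.raises(ValueError, match="fold"):
            train_predict_flat(features, gold, graph, folds=5)
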
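import networkx as nx
import pytest
from hypothesis import given, strategies as st

from herbtox.calibration import AMBIGUOUS, NA, NONTOXIC, TOXIC, AnnotationRecord
from herbtox.prediction import (
    ANTAGONISTIC,
    CATEGORIES,
    ENHANCED_RADIOTHERAPY,
    SYNERGISTIC,
    WEAKENED_TARGET_THERAPY,
    InteractionEdge,
    build_interaction_network,
    classify_interaction,
    classify_interaction_rows,
    predict_endpoint,
    split_interactions,
    write_sif,
)
from herbtox.simscreen import SimilarityHit


def hit(query_id, cid, score):
    return SimilarityHit(query_id=query_id, cid=cid, score=score, descriptor="test")


def ann(cid, verdict, endpoint="Carcinogenicity"):
    return AnnotationRecord(cid=cid, endpoint=endpoint, verdict=verdict)


class TestPredictEndpoint:
    def test_worked_example_single_nontoxic_indicator(self):
        # published sterol example: only the 0.999 hit clears 0.6171 with an
        # informative carcinogenicity verdict (-1)
        hits = [hit("beta-sitosterol", "5997", 0.999),
                hit("beta-sitosterol", "5280453", 0.804),
                hit("beta-sitosterol", "445354", 0.588)]
        annotations = [ann("5997", NONTOXIC), ann("5280453", NA), ann("445354", NA)]
        pred = predict_endpoint("beta-sitosterol", "Carcinogenicity", hits, annotations,
                                threshold=0.6171)
        assert pred.indicators == [("5997", 0.999, NONTOXIC)]
        assert pred.verdict == NONTOXIC

    def test_no_hits_above_threshold_is_na(self):
        pred = predict_endpoint("q", "Carcinogenicity", [hit("q", "1", 0.5)],
                                [ann("1", TOXIC)], threshold=0.9)
        assert pred.verdict is NA
        assert pred.indicators == []

    def test_strict_majority_toxic(self):
        hits = [hit("q", str(i), 0.9) for i in range(3)]
        annotations = [ann("0", TOXIC), ann("1", TOXIC), ann("2", NONTOXIC)]
        assert predict_endpoint("q", "Carcinogenicity", hits, annotations).verdict == TOXIC

    def test_mixed_without_majority_is_ambiguous(self):
        hits = [hit("q", str(i), 0.9) for i in range(2)]
        annotations = [ann("0", TOXIC), ann("1", NONTOXIC)]
        assert predict_endpoint("q", "Carcinogenicity", hits, annotations).verdict == AMBIGUOUS

    def test_all_nontoxic(self):
        hits = [hit("q", str(i), 0.9) for i in range(3)]
        annotations = [ann(str(i), NONTOXIC) for i in range(3)]
        assert predict_endpoint("q", "Carcinogenicity", hits, annotations).verdict == NONTOXIC

    def test_threshold_comparison_is_strict(self):
        pred = predict_endpoint("q", "Carcinogenicity", [hit("q", "1", 0.6171)],
                                [ann("1", TOXIC)], threshold=0.6171)
        assert pred.verdict is NA

    @given(st.permutations([TOXIC, TOXIC, NONTOXIC, AMBIGUOUS, NONTOXIC]))
    def test_order_invariance(self, verdicts):
        hits = [hit("q", str(i), 0.9) for i in range(len(verdicts))]
        annotations = [ann(str(i), v) for i, v in enumerate(verdicts)]
        pred = predict_endpoint("q", "Carcinogenicity", hits, annotations)
        assert pred.verdict == AMBIGUOUS  # 2 toxic vs 3 others, mixed

    def test_singleton_indicator_yields_own_verdict(self):
        for v in (TOXIC, AMBIGUOUS, NONTOXIC):
            pred = predict_endpoint("q", "Carcinogenicity", [hit("q", "1", 0.9)], [ann("1", v)])
            assert pred.verdict == v

    def test_ambiguous_counts_in_denominator(self):
        # +1, +1, 0 -> 2 > 1: toxic; +1, 0 -> 1 == 1: not a strict majority
        hits2 = [hit("q", str(i), 0.9) for i in range(2)]
        annotations2 = [ann("0", TOXIC), ann("1", AMBIGUOUS)]
        assert predict_endpoint("q", "Carcinogenicity", hits2, annotations2).verdict == AMBIGUOUS


class TestSplitInteractions:
    def test_three_statements(self):
        assert len(split_interactions("One fact. Another fact. A third fact.")) == 3

    def test_single_statement_identity(self):
        text = "A single statement without trailing space"
        assert split_interactions(text) == [text]

    def test_empty_payload(self):
        assert split_interactions("") == []
        assert split_interactions("   ") == []

    def test_abbreviations_protected(self):
        rows = split_interactions("It inhibits growth, e.g. in mice. It is dosed i.p. daily.")
        assert len(rows) == 2
        assert "e.g." in rows[0]

    def test_explicit_separator(self):
        assert split_interactions("a ||| b ||| c", separator="|||") == ["a", "b", "c"]

    def test_seven_statement_fixture(self):
        from herbtox.synthdata import gen_interaction_payload

        payload, expected = gen_interaction_payload(7, seed=3)
        rows = split_interactions(payload)
        assert len(rows) == len(expected) == 7


class TestClassifyInteraction:
    def test_radiation_sensitization(self):
        c = classify_interaction("may potentiate the sensitivity of cancer cells to ionizing radiation")
        assert (c.category, c.direction) == (ENHANCED_RADIOTHERAPY, SYNERGISTIC)

    def test_weakened_target_therapy(self):
        c = classify_interaction("weakened target therapy of bortezomib may occur")
        assert (c.category, c.direction) == (WEAKENED_TARGET_THERAPY, ANTAGONISTIC)

    def test_unclassifiable(self):
        assert classify_interaction("the moon is made of cheese") is None

    def test_genotoxicity_flagged_as_alert(self):
        c = classify_interaction("co-exposure showed enhanced genotoxicity in vitro")
        assert c.alert is True
        assert c.direction == SYNERGISTIC

    def test_template_fixtures_all_recovered(self):
        from herbtox.synthdata import gen_interaction_payload

        payload, expected = gen_interaction_payload(30, seed=11)
        rows = split_interactions(payload)
        for row, want in zip(rows, expected):
            got = classify_interaction(row)
            if want is None:
                assert got is None
            else:
                assert got.category == want

    def test_partition_sums_to_input(self):
        rows = ["enhanced genotoxicity seen", "cheese", "chemotherapy synergy noted", "more cheese"]
        classified, unclassified = classify_interaction_rows(rows)
        assert len(classified) + len(unclassified) == len(rows)
        assert len(unclassified) == 2

    def test_every_classified_row_has_one_category(self):
        for text in ("radiotherapy boost", "bioavailability increase", "genotoxicity up"):
            c = classify_interaction(text)
            assert c is not None and c.category in CATEGORIES


def edge(compound, partner, category=ENHANCED_RADIOTHERAPY, direction=SYNERGISTIC):
    return InteractionEdge(compound=compound, partner=partner, category=category,
                           direction=direction)


class TestNetwork:
    def test_counts(self):
        edges = [edge(f"c{i}", f"p{i}") for i in range(9)]
        g = build_interaction_network(edges)
        assert g.number_of_nodes() == 18
        assert g.number_of_edges() == 9

    def test_star_topology_counts(self):
        g = build_interaction_network([edge(f"c{i}", "docetaxel") for i in range(9)])
        assert (g.number_of_nodes(), g.number_of_edges()) == (10, 9)

    def test_empty(self):
        g = build_interaction_network([])
        assert g.number_of_nodes() == 0

    def test_duplicate_edges_collapsed_with_multiplicity(self):
        edges = [edge("c1", "p1"), edge("c1", "p1"), edge("c2", "p2"),
                 edge("c3", "p3"), edge("c4", "p4")]
        g = build_interaction_network(edges)
        assert g.number_of_edges() == 4
        mults = sorted(d["multiplicity"] for _, _, d in g.edges(data=True))
        assert mults == [1, 1, 1, 2]

    def test_bipartite_node_kinds(self):
        g = build_interaction_network([edge("c1", "p1")])
        assert g.nodes["c1"]["kind"] == "compound"
        assert g.nodes["p1"]["kind"] == "partner"

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            InteractionEdge("c", "p", "Teleportation", SYNERGISTIC)

    def test_sif_export_deterministic(self, tmp_path):
        edges = [edge("b", "p2"), edge("a", "p1")]
        g = build_interaction_network(edges)
        p1, p2 = tmp_path / "a.sif", tmp_path / "b.sif"
        write_sif(g, p1)
        write_sif(g, p2)
        assert p1.read_text() == p2.read_text()
        lines = p1.read_text().splitlines()
        assert lines[0].startswith("a\t")

    def test_graphml_loads_back(self, tmp_path):
        from herbtox.prediction import write_graphml

        g = build_interaction_network([edge("c1", "p1"), edge("c2", "p1")])
        path = tmp_path / "net.graphml"
        write_graphml(g, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == {"c1", "c2", "p1"}
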
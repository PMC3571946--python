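"""OBO parsing, ranked search, terminize, and term attachment."""

import random

import pytest
from hypothesis import given, settings, strategies as st

import expgraph as eg
from expgraph.ontology import annotatable_fields

from conftest import random_queries, search_oracle


class TestLoadObo:
    def test_term_count_matches_stanzas(self, tmp_path):
        path = tmp_path / "t.obo"
        eg.generate_toy_obo(3, 3, synonym_rate=1.0, path=path)
        assert eg.load_obo(path).term_count == 3

    def test_obsolete_terms_indexed_but_hidden(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(
            "format-version: 1.2\nontology: toy\n\n"
            "[Term]\nid: TOY:0000001\nname: living thing\n\n"
            "[Term]\nid: TOY:0000002\nname: dead thing\nis_obsolete: true\n",
            encoding="utf-8")
        index = eg.load_obo(path)
        assert index.term_count == 2
        assert index.get("TOY", "TOY:0000002").obsolete
        assert index.search("dead thing") == []
        hits = index.search("dead thing", include_obsolete=True)
        assert hits and hits[0].term.accession == "TOY:0000002"

    def test_stanza_missing_id_names_the_line(self, tmp_path):
        path = tmp_path / "bad.obo"
        path.write_text(
            "format-version: 1.2\n\n"
            "[Term]\nid: TOY:0000001\nname: fine\n\n"
            "[Term]\nname: no id here\n",
            encoding="utf-8")
        with pytest.raises(eg.ParseError) as err:
            eg.load_obo(path)
        assert err.value.line == 7

    def test_missing_file_is_ioerror(self, tmp_path):
        with pytest.raises(IOError):
            eg.load_obo(tmp_path / "absent.obo")

    def test_synonym_scopes_parsed(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: X:1\nname: alpha\n"
            'synonym: "first letter" EXACT []\n'
            'synonym: "a" RELATED []\n', encoding="utf-8")
        term = eg.load_obo(path, "X").get("X", "X:1")
        assert ("first letter", "EXACT") in term.synonyms
        assert ("a", "RELATED") in term.synonyms


class TestSearch:
    def test_exact_name_ranks_first_with_score_one(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(eg.FIGURE1_OBO, encoding="utf-8")
        index = eg.load_obo(path)
        hits = index.search("Gallus gallus")
        assert hits[0].term.accession == "TOY:0000001"
        assert hits[0].match_type == "exact_name" and hits[0].score == 1.0
        # score 1.0 iff exact_name
        assert all((m.score == 1.0) == (m.match_type == "exact_name")
                   for m in hits)

    def test_empty_query_returns_empty(self, toy_obo):
        index = eg.load_obo(toy_obo)
        assert index.search("") == [] and index.search("   ") == []

    def test_token_match_case_insensitive(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(eg.FIGURE1_OBO, encoding="utf-8")
        index = eg.load_obo(path)
        hits = index.search("GALLUS")
        assert hits[0].term.accession == "TOY:0000001"
        assert hits[0].match_type == "token"

    def test_unknown_source_rejected(self, toy_obo):
        index = eg.load_obo(toy_obo)
        with pytest.raises(eg.NoSuchSource):
            index.search("x", sources=["NOPE"])

    def test_source_restriction(self, tmp_path):
        a, b = tmp_path / "a.obo", tmp_path / "b.obo"
        eg.generate_toy_obo(1, 50, path=a)
        eg.generate_toy_obo(2, 50, path=b)
        index = eg.OntologyIndex()
        index.add_obo(a, "A")
        index.add_obo(b, "B")
        for m in index.search("sample", sources=["A"], limit=100):
            assert m.term.source == "A"

    def test_agrees_with_brute_force_scan(self, toy_obo):
        """Indexed search equals a from-scratch linear scan applying the
        documented match/score rules, over a realistic query mix."""
        index = eg.load_obo(toy_obo)
        rng = random.Random(42)
        for q in random_queries(index, rng, 150):
            got = [(m.term.accession, m.match_type, m.score)
                   for m in index.search(q, limit=25)]
            assert got == search_oracle(index, q, limit=25), q

    def test_limit_prefix_monotonicity(self, toy_obo):
        index = eg.load_obo(toy_obo)
        rng = random.Random(7)
        for q in random_queries(index, rng, 30):
            small = index.search(q, limit=5)
            big = index.search(q, limit=50)
            assert [m.term.accession for m in small] == \
                [m.term.accession for m in big][:len(small)]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.text(alphabet="abcdefg h", max_size=12), st.integers(1, 30))
    def test_arbitrary_queries_never_break_ranking(self, query, limit):
        index = getattr(self, "_index", None)
        if index is None:
            import tempfile, pathlib
            d = pathlib.Path(tempfile.mkdtemp())
            eg.generate_toy_obo(5, 80, path=d / "t.obo")
            index = type(self)._index = eg.load_obo(d / "t.obo")
        hits = index.search(query, limit=limit)
        assert len(hits) <= limit
        scores = [m.score for m in hits]
        assert scores == sorted(scores, reverse=True)

    def test_json_contract_field_names(self, tmp_path):
        path = tmp_path / "t.obo"
        path.write_text(eg.FIGURE1_OBO, encoding="utf-8")
        index = eg.load_obo(path)
        doc = eg.search_json(index, "chicken")
        assert set(doc) == {"query", "matches"}
        assert set(doc["matches"][0]) == \
            {"accession", "name", "source", "match_type", "score"}


class TestTerminize:
    def test_worked_example_chicken_matches_by_synonym(self, figure1, figure1_obo):
        _, _, study = figure1
        index = eg.load_obo(figure1_obo)
        report = eg.terminize(study, index)
        chicken = next(n for n in study.nodes.values() if n.label == "chicken")
        entry = next(e for e in report.entries
                     if e.entity_id == chicken.id and e.field_path == "label")
        assert entry.matches[0].term.name == "Gallus gallus"

    def test_root_only_study_has_no_candidates(self, figure1_obo):
        index = eg.load_obo(figure1_obo)
        study = eg.StudyGraph("s", "lonely", seed=0)
        report = eg.terminize(study, index)
        assert report.non_empty() == []

    def test_report_covers_exactly_the_annotatable_fields(self, figure1,
                                                          figure1_obo):
        _, _, study = figure1
        index = eg.load_obo(figure1_obo)
        report = eg.terminize(study, index)
        got = sorted((e.entity_id, e.field_path, e.query)
                     for e in report.entries)
        want = sorted(annotatable_fields(study))
        assert got == want

    def test_deterministic_reports(self, figure1_obo):
        index = eg.load_obo(figure1_obo)
        import json
        docs = [json.dumps(eg.terminize(eg.build_figure1_study(),
                                        index).to_json_dict(), sort_keys=True)
                for _ in range(2)]
        assert docs[0] == docs[1]

    def test_action_text_is_scanned(self, figure1, figure1_obo):
        _, _, study = figure1
        index = eg.load_obo(figure1_obo)
        report = eg.terminize(study, index)
        action_entries = [e for e in report.entries
                          if e.field_path == "protocol_application.action"]
        assert action_entries  # the sequencing arc has a deviation note


class TestAttachTerm:
    def test_attach_and_idempotence(self, figure1):
        _, inv, study = figure1
        b = next(n for n in study.nodes.values()
                 if n.label == "bacterial_replicate_1")
        term = eg.OntologyTerm("TOY:0000002", "Escherichia coli", "TOY")
        for _ in range(2):
            eg.attach_term(inv, b, "annotations[0].value", term)
        assert len(b.annotations[0].value_terms) == 1

    def test_foreign_source_rejected(self, figure1):
        _, inv, study = figure1
        b = next(n for n in study.nodes.values() if n.label == "chicken")
        alien = eg.OntologyTerm("ZZ:1", "alien", "UNDECLARED")
        with pytest.raises(eg.SourceNotRegistered):
            eg.attach_term(inv, b, "annotations[0].value", alien)
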
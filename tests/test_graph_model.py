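"""Typed construction, shortcuts and validation of study graphs."""

import random

import pytest

import expgraph as eg
from expgraph.graph import NodeKind

from conftest import brute_force_violation_codes, build_random_study, corruptions


@pytest.fixture()
def repo_inv_study():
    repo = eg.Repository(seed=0)
    alice = repo.add_user("alice", id="alice")
    inv = repo.create_investigation(
        "Chick infection study", [eg.OntologySource("TOY", "toy.obo")], alice)
    study = repo.add_study(inv, "Study 1", alice)
    return repo, alice, inv, study


class TestInvestigation:
    def test_create_investigation_sets_up_private_access(self, repo_with_users):
        repo, alice, bob = repo_with_users
        inv = repo.create_investigation(
            "Chick infection study", [eg.OntologySource("EFO", "efo.obo")], alice)
        assert len(inv.ontology_sources) == 1
        assert repo.groups[inv.access_group].members == {"alice"}
        assert repo.check_permission(alice, inv, "delete")
        assert not repo.check_permission(bob, inv, "read")

    def test_zero_ontology_sources_is_fine(self, repo_with_users):
        repo, alice, _ = repo_with_users
        inv = repo.create_investigation("X", [], alice)
        assert inv.ontology_sources == [] and inv.studies == []

    def test_duplicate_source_short_names_rejected(self, repo_with_users):
        repo, alice, _ = repo_with_users
        with pytest.raises(eg.DuplicateOntologySource):
            repo.create_investigation(
                "X", [eg.OntologySource("A", "a.obo"),
                      eg.OntologySource("A", "b.obo")], alice)

    def test_add_study_appends_fresh_root_only_graphs(self, repo_with_users):
        repo, alice, _ = repo_with_users
        inv = repo.create_investigation("X", [], alice)
        s1 = repo.add_study(inv, "Study 1", alice)
        s2 = repo.add_study(inv, "Study 2", alice)
        assert len(inv.studies) == 2 and s1.id != s2.id
        assert len(s1.nodes) == 1 and len(s1.arcs) == 0
        assert s1.root.kind is NodeKind.ROOT

    def test_add_study_requires_write_permission(self, repo_with_users):
        repo, alice, bob = repo_with_users
        inv = repo.create_investigation("X", [], alice)
        with pytest.raises(eg.AccessDenied):
            repo.add_study(inv, "intruder study", bob)


class TestAddChild:
    def test_legal_pairs(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "chicken")
        c = study.add_child(b.id, "container", "dish")
        c2 = study.add_child(c.id, "container", "aliquot")
        a = study.add_child(c2.id, "assay", "seq", modality="sequencing")
        assert [n.kind.value for n in (b, c, c2, a)] == \
            ["biosource", "container", "container", "assay"]
        assert study.arc_between(study.root_id, b.id).protocol_application is None
        assert study.validate() == []

    @pytest.mark.parametrize("parent_kind,child_kind", [
        ("root", "container"), ("root", "assay"), ("root", "root"),
        ("biosource", "assay"), ("biosource", "biosource"),
        ("container", "biosource"),
    ])
    def test_illegal_pairs_rejected(self, repo_inv_study, parent_kind, child_kind):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        parent = {"root": study.root, "biosource": b, "container": c}[parent_kind]
        with pytest.raises(eg.IllegalChildKind):
            study.add_child(parent.id, child_kind, "x")

    def test_assays_are_sinks(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        a = study.add_child(c.id, "assay", "a", modality="imaging")
        for kind in ("biosource", "container", "assay"):
            with pytest.raises(eg.IllegalChildKind):
                study.add_child(a.id, kind, "x")

    def test_unknown_parent(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        with pytest.raises(eg.NoSuchNode):
            study.add_child("nope", "biosource", "x")

    def test_kind_specific_fields_rejected_elsewhere(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        with pytest.raises(eg.KindError):
            study.add_child(b.id, "container", "c", modality="sequencing")
        assert b.miabs == {}


class TestPoolAndBulk:
    def test_pool_gives_one_child_with_one_arc_per_parent(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        bios = [study.add_child(study.root_id, "biosource", f"b{i}")
                for i in range(3)]
        tube = study.pool([b.id for b in bios], "container", "eppendorf")
        assert len(study.arcs_in(tube.id)) == 3
        assert study.validate() == []

    def test_pool_rejects_mixed_kinds_and_single_parent(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        with pytest.raises(eg.MixedSelection):
            study.pool([b.id, c.id], "container", "x")
        with pytest.raises(eg.PoolArityError):
            study.pool([b.id], "container", "x")

    def test_pooled_assay_from_containers_is_legal(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c1 = study.add_child(b.id, "container", "c1")
        c2 = study.add_child(b.id, "container", "c2")
        a = study.pool([c1.id, c2.id], "assay", "joint", modality="sequencing")
        assert len(study.arcs_in(a.id)) == 2
        assert study.validate() == []

    def test_bulk_add_children_labels_and_count(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        bios = [study.add_child(study.root_id, "biosource", f"b{i}")
                for i in range(3)]
        kids = study.bulk_add_children([b.id for b in bios], "container", "dish_")
        assert [k.label for k in kids] == ["dish_1", "dish_2", "dish_3"]
        assert [study.parents(k.id)[0].id for k in kids] == [b.id for b in bios]

    def test_bulk_add_equivalent_to_sequential_add(self, repo_inv_study):
        """The shortcut must be plain repetition, up to labels and ids."""
        _, _, _, study = repo_inv_study
        twin = eg.StudyGraph("twin", "twin", seed=0)
        for s in (study, twin):
            for i in range(3):
                s.add_child(s.root_id, "biosource", f"b{i}")
        bios = [n.id for n in study.nodes_of_kind("biosource")]
        study.bulk_add_children(bios, "container", "x_")
        for b in [n.id for n in twin.nodes_of_kind("biosource")]:
            twin.add_child(b, "container", "x")
        shape = lambda s: sorted(
            (s.nodes[a.parent_id].label if a.parent_id != s.root_id else "<root>",
             s.nodes[a.child_id].kind.value)
            for a in s.arcs.values())
        assert shape(study) == shape(twin)

    def test_bulk_operations_reject_mixed_selection(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        with pytest.raises(eg.MixedSelection):
            study.bulk_add_children([b.id, c.id], "container", "x")
        with pytest.raises(eg.MixedSelection):
            study.bulk_edit([b.id, c.id], "x", "y")

    def test_bulk_add_single_parent_degenerate(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        assert len(study.bulk_add_children([b.id], "container", "x")) == 1


class TestEditShortcuts:
    def test_duplicate_biosource_copies_values_not_identity(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "coli")
        study.annotate(b.id, "species", "E. coli")
        study.annotate(b.id, "strain", "K-12")
        b.miabs["species"] = "E. coli"
        study.add_child(b.id, "container", "child")
        dup = study.duplicate_biosource(b.id)
        assert dup.id != b.id
        assert [(a.name, a.value) for a in dup.annotations] == \
            [(a.name, a.value) for a in b.annotations]
        assert dup.miabs == b.miabs
        assert study.children(dup.id) == []  # descendants not copied
        dup.annotations[0].value = "mutant"
        dup.miabs["species"] = "other"
        assert b.annotations[0].value == "E. coli"
        assert b.miabs["species"] == "E. coli"

    def test_duplicate_non_biosource_rejected(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        with pytest.raises(eg.KindError):
            study.duplicate_biosource(c.id)

    def test_bulk_edit_sets_or_replaces_by_name(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        bios = [study.add_child(study.root_id, "biosource", f"b{i}")
                for i in range(3)]
        study.annotate(bios[0].id, "growth_temp", "30C")
        n = study.bulk_edit([b.id for b in bios], "growth_temp", "37C")
        assert n == 3
        for b in bios:
            assert b.annotation_values("growth_temp") == ["37C"]
        assert study.bulk_edit([], "x", "y") == 0


class TestProtocolApplication:
    def test_apply_records_deviation_and_replaces(self, repo_inv_study):
        repo, alice, _, study = repo_inv_study
        p1 = repo.protocols.register("extraction", "step 1", alice)
        p2 = repo.protocols.register("extraction v2", "step 1b", alice)
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        arc = study.arc_between(b.id, c.id)
        study.apply_protocol(arc.id, p1, "incubated 5 min longer",
                             [("temp", "37C")], registry=repo.protocols)
        app = arc.protocol_application
        assert app.action == "incubated 5 min longer"
        assert app.parameters == [("temp", "37C")]
        study.apply_protocol(arc.id, p2, registry=repo.protocols)
        assert arc.protocol_application.protocol_id == p2.id  # one per arc

    def test_root_arcs_refuse_protocols(self, repo_inv_study):
        repo, alice, _, study = repo_inv_study
        p = repo.protocols.register("x", "y", alice)
        b = study.add_child(study.root_id, "biosource", "b")
        arc = study.arc_between(study.root_id, b.id)
        with pytest.raises(eg.RootArcError):
            study.apply_protocol(arc.id, p, registry=repo.protocols)

    def test_unregistered_protocol_rejected(self, repo_inv_study):
        repo, _, _, study = repo_inv_study
        ghost = eg.Protocol("ghost", "ghost", "body", "alice")
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        arc = study.arc_between(b.id, c.id)
        with pytest.raises(eg.NoSuchProtocol):
            study.apply_protocol(arc.id, ghost, registry=repo.protocols)


class TestDelete:
    def test_delete_requires_cascade_for_parents(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b = study.add_child(study.root_id, "biosource", "b")
        c = study.add_child(b.id, "container", "c")
        a = study.add_child(c.id, "assay", "a", modality="imaging")
        with pytest.raises(eg.CascadeRequired):
            study.delete_node(b.id)
        gone = study.delete_node(b.id, cascade=True)
        assert set(gone) == {b.id, c.id, a.id}
        assert study.validate() == []

    def test_pooled_child_survives_one_parent_deletion(self, repo_inv_study):
        _, _, _, study = repo_inv_study
        b1 = study.add_child(study.root_id, "biosource", "b1")
        b2 = study.add_child(study.root_id, "biosource", "b2")
        tube = study.pool([b1.id, b2.id], "container", "tube")
        study.delete_node(b1.id, cascade=True)
        assert tube.id in study.nodes
        assert study.validate() == []


class TestValidate:
    def test_canonical_worked_example_is_legal(self, figure1):
        _, _, study = figure1
        assert study.validate() == []

    def test_hand_built_biosource_chain_caught(self, repo_inv_study):
        from expgraph.graph import Arc
        _, _, _, study = repo_inv_study
        b1 = study.add_child(study.root_id, "biosource", "b1")
        b2 = study.add_child(study.root_id, "biosource", "b2")
        study.arcs["bad"] = Arc("bad", b1.id, b2.id)
        codes = {v.code for v in study.validate()}
        assert "ILLEGAL_CHILD" in codes
        assert "MULTIPARENT_KIND" in codes  # b2 now has two parents

    def test_two_roots_caught(self, repo_inv_study):
        from expgraph.graph import GraphNode
        _, _, _, study = repo_inv_study
        study.nodes["r2"] = GraphNode("r2", NodeKind.ROOT, "impostor")
        codes = {v.code for v in study.validate()}
        assert "UNIQUE_ROOT" in codes

    @pytest.mark.parametrize("seed", range(25))
    def test_construction_safety(self, seed):
        """Any graph built through the public API validates clean."""
        rng = random.Random(seed)
        study = build_random_study(rng, n_ops=30)
        assert study.validate() == []
        assert brute_force_violation_codes(study) == set()

    @pytest.mark.parametrize("seed", range(10))
    def test_every_single_edit_corruption_is_caught(self, seed):
        """Single-edit corruptions are detected, in agreement with an
        independent per-invariant brute-force checker."""
        # the graph is rebuilt per corruption so every edit stays single
        def base():
            return build_random_study(random.Random(1000 + seed), n_ops=12)

        n_edits = len(corruptions(base(), random.Random(seed)))
        assert n_edits >= 4
        for i in range(n_edits):
            study = base()
            description, thunk = corruptions(study, random.Random(seed))[i]
            thunk()
            got = {v.code for v in study.validate()}
            expected = brute_force_violation_codes(study)
            assert got, f"corruption not detected: {description}"
            assert got == expected, description
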
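"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive everything from first
principles (hand-rolled DFS, linear scans over raw term fields) so that
agreement with the library is a real cross-check, not a tautology.
"""

from __future__ import annotations

import random
from collections import Counter

import pytest

import expgraph as eg
from expgraph.graph import NodeKind

# ---------------------------------------------------------------------------
# independent brute-force graph checker
# ---------------------------------------------------------------------------

_LEGAL = {
    ("root", "biosource"),
    ("biosource", "container"),
    ("container", "container"),
    ("container", "assay"),
}


def brute_force_violation_codes(study) -> set[str]:
    """Re-derive the violation code set without touching validate()."""
    codes: set[str] = set()
    nodes = study.nodes
    arcs = list(study.arcs.values())

    roots = [n for n in nodes.values() if n.kind.value == "root"]
    if not (len(roots) == 1 and study.root_id in nodes
            and nodes[study.root_id].kind.value == "root"):
        codes.add("UNIQUE_ROOT")

    for a in arcs:
        p, c = nodes.get(a.parent_id), nodes.get(a.child_id)
        if p is None or c is None:
            codes.add("DISCONNECTED")
            continue
        if (p.kind.value, c.kind.value) not in _LEGAL:
            codes.add("ILLEGAL_CHILD")
        if p.kind.value == "root" and a.protocol_application is not None:
            codes.add("ROOT_ARC_PROTOCOL")

    # cycle detection: iterative colouring DFS
    out_edges: dict[str, list[str]] = {nid: [] for nid in nodes}
    in_count: dict[str, int] = {nid: 0 for nid in nodes}
    for a in arcs:
        if a.parent_id in nodes and a.child_id in nodes:
            out_edges[a.parent_id].append(a.child_id)
            in_count[a.child_id] += 1
    colour = {nid: 0 for nid in nodes}

    def has_cycle(start: str) -> bool:
        stack = [(start, iter(out_edges[start]))]
        colour[start] = 1
        while stack:
            nid, it = stack[-1]
            advanced = False
            for nxt in it:
                if colour[nxt] == 1:
                    return True
                if colour[nxt] == 0:
                    colour[nxt] = 1
                    stack.append((nxt, iter(out_edges[nxt])))
                    advanced = True
                    break
            if not advanced:
                colour[nid] = 2
                stack.pop()
        return False

    if any(colour[nid] == 0 and has_cycle(nid) for nid in nodes):
        codes.add("CYCLE")

    if "UNIQUE_ROOT" not in codes:
        seen = {study.root_id}
        todo = [study.root_id]
        while todo:
            for nxt in out_edges[todo.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    todo.append(nxt)
        if set(nodes) - seen:
            codes.add("DISCONNECTED")

    for nid in nodes:
        if nodes[nid].kind.value in ("root", "biosource") and in_count[nid] > 1:
            codes.add("MULTIPARENT_KIND")
    return codes


# ---------------------------------------------------------------------------
# random construction sequences and single-edit corruptions
# ---------------------------------------------------------------------------

def build_random_study(rng: random.Random, n_ops: int = 25):
    """Drive the construction API at random; must always stay valid."""
    repo = eg.Repository(seed=rng.randrange(2 ** 30))
    owner = repo.add_user("owner")
    inv = repo.create_investigation("random build", [], owner)
    study = repo.add_study(inv, "random study", owner)
    proto = repo.protocols.register("generic protocol", "do the thing", owner)
    study.add_child(study.root_id, "biosource", "b0")
    for i in range(n_ops):
        op = rng.randrange(8)
        bios = study.nodes_of_kind("biosource")
        conts = study.nodes_of_kind("container")
        if op == 0 or not conts:
            study.add_child(study.root_id, "biosource", f"b{i}")
        elif op == 1:
            study.add_child(rng.choice(bios).id, "container", f"c{i}")
        elif op == 2:
            study.add_child(rng.choice(conts).id, "container", f"c{i}")
        elif op == 3:
            study.add_child(rng.choice(conts).id, "assay", f"a{i}",
                            modality="sequencing")
        elif op == 4 and len(bios) >= 2:
            k = min(len(bios), rng.randrange(2, 4))
            study.pool([b.id for b in rng.sample(bios, k)], "container", f"p{i}")
        elif op == 5:
            study.bulk_add_children([b.id for b in bios], "container", f"k{i}_")
        elif op == 6:
            study.duplicate_biosource(rng.choice(bios).id)
        else:
            arcs = [a for a in study.arcs.values()
                    if a.parent_id != study.root_id]
            if arcs:
                study.apply_protocol(rng.choice(arcs).id, proto,
                                     action="slightly longer",
                                     registry=repo.protocols)
            study.bulk_edit([b.id for b in bios], "batch", str(i))
    return study


def corruptions(study, rng: random.Random):
    """Yield (description, corrupting thunk) single edits of a valid graph.

    Each thunk mutates the graph in place; each breaks at least one
    invariant.
    """
    from expgraph.graph import Arc, GraphNode, ProtocolApplication

    nodes = list(study.nodes.values())
    nonroot = [n for n in nodes if n.kind is not NodeKind.ROOT]
    arcs = list(study.arcs.values())
    root_arcs = [a for a in arcs if a.parent_id == study.root_id]
    edits = []

    def add_second_root():
        n = GraphNode("xx_root2", NodeKind.ROOT, "second root")
        study.nodes[n.id] = n
    edits.append(("second root node", add_second_root))

    if nonroot:
        victim = rng.choice(nonroot)

        def retype():
            victim.kind = NodeKind.ROOT
        edits.append(("retype a node to root", retype))

    bios = [n for n in nodes if n.kind is NodeKind.BIOSOURCE]
    if len(bios) >= 2:
        b1, b2 = rng.sample(bios, 2)

        def biosource_chain():
            study.arcs["xx_bb"] = Arc("xx_bb", b1.id, b2.id)
        edits.append(("arc biosource -> biosource", biosource_chain))

    if root_arcs:
        arc = rng.choice(root_arcs)

        def root_protocol():
            arc.protocol_application = ProtocolApplication("p1", "p")
        edits.append(("protocol on a root arc", root_protocol))

        def orphan():
            del study.arcs[arc.id]
        edits.append(("remove a root arc (orphan biosource)", orphan))

    conts = [n for n in nodes if n.kind is NodeKind.CONTAINER]
    if conts:
        c = rng.choice(conts)

        def back_edge():
            study.arcs["xx_cycle"] = Arc("xx_cycle", c.id, study.root_id)
        edits.append(("back edge into the root", back_edge))
    chains = [(a.parent_id, a.child_id) for a in arcs
              if study.nodes[a.parent_id].kind is NodeKind.CONTAINER
              and study.nodes[a.child_id].kind is NodeKind.CONTAINER]
    if chains:
        p, c = rng.choice(chains)

        def cycle2():
            study.arcs["xx_loop"] = Arc("xx_loop", c, p)
        edits.append(("container two-cycle", cycle2))

    if bios and root_arcs:
        b = rng.choice(bios)
        other = [n for n in conts if n.id != b.id]
        if other:
            src = rng.choice(other)

            def second_parent():
                study.arcs["xx_mp"] = Arc("xx_mp", src.id, b.id)
            edits.append(("give a biosource a second parent", second_parent))
    return edits


# ---------------------------------------------------------------------------
# path signatures (round-trip oracle)
# ---------------------------------------------------------------------------

def path_signature_multiset(study) -> Counter:
    """Multiset of root-to-leaf paths with labels, annotations, attached
    terms and protocol names, computed by plain DFS."""
    sigs = []

    def node_sig(n):
        anns = tuple(sorted(
            (a.name, a.value,
             tuple(sorted((t.source, t.accession) for t in a.value_terms)))
            for a in n.annotations))
        return (n.kind.value, n.label, n.modality or "", anns)

    def walk(nid, acc):
        kids = study.arcs_out(nid)
        if not kids:
            sigs.append(tuple(acc))
        for arc in kids:
            app = arc.protocol_application
            pname = app.protocol_name if app else ""
            walk(arc.child_id,
                 acc + [(pname, node_sig(study.nodes[arc.child_id]))])

    walk(study.root_id, [])
    return Counter(sigs)


def dfs_terminal_path_count(study) -> int:
    """Brute-force count of root -> assay-input-container paths."""
    count = 0

    def walk(nid):
        nonlocal count
        node = study.nodes[nid]
        kids = [a for a in study.arcs_out(nid)]
        if node.kind is NodeKind.CONTAINER:
            child_kinds = {study.nodes[a.child_id].kind for a in kids}
            if not kids or NodeKind.ASSAY in child_kinds:
                count += 1
        for a in kids:
            if study.nodes[a.child_id].kind is not NodeKind.ASSAY:
                walk(a.child_id)

    walk(study.root_id)
    return count


# ---------------------------------------------------------------------------
# search oracle
# ---------------------------------------------------------------------------

def search_oracle(index, query, sources=None, limit=20):
    """Linear scan over raw term fields applying the documented rules."""
    ql = str(query).strip().lower()
    if not ql:
        return []
    tokens = set(ql.split())
    hits = []
    for term in index.terms() if sources is None else \
            [t for s in sources for t in index.terms(s)]:
        if term.obsolete:
            continue
        fields = [term.name.lower()] + [s.lower() for s, _ in term.synonyms]
        if ql == fields[0]:
            mt = "exact_name"
        elif ql in fields[1:]:
            mt = "exact_synonym"
        elif any(tokens <= set(f.split()) for f in fields):
            mt = "token"
        elif any(ql in f for f in fields):
            mt = "substring"
        else:
            continue
        hits.append((-eg.MATCH_SCORES[mt], term.accession, mt))
    hits.sort()
    return [(acc, mt, -neg) for neg, acc, mt in hits[:limit]]


def random_queries(index, rng: random.Random, n: int):
    """Realistic query mix: names, case variants, tokens, substrings, junk."""
    terms = index.terms()
    out = []
    for _ in range(n):
        t = rng.choice(terms)
        mode = rng.randrange(6)
        if mode == 0:
            out.append(t.name)
        elif mode == 1:
            out.append(t.name.upper())
        elif mode == 2 and t.synonyms:
            out.append(t.synonyms[0][0])
        elif mode == 3:
            out.append(rng.choice(t.name.split()))
        elif mode == 4 and len(t.name) > 6:
            i = rng.randrange(len(t.name) - 4)
            out.append(t.name[i:i + 4])
        else:
            out.append("xyz nothing matches this " + str(rng.randrange(10)))
    return out


# ---------------------------------------------------------------------------
# pytest fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def figure1():
    repo, inv, study = eg.build_figure1_investigation()
    return repo, inv, study


@pytest.fixture()
def toy_obo(tmp_path):
    path = tmp_path / "toy.obo"
    eg.generate_toy_obo(1, 200, synonym_rate=0.4, path=path)
    return path


@pytest.fixture()
def figure1_obo(tmp_path):
    path = tmp_path / "figure1.obo"
    path.write_text(eg.FIGURE1_OBO, encoding="utf-8")
    return path


@pytest.fixture()
def repo_with_users():
    repo = eg.Repository(seed=0)
    alice = repo.add_user("alice", id="alice")
    bob = repo.add_user("bob", id="bob")
    return repo, alice, bob
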
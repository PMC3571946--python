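"""The typed provenance graph of one study.

A study is captured as a directed acyclic graph with a single root node
standing for the study itself.  Besides the root there are only three
node kinds, mirroring what actually sits on a laboratory bench:

* ``biosource`` — raw biological input material (an organism, a culture);
* ``container`` — a physical vessel holding extracted material (tube,
  dish, flask); the "sample" of the ISA-Tab world;
* ``assay``     — a measurement event (a sequencing run, an image
  acquisition, an MS run) consuming a sample.

Arcs represent laboratory actions and may carry a protocol application;
the arcs out of the root merely record the inclusion of a biosource in
the study and therefore never carry one.  Legal parent/child kinds:

    root -> biosource,  biosource -> container,
    container -> container,  container -> assay

Splitting a sample is just adding several children to one container.
Pooling gives the pooled container (or assay) one incoming arc per
source.  Only containers and assays may have multiple parents; a
biosource always hangs directly off the root.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import networkx as nx

from ._ids import IdGen
from .errors import (
    CascadeRequired,
    IllegalChildKind,
    KindError,
    MixedSelection,
    NoSuchArc,
    NoSuchNode,
    NoSuchProtocol,
    PoolArityError,
    RootArcError,
)


class NodeKind(str, Enum):
    ROOT = "root"
    BIOSOURCE = "biosource"
    CONTAINER = "container"
    ASSAY = "assay"


#: parent kind -> child kinds allowed beneath it
LEGAL_CHILD_KINDS: dict[NodeKind, frozenset[NodeKind]] = {
    NodeKind.ROOT: frozenset({NodeKind.BIOSOURCE}),
    NodeKind.BIOSOURCE: frozenset({NodeKind.CONTAINER}),
    NodeKind.CONTAINER: frozenset({NodeKind.CONTAINER, NodeKind.ASSAY}),
    NodeKind.ASSAY: frozenset(),
}

#: kinds that may legally have more than one parent (pooling)
POOLABLE_CHILD_KINDS = frozenset({NodeKind.CONTAINER, NodeKind.ASSAY})

#: technology-independent minimum fields describing a biological sample
MIABS_FIELDS = (
    "species",
    "strain",
    "genetic_modification",
    "sex",
    "age",
    "tissue",
    "treatment",
)


@dataclass(frozen=True)
class TermRef:
    """A reference to an ontology term attached to a piece of text."""

    source: str
    accession: str
    name: str = ""


@dataclass
class Annotation:
    """A free name/value pair; either side may carry ontology terms.

    Repeated name/value pairs on one node are allowed and order is
    preserved.
    """

    name: str
    value: str
    name_terms: list[TermRef] = field(default_factory=list)
    value_terms: list[TermRef] = field(default_factory=list)

    def __post_init__(self):
        if not str(self.name).strip():
            raise ValueError("annotation name must be non-empty")


@dataclass
class FileAttachment:
    """An opaque attached file, recorded by path plus checksum."""

    filename: str
    uri_or_path: str = ""
    checksum: str = ""
    size: int = 0
    attached_to: str = ""


@dataclass
class ProtocolApplication:
    """The attachment of a registered protocol to an action (arc).

    ``action`` records deviations from the protocol text verbatim; it may
    be empty when the protocol was followed exactly.
    """

    protocol_id: str
    protocol_name: str = ""
    action: str = ""
    parameters: list[tuple[str, str]] = field(default_factory=list)
    performer: str | None = None
    date: str | None = None


@dataclass
class GraphNode:
    id: str
    kind: NodeKind
    label: str
    annotations: list[Annotation] = field(default_factory=list)
    attachments: list[FileAttachment] = field(default_factory=list)
    # kind-specific; must be absent (None) on other kinds
    miabs: dict[str, str] | None = None          # biosource only
    modality: str | None = None                  # assay only
    template_ref: str | None = None              # assay only
    external_link: str | None = None             # assay only

    def __post_init__(self):
        self.kind = NodeKind(self.kind)
        if self.miabs is not None and self.kind is not NodeKind.BIOSOURCE:
            raise KindError("miabs is a biosource-only field")
        for f in ("modality", "template_ref", "external_link"):
            if getattr(self, f) is not None and self.kind is not NodeKind.ASSAY:
                raise KindError(f"{f} is an assay-only field")
        if self.kind is NodeKind.BIOSOURCE and self.miabs is None:
            self.miabs = {}

    def annotation_values(self, name: str) -> list[str]:
        return [a.value for a in self.annotations if a.name == name]


@dataclass
class Arc:
    id: str
    parent_id: str
    child_id: str
    protocol_application: ProtocolApplication | None = None
    attachments: list[FileAttachment] = field(default_factory=list)


@dataclass
class Violation:
    """One broken study-graph invariant, with the offending node/arc ids."""

    code: str
    message: str
    ids: tuple[str, ...] = ()


class StudyGraph:
    """One experiment: a root plus biosources, containers and assays.

    Construction through :meth:`add_child`, :meth:`pool` and the bulk
    helpers can only produce graphs satisfying every invariant; a graph
    assembled (or mutated) by hand can be checked with :meth:`validate`.
    """

    def __init__(self, id: str, title: str, *, seed: int | None = None,
                 idgen: IdGen | None = None, creator: str | None = None,
                 root_label: str | None = None):
        self.id = id
        self.title = title
        self.creator = creator
        self.grants: dict[str, object] = {}
        self._ids = idgen if idgen is not None else IdGen(seed)
        self.nodes: dict[str, GraphNode] = {}
        self.arcs: dict[str, Arc] = {}
        root = GraphNode(self._ids.new("n"), NodeKind.ROOT,
                         root_label if root_label is not None else title)
        self.nodes[root.id] = root
        self.root_id = root.id

    # -- basic accessors ----------------------------------------------------

    @property
    def root(self) -> GraphNode:
        return self.nodes[self.root_id]

    def node(self, node_id: str) -> GraphNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise NoSuchNode(f"no node {node_id!r} in study {self.id}") from None

    def arc(self, arc_id: str) -> Arc:
        try:
            return self.arcs[arc_id]
        except KeyError:
            raise NoSuchArc(f"no arc {arc_id!r} in study {self.id}") from None

    def arcs_out(self, node_id: str) -> list[Arc]:
        return [a for a in self.arcs.values() if a.parent_id == node_id]

    def arcs_in(self, node_id: str) -> list[Arc]:
        return [a for a in self.arcs.values() if a.child_id == node_id]

    def children(self, node_id: str) -> list[GraphNode]:
        return [self.nodes[a.child_id] for a in self.arcs_out(node_id)]

    def parents(self, node_id: str) -> list[GraphNode]:
        return [self.nodes[a.parent_id] for a in self.arcs_in(node_id)]

    def arc_between(self, parent_id: str, child_id: str) -> Arc:
        for a in self.arcs.values():
            if a.parent_id == parent_id and a.child_id == child_id:
                return a
        raise NoSuchArc(f"no arc {parent_id!r} -> {child_id!r}")

    def nodes_of_kind(self, kind: NodeKind | str) -> list[GraphNode]:
        kind = NodeKind(kind)
        return [n for n in self.nodes.values() if n.kind is kind]

    # -- construction -------------------------------------------------------

    def _check_pair(self, parent: GraphNode, kind: NodeKind) -> None:
        if kind not in LEGAL_CHILD_KINDS[parent.kind]:
            raise IllegalChildKind(
                f"a {parent.kind.value} node cannot have a {kind.value} child")

    def _new_node(self, kind: NodeKind, label: str, **extra) -> GraphNode:
        node = GraphNode(self._ids.new("n"), kind, label, **extra)
        self.nodes[node.id] = node
        return node

    def _new_arc(self, parent_id: str, child_id: str) -> Arc:
        for a in self.arcs.values():
            if a.parent_id == parent_id and a.child_id == child_id:
                raise IllegalChildKind(
                    f"arc {parent_id!r} -> {child_id!r} already exists")
        arc = Arc(self._ids.new("a"), parent_id, child_id)
        self.arcs[arc.id] = arc
        return arc

    def add_child(self, parent_id: str, kind: NodeKind | str, label: str,
                  **extra) -> GraphNode:
        """Add one node beneath ``parent_id`` with the connecting arc.

        The child kind is constrained by the parent's kind (see module
        docstring).  Splitting a sample is nothing more than calling this
        repeatedly on the same container.
        """
        parent = self.node(parent_id)
        kind = NodeKind(kind)
        self._check_pair(parent, kind)
        node = self._new_node(kind, label, **extra)
        self._new_arc(parent.id, node.id)
        return node

    def pool(self, parent_ids: Sequence[str], kind: NodeKind | str,
             label: str, **extra) -> GraphNode:
        """Pool two or more same-kind nodes into one new child.

        The child gets one incoming arc per source; each arc can carry
        its own protocol application.
        """
        parents = [self.node(p) for p in parent_ids]
        if len(parents) < 2:
            raise PoolArityError("pooling needs at least two source nodes")
        kinds = {p.kind for p in parents}
        if len(kinds) > 1:
            raise MixedSelection("pooled sources must all be of the same kind")
        kind = NodeKind(kind)
        if kind not in POOLABLE_CHILD_KINDS:
            raise IllegalChildKind(f"cannot pool into a {kind.value} node")
        self._check_pair(parents[0], kind)
        node = self._new_node(kind, label, **extra)
        for p in parents:
            self._new_arc(p.id, node.id)
        return node

    def bulk_add_children(self, parent_ids: Sequence[str],
                          kind: NodeKind | str, label_prefix: str,
                          **extra) -> list[GraphNode]:
        """Add one child of ``kind`` to every selected parent.

        All parents must be of the same kind; children are labelled
        ``label_prefix`` + 1-based index.
        """
        parents = [self.node(p) for p in parent_ids]
        if len({p.kind for p in parents}) > 1:
            raise MixedSelection(
                "bulk add is only available for graph objects of the same type")
        kind = NodeKind(kind)
        out = []
        for i, p in enumerate(parents, start=1):
            out.append(self.add_child(p.id, kind, f"{label_prefix}{i}", **extra))
        return out

    def duplicate_biosource(self, node_id: str) -> GraphNode:
        """Copy a biosource (and all its annotation) as a fresh root child.

        Annotations and MIABS values are deep-copied; attachments are
        shared by reference; descendants are not copied.
        """
        orig = self.node(node_id)
        if orig.kind is not NodeKind.BIOSOURCE:
            raise KindError("only biosources can be duplicated")
        copy_node = self.add_child(self.root_id, NodeKind.BIOSOURCE, orig.label)
        copy_node.annotations = copy.deepcopy(orig.annotations)
        copy_node.miabs = dict(orig.miabs or {})
        copy_node.attachments = list(orig.attachments)
        return copy_node

    def bulk_edit(self, node_ids: Sequence[str], name: str, value: str) -> int:
        """Set annotation ``name`` to ``value`` on every selected node.

        Replaces the first annotation with that name if present, appends
        otherwise.  Returns the number of nodes edited.
        """
        nodes = [self.node(n) for n in node_ids]
        if len({n.kind for n in nodes}) > 1:
            raise MixedSelection(
                "bulk edit is only available for graph objects of the same type")
        for node in nodes:
            for ann in node.annotations:
                if ann.name == name:
                    ann.value = value
                    break
            else:
                node.annotations.append(Annotation(name, value))
        return len(nodes)

    def annotate(self, node_id: str, name: str, value: str) -> Annotation:
        """Append one name/value pair to a node (duplicates allowed)."""
        ann = Annotation(name, value)
        self.node(node_id).annotations.append(ann)
        return ann

    def attach_file(self, target_id: str, attachment: FileAttachment) -> None:
        """Attach an opaque file to any node or arc."""
        target = self.nodes.get(target_id) or self.arcs.get(target_id)
        if target is None:
            raise NoSuchNode(f"no node or arc {target_id!r}")
        attachment.attached_to = target_id
        target.attachments.append(attachment)

    def apply_protocol(self, arc_id: str, protocol, action: str = "",
                       parameters: Iterable[tuple[str, str]] = (),
                       *, registry=None, performer: str | None = None,
                       date: str | None = None) -> Arc:
        """Attach a registered protocol to an action (arc).

        ``action`` records any deviation from the protocol text and is
        stored verbatim.  Re-applying replaces the previous application:
        an arc carries at most one.  Root arcs represent inclusion of a
        biosource, not an action, and refuse protocols.
        """
        arc = self.arc(arc_id)
        if arc.parent_id == self.root_id:
            raise RootArcError("arcs out of the root cannot carry a protocol")
        if registry is not None and protocol.id not in registry:
            raise NoSuchProtocol(f"protocol {protocol.id!r} is not registered")
        arc.protocol_application = ProtocolApplication(
            protocol_id=protocol.id,
            protocol_name=getattr(protocol, "name", protocol.id),
            action=action,
            parameters=[(str(k), str(v)) for k, v in parameters],
            performer=performer,
            date=date,
        )
        return arc

    def delete_node(self, node_id: str, *, cascade: bool = False) -> list[str]:
        """Delete a node (never the root) and its incident arcs.

        A node with children is only deleted when ``cascade`` is set, in
        which case descendants reachable solely through it go too.
        Returns the deleted node ids.
        """
        node = self.node(node_id)
        if node.id == self.root_id:
            raise KindError("the root node cannot be deleted")
        kids = self.children(node_id)
        if kids and not cascade:
            raise CascadeRequired(
                f"node {node_id!r} has {len(kids)} children; pass cascade=True")
        doomed = [node_id]
        i = 0
        while i < len(doomed):
            for arc in self.arcs_out(doomed[i]):
                child = arc.child_id
                other = [a for a in self.arcs_in(child)
                         if a.parent_id not in doomed]
                if not other and child not in doomed:
                    doomed.append(child)
            i += 1
        doomed_set = set(doomed)
        self.arcs = {aid: a for aid, a in self.arcs.items()
                     if a.parent_id not in doomed_set and a.child_id not in doomed_set}
        for nid in doomed:
            del self.nodes[nid]
        return doomed

    # -- validation ---------------------------------------------------------

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, kind=n.kind.value, label=n.label)
        for a in self.arcs.values():
            if a.parent_id in self.nodes and a.child_id in self.nodes:
                g.add_edge(a.parent_id, a.child_id, key=a.id)
        return g

    def validate(self) -> list[Violation]:
        """Batch-check every structural invariant; [] iff the graph is legal.

        Codes: UNIQUE_ROOT, ILLEGAL_CHILD, CYCLE, DISCONNECTED,
        ROOT_ARC_PROTOCOL, MULTIPARENT_KIND.
        """
        out: list[Violation] = []
        roots = [n for n in self.nodes.values() if n.kind is NodeKind.ROOT]
        root_ok = (len(roots) == 1 and self.root_id in self.nodes
                   and self.nodes[self.root_id].kind is NodeKind.ROOT)
        if not root_ok:
            out.append(Violation(
                "UNIQUE_ROOT",
                f"expected exactly one root node, found {len(roots)}",
                tuple(sorted(n.id for n in roots))))

        for a in sorted(self.arcs.values(), key=lambda a: a.id):
            p, c = self.nodes.get(a.parent_id), self.nodes.get(a.child_id)
            if p is None or c is None:
                out.append(Violation("DISCONNECTED",
                                     f"arc {a.id} references a missing node",
                                     (a.id,)))
                continue
            if c.kind not in LEGAL_CHILD_KINDS[p.kind]:
                out.append(Violation(
                    "ILLEGAL_CHILD",
                    f"{p.kind.value} -> {c.kind.value} is not allowed",
                    (a.id, p.id, c.id)))
            if p.kind is NodeKind.ROOT and a.protocol_application is not None:
                out.append(Violation(
                    "ROOT_ARC_PROTOCOL",
                    "arcs out of the root cannot carry a protocol application",
                    (a.id,)))

        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            cyc = tuple(sorted({e[0] for e in nx.find_cycle(g)}))
            out.append(Violation("CYCLE", "the graph contains a cycle", cyc))

        if root_ok:
            reachable = set(nx.descendants(g, self.root_id)) | {self.root_id}
            stranded = sorted(set(self.nodes) - reachable)
            if stranded:
                out.append(Violation(
                    "DISCONNECTED",
                    f"{len(stranded)} node(s) unreachable from the root",
                    tuple(stranded)))

        for n in sorted(self.nodes.values(), key=lambda n: n.id):
            if n.kind in POOLABLE_CHILD_KINDS:
                continue
            if len(self.arcs_in(n.id)) > 1:
                out.append(Violation(
                    "MULTIPARENT_KIND",
                    f"a {n.kind.value} node may not have multiple parents",
                    (n.id,)))
        return out
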
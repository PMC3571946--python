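"""Persistence: the ``expgraph-1`` structured document.

A whole repository — users, groups, protocols, templates and every
investigation with its study graphs — round-trips through one
JSON-compatible document.  This is the CLI's native load/save format.
Serialization is deterministic: dictionaries keep insertion order and
the writer is configured for stable output, so identical repositories
give byte-identical documents.
"""

from __future__ import annotations

import json
from pathlib import Path

from .access import AccessGroup, PermLevel, User
from .graph import (
    Annotation,
    Arc,
    FileAttachment,
    GraphNode,
    NodeKind,
    ProtocolApplication,
    StudyGraph,
    TermRef,
)
from .investigation import Investigation, Repository
from .ontology import OntologySource
from .protocols import Comment, Protocol, TechnologyTemplate, TemplateField

FORMAT = "expgraph-1"


# -- encoding ----------------------------------------------------------------

def _term(t: TermRef) -> dict:
    return {"source": t.source, "accession": t.accession, "name": t.name}


def _annotation(a: Annotation) -> dict:
    return {"name": a.name, "value": a.value,
            "name_terms": [_term(t) for t in a.name_terms],
            "value_terms": [_term(t) for t in a.value_terms]}


def _attachment(f: FileAttachment) -> dict:
    return {"filename": f.filename, "uri_or_path": f.uri_or_path,
            "checksum": f.checksum, "size": f.size,
            "attached_to": f.attached_to}


def _node(n: GraphNode) -> dict:
    d = {"id": n.id, "kind": n.kind.value, "label": n.label,
         "annotations": [_annotation(a) for a in n.annotations],
         "attachments": [_attachment(f) for f in n.attachments]}
    if n.kind is NodeKind.BIOSOURCE:
        d["miabs"] = dict(n.miabs or {})
    if n.kind is NodeKind.ASSAY:
        d["modality"] = n.modality
        d["template_ref"] = n.template_ref
        d["external_link"] = n.external_link
    return d


def _arc(a: Arc) -> dict:
    d = {"id": a.id, "parent_id": a.parent_id, "child_id": a.child_id,
         "attachments": [_attachment(f) for f in a.attachments]}
    app = a.protocol_application
    d["protocol_application"] = None if app is None else {
        "protocol_id": app.protocol_id, "protocol_name": app.protocol_name,
        "action": app.action, "parameters": [list(p) for p in app.parameters],
        "performer": app.performer, "date": app.date}
    return d


def study_to_dict(s: StudyGraph) -> dict:
    return {"id": s.id, "title": s.title, "creator": s.creator,
            "grants": {g: PermLevel(l).value for g, l in s.grants.items()},
            "root_id": s.root_id,
            "nodes": [_node(n) for n in s.nodes.values()],
            "arcs": [_arc(a) for a in s.arcs.values()]}


def investigation_to_dict(inv: Investigation) -> dict:
    return {
        "id": inv.id, "title": inv.title, "description": inv.description,
        "creator": inv.creator, "access_group": inv.access_group,
        "grants": {g: PermLevel(l).value for g, l in inv.grants.items()},
        "ontology_sources": [
            {"short_name": s.short_name, "file": s.file,
             "version": s.version, "description": s.description}
            for s in inv.ontology_sources],
        "studies": [study_to_dict(s) for s in inv.studies],
    }


def repository_to_dict(repo: Repository) -> dict:
    return {
        "format": FORMAT,
        "users": [{"id": u.id, "name": u.name} for u in repo.users.values()],
        "groups": [{"id": g.id, "members": sorted(g.members)}
                   for g in repo.groups.values()],
        "protocols": [
            {"id": p.id, "name": p.name, "text": p.text, "creator": p.creator,
             "shared": p.shared,
             "comments": [{"author": c.author, "timestamp": c.timestamp,
                           "text": c.text} for c in p.comments]}
            for p in repo.protocols],
        "templates": [
            {"id": t.id, "name": t.name,
             "fields": [{"name": f.name, "required": f.required,
                         "description": f.description} for f in t.fields]}
            for t in repo.templates.values()],
        "investigations": [investigation_to_dict(i)
                           for i in repo.investigations.values()],
    }


def dumps(repo: Repository) -> str:
    return json.dumps(repository_to_dict(repo), indent=2, sort_keys=False,
                      ensure_ascii=False) + "\n"


def save(repo: Repository, path: str | Path) -> None:
    Path(path).write_text(dumps(repo), encoding="utf-8")


# -- decoding ----------------------------------------------------------------

def _term_from(d: dict) -> TermRef:
    return TermRef(d["source"], d["accession"], d.get("name", ""))


def _annotation_from(d: dict) -> Annotation:
    a = Annotation(d["name"], d["value"])
    a.name_terms = [_term_from(t) for t in d.get("name_terms", [])]
    a.value_terms = [_term_from(t) for t in d.get("value_terms", [])]
    return a


def _attachment_from(d: dict) -> FileAttachment:
    return FileAttachment(d["filename"], d.get("uri_or_path", ""),
                          d.get("checksum", ""), d.get("size", 0),
                          d.get("attached_to", ""))


def study_from_dict(d: dict) -> StudyGraph:
    s = StudyGraph.__new__(StudyGraph)
    s.id = d["id"]
    s.title = d["title"]
    s.creator = d.get("creator")
    s.grants = {g: PermLevel(l) for g, l in d.get("grants", {}).items()}
    from ._ids import IdGen
    s._ids = IdGen(0)
    s._ids._n = sum(len(d[k]) for k in ("nodes", "arcs"))
    s.root_id = d["root_id"]
    s.nodes = {}
    for nd in d["nodes"]:
        n = GraphNode(nd["id"], NodeKind(nd["kind"]), nd["label"],
                      miabs=nd.get("miabs") if nd["kind"] == "biosource" else None,
                      modality=nd.get("modality"),
                      template_ref=nd.get("template_ref"),
                      external_link=nd.get("external_link"))
        n.annotations = [_annotation_from(a) for a in nd.get("annotations", [])]
        n.attachments = [_attachment_from(f) for f in nd.get("attachments", [])]
        s.nodes[n.id] = n
    s.arcs = {}
    for ad in d["arcs"]:
        a = Arc(ad["id"], ad["parent_id"], ad["child_id"])
        a.attachments = [_attachment_from(f) for f in ad.get("attachments", [])]
        app = ad.get("protocol_application")
        if app is not None:
            a.protocol_application = ProtocolApplication(
                protocol_id=app["protocol_id"],
                protocol_name=app.get("protocol_name", ""),
                action=app.get("action", ""),
                parameters=[tuple(p) for p in app.get("parameters", [])],
                performer=app.get("performer"),
                date=app.get("date"))
        s.arcs[a.id] = a
    return s


def repository_from_dict(d: dict) -> Repository:
    if d.get("format") != FORMAT:
        raise ValueError(f"not an {FORMAT} document "
                         f"(format={d.get('format')!r})")
    repo = Repository()
    for ud in d.get("users", []):
        repo.users[ud["id"]] = User(ud["id"], ud["name"])
    for gd in d.get("groups", []):
        repo.groups[gd["id"]] = AccessGroup(gd["id"], set(gd.get("members", [])))
    for pd in d.get("protocols", []):
        p = Protocol(pd["id"], pd["name"], pd["text"], pd["creator"])
        p.shared = pd.get("shared", False)
        for cd in pd.get("comments", []):
            p.comments.append(Comment(cd["author"], cd.get("timestamp", ""),
                                      cd["text"]))
        repo.protocols._protocols[p.id] = p
    for td in d.get("templates", []):
        t = TechnologyTemplate(td["id"], td["name"],
                               [TemplateField(f["name"], f.get("required", False),
                                              f.get("description", ""))
                                for f in td.get("fields", [])])
        repo.templates[t.id] = t
    for idd in d.get("investigations", []):
        inv = Investigation(
            id=idd["id"], title=idd["title"],
            description=idd.get("description", ""),
            creator=idd.get("creator", ""),
            access_group=idd.get("access_group", ""),
            grants={g: PermLevel(l) for g, l in idd.get("grants", {}).items()},
            ontology_sources=[OntologySource(sd["short_name"], sd.get("file", ""),
                                             sd.get("version", ""),
                                             sd.get("description", ""))
                              for sd in idd.get("ontology_sources", [])],
        )
        inv.studies = [study_from_dict(sd) for sd in idd.get("studies", [])]
        repo.investigations[inv.id] = inv
    return repo


def loads(text: str) -> Repository:
    return repository_from_dict(json.loads(text))


def load(path: str | Path) -> Repository:
    return loads(Path(path).read_text(encoding="utf-8"))
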
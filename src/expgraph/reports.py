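"""Human-readable study and protocol reports.

Emitted as deterministic structured text plus a matching minimal HTML
rendering — the content, not the typesetting, is the contract.  The
study report lists every item (node) with its kind, label, annotations
and attached terms, then every action (arc) with its protocol name,
deviation text and parameters, in breadth-first traversal order.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass

from .graph import NodeKind, StudyGraph
from .investigation import Investigation
from .ontology import annotatable_fields
from .protocols import Protocol


@dataclass(frozen=True)
class ReportDocument:
    title: str
    text: str
    html: str


def _traversal_node_order(study: StudyGraph) -> list[str]:
    order, seen = [], set()
    for entity_id, path, _ in annotatable_fields(study):
        if path == "label" and entity_id not in seen:
            seen.add(entity_id)
            order.append(entity_id)
    return order


def _term_suffix(terms) -> str:
    if not terms:
        return ""
    return " {" + ", ".join(f"{t.source}:{t.accession.split(':')[-1]}"
                            for t in terms) + "}"


def export_study_report(inv: Investigation, study: StudyGraph) -> ReportDocument:
    lines = [
        f"STUDY REPORT: {study.title}",
        f"study id: {study.id}",
        f"investigation: {inv.title} ({inv.id})",
        "",
        "ITEMS",
    ]
    order = _traversal_node_order(study)
    for nid in order:
        node = study.nodes[nid]
        if node.kind is NodeKind.ROOT:
            continue
        extra = f" [{node.modality}]" if node.modality else ""
        lines.append(f"- {node.kind.value}: {node.label}{extra} ({node.id})")
        for ann in node.annotations:
            lines.append(f"    {ann.name} = {ann.value}"
                         + _term_suffix(ann.value_terms))
        for key, value in (node.miabs or {}).items():
            lines.append(f"    miabs.{key} = {value}")
        for att in node.attachments:
            lines.append(f"    file: {att.filename}")
    lines += ["", "ACTIONS"]
    pos = {nid: i for i, nid in enumerate(order)}
    arcs = sorted(study.arcs.values(),
                  key=lambda a: (pos.get(a.child_id, len(pos)), a.id))
    for arc in arcs:
        parent, child = study.nodes[arc.parent_id], study.nodes[arc.child_id]
        app = arc.protocol_application
        head = f"- {parent.label} -> {child.label}"
        if app is None:
            lines.append(head + (": (inclusion)" if arc.parent_id == study.root_id
                                 else ": (no protocol)"))
            continue
        lines.append(head + f": protocol {app.protocol_name or app.protocol_id}")
        if app.action:
            lines.append(f"    deviation: {app.action}")
        for name, value in app.parameters:
            lines.append(f"    {name} = {value}")
    text = "\n".join(lines) + "\n"
    return ReportDocument(study.title, text, _as_html(study.title, lines))


def export_protocol_report(protocol: Protocol) -> ReportDocument:
    lines = [
        f"PROTOCOL REPORT: {protocol.name}",
        f"protocol id: {protocol.id}",
        f"creator: {protocol.creator}",
        "",
        "TEXT",
        protocol.text,
        "",
        f"COMMENTS ({len(protocol.comments)})",
    ]
    for c in protocol.comments:
        stamp = f" [{c.timestamp}]" if c.timestamp else ""
        lines.append(f"- {c.author}{stamp}: {c.text}")
    text = "\n".join(lines) + "\n"
    return ReportDocument(protocol.name, text, _as_html(protocol.name, lines))


def _as_html(title: str, lines: list[str]) -> str:
    body = "\n".join(f"<p>{_html.escape(line)}</p>" if line else "<br/>"
                     for line in lines)
    return (
        "<!DOCTYPE html>\n<html><head><meta charset=\"utf-8\"/>"
        f"<title>{_html.escape(title)}</title></head>\n"
        f"<body>\n{body}\n</body></html>\n"
    )
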
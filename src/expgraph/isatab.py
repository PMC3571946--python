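"""ISA-Tab export, import and structural validation.

An investigation is exported as the classic tab-delimited trio: one
``i_<inv>.txt`` investigation file, one ``s_<study>.txt`` sample table
per study, and one ``a_<study>_<modality>.txt`` assay table per distinct
assay modality per study.

The mapping from the provenance graph to the study table follows the
sample-path convention: one data row per distinct path from the root to
an assay-input container.  The biosource label becomes the Source Name
and the terminal container the Sample Name; splits therefore repeat a
Source Name across rows and pooled containers repeat a Sample Name.
Biosource annotations become ``Characteristics[...]`` columns (followed
by ``Term Source REF`` / ``Term Accession Number`` columns wherever a
term is attached), each non-root arc contributes a ``Protocol REF``
column valued with the protocol name, and protocol parameters follow
their step as ``Parameter Value[...]`` columns.

Dialect notes (this writer's own choices, read back by the importer):

* intermediate containers of a chain appear as additional
  ``Protocol REF`` + ``Sample Name`` steps rather than being collapsed;
* repeated annotations with one name are grouped into adjacent columns;
* only the first attached term of a value is written;
* a leaf container with no assay still gets a row, so no material is
  silently dropped;
* multiple raw data files are ";"-joined in one cell.

Output is byte-reproducible: UTF-8, LF line endings, rows in
lexicographic path order, columns in annotation insertion order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import InvalidGraph, IsaTabError
from .graph import (
    Annotation,
    FileAttachment,
    GraphNode,
    NodeKind,
    ProtocolApplication,
    StudyGraph,
    TermRef,
)
from .investigation import Investigation
from .ontology import OntologySource


@dataclass
class IsaViolation:
    """One structural problem found in a bundle (machine-readable code)."""

    code: str
    message: str
    file: str = ""
    line: int | None = None


@dataclass
class IsaTabBundle:
    directory: Path
    investigation_file: Path
    study_files: dict[str, Path] = field(default_factory=dict)
    assay_files: dict[tuple[str, str], Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# path enumeration
# ---------------------------------------------------------------------------

def terminal_container_paths(study: StudyGraph) -> list[list[str]]:
    """All root -> assay-input container paths, in lexicographic label order.

    A container is a row terminal when it feeds at least one assay or is
    a leaf.  A container can be both a terminal and an intermediate of a
    deeper chain; it then contributes a row *and* the walk continues.
    """
    paths: list[list[str]] = []

    def walk(node_id: str, path: list[str]) -> None:
        node = study.nodes[node_id]
        kids = study.arcs_out(node_id)
        if node.kind is NodeKind.CONTAINER:
            child_kinds = {study.nodes[a.child_id].kind for a in kids}
            if not kids or NodeKind.ASSAY in child_kinds:
                paths.append(path)
        for arc in kids:
            if study.nodes[arc.child_id].kind is not NodeKind.ASSAY:
                walk(arc.child_id, path + [arc.child_id])

    walk(study.root_id, [study.root_id])
    paths.sort(key=lambda p: tuple(study.nodes[n].label for n in p[1:]))
    return paths


# ---------------------------------------------------------------------------
# characteristics / parameter column blocks
# ---------------------------------------------------------------------------

class _CharBlock:
    """Characteristics columns for a set of nodes occupying one position."""

    def __init__(self):
        self.slots: list[tuple[str, int]] = []   # (name, occurrence)
        self.has_term: dict[tuple[str, int], bool] = {}

    def observe(self, node: GraphNode) -> None:
        counts: dict[str, int] = {}
        for ann in node.annotations:
            occ = counts.get(ann.name, 0)
            counts[ann.name] = occ + 1
            slot = (ann.name, occ)
            if slot not in self.has_term:
                self.slots.append(slot)
                self.has_term[slot] = False
            if ann.value_terms:
                self.has_term[slot] = True
        # keep slots grouped by name, occurrences adjacent
        order: list[str] = []
        for name, _ in self.slots:
            if name not in order:
                order.append(name)
        self.slots.sort(key=lambda s: (order.index(s[0]), s[1]))

    def header(self) -> list[str]:
        cells = []
        for slot in self.slots:
            cells.append(f"Characteristics[{slot[0]}]")
            if self.has_term[slot]:
                cells += ["Term Source REF", "Term Accession Number"]
        return cells

    def cells(self, node: GraphNode | None) -> list[str]:
        by_slot: dict[tuple[str, int], Annotation] = {}
        if node is not None:
            counts: dict[str, int] = {}
            for ann in node.annotations:
                occ = counts.get(ann.name, 0)
                counts[ann.name] = occ + 1
                by_slot[(ann.name, occ)] = ann
        cells = []
        for slot in self.slots:
            ann = by_slot.get(slot)
            cells.append(ann.value if ann is not None else "")
            if self.has_term[slot]:
                term = ann.value_terms[0] if ann is not None and ann.value_terms else None
                cells += [term.source, term.accession] if term else ["", ""]
        return cells


class _ParamBlock:
    """Parameter Value columns following one Protocol REF step."""

    def __init__(self):
        self.slots: list[tuple[str, int]] = []

    def observe(self, app: ProtocolApplication | None) -> None:
        if app is None:
            return
        counts: dict[str, int] = {}
        for name, _value in app.parameters:
            occ = counts.get(name, 0)
            counts[name] = occ + 1
            if (name, occ) not in self.slots:
                self.slots.append((name, occ))

    def header(self) -> list[str]:
        return [f"Parameter Value[{name}]" for name, _ in self.slots]

    def cells(self, app: ProtocolApplication | None) -> list[str]:
        by_slot: dict[tuple[str, int], str] = {}
        if app is not None:
            counts: dict[str, int] = {}
            for name, value in app.parameters:
                occ = counts.get(name, 0)
                counts[name] = occ + 1
                by_slot[(name, occ)] = value
        return [by_slot.get(slot, "") for slot in self.slots]


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _write_table(path: Path, rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for row in rows:
            fh.write("\t".join(row) + "\n")


def _study_table(study: StudyGraph) -> list[list[str]]:
    paths = terminal_container_paths(study)
    bio_block = _CharBlock()
    seen_bio: set[str] = set()
    for p in paths:
        if p[1] not in seen_bio:
            seen_bio.add(p[1])
            bio_block.observe(study.nodes[p[1]])
    n_steps = max((len(p) - 2 for p in paths), default=0)
    step_params = [_ParamBlock() for _ in range(n_steps)]
    step_chars = [_CharBlock() for _ in range(n_steps)]
    seen_step: list[set[str]] = [set() for _ in range(n_steps)]
    for p in paths:
        for s in range(len(p) - 2):
            arc = study.arc_between(p[s + 1], p[s + 2])
            step_params[s].observe(arc.protocol_application)
            if p[s + 2] not in seen_step[s]:
                seen_step[s].add(p[s + 2])
                step_chars[s].observe(study.nodes[p[s + 2]])

    header = ["Source Name"] + bio_block.header()
    for s in range(n_steps):
        header += ["Protocol REF"] + step_params[s].header()
        header += ["Sample Name"] + step_chars[s].header()

    rows = [header]
    for p in paths:
        row = [study.nodes[p[1]].label] + bio_block.cells(study.nodes[p[1]])
        for s in range(n_steps):
            if s < len(p) - 2:
                arc = study.arc_between(p[s + 1], p[s + 2])
                app = arc.protocol_application
                row += [app.protocol_name if app else ""]
                row += step_params[s].cells(app)
                row += [study.nodes[p[s + 2]].label]
                row += step_chars[s].cells(study.nodes[p[s + 2]])
            else:
                row += [""] + step_params[s].cells(None)
                row += [""] + step_chars[s].cells(None)
        rows.append(row)
    return rows


def _assay_rows(study: StudyGraph, modality: str) -> list[list[str]]:
    rows = []
    for arc in study.arcs.values():
        child = study.nodes[arc.child_id]
        if child.kind is not NodeKind.ASSAY or (child.modality or "") != modality:
            continue
        app = arc.protocol_application
        files = ";".join(f.filename for f in child.attachments)
        rows.append([study.nodes[arc.parent_id].label,
                     app.protocol_name if app else "", child.label, files])
    rows.sort(key=lambda r: (r[0], r[2]))
    return [["Sample Name", "Protocol REF", "Assay Name", "Raw Data File"]] + rows


def _study_modalities(study: StudyGraph) -> list[str]:
    return sorted({n.modality or "" for n in study.nodes_of_kind(NodeKind.ASSAY)})


def _study_protocol_names(study: StudyGraph) -> list[str]:
    names = {a.protocol_application.protocol_name
             for a in study.arcs.values() if a.protocol_application}
    return sorted(n for n in names if n)


def _investigation_table(inv: Investigation) -> list[list[str]]:
    rows: list[list[str]] = []
    srcs = list(inv.ontology_sources)
    rows.append(["ONTOLOGY SOURCE REFERENCE"])
    rows.append(["Term Source Name"] + [s.short_name for s in srcs])
    rows.append(["Term Source File"] + [s.file for s in srcs])
    rows.append(["Term Source Version"] + [s.version for s in srcs])
    rows.append(["Term Source Description"] + [s.description for s in srcs])
    rows.append(["INVESTIGATION"])
    rows.append(["Investigation Identifier", inv.id])
    rows.append(["Investigation Title", inv.title])
    rows.append(["Investigation Description", inv.description])
    for study in inv.studies:
        modalities = _study_modalities(study)
        rows.append(["STUDY"])
        rows.append(["Study Identifier", study.id])
        rows.append(["Study Title", study.title])
        rows.append(["Study File Name", f"s_{study.id}.txt"])
        rows.append(["STUDY PROTOCOLS"])
        rows.append(["Study Protocol Name"] + _study_protocol_names(study))
        rows.append(["STUDY ASSAYS"])
        rows.append(["Study Assay Measurement Type"] + modalities)
        rows.append(["Study Assay File Name"]
                    + [f"a_{study.id}_{m}.txt" for m in modalities])
    return rows


def export_isatab(inv: Investigation, out_dir: str | Path) -> IsaTabBundle:
    """Write the ISA-Tab bundle for one investigation.

    Every study must pass :meth:`StudyGraph.validate`; otherwise
    :class:`InvalidGraph` is raised and nothing is written.
    """
    for study in inv.studies:
        violations = study.validate()
        if violations:
            raise InvalidGraph(violations)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = IsaTabBundle(out, out / f"i_{inv.id}.txt")
    _write_table(bundle.investigation_file, _investigation_table(inv))
    for study in inv.studies:
        spath = out / f"s_{study.id}.txt"
        _write_table(spath, _study_table(study))
        bundle.study_files[study.id] = spath
        for m in _study_modalities(study):
            apath = out / f"a_{study.id}_{m}.txt"
            _write_table(apath, _assay_rows(study, m))
            bundle.assay_files[(study.id, m)] = apath
    return bundle


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_SECTIONS = ("ONTOLOGY SOURCE REFERENCE", "INVESTIGATION", "STUDY",
             "STUDY PROTOCOLS", "STUDY ASSAYS")


def _read_table(path: Path) -> list[list[str]]:
    with open(path, encoding="utf-8") as fh:
        return [line.rstrip("\n").split("\t") for line in fh if line.rstrip("\n")]


def _parse_investigation_file(path: Path):
    """Sections in file order: list of (name, {label: [values...]})."""
    sections: list[tuple[str, dict[str, list[str]]]] = []
    for row in _read_table(path):
        if row[0] in _SECTIONS and all(not c for c in row[1:]):
            sections.append((row[0], {}))
        elif sections:
            sections[-1][1][row[0]] = row[1:]
    return sections


@dataclass
class _StudyBlock:
    identifier: str = ""
    title: str = ""
    file_name: str = ""
    protocols: list[str] = field(default_factory=list)
    assay_types: list[str] = field(default_factory=list)
    assay_files: list[str] = field(default_factory=list)


def _study_blocks(sections) -> list[_StudyBlock]:
    blocks: list[_StudyBlock] = []
    for name, rows in sections:
        if name == "STUDY":
            b = _StudyBlock(
                identifier=(rows.get("Study Identifier", [""]) + [""])[0],
                title=(rows.get("Study Title", [""]) + [""])[0],
                file_name=(rows.get("Study File Name", [""]) + [""])[0],
            )
            blocks.append(b)
        elif name == "STUDY PROTOCOLS" and blocks:
            blocks[-1].protocols = [v for v in rows.get("Study Protocol Name", []) if v]
        elif name == "STUDY ASSAYS" and blocks:
            blocks[-1].assay_types = [v for v in rows.get("Study Assay Measurement Type", []) if v]
            blocks[-1].assay_files = [v for v in rows.get("Study Assay File Name", []) if v]
    return blocks


def _section_order_ok(sections) -> bool:
    names = [n for n, _ in sections]
    if names[:2] != ["ONTOLOGY SOURCE REFERENCE", "INVESTIGATION"]:
        return False
    rest = names[2:]
    if len(rest) % 3 != 0:
        return False
    for i in range(0, len(rest), 3):
        if rest[i:i + 3] != ["STUDY", "STUDY PROTOCOLS", "STUDY ASSAYS"]:
            return False
    return True


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _find_investigation_file(directory: Path) -> Path | None:
    hits = sorted(directory.glob("i_*.txt"))
    return hits[0] if hits else None


def _table_term_source_cells(table: list[list[str]]) -> list[str]:
    header = table[0]
    idx = [i for i, c in enumerate(header) if c == "Term Source REF"]
    return [row[i] for row in table[1:] for i in idx if i < len(row) and row[i]]


def _table_column_cells(table: list[list[str]], column: str) -> list[str]:
    header = table[0]
    idx = [i for i, c in enumerate(header) if c == column]
    return [row[i] for row in table[1:] for i in idx if i < len(row) and row[i]]


def validate_isatab(directory: str | Path) -> list[IsaViolation]:
    """Structural check of a bundle; [] iff it is internally consistent.

    Checks: section order of the investigation file; existence of every
    referenced study and assay file; every Protocol REF declared in its
    study's STUDY PROTOCOLS; every Term Source REF declared in the
    ONTOLOGY SOURCE REFERENCE; every assay-file Sample Name present in
    its study file.
    """
    directory = Path(directory)
    out: list[IsaViolation] = []
    inv_path = _find_investigation_file(directory)
    if inv_path is None:
        return [IsaViolation("NO_INVESTIGATION_FILE",
                             f"no i_*.txt file in {directory}")]
    sections = _parse_investigation_file(inv_path)
    if not _section_order_ok(sections):
        out.append(IsaViolation(
            "SECTION_ORDER",
            "investigation sections out of order or incomplete",
            inv_path.name))
    declared_sources = set()
    for name, rows in sections:
        if name == "ONTOLOGY SOURCE REFERENCE":
            declared_sources = {v for v in rows.get("Term Source Name", []) if v}

    for block in _study_blocks(sections):
        declared_protocols = set(block.protocols)
        spath = directory / block.file_name if block.file_name else None
        samples: set[str] = set()
        if spath is None or not spath.exists():
            out.append(IsaViolation(
                "MISSING_FILE",
                f"declared study file {block.file_name!r} not found",
                inv_path.name))
        else:
            table = _read_table(spath)
            samples = set(_table_column_cells(table, "Sample Name"))
            for v in set(_table_column_cells(table, "Protocol REF")):
                if v not in declared_protocols:
                    out.append(IsaViolation(
                        "UNDECLARED_PROTOCOL",
                        f"Protocol REF {v!r} not declared in STUDY PROTOCOLS",
                        spath.name))
            for v in set(_table_term_source_cells(table)):
                if v not in declared_sources:
                    out.append(IsaViolation(
                        "UNDECLARED_TERM_SOURCE",
                        f"Term Source REF {v!r} not declared",
                        spath.name))
        for aname in block.assay_files:
            apath = directory / aname
            if not apath.exists():
                out.append(IsaViolation(
                    "MISSING_FILE",
                    f"declared assay file {aname!r} not found",
                    inv_path.name))
                continue
            table = _read_table(apath)
            for v in set(_table_column_cells(table, "Protocol REF")):
                if v not in declared_protocols:
                    out.append(IsaViolation(
                        "UNDECLARED_PROTOCOL",
                        f"Protocol REF {v!r} not declared in STUDY PROTOCOLS",
                        apath.name))
            for v in set(_table_column_cells(table, "Sample Name")):
                if v not in samples:
                    out.append(IsaViolation(
                        "UNKNOWN_SAMPLE",
                        f"assay Sample Name {v!r} missing from study file",
                        apath.name))
    return out


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

@dataclass
class _Slot:
    name: str
    value_idx: int
    term_src_idx: int | None = None
    term_acc_idx: int | None = None


@dataclass
class _Step:
    protocol_idx: int
    params: list[_Slot] = field(default_factory=list)
    sample_idx: int = -1
    chars: list[_Slot] = field(default_factory=list)


def _parse_study_header(header: list[str]):
    """Positional parse of the study-table header into schema blocks."""
    def char_name(cell: str) -> str | None:
        if cell.startswith("Characteristics[") and cell.endswith("]"):
            return cell[len("Characteristics["):-1]
        return None

    def param_name(cell: str) -> str | None:
        if cell.startswith("Parameter Value[") and cell.endswith("]"):
            return cell[len("Parameter Value["):-1]
        return None

    def take_chars(i: int, into: list[_Slot]) -> int:
        while i < len(header) and char_name(header[i]) is not None:
            slot = _Slot(char_name(header[i]), i)
            i += 1
            if i + 1 < len(header) and header[i] == "Term Source REF":
                slot.term_src_idx, slot.term_acc_idx = i, i + 1
                i += 2
            into.append(slot)
        return i

    bio_chars: list[_Slot] = []
    steps: list[_Step] = []
    i = 1  # header[0] == "Source Name"
    i = take_chars(i, bio_chars)
    while i < len(header):
        step = _Step(protocol_idx=i)  # "Protocol REF"
        i += 1
        while i < len(header) and param_name(header[i]) is not None:
            step.params.append(_Slot(param_name(header[i]), i))
            i += 1
        step.sample_idx = i  # "Sample Name"
        i += 1
        i = take_chars(i, step.chars)
        steps.append(step)
    return bio_chars, steps


def _cell(row: list[str], idx: int | None) -> str:
    if idx is None or idx >= len(row):
        return ""
    return row[idx]


def _annotations_from(row: list[str], slots: list[_Slot]) -> list[Annotation]:
    anns = []
    for slot in slots:
        value = _cell(row, slot.value_idx)
        if not value:
            continue
        ann = Annotation(slot.name, value)
        src = _cell(row, slot.term_src_idx)
        acc = _cell(row, slot.term_acc_idx)
        if src and acc:
            ann.value_terms.append(TermRef(src, acc))
        anns.append(ann)
    return anns


def import_isatab(directory: str | Path) -> Investigation:
    """Rebuild an investigation from a bundle written by this module.

    The reconstruction is a prefix tree over sample paths: it preserves
    the multiset of root-to-leaf paths with their labels, annotations,
    attached terms and protocol names, which is exactly what the tabular
    form captures (a pooled container reappears as one node per source
    path).
    """
    directory = Path(directory)
    violations = validate_isatab(directory)
    if violations:
        raise IsaTabError(violations)
    inv_path = _find_investigation_file(directory)
    sections = _parse_investigation_file(inv_path)
    sec = dict(sections)
    osr = sec.get("ONTOLOGY SOURCE REFERENCE", {})
    names = osr.get("Term Source Name", [])
    files = osr.get("Term Source File", [])
    versions = osr.get("Term Source Version", [])
    descs = osr.get("Term Source Description", [])

    def pick(lst, i):
        return lst[i] if i < len(lst) else ""

    sources = [OntologySource(n, pick(files, i), pick(versions, i), pick(descs, i))
               for i, n in enumerate(names) if n]
    invrows = sec.get("INVESTIGATION", {})
    inv = Investigation(
        id=(invrows.get("Investigation Identifier", [""]) + [""])[0] or "imported",
        title=(invrows.get("Investigation Title", [""]) + [""])[0],
        description=(invrows.get("Investigation Description", [""]) + [""])[0],
        ontology_sources=sources,
        creator="importer",
    )

    for block in _study_blocks(sections):
        study = StudyGraph(block.identifier or "imported_study", block.title,
                           seed=0, creator="importer")
        table = _read_table(directory / block.file_name)
        bio_chars, steps = _parse_study_header(table[0])
        by_prefix: dict[tuple, GraphNode] = {}
        for row in table[1:]:
            source_label = row[0]
            key = ("bio", source_label)
            node = by_prefix.get(key)
            if node is None:
                node = study.add_child(study.root_id, NodeKind.BIOSOURCE,
                                       source_label)
                node.annotations = _annotations_from(row, bio_chars)
                by_prefix[key] = node
            for step in steps:
                sample = _cell(row, step.sample_idx)
                if not sample:
                    break
                protocol = _cell(row, step.protocol_idx)
                key = key + (protocol, sample)
                child = by_prefix.get(key)
                if child is None:
                    parent = node
                    child = study.add_child(parent.id, NodeKind.CONTAINER, sample)
                    child.annotations = _annotations_from(row, step.chars)
                    params = [(s.name, _cell(row, s.value_idx))
                              for s in step.params if _cell(row, s.value_idx)]
                    if protocol or params:
                        arc = study.arc_between(parent.id, child.id)
                        arc.protocol_application = ProtocolApplication(
                            protocol_id=protocol or "unspecified",
                            protocol_name=protocol,
                            parameters=params)
                    by_prefix[key] = child
                node = child

        for mtype, aname in zip(block.assay_types, block.assay_files):
            atable = _read_table(directory / aname)
            header = atable[0]
            col = {c: i for i, c in enumerate(header)}
            for row in atable[1:]:
                sample = _cell(row, col.get("Sample Name"))
                protocol = _cell(row, col.get("Protocol REF"))
                label = _cell(row, col.get("Assay Name"))
                raw = _cell(row, col.get("Raw Data File"))
                hosts = [n for n in study.nodes.values()
                         if n.kind is NodeKind.CONTAINER and n.label == sample]
                for host in hosts:
                    assay = study.add_child(host.id, NodeKind.ASSAY, label,
                                            modality=mtype)
                    if raw:
                        assay.attachments = [
                            FileAttachment(filename=f, attached_to=assay.id)
                            for f in raw.split(";")]
                    if protocol:
                        arc = study.arc_between(host.id, assay.id)
                        arc.protocol_application = ProtocolApplication(
                            protocol_id=protocol, protocol_name=protocol)
        inv.studies.append(study)
    return inv
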
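"""OBO ontology indexing, ranked term lookup and the terminize traversal.

Investigations declare a fixed set of ontology sources up front, so that
annotation stays consistent within and across studies.  This module is
deliberately a lookup service, not a reasoner: it parses OBO 1.2 flat
files (via :mod:`obonet`), indexes names and synonyms, and ranks matches
for free-text queries.

Matching is case-insensitive, in four tiers::

    exact_name     query == term name              score 1.00
    exact_synonym  query == one synonym            score 0.90
    token          every query token appears as a  score 0.70
                   whole token of the name or of
                   a single synonym
    substring      query is a contiguous substring score 0.50
                   of the name or a synonym

A term is reported once with its best tier; results are ordered by
(score desc, accession asc) and are fully deterministic.  Obsolete terms
are kept in the index but excluded from search unless asked for.

``terminize`` walks a study graph breadth-first and runs every node
label, annotation name, annotation value and protocol-application action
text through the search, collecting ranked candidates for the user to
attach.
"""

from __future__ import annotations

import re
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import obonet

from .errors import NoSuchSource, ParseError, SourceNotRegistered
from .graph import Annotation, StudyGraph, TermRef
from .investigation import Investigation

_SYN_RE = re.compile(r'^"(?P<text>.*)"(?:\s+(?P<scope>[A-Z_]+))?')

MATCH_SCORES = {
    "exact_name": 1.0,
    "exact_synonym": 0.9,
    "token": 0.7,
    "substring": 0.5,
}


@dataclass(frozen=True)
class OntologySource:
    """One declared ontology: a short name plus the OBO file behind it."""

    short_name: str
    file: str = ""
    version: str = ""
    description: str = ""


@dataclass
class OntologyTerm:
    accession: str
    name: str
    source: str
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    definition: str = ""
    obsolete: bool = False
    alt_ids: list[str] = field(default_factory=list)
    namespace: str = ""


@dataclass(frozen=True)
class TermMatch:
    query: str
    term: OntologyTerm
    match_type: str
    score: float


class _Entry:
    """Precomputed lowercase fields for one term (the search index)."""

    __slots__ = ("term", "name", "synonyms", "token_sets")

    def __init__(self, term: OntologyTerm):
        self.term = term
        self.name = term.name.lower()
        self.synonyms = [s.lower() for s, _scope in term.synonyms]
        self.token_sets = [frozenset(f.split())
                           for f in [self.name] + self.synonyms]


def classify_match(query_lower: str, name: str,
                   synonyms: list[str]) -> str | None:
    """Best match tier of a lowercased query against lowercased fields.

    This is the single rule both the index and any from-scratch scan
    must implement.
    """
    if query_lower == name:
        return "exact_name"
    if query_lower in synonyms:
        return "exact_synonym"
    tokens = set(query_lower.split())
    for f in [name] + synonyms:
        if tokens <= set(f.split()):
            return "token"
    for f in [name] + synonyms:
        if query_lower in f:
            return "substring"
    return None


def _prescan_obo(path: Path) -> None:
    """Reject [Term] stanzas without an id or a name, naming the line."""
    stanza_line = None
    have_id = have_name = True
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("["):
                if in_term:
                    if not have_id:
                        raise ParseError("[Term] stanza missing id:", stanza_line)
                    if not have_name:
                        raise ParseError("[Term] stanza missing name:", stanza_line)
                in_term = line == "[Term]"
                stanza_line = lineno
                have_id = have_name = False
            elif in_term:
                if line.startswith("id:"):
                    have_id = True
                elif line.startswith("name:"):
                    have_name = True
    if in_term:
        if not have_id:
            raise ParseError("[Term] stanza missing id:", stanza_line)
        if not have_name:
            raise ParseError("[Term] stanza missing name:", stanza_line)


def _parse_synonym(raw: str) -> tuple[str, str]:
    m = _SYN_RE.match(raw)
    if m:
        return m.group("text"), m.group("scope") or "RELATED"
    return raw, "RELATED"


def _parse_def(raw: str) -> str:
    m = re.match(r'^"(?P<text>.*)"', raw)
    return m.group("text") if m else raw


class OntologyIndex:
    """Terms from one or more OBO sources, ready for ranked lookup."""

    def __init__(self):
        self._sources: dict[str, dict[str, OntologyTerm]] = {}
        self._entries: dict[str, list[_Entry]] = {}

    # -- population ---------------------------------------------------------

    def add_obo(self, file: str | Path, short_name: str | None = None) -> str:
        """Parse one OBO 1.2 file into the index; returns the source name.

        Only the lookup-relevant tags (id, name, synonym, def,
        is_obsolete, alt_id, namespace) are used; typedefs and
        relationships are ignored.  Obsolete terms are retained but
        flagged.
        """
        path = Path(file)
        if not path.exists():
            raise IOError(f"no such OBO file: {path}")
        _prescan_obo(path)
        try:
            graph = obonet.read_obo(str(path), ignore_obsolete=False)
        except Exception as exc:  # malformed beyond the prescan
            raise ParseError(f"cannot parse OBO file {path}: {exc}") from exc
        if short_name is None:
            short_name = str(graph.graph.get("ontology") or path.stem).upper()
        terms: dict[str, OntologyTerm] = {}
        for acc, data in graph.nodes(data=True):
            if "name" not in data:
                continue
            terms[acc] = OntologyTerm(
                accession=acc,
                name=data["name"],
                source=short_name,
                synonyms=[_parse_synonym(s) for s in data.get("synonym", [])],
                definition=_parse_def(data.get("def", "")),
                obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                alt_ids=list(data.get("alt_id", [])),
                namespace=data.get("namespace", ""),
            )
        self._sources[short_name] = terms
        self._entries[short_name] = [
            _Entry(t) for t in sorted(terms.values(), key=lambda t: t.accession)]
        return short_name

    # -- introspection ------------------------------------------------------

    @property
    def sources(self) -> list[str]:
        return sorted(self._sources)

    @property
    def term_count(self) -> int:
        return sum(len(v) for v in self._sources.values())

    def terms(self, source: str | None = None) -> list[OntologyTerm]:
        if source is not None:
            self._check_source(source)
            return list(self._sources[source].values())
        return [t for s in sorted(self._sources) for t in self._sources[s].values()]

    def get(self, source: str, accession: str) -> OntologyTerm:
        self._check_source(source)
        try:
            return self._sources[source][accession]
        except KeyError:
            raise NoSuchSource(f"no term {accession!r} in {source!r}") from None

    def _check_source(self, name: str) -> None:
        if name not in self._sources:
            raise NoSuchSource(f"unknown ontology source {name!r}")

    # -- search -------------------------------------------------------------

    def search(self, query: str, sources: list[str] | None = None,
               limit: int = 20, include_obsolete: bool = False,
               ) -> list[TermMatch]:
        """Ranked matches for a free-text query against selected sources."""
        if limit < 1:
            raise ValueError("limit must be >= 1")
        if sources is None:
            sources = self.sources
        for s in sources:
            self._check_source(s)
        q = str(query).strip().lower()
        if not q:
            return []
        hits: list[TermMatch] = []
        tokens = frozenset(q.split())
        for s in sources:
            for e in self._entries[s]:
                if e.term.obsolete and not include_obsolete:
                    continue
                if q == e.name:
                    mt = "exact_name"
                elif q in e.synonyms:
                    mt = "exact_synonym"
                elif any(tokens <= ts for ts in e.token_sets):
                    mt = "token"
                elif any(q in f for f in [e.name] + e.synonyms):
                    mt = "substring"
                else:
                    continue
                hits.append(TermMatch(query, e.term, mt, MATCH_SCORES[mt]))
        hits.sort(key=lambda m: (-m.score, m.term.accession))
        return hits[:limit]


def load_obo(file: str | Path, short_name: str | None = None) -> OntologyIndex:
    """Build a fresh index from one OBO file."""
    index = OntologyIndex()
    index.add_obo(file, short_name)
    return index


def search(index: OntologyIndex, query: str, sources=None, limit: int = 20,
           include_obsolete: bool = False) -> list[TermMatch]:
    """Function-style alias for :meth:`OntologyIndex.search`."""
    return index.search(query, sources, limit, include_obsolete)


def search_json(index: OntologyIndex, query: str, sources=None,
                limit: int = 20) -> dict:
    """The wire form of a lookup: the JSON document a service would return."""
    return {
        "query": query,
        "matches": [
            {
                "accession": m.term.accession,
                "name": m.term.name,
                "source": m.term.source,
                "match_type": m.match_type,
                "score": m.score,
            }
            for m in index.search(query, sources, limit)
        ],
    }


# -- terminize ---------------------------------------------------------------

@dataclass(frozen=True)
class ReportEntry:
    entity_id: str
    field_path: str
    query: str
    matches: tuple[TermMatch, ...]


@dataclass
class TerminizeReport:
    study_id: str
    entries: list[ReportEntry] = field(default_factory=list)

    def non_empty(self) -> list[ReportEntry]:
        return [e for e in self.entries if e.matches]

    def to_json_dict(self) -> dict:
        return {
            "study": self.study_id,
            "entries": [
                {
                    "entity": e.entity_id,
                    "field": e.field_path,
                    "query": e.query,
                    "matches": [
                        {
                            "accession": m.term.accession,
                            "name": m.term.name,
                            "source": m.term.source,
                            "match_type": m.match_type,
                            "score": m.score,
                        }
                        for m in e.matches
                    ],
                }
                for e in self.entries
            ],
        }


def annotatable_fields(study: StudyGraph) -> list[tuple[str, str, str]]:
    """(entity id, field path, text) for every annotatable text field.

    Breadth-first from the root; each node's label and annotations come
    first, then the action text of the arcs arriving at that node.
    """
    out: list[tuple[str, str, str]] = []
    seen = {study.root_id}
    queue = deque([study.root_id])
    while queue:
        nid = queue.popleft()
        node = study.nodes[nid]
        out.append((nid, "label", node.label))
        for i, ann in enumerate(node.annotations):
            out.append((nid, f"annotations[{i}].name", ann.name))
            out.append((nid, f"annotations[{i}].value", ann.value))
        if nid != study.root_id:
            for arc in sorted(study.arcs_in(nid), key=lambda a: a.id):
                app = arc.protocol_application
                if app is not None:
                    out.append((arc.id, "protocol_application.action", app.action))
        for arc in study.arcs_out(nid):
            if arc.child_id not in seen:
                seen.add(arc.child_id)
                queue.append(arc.child_id)
    return out


def terminize(study: StudyGraph, index: OntologyIndex,
              sources: list[str] | None = None, limit: int = 20,
              ) -> TerminizeReport:
    """Collect ranked term candidates for every text field of a study.

    Fields with no candidates still appear, with empty match lists, so
    the report enumerates exactly the annotatable surface of the graph.
    """
    report = TerminizeReport(study.id)
    for entity_id, path, text in annotatable_fields(study):
        matches = tuple(index.search(text, sources, limit)) if text.strip() else ()
        report.entries.append(ReportEntry(entity_id, path, text, matches))
    return report


# -- attaching terms ---------------------------------------------------------

_FIELD_RE = re.compile(r"^annotations\[(\d+)\]\.(name|value)$")


def attach_term(investigation: Investigation, entity, field_path: str,
                term: OntologyTerm | TermRef):
    """Attach a term reference to an annotation name or value.

    The term must come from one of the investigation's declared
    ontology sources.  Idempotent for the same (field, source,
    accession).
    """
    source = term.source
    declared = {s.short_name for s in investigation.ontology_sources}
    if source not in declared:
        raise SourceNotRegistered(
            f"source {source!r} is not declared on investigation {investigation.id}")
    ref = TermRef(source=term.source,
                  accession=getattr(term, "accession", ""),
                  name=getattr(term, "name", ""))
    if isinstance(entity, Annotation):
        ann, side = entity, field_path
    else:
        m = _FIELD_RE.match(field_path)
        if not m:
            raise ValueError(
                f"cannot attach a term to field {field_path!r}; "
                "use annotations[i].name or annotations[i].value")
        ann = entity.annotations[int(m.group(1))]
        side = m.group(2)
    if side not in ("name", "value"):
        raise ValueError("terms attach to an annotation name or value")
    bucket = ann.name_terms if side == "name" else ann.value_terms
    if not any(t.source == ref.source and t.accession == ref.accession
               for t in bucket):
        bucket.append(ref)
    return entity
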
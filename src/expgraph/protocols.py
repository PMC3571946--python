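"""Protocol registry and minimum-information templates.

Once registered, the text of a protocol may never be altered: if the
bench work deviated from the written method, the deviation is recorded
in the ``action`` field of the protocol application on the arc, not by
editing the protocol.  "Editing" a protocol therefore means registering
a new one.  Users may append arbitrary comments, which are searchable
together with the body text.  Protocols are private to their creator
until shared (with everyone, or with one access group).

Technology templates capture the minimum information about the machine
or platform that produced the data (e.g. one completed template per
array design); the MIABS fields on a biosource capture the
technology-independent minimum about the sample.  Compiling the two
gives a single minimum-information record for a data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from ._ids import IdGen
from .access import AccessGroup
from .errors import (
    EmptyProtocol,
    KindError,
    MissingField,
    NoSuchProtocol,
    ProtocolImmutable,
)
from .graph import FileAttachment, GraphNode, NodeKind


@dataclass(frozen=True)
class Comment:
    author: str
    timestamp: str
    text: str


class Protocol:
    """An immutable method text with append-only comments."""

    def __init__(self, id: str, name: str, text: str, creator: str):
        if not str(text).strip():
            raise EmptyProtocol("a protocol needs a non-empty body")
        self.id = id
        self.name = name
        self.__text = str(text)
        self.creator = creator
        #: False = private, True = everyone, or an access-group id
        self.shared: bool | str = False
        self.comments: list[Comment] = []
        self.grants: dict[str, object] = {}

    @property
    def text(self) -> str:
        return self.__text

    @text.setter
    def text(self, _value):
        raise ProtocolImmutable("the text of a protocol may not be altered")

    def set_text(self, _value):
        raise ProtocolImmutable("the text of a protocol may not be altered")

    def add_comment(self, author: str, text: str, timestamp: str = "") -> Comment:
        c = Comment(author, timestamp, text)
        self.comments.append(c)
        return c

    def readable_by(self, user, groups: dict[str, AccessGroup]) -> bool:
        uid = user if isinstance(user, str) else user.id
        if uid == self.creator or self.shared is True:
            return True
        if isinstance(self.shared, str):
            g = groups.get(self.shared)
            return g is not None and uid in g.members
        return False

    def __repr__(self):
        return f"Protocol({self.id!r}, {self.name!r})"


class ProtocolRegistry:
    """All protocols known to one repository instance."""

    def __init__(self, idgen: IdGen | None = None):
        self._ids = idgen if idgen is not None else IdGen()
        self._protocols: dict[str, Protocol] = {}

    def __contains__(self, protocol_id: str) -> bool:
        return protocol_id in self._protocols

    def __iter__(self):
        return iter(self._protocols.values())

    def __len__(self):
        return len(self._protocols)

    def register(self, name: str, text: str, creator) -> Protocol:
        uid = creator if isinstance(creator, str) else creator.id
        p = Protocol(self._ids.new("p"), name, text, uid)
        self._protocols[p.id] = p
        return p

    def get(self, protocol_id: str) -> Protocol:
        try:
            return self._protocols[protocol_id]
        except KeyError:
            raise NoSuchProtocol(f"no protocol {protocol_id!r}") from None

    def by_name(self, name: str) -> Protocol:
        for p in self._protocols.values():
            if p.name == name:
                return p
        raise NoSuchProtocol(f"no protocol named {name!r}")

    def search(self, query: str, caller, groups: dict[str, AccessGroup] | None = None,
               ) -> list[Protocol]:
        """Protocols whose body or any comment contains ``query``.

        Case-insensitive substring match, restricted to protocols the
        caller may read; ordered by (name, id).
        """
        groups = groups or {}
        q = str(query).lower()
        hits = []
        for p in self._protocols.values():
            if not p.readable_by(caller, groups):
                continue
            haystacks = [p.name, p.text] + [c.text for c in p.comments]
            if any(q in h.lower() for h in haystacks):
                hits.append(p)
        return sorted(hits, key=lambda p: (p.name, p.id))


# -- templates ---------------------------------------------------------------

@dataclass(frozen=True)
class TemplateField:
    name: str
    required: bool = False
    description: str = ""


@dataclass
class TechnologyTemplate:
    """The shape of the minimum information about one technology."""

    id: str
    name: str
    fields: list[TemplateField] = field(default_factory=list)

    def __post_init__(self):
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise ValueError("template field names must be unique")

    @property
    def required_fields(self) -> list[str]:
        return [f.name for f in self.fields if f.required]


@dataclass
class CompletedTemplate:
    """A filled template, e.g. for one particular array design."""

    template: TechnologyTemplate
    values: dict[str, str]
    associated_files: list[FileAttachment] = field(default_factory=list)

    @property
    def template_ref(self) -> str:
        return self.template.id


def fill_template(template: TechnologyTemplate,
                  values: dict[str, str]) -> CompletedTemplate:
    """Complete a template; every required field needs a non-empty value."""
    missing = [n for n in template.required_fields
               if not str(values.get(n, "")).strip()]
    if missing:
        raise MissingField(missing)
    known = {f.name for f in template.fields}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ValueError("unknown template fields: " + ", ".join(unknown))
    return CompletedTemplate(template, dict(values))


def associate_files(ct: CompletedTemplate,
                    files: Iterable[FileAttachment]) -> CompletedTemplate:
    """Associate any number of data files with a completed template at once."""
    ct.associated_files.extend(files)
    return ct


@dataclass
class MinimumInfoRecord:
    """MIABS sample fields merged with ``tech:``-prefixed template values."""

    biosource_ref: str
    miabs: dict[str, str]
    technology: dict[str, str]
    data_files: list[str]

    def as_dict(self) -> dict[str, str]:
        merged = dict(self.miabs)
        merged.update(self.technology)
        return merged


def compile_minimum_info(biosource: GraphNode,
                         completed: CompletedTemplate | None = None,
                         ) -> MinimumInfoRecord:
    """Compile sample- and technology-level minimum information.

    Technology keys are prefixed ``tech:`` so the two key sets stay
    disjoint and the merge is lossless.
    """
    if biosource.kind is not NodeKind.BIOSOURCE:
        raise KindError("minimum information is compiled for biosources only")
    tech = {} if completed is None else {
        f"tech:{k}": v for k, v in completed.values.items()}
    files = [] if completed is None else [
        f.filename for f in completed.associated_files]
    return MinimumInfoRecord(
        biosource_ref=biosource.id,
        miabs=dict(biosource.miabs or {}),
        technology=tech,
        data_files=files,
    )
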
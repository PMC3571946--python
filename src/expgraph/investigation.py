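"""Investigations and the repository that holds them.

The root item of the data model is the Investigation: a container for a
collection of studies, with its own set of declared ontology sources and
an access group created alongside it.  The :class:`Repository` is the
in-memory store binding investigations, users, groups, protocols and
templates together; it is what the serialization layer persists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import access as _access
from ._ids import IdGen
from .access import AccessGroup, PermLevel, User
from .errors import AccessDenied, DuplicateOntologySource, NoSuchObject
from .graph import StudyGraph
from .protocols import ProtocolRegistry, TechnologyTemplate


@dataclass
class Investigation:
    id: str
    title: str
    description: str = ""
    ontology_sources: list = field(default_factory=list)
    studies: list[StudyGraph] = field(default_factory=list)
    creator: str = ""
    access_group: str = ""
    grants: dict[str, PermLevel] = field(default_factory=dict)

    @property
    def owner(self) -> str:
        return self.creator

    def study(self, study_id: str) -> StudyGraph:
        for s in self.studies:
            if s.id == study_id:
                return s
        raise NoSuchObject(f"no study {study_id!r} in investigation {self.id}")

    def source(self, short_name: str):
        for s in self.ontology_sources:
            if s.short_name == short_name:
                return s
        raise NoSuchObject(f"no ontology source {short_name!r} declared")


class Repository:
    """One instance of the store: users, groups, protocols, investigations."""

    def __init__(self, seed: int | None = None):
        self._ids = IdGen(seed)
        self._seed = seed
        self.users: dict[str, User] = {}
        self.groups: dict[str, AccessGroup] = {}
        self.investigations: dict[str, Investigation] = {}
        self.protocols = ProtocolRegistry(idgen=self._ids)
        self.templates: dict[str, TechnologyTemplate] = {}

    # -- users and groups ---------------------------------------------------

    def add_user(self, name: str, id: str | None = None) -> User:
        uid = id if id is not None else self._ids.new("u")
        if uid in self.users:
            raise ValueError(f"user id {uid!r} already taken")
        user = User(uid, name)
        self.users[uid] = user
        return user

    def create_group(self, members=()) -> AccessGroup:
        group = AccessGroup(self._ids.new("g"))
        for m in members:
            group.add_member(m)
        self.groups[group.id] = group
        return group

    # -- investigations and studies -----------------------------------------

    def create_investigation(self, title: str, ontology_sources, owner: User,
                             description: str = "") -> Investigation:
        """Create an investigation, private to ``owner``.

        A fresh access group containing only the owner is created with
        it and granted full permission.
        """
        if not str(title).strip():
            raise ValueError("investigation title must be non-empty")
        sources = list(ontology_sources)
        names = [s.short_name for s in sources]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DuplicateOntologySource(
                "duplicate ontology source short names: " + ", ".join(dupes))
        group = self.create_group([owner])
        inv = Investigation(
            id=self._ids.new("inv"),
            title=title,
            description=description,
            ontology_sources=sources,
            creator=owner.id,
            access_group=group.id,
            grants={group.id: PermLevel.FULL},
        )
        self.investigations[inv.id] = inv
        return inv

    def add_study(self, inv: Investigation, title: str, actor: User) -> StudyGraph:
        """Append a new study (root node only) to an investigation."""
        if not self.check_permission(actor, inv, "write"):
            raise AccessDenied(
                f"{actor.id} has no write permission on investigation {inv.id}")
        study = StudyGraph(self._ids.new("s"), title,
                           idgen=IdGen(self._seed if self._seed is not None else None),
                           creator=actor.id)
        inv.studies.append(study)
        return study

    def investigation_of(self, obj) -> Investigation | None:
        for inv in self.investigations.values():
            if obj is inv or any(s is obj for s in inv.studies):
                return inv
        return None

    def _resolve(self, obj):
        if isinstance(obj, str):
            if obj in self.investigations:
                return self.investigations[obj]
            if obj in self.protocols:
                return self.protocols.get(obj)
            for inv in self.investigations.values():
                for s in inv.studies:
                    if s.id == obj:
                        return s
            raise NoSuchObject(f"no object with id {obj!r}")
        return obj

    # -- access control -----------------------------------------------------

    def check_permission(self, user, obj, action: str) -> bool:
        """True iff ``user`` may ``action`` the object (or object id).

        Objects inside an investigation honour the investigation-level
        grants in union with their own.
        """
        obj = self._resolve(obj)
        return _access.allows(user, obj, action, self.groups,
                              investigation=self.investigation_of(obj))

    def grant(self, obj, group: AccessGroup, level, actor) -> None:
        obj = self._resolve(obj)
        _access.grant(obj, group, PermLevel(level), actor, self.groups,
                      investigation=self.investigation_of(obj))

    def revoke(self, obj, group: AccessGroup, actor) -> None:
        obj = self._resolve(obj)
        _access.revoke(obj, group, actor, self.groups,
                       investigation=self.investigation_of(obj))
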
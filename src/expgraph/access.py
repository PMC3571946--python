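"""Object-level access control.

Every securable object (investigation, study, protocol) is private by
default: only its creator can read, write or delete it.  Wider access is
granted by attaching an access group at one of two levels:

* ``read_only`` — read
* ``full``      — read, write and delete

Each investigation is born with its own access group containing just the
owner.  Objects inside an investigation additionally honour the
investigation-level grants; object-level grants are unioned with them, so
granting at either level is sufficient and never removes a capability.

Users are trusted identities; there is no authentication layer here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import AccessDenied


class PermLevel(str, Enum):
    READ_ONLY = "read_only"
    FULL = "full"

    def allows(self, action: str) -> bool:
        if self is PermLevel.FULL:
            return action in ("read", "write", "delete")
        return action == "read"


ACTIONS = ("read", "write", "delete")


@dataclass
class User:
    id: str
    name: str


@dataclass
class AccessGroup:
    id: str
    members: set[str] = field(default_factory=set)

    def add_member(self, user: "User | str") -> None:
        self.members.add(user.id if isinstance(user, User) else user)

    def remove_member(self, user: "User | str") -> None:
        self.members.discard(user.id if isinstance(user, User) else user)


@dataclass
class Permission:
    """A single grant: ``group`` may act on ``obj`` at ``level``."""

    object_id: str
    group_id: str
    level: PermLevel


def _uid(user) -> str:
    return user.id if isinstance(user, User) else str(user)


def allows(user, obj, action: str, groups: dict[str, AccessGroup],
           investigation=None) -> bool:
    """True iff ``user`` may perform ``action`` on ``obj``.

    ``obj`` (and the optional enclosing ``investigation``) expose
    ``creator`` and a ``grants`` mapping of group id -> PermLevel.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    uid = _uid(user)
    if getattr(obj, "creator", None) == uid:
        return True
    if investigation is not None and getattr(investigation, "creator", None) == uid:
        return True
    pools: list[dict] = [getattr(obj, "grants", {})]
    if investigation is not None and investigation is not obj:
        pools.append(getattr(investigation, "grants", {}))
    for grants in pools:
        for gid, level in grants.items():
            group = groups.get(gid)
            if group is not None and uid in group.members and PermLevel(level).allows(action):
                return True
    return False


def grant(obj, group: AccessGroup, level: PermLevel, actor,
          groups: dict[str, AccessGroup], investigation=None) -> None:
    """Attach ``group`` to ``obj`` at ``level``.  Idempotent.

    Only users with full permission on the object (which includes the
    creator of the enclosing investigation) may administer grants.
    """
    if not allows(actor, obj, "delete", groups, investigation):
        raise AccessDenied(f"{_uid(actor)} may not administer permissions here")
    obj.grants[group.id] = PermLevel(level)


def revoke(obj, group: AccessGroup, actor, groups: dict[str, AccessGroup],
           investigation=None) -> None:
    """Remove a grant.  Idempotent: revoking an absent grant is a no-op."""
    if not allows(actor, obj, "delete", groups, investigation):
        raise AccessDenied(f"{_uid(actor)} may not administer permissions here")
    obj.grants.pop(group.id, None)
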
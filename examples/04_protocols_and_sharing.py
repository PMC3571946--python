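"""Immutable protocols, searchable comments, and object-level sharing.

Everything a user creates is private by default; access groups widen it
to read-only or full (read/write/delete).
"""

import expgraph as eg

repo = eg.Repository(seed=0)
alice = repo.add_user("alice", id="alice")
bob = repo.add_user("bob", id="bob")

proto = repo.protocols.register(
    "RNA extraction", "Lyse cells, bind, wash twice, elute in 30 ul.", alice)
proto.add_comment("alice", "works better at 4C", timestamp="2013-01-16")

try:
    proto.set_text("shortcut: skip the washes")
except eg.ProtocolImmutable as exc:
    print(f"edit refused: {exc}")

print("alice searches '4C':",
      [p.name for p in repo.protocols.search("4C", alice, repo.groups)])
print("bob searches '4C':  ",
      [p.name for p in repo.protocols.search("4C", bob, repo.groups)])

inv = repo.create_investigation("Shared study", [], alice)
print(f"\nbob may read the investigation: "
      f"{repo.check_permission(bob, inv, 'read')}")
group = repo.create_group([bob])
repo.grant(inv, group, eg.PermLevel.READ_ONLY, alice)
print("after a read-only grant: read ->",
      repo.check_permission(bob, inv, "read"), "| write ->",
      repo.check_permission(bob, inv, "write"))
# Deviations from a protocol are recorded on the arc that applied it,
# never by editing the registered text.
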
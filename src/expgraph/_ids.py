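"""Identifier generation.

Ids are opaque strings.  With a seed, ids come from a plain counter so
that rebuilding the same fixture gives byte-identical serializations;
without one they are random UUID fragments.
"""

from __future__ import annotations

import uuid


class IdGen:
    def __init__(self, seed: int | None = None):
        self._seeded = seed is not None
        self._n = 0

    def new(self, tag: str) -> str:
        self._n += 1
        if self._seeded:
            return f"{tag}{self._n:04d}"
        return f"{tag}-{uuid.uuid4().hex[:12]}"
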
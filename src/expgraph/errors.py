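"""Exception hierarchy.

Every error raised by the public API derives from :class:`ExpgraphError`,
so callers (and the CLI) can distinguish domain errors from bugs.
"""

from __future__ import annotations


class ExpgraphError(Exception):
    """Base class for all domain errors."""


# --- investigation / repository -------------------------------------------

class DuplicateOntologySource(ExpgraphError):
    """Two ontology sources with the same short name on one investigation."""


class NoSuchObject(ExpgraphError):
    """An object id does not resolve within the repository."""


# --- graph construction ----------------------------------------------------

class NoSuchNode(ExpgraphError):
    pass


class NoSuchArc(ExpgraphError):
    pass


class IllegalChildKind(ExpgraphError):
    """(parent kind, child kind) is not in the typing table."""


class MixedSelection(ExpgraphError):
    """A bulk operation was given nodes of more than one kind."""


class PoolArityError(ExpgraphError):
    """Pooling needs at least two source nodes."""


class KindError(ExpgraphError):
    """Operation applied to a node of the wrong kind."""


class RootArcError(ExpgraphError):
    """Arcs out of the root node represent inclusion, not actions: they
    cannot carry a protocol application."""


class CascadeRequired(ExpgraphError):
    """Deleting a node with children requires an explicit cascade flag."""


class InvalidGraph(ExpgraphError):
    """A study graph failed validation; ``violations`` holds the detail."""

    def __init__(self, violations):
        self.violations = list(violations)
        codes = ", ".join(sorted({v.code for v in self.violations}))
        super().__init__(f"study graph is invalid: {codes}")


# --- ontology --------------------------------------------------------------

class ParseError(ExpgraphError):
    """Malformed OBO input; ``line`` is the 1-based offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NoSuchSource(ExpgraphError):
    """Search asked for an ontology source that is not in the index."""


class SourceNotRegistered(ExpgraphError):
    """Term attach from a source not declared on the investigation."""


# --- protocols / templates -------------------------------------------------

class NoSuchProtocol(ExpgraphError):
    pass


class EmptyProtocol(ExpgraphError):
    pass


class ProtocolImmutable(ExpgraphError):
    """The body of a registered protocol can never be altered."""


class MissingField(ExpgraphError):
    """Required template fields were left empty; ``names`` lists them."""

    def __init__(self, names):
        self.names = sorted(names)
        super().__init__("missing required fields: " + ", ".join(self.names))


# --- access control --------------------------------------------------------

class AccessDenied(ExpgraphError):
    pass


# --- fixtures / export -----------------------------------------------------

class SpecError(ExpgraphError):
    """Invalid synthetic-fixture specification."""


class IsaTabError(ExpgraphError):
    """An ISA-Tab bundle failed structural validation on import."""

    def __init__(self, violations):
        self.violations = list(violations)
        codes = ", ".join(sorted({v.code for v in self.violations}))
        super().__init__(f"ISA-Tab bundle is invalid: {codes}")
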
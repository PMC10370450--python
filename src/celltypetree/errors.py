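"""Exception hierarchy shared by all modules."""


class CellTreeError(Exception):
    """Base class for package errors."""


class NotFoundError(CellTreeError, KeyError):
    """A referenced node, file slot, or column does not exist."""


class ConflictError(CellTreeError):
    """An alias is already housed elsewhere in the tree."""


class ValidationError(CellTreeError, ValueError):
    """Input data violates an invariant (non-finite values, bad labels, ...)."""


class StateError(CellTreeError, RuntimeError):
    """Operation requires fitted state that is absent (e.g. unfitted classifier)."""


class ParseError(CellTreeError, ValueError):
    """A serialized tree file could not be parsed."""
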
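"""Exception hierarchy used across the package.

All exceptions derive from :class:`MvdstError` so callers can catch
package-level failures with a single except clause; each subclass maps to
one failure category of the public contracts.
"""


class MvdstError(Exception):
    """Base class for all mvdst errors."""


class InputError(MvdstError, ValueError):
    """A required input file/array is missing or malformed."""


class ConsistencyError(MvdstError, ValueError):
    """Cross-file or cross-array bookkeeping does not line up."""


class ParameterError(MvdstError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class ContractError(MvdstError, ValueError):
    """An internal shape/width contract between operations is violated."""


class StateError(MvdstError, RuntimeError):
    """An operation was called on an object in the wrong state."""
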
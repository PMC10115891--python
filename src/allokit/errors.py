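"""Exception types shared across the toolkit.

Argument-contract violations raise plain :class:`ValueError` / :class:`KeyError`;
the classes below mark failures that carry domain meaning (malformed ensemble
files, disconnected networks, under-determined fits) so callers can catch them
specifically.
"""


class AllokitError(Exception):
    """Base class for toolkit-specific failures."""


class FormatError(AllokitError):
    """An external file violates its format contract (e.g. inconsistent models)."""


class InsufficientDataError(AllokitError):
    """Too few frames / points / matched pairs to evaluate the statistic."""


class DegenerateNetworkError(AllokitError):
    """A network has no usable structure (e.g. all-zero adjacency)."""


class NoPathError(AllokitError):
    """Destination unreachable from every source node."""


class DegenerateFitError(AllokitError):
    """Geometric fit is under-determined (e.g. collinear Cα set)."""
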
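"""Exception hierarchy for :mod:`pathpid`."""


class PathPIDError(Exception):
    """Base class for all errors raised by this package."""


class InputError(PathPIDError, ValueError):
    """Invalid user input: malformed files, unknown variables, bad groups."""


class DiagnosticError(PathPIDError):
    """A decomposition produced a value that signals an inconsistent system.

    Raised, for example, when a unique-information atom is negative beyond
    tolerance; such negativity indicates hidden variables or an
    over-determined system rather than a numerical accident, so it is
    surfaced instead of silently clipped.
    """
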
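"""Exception hierarchy for fundusquant.

All package-specific failures derive from :class:`FundusQuantError` so callers
can catch one base class; subclasses distinguish schema problems (malformed
input files), validation problems (well-formed but inconsistent data),
degenerate geometry/statistics, and solver non-convergence.
"""


class FundusQuantError(Exception):
    """Base class for all fundusquant errors."""


class FormatError(FundusQuantError):
    """An input file is readable but has the wrong format (depth, channels)."""


class SchemaError(FundusQuantError):
    """A structured input (JSON/CSV) is missing required keys or columns."""


class ValidationError(FundusQuantError):
    """Data violates a documented invariant (named in the message)."""


class DegenerateGeometryError(ValidationError):
    """A geometric construction is undefined (coincident points, vertical fovea)."""


class DegenerateInputError(ValidationError):
    """A statistic is undefined for this input (e.g. constant vector)."""


class EmptyRegionError(ValidationError):
    """A sampling region contains no image pixels."""


class ConvergenceError(FundusQuantError):
    """The coordinate-descent solver did not converge within the sweep budget."""
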
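"""Exception hierarchy.

Data/format problems derive from :class:`DataError`; numerical failures
(rank deficiency and the like) from :class:`NumericalError`.  The CLI maps
these onto distinct exit codes.
"""


class IRPreclassError(Exception):
    """Base class for all errors raised by this package."""


class DataError(IRPreclassError):
    """Malformed, inconsistent, or out-of-contract input data."""


class ParseError(DataError):
    """A cell or record could not be parsed; message names the location."""


class ShapeError(DataError):
    """Ragged rows or otherwise inconsistent array shapes."""


class AxisError(DataError):
    """Invalid wavenumber axis (duplicates, non-finite, non-positive)."""


class RangeError(DataError):
    """A requested wavenumber lies outside the available axis range."""


class RegionError(DataError):
    """A fit/statistic region selects too few channels."""


class UnmatchedTargetError(DataError):
    """No axis channel lies within tolerance of a requested wavenumber."""


class ChannelCollisionError(DataError):
    """Two requested wavenumbers map to the same axis channel."""


class UnsupportedDialectError(DataError):
    """JCAMP-DX data use a compression scheme this reader does not support."""


class IntegrityError(DataError):
    """A file's internal bookkeeping (e.g. NPOINTS) disagrees with its data."""


class ContractViolation(IRPreclassError):
    """A call violated a documented precondition."""


class NumericalError(IRPreclassError):
    """A numerical operation cannot be carried out (e.g. rank deficiency)."""


class RankDeficiencyError(NumericalError):
    """The reference spectrum is constant over the fit region."""
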
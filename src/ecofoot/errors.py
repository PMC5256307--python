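"""Exception hierarchy for ecofoot.

Every error raised by the package derives from :class:`EcofootError`, so
callers (including the CLI) can catch one base class.
"""


class EcofootError(Exception):
    """Base class for all ecofoot errors."""


class StructuralError(EcofootError):
    """Dimension or label mismatch between co-used structures."""


class AccountInconsistencyError(EcofootError):
    """Nonzero transaction or pressure recorded against a zero-output sector."""


class NonProductiveEconomyError(EcofootError):
    """Technical-coefficient matrix with spectral radius at or above one."""


class NumericalError(EcofootError):
    """A computed result failed its residual check."""


class AlignmentError(EcofootError):
    """Raster layers do not share grid shape and geotransform."""


class DataError(EcofootError):
    """Invalid data value (negative pressure cell, negative factor, ...)."""


class MappingError(EcofootError):
    """Satellite pressure label without a pressure-to-pathway mapping entry."""


class AssemblyError(EcofootError):
    """Characterization-factor rows could not be assembled in satellite order."""


class UnitError(EcofootError):
    """Unit label outside the registry, or mixed units where one is required."""


class GroupingError(EcofootError):
    """Country without a group assignment."""


class ParameterError(EcofootError):
    """Infeasible scenario or function parameter."""


class ParseError(EcofootError):
    """Malformed input file (ragged rows, duplicate labels, unknown units)."""
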
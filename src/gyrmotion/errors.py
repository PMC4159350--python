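"""Exception hierarchy for gyrmotion.

All package-specific failures derive from :class:`GyrmotionError` so callers
can catch one base class at pipeline boundaries.
"""


class GyrmotionError(Exception):
    """Base class for all gyrmotion errors."""


class StructureFormatError(GyrmotionError):
    """A coordinate file could not be parsed in the requested format."""


class SymmetryUnavailableError(GyrmotionError):
    """Crystal symmetry operators are required but cannot be determined."""


class EmptySelectionError(GyrmotionError):
    """An atom selection matched nothing where atoms were required."""


class InsufficientPairsError(GyrmotionError):
    """Fewer than the minimum number of paired atoms for superposition."""


class DegenerateGeometryError(GyrmotionError):
    """Point set is collinear or coincident; superposition is ill-posed."""


class InvalidRotationError(GyrmotionError):
    """Matrix is not a proper rotation (orthonormal, det = +1)."""


class NotADyadError(GyrmotionError):
    """The subunit-relating transform is not close to a two-fold rotation."""


class MissingChainError(GyrmotionError):
    """A requested chain is absent from the structure."""


class AtomResolutionError(GyrmotionError):
    """An atom specification resolved to zero or to multiple atoms."""


class SyntheticSpecError(GyrmotionError):
    """A synthetic-structure specification is internally inconsistent."""


class ConfigError(GyrmotionError):
    """An analysis configuration file is invalid."""
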
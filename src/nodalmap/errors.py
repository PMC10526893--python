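"""Exception hierarchy for the pipeline.

All errors derive from :class:`NodalMapError` so callers can catch pipeline
failures as a group while the CLI reports the concrete stage and objects
involved.
"""


class NodalMapError(Exception):
    """Base class for all package-specific errors."""


class VolumeFormatError(NodalMapError, ValueError):
    """A volume file violates the format contract (non-integer labels, 4D data, ...)."""


class GridMismatchError(NodalMapError, ValueError):
    """Two volumes that must share a grid do not. No silent resampling is performed."""


class PhantomSpecError(NodalMapError, ValueError):
    """A phantom specification is internally inconsistent (overlaps, bad probabilities)."""


class PlacementError(NodalMapError, RuntimeError):
    """A synthetic node could not be placed inside its target level."""


class AssignmentError(NodalMapError, ValueError):
    """Level assignment is impossible (e.g. label volume with no foreground)."""


class ReviewError(NodalMapError, ValueError):
    """Reader-vote tables violate their contract (duplicates, self-corrections)."""


class TransformError(NodalMapError, ValueError):
    """A spatial transform violates its invariants (singular affine, non-finite field)."""


class MappingError(NodalMapError, RuntimeError):
    """Cohort mapping failed (e.g. patients without transforms)."""


class DensityError(NodalMapError, ValueError):
    """Density estimation or comparison is ill-posed (no points, empty levels, ...)."""


class ConfigurationError(NodalMapError, ValueError):
    """A run configuration references missing stages, paths or backends."""
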
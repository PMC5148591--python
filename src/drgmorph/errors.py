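"""Exception hierarchy for the morphometry pipeline.

Every stage raises a subclass of :class:`DrgMorphError` so that the
pipeline driver can distinguish a per-neuron analysis failure (recorded,
neuron excluded, run continues) from a configuration error (fatal).
"""


class DrgMorphError(Exception):
    """Base class for all drgmorph errors."""


class InvalidParameterError(DrgMorphError, ValueError):
    """A parameter violates its documented domain."""


class FrameTooSmallError(DrgMorphError):
    """The arbor does not fit inside the requested raster frame."""


class NoForegroundError(DrgMorphError):
    """Thresholding produced no foreground (e.g. constant image)."""


class SeedNotOnForegroundError(DrgMorphError):
    """The soma seed point falls on background in the binary mask."""


class SomaNotFoundError(DrgMorphError):
    """Morphological opening removed everything: no soma-scale structure."""


class GridExceedsFrameError(DrgMorphError):
    """The largest Sholl radius leaves the image bounds."""
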
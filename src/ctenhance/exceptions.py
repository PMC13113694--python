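"""Exception types shared across the package."""


class CTEnhanceError(Exception):
    """Base class for package-specific errors."""


class FormatError(CTEnhanceError):
    """A file or header does not conform to the expected dialect."""


class ParseError(FormatError):
    """A record inside an otherwise well-formed file could not be parsed."""


class OutOfBoundsError(CTEnhanceError):
    """A requested location lies outside the volume; carries the index."""

    def __init__(self, message, index=None):
        super().__init__(message)
        self.index = index


class EmptyClassError(CTEnhanceError):
    """An operation requiring both classes received only one."""


class EmptyRegionError(CTEnhanceError):
    """A statistic over a region is undefined because the region is empty."""


class DegenerateTileError(CTEnhanceError):
    """A tile histogram carries no mass, so its mapping is undefined."""


class CapacityError(CTEnhanceError):
    """Object placement failed repeatedly; fewer or smaller objects needed."""
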
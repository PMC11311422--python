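"""Exception types raised by funduslight."""


class FunduslightError(Exception):
    """Base class for all funduslight errors."""


class InvalidParameterError(FunduslightError, ValueError):
    """A parameter violates an operation's preconditions."""


class ROINotFoundError(FunduslightError, RuntimeError):
    """Thresholding produced an empty eye-region mask."""


class UndefinedGainError(FunduslightError, ValueError):
    """A relative gain was requested against a non-positive baseline."""


class MappingError(FunduslightError, RuntimeError):
    """A grey level in the region of interest has no entry in the level mapping."""


class ImageFormatError(FunduslightError, ValueError):
    """The input raster cannot be interpreted as an 8-bit RGB image."""
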
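"""Exception hierarchy shared across the package."""


class SDMError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SDMError, ValueError):
    """A file does not conform to the expected on-disk format."""


class AlignmentError(SDMError, ValueError):
    """Grids that must share shape/origin/cell size do not."""


class ArgumentError(SDMError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SDMError, ValueError):
    """Input is structurally valid but leaves nothing to compute on."""
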
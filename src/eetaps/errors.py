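"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its documented range."""


class PlacementError(ValueError):
    """Requested region layout cannot fit in the genome."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the operation."""


class FormatError(ValueError):
    """A file or stream does not conform to the expected format."""
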
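"""Exception types shared across the package."""


class MSINRFError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MSINRFError, ValueError):
    """A model or stimulus parameter is outside its admissible range."""


class InvalidInputError(MSINRFError, ValueError):
    """An input sequence or image cannot be processed (e.g. too short)."""


class OutOfBoundsError(MSINRFError, IndexError):
    """A sensor location falls outside the image, or too close to the
    border for the kernels to be fully supported."""


class ConfigError(MSINRFError, ValueError):
    """A run configuration file failed validation.

    The message lists every violation found, one per line.
    """
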
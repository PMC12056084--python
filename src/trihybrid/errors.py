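"""Exception hierarchy shared across the package."""


class TrihybridError(Exception):
    """Base class for all package errors."""


class InputError(TrihybridError):
    """A file could not be read or is malformed."""


class PopmapError(TrihybridError):
    """Population-map contents are inconsistent with the request or the genotypes."""


class EmptyResultError(TrihybridError):
    """A filter removed every record; the message names the filter responsible."""


class ParameterError(TrihybridError):
    """A numeric parameter is outside its legal domain."""
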
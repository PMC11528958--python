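"""Exception types shared across psnet modules."""


class PsnetError(Exception):
    """Base class for all psnet errors."""


class ConfigurationError(PsnetError):
    """A configuration object is invalid; the message names the field."""


class SpecificationError(PsnetError):
    """A model or subgroup specification is malformed or unsupported."""


class DataError(PsnetError):
    """Input data violate the expected schema or invariants."""
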
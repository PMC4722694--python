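"""Exception hierarchy for the pipeline."""


class ProtxError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtxError):
    """Invalid configuration; the message names the offending field."""


class DesignError(ProtxError):
    """Design matrix is rank deficient or otherwise unusable."""


class NormalizationError(ProtxError):
    """A protein cannot be normalized (zero total or zero mean)."""


class MappingError(ProtxError):
    """Ambiguous protein-to-gene mapping."""


class ParseError(ProtxError):
    """Malformed input file; carries a line number where possible."""
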
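"""Exception hierarchy for gpmix."""


class GpmixError(Exception):
    """Base class for all gpmix errors."""


class ParseError(GpmixError):
    """A tabular input file could not be parsed."""


class ValidationError(GpmixError):
    """An input value violates its domain contract."""


class SchemaError(GpmixError):
    """A required column or config key is missing or malformed."""
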
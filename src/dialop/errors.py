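"""Exception hierarchy for the dialop package."""


class DialopError(Exception):
    """Base class for all dialop errors."""


class FormatError(DialopError):
    """A file does not conform to the expected tabular format."""


class ParseError(DialopError):
    """A cell could not be parsed; carries the offending line number."""


class ValidationError(DialopError):
    """Data violates a pipeline contract (design mismatch, duplicates, ...)."""
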
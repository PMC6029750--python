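"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object or field failed validation.

    Messages always name the offending field (and file/row for tabular
    inputs) so failures are actionable.
    """


class RangeError(ValidationError):
    """A scalar argument fell outside its documented domain."""
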
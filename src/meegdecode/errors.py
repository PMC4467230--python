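"""Shared exception types."""


class ConfigurationError(ValueError):
    """A recipe/config combination that cannot be realised."""


class DomainError(ValueError):
    """An input value outside its stated domain."""
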
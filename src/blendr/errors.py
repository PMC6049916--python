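"""Exception hierarchy shared across blendr modules."""


class BlendrError(Exception):
    """Base class for all blendr errors."""


class SchemaError(BlendrError):
    """A required column or field is missing from an input table."""


class ValidationError(BlendrError):
    """An input value violates a documented invariant."""


class InputError(BlendrError):
    """An input is structurally unusable (empty file, too few samples, ...)."""


class ConfigurationError(BlendrError):
    """Options were combined in a way that leaves nothing to compute."""
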
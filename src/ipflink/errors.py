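"""Exception hierarchy for the ipflink pipeline."""


class IpflinkError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IpflinkError):
    """A table or codelist file does not match its declared schema."""


class IntegrityError(IpflinkError):
    """Parsed data violate a structural invariant (duplicate ids, bad dates, position gaps)."""


class ConfigurationError(IpflinkError):
    """An algorithm, recipe or run configuration is invalid."""


class InfeasibleRecipeError(ConfigurationError):
    """A fixture recipe or marginal set implies a negative region count."""
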
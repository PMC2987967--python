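"""Exception hierarchy shared by all gboxui modules."""


class GboxUiError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(GboxUiError):
    """An input document could not be parsed (carries line info when known)."""


class IntegrityError(GboxUiError):
    """A knowledge-base invariant is violated; the message names offending ids."""


class NotFoundError(GboxUiError):
    """A referenced resource does not exist."""


class ConfigurationError(GboxUiError):
    """A mapping or configuration input is incomplete or inconsistent."""


class SchemaError(GboxUiError):
    """A graphic-descriptor document violates the fixed GBox schema."""


class PlanError(GboxUiError):
    """A query selection cannot be turned into a valid plan."""


class UsageError(GboxUiError):
    """An invocation is malformed (missing or unknown parameters)."""


class AuthenticationError(GboxUiError):
    """An access key does not match the target project's key."""
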
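"""Exception hierarchy shared across the package."""


class ImprintKitError(Exception):
    """Base class for all imprintkit errors."""


class ConfigurationError(ImprintKitError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class InputError(ImprintKitError, ValueError):
    """Semantically invalid input to an operation (empty groups, homozygous SNP...)."""


class ParseError(ImprintKitError, ValueError):
    """A malformed file; the message carries the path and line number."""


class ValidationError(ImprintKitError, ValueError):
    """Well-formed input violating a domain invariant (e.g. negative counts)."""
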
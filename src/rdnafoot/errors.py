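"""Exception hierarchy shared across the package."""


class RdnafootError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RdnafootError, KeyError):
    """A configuration document is missing a required key or is malformed."""


class LandmarkValidationError(RdnafootError, ValueError):
    """A landmark set violates an ordering or containment constraint."""


class BedParseError(RdnafootError, ValueError):
    """A BED line could not be parsed; the message names the line."""


class InputError(RdnafootError, ValueError):
    """An alignment/interval input file is unusable (truncated, wrong type)."""


class NormalizationError(RdnafootError, ZeroDivisionError):
    """A normalizer (Reb1 signal, matrix mass, first-nucleosome signal) is zero."""


class SignalDomainError(RdnafootError, ValueError):
    """A statistic was requested on empty or out-of-domain signal."""


class ModelError(RdnafootError, ValueError):
    """A chromatin model is internally inconsistent (e.g. no tagged particle)."""
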
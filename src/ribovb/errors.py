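"""Exception hierarchy shared across the package."""


class RibovbError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RibovbError):
    """Invalid or inconsistent user-supplied configuration."""


class PairingError(RibovbError):
    """A sample is missing one of its two preparations (mRNA / RPF)."""


class FormatError(RibovbError):
    """Malformed input file or count table."""


class NumericError(RibovbError):
    """Non-finite or out-of-domain numeric input."""


class ConvergenceError(RibovbError):
    """The variational update loop failed irrecoverably."""
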
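"""Exception hierarchy shared across the package."""


class CardioporeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(CardioporeError, ValueError):
    """A domain parameter violates its documented invariants."""


class ConfigurationError(CardioporeError, ValueError):
    """Inconsistent or incomplete configuration of a simulation/analysis."""


class SchemaError(ConfigurationError):
    """Config-file validation failure; ``problems`` lists offending keys."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration: " + "; ".join(self.problems))


class FormatError(CardioporeError, ValueError):
    """A serialized container is missing mandatory structure."""


class FeatureUndefinedError(CardioporeError, ValueError):
    """A waveform feature cannot be computed on the given input."""


class MemoryGuardError(CardioporeError, RuntimeError):
    """Requested simulation exceeds the configured in-memory size cap."""
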
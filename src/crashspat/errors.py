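"""Exception types shared across the package."""


class CrashspatError(ValueError):
    """Base class for all crashspat errors."""


class SchemaError(CrashspatError):
    """A required column is missing from an input table."""


class ValidationError(CrashspatError):
    """A cell value violates a segment-table invariant."""


class OrderingError(CrashspatError):
    """Segment ids are not consecutive 1..n in chain order."""


class ConfigError(CrashspatError):
    """A model, prior, or sampler configuration is inconsistent."""


class ScenarioError(CrashspatError):
    """A simulation scenario produced an unusable configuration or state."""
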
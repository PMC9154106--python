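"""Exception and warning types shared across the pipeline."""


class HSSError(Exception):
    """Base class for pipeline errors."""


class FormatError(HSSError):
    """Input file does not match the expected column layout."""


class EmptyInputError(HSSError):
    """No usable events remain after validation."""


class ConfigurationError(HSSError):
    """Manifest or run configuration is inconsistent."""


class NormalizationError(HSSError):
    """ON-control median ratio is zero; normalization undefined."""


class DegenerateGridError(HSSError):
    """Off/on controls overlap so much that grid boundaries invert."""


class DegenerateControlError(HSSError):
    """A control population is unusable (e.g. no ON cells above 0.5)."""


class EmptyGateWarning(UserWarning):
    """Green-off gate retained zero cells; strain should be skipped."""


class LowEventCountWarning(UserWarning):
    """Event count below the configured minimum."""


class ClusteringDegenerateWarning(UserWarning):
    """Counts matrix is constant; cluster order is arbitrary but fixed."""
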
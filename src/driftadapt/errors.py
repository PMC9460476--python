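"""Exception hierarchy for driftadapt."""


class DriftAdaptError(Exception):
    """Base class for all driftadapt errors."""


class ConfigurationError(DriftAdaptError):
    """A configuration value violates its constraints."""


class ValidationError(DriftAdaptError):
    """An input value fails a precondition."""


class WindowingError(DriftAdaptError):
    """A requested window cannot be cut from the available signal."""


class TrainingError(DriftAdaptError):
    """A classifier cannot be trained on the given data."""


class ManifestError(DriftAdaptError):
    """A session manifest or trial table is malformed."""
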
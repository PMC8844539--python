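"""Exception hierarchy for the proxiglyc pipeline."""


class ProxiglycError(Exception):
    """Base class for all package errors."""


class TableFormatError(ProxiglycError):
    """A tabular input violates the expected format (bad cell, missing
    column, duplicate key...). The message names the offending column,
    accession or line."""


class FixtureIntegrityError(ProxiglycError):
    """A packaged data fixture is missing or corrupt."""


class ConfigurationError(ProxiglycError):
    """Inputs and configuration are mutually inconsistent (e.g. a dataset
    lacking one side of its bait/control pair)."""


class InsufficientDataError(ProxiglycError):
    """Too few observations to run an operation (e.g. tail assessment on a
    near-empty dataset)."""


class PipelineError(ProxiglycError):
    """The filtration pipeline cannot proceed (e.g. no dataset shows a
    labelling tail)."""


class RulerError(ProxiglycError):
    """Histone-ruler copy-number estimation failed (e.g. zero total histone
    signal)."""
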
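"""Exception hierarchy used across the package."""


class PanelGwasError(Exception):
    """Base class for all panelgwas errors."""


class ConfigError(PanelGwasError):
    """Invalid configuration (simulation, filter or pipeline settings)."""


class FormatError(PanelGwasError):
    """Malformed input file (ragged rows, duplicate ids, bad symbols)."""


class ValidationError(PanelGwasError):
    """Structurally valid input that violates a semantic contract."""


class EstimationError(PanelGwasError):
    """A statistical estimate is undefined for the given data."""
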
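"""Exception hierarchy for punctakit."""


class PunctakitError(Exception):
    """Base class for all punctakit-specific errors."""


class ConfigError(PunctakitError, ValueError):
    """Invalid configuration value or combination."""


class DegenerateHistogramError(PunctakitError, ValueError):
    """Histogram thresholding attempted on a constant (single-valued) image."""


class PlacementError(PunctakitError, RuntimeError):
    """Droplet placement inside the cell footprint failed after bounded retries."""


class UndefinedStatisticError(PunctakitError, ValueError):
    """A statistic's denominator is zero or negative, so the value is undefined."""


class FitError(PunctakitError, ValueError):
    """Curve fit cannot be attempted on the given series."""
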
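"""Exception hierarchy shared across the package."""


class ArcGaitError(Exception):
    """Base class for all arcgait errors."""


class DomainError(ArcGaitError, ValueError):
    """A model quantity was requested outside its mathematical domain,
    e.g. a roll factor outside the pendular band 1 < rho < 2."""


class SingularStepError(DomainError):
    """Step length equals foot length (within floating tolerance): the
    roll factor 1 + f/(Sl - f) is singular.  Downstream classification
    maps this case to the small-broken-step style."""


class GeometryError(ArcGaitError, ValueError):
    """Inconsistent or non-physical geometry (e.g. non-positive contact
    distance, rocker radius exceeding leg length)."""


class IntegrationError(ArcGaitError, ValueError):
    """Non-finite state encountered while integrating the dynamics."""


class SchemaError(ArcGaitError, ValueError):
    """A tabular input file is missing required columns."""


class ParseError(ArcGaitError, ValueError):
    """A structured text file (TRC, YAML config) could not be parsed."""


class ConfigError(ArcGaitError, ValueError):
    """Invalid run configuration (unknown keys, out-of-range gates)."""
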
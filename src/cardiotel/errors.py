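"""Exception hierarchy shared across the package."""


class CardiotelError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CardiotelError, ValueError):
    """Malformed beat-event file or table."""


class InsufficientDataError(CardiotelError, ValueError):
    """Input too short/small for the requested computation."""


class ConfigurationError(CardiotelError, ValueError):
    """Missing or inconsistent metadata / scenario configuration."""


class PlacementError(CardiotelError, RuntimeError):
    """An injected event could not be placed without overlap."""


class DomainError(CardiotelError, ValueError):
    """Argument outside the mathematical domain of a formula."""
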
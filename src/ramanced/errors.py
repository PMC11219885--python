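"""Exception types shared across the package."""


class RamancedError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RamancedError):
    """An invalid parameter value or an unknown configuration key."""


class ParseError(RamancedError):
    """A malformed on-disk cohort or configuration file."""


class GridMismatchError(RamancedError):
    """Spectra that should share a wavenumber grid do not."""
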
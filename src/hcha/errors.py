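"""Exception hierarchy shared across the package."""


class HchaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HchaError):
    """A file could not be decoded in any supported image format."""


class UnsupportedInputError(HchaError):
    """The input is recognised but outside the supported subset
    (e.g. multi-frame DICOM, compressed transfer syntaxes)."""


class DimensionError(HchaError):
    """An array argument has incompatible or degenerate dimensions."""


class ConfigError(HchaError):
    """An invalid configuration value (tile grid, clip limit, ...)."""


class PhantomSpecError(HchaError):
    """A phantom specification violates its geometric invariants."""
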
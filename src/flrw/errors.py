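"""Exception hierarchy shared by all flrw modules."""


class FlrwError(Exception):
    """Base class for all errors raised by flrw."""


class ConfigError(FlrwError, ValueError):
    """Invalid configuration value or unknown option."""


class FormatError(FlrwError, ValueError):
    """File content does not match the expected image/model format."""


class IOError_(FlrwError, OSError):
    """File could not be read or written."""


class SeedSelectionError(FlrwError, RuntimeError):
    """Automatic seed selection failed (empty histogram range, empty seed set)."""


class WalkerError(FlrwError, RuntimeError):
    """Random-walker solve failed to converge."""


class EvaluationError(FlrwError, ValueError):
    """Segmentation metrics undefined for the given masks."""
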
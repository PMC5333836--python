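"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class VasctreeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VasctreeError):
    """Invalid configuration (bad parameter values, unknown keys)."""


class DataError(VasctreeError):
    """Invalid or degenerate input data (unreadable file, empty graph...)."""
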
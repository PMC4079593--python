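"""Exception types shared across the package."""


class MtHapNetError(Exception):
    """Base class for all package errors."""


class CoordinateError(MtHapNetError):
    """A reference position or interval is outside the circular reference."""


class InputError(MtHapNetError):
    """An input container violates a precondition (empty, ragged, mismatched)."""


class CompositionError(MtHapNetError):
    """Base-composition scaling is undefined (a zero denominator)."""


class TopologyError(MtHapNetError):
    """A network operation is undefined for the given node set (e.g. the
    haplogroup side or its complement is disconnected, so no single stem
    cut separates the haplogroup)."""


class ConfigError(MtHapNetError):
    """A pipeline or simulation configuration is invalid."""
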
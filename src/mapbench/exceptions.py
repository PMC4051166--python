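"""Exception hierarchy shared across the toolkit."""


class MapBenchError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MapBenchError, ValueError):
    """A file or record does not conform to its declared format."""


class CodecError(FormatError):
    """A read name does not conform to the ground-truth name codec."""


class MissingTagError(FormatError):
    """A SAM record lacks the tags needed to count substitutions."""


class ConfigurationError(MapBenchError, ValueError):
    """Parameters are individually valid but jointly infeasible."""


class CoordinateSystemError(MapBenchError, ValueError):
    """Truth and calls do not share a coordinate system."""
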
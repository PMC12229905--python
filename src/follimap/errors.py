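"""Exception hierarchy for follimap."""


class FollimapError(Exception):
    """Base class for all follimap errors."""


class ConfigError(FollimapError):
    """Invalid configuration value or missing configuration key."""


class CoverageInfeasibleError(FollimapError):
    """The requested HFG area fraction cannot be realised by the
    configured group-size distribution within the attempt budget."""


class DensityInfeasibleError(FollimapError):
    """The requested follicle density cannot be realised under the
    minimum point-separation constraint."""


class RenderScaleError(FollimapError):
    """The raster scale is too coarse: rendered follicle dots would
    touch or merge, breaking the extraction round trip."""


class PointTableFormatError(FollimapError):
    """A point-table CSV row could not be parsed; carries the 1-based
    line number of the offending row."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
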
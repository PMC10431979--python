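"""Exception hierarchy shared by all perfquant stages."""


class PerfquantError(Exception):
    """Base class for all perfquant errors."""


class OrderingError(PerfquantError):
    """DICOM series temporal/slice ordering cannot be resolved."""


class GeometryError(PerfquantError):
    """Array/raster dimensions are inconsistent."""


class MetadataError(PerfquantError):
    """Required acquisition metadata (TE, TR, ...) missing or invalid."""


class EmptyMaskError(PerfquantError):
    """A mask contains no nonzero pixel where one is required."""


class ParameterError(PerfquantError):
    """An operation parameter violates its precondition."""


class DataError(PerfquantError):
    """Input data is unusable for the requested operation (e.g. negative-peak AIF)."""


class FitError(PerfquantError):
    """Nonlinear fit failed to converge; carries diagnostics in args."""


class SingularSystemError(PerfquantError):
    """The convolution system is singular (e.g. all-zero AIF)."""


class ConfigError(PerfquantError):
    """Run configuration invalid; message enumerates every violation found."""


class StageError(PerfquantError):
    """Pipeline stage failure wrapper: names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
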
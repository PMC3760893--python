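"""Exception types shared across the package."""


class BrainevoError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(BrainevoError, ValueError):
    """A caller-supplied argument violates a precondition."""


class ZeroVarianceError(InvalidArgumentError):
    """A region's time series is constant, so Pearson r is undefined."""

    def __init__(self, region: int):
        self.region = region
        super().__init__(f"region {region} has zero variance; Pearson correlation is undefined")


class DegenerateFeatureError(InvalidArgumentError):
    """A feature has no spread in the training set and cannot be classified."""


class CovarianceError(BrainevoError):
    """The planted covariance failed to be positive definite."""


class ParseError(BrainevoError, ValueError):
    """A delimited text file could not be parsed."""

    def __init__(self, path, line: int, message: str):
        self.path = path
        self.line = line
        super().__init__(f"{path}:{line}: {message}")
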
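"""From time series to correlation matrices to thresholded binary networks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, ZeroVarianceError
from .synthetic import SubjectTimeSeries


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson correlations of one subject's regional time series."""

    values: np.ndarray
    subject_id: str
    group: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidArgumentError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise InvalidArgumentError("correlation diagonal must be 1")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise InvalidArgumentError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinaryNetwork:
    """Symmetric, hollow-diagonal 0/1 adjacency at a stated threshold.

    ``threshold`` is ``None`` for planted or evolved networks that did not
    come from binarizing a correlation matrix.
    """

    adjacency: np.ndarray
    threshold: float | None
    subject_id: str
    group: str = ""

    def __post_init__(self):
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise InvalidArgumentError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise InvalidArgumentError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise InvalidArgumentError("adjacency diagonal must be 0")
        if not np.isin(a, (0.0, 1.0)).all():
            raise InvalidArgumentError("adjacency entries must be 0/1")
        object.__setattr__(self, "adjacency", a)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass(frozen=True)
class ThresholdGrid:
    """Correlation cut-offs swept in the analysis: 0.50 to 0.60 by 0.01."""

    start: float = 0.50
    stop: float = 0.60
    step: float = 0.01

    def values(self) -> list[float]:
        # integer-index construction avoids floating accumulation drift
        k = int(round((self.stop - self.start) / self.step))
        vals = [round(self.start + i * self.step, 2) for i in range(k + 1)]
        if not vals or vals[-1] != round(self.stop, 2):
            raise InvalidArgumentError("grid endpoints are not step-aligned")
        return vals


def pearson_matrix(ts: SubjectTimeSeries) -> CorrelationMatrix:
    """Sample Pearson correlation between every pair of regional series.

    Rejects constant regions: a zero-variance series has no defined
    correlation, and silently propagating NaN would poison every network
    downstream.
    """
    x = ts.signal
    if x.shape[1] < 3:
        raise InvalidArgumentError("need at least 3 timepoints for a correlation")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ZeroVarianceError(int(dead[0]))
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(values=r, subject_id=ts.subject_id, group=ts.group)


def binarize(corr: CorrelationMatrix, threshold: float) -> BinaryNetwork:
    """Edge (i, j) iff i != j and r(i, j) >= threshold (signed r, inclusive)."""
    if not 0 <= threshold <= 1:
        raise InvalidArgumentError("threshold must lie in [0, 1]")
    a = (corr.values >= threshold).astype(float)
    np.fill_diagonal(a, 0.0)
    return BinaryNetwork(
        adjacency=a, threshold=threshold, subject_id=corr.subject_id, group=corr.group
    )


def threshold_sweep(
    corr: CorrelationMatrix, grid: ThresholdGrid | None = None
) -> list[BinaryNetwork]:
    """Binarize at every grid threshold; edge counts are non-increasing."""
    grid = grid or ThresholdGrid()
    return [binarize(corr, tau) for tau in grid.values()]
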
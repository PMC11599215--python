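"""Functional-connectivity matrices and network summaries.

Builds a connectivity matrix from a multichannel recording with any pairwise
coupling estimator, and provides the standard summaries used downstream:
signed node strength, Fisher-z averaging of correlation matrices (across
segments, sessions or encodings), and segment-wise estimation with
across-segment averaging of node strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .core import CouplingResult, DetrendConfig, FrequencyGrid
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "FCMatrix",
    "SegmentPlan",
    "PAIR_ESTIMATORS",
    "fc_matrix",
    "node_strength",
    "fisher_average",
    "segment_and_estimate",
]


def _mdc3_pair(x, y, grid, cfg) -> CouplingResult:
    return core.mdc3(x, y, grid, cfg)


def _pearson_pair(x, y, grid, cfg) -> CouplingResult:
    return CouplingResult(value=core.pearson_r(x, y))


def _dmdc3_pair(x, y, grid, cfg) -> CouplingResult:
    return core.dmdc3(x, y, grid, cfg)


def _lg_pair(x, y, grid, cfg) -> CouplingResult:
    return core.global_lagged_covariance(x, y, cfg)


#: name -> pairwise estimator with the uniform (x, y, grid, cfg) signature
PAIR_ESTIMATORS = {
    "mdc3": _mdc3_pair,
    "pearson": _pearson_pair,
    "dmdc3": _dmdc3_pair,
    "lg": _lg_pair,
}


@dataclass(frozen=True)
class FCMatrix:
    """A labeled square connectivity matrix.

    Undirected matrices are symmetric with unit diagonal (self-coupling);
    directed matrices store at (i, j) the strength of channel i driving
    channel j, with zero diagonal.
    """

    labels: tuple
    weights: np.ndarray
    estimator_name: str = ""
    directed: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", tuple(self.labels))
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidInputError(f"weights must be square, got shape {w.shape}")
        if len(self.labels) != w.shape[0]:
            raise InvalidInputError(
                f"{len(self.labels)} labels for a {w.shape[0]}-node matrix"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class SegmentPlan:
    """Consecutive non-overlapping segmentation of a recording."""

    segment_length: int

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise InvalidParameterError(
                f"segment_length must be >= 2, got {self.segment_length}"
            )

    def n_segments(self, total_length: int) -> int:
        return total_length // self.segment_length


def _as_channels(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise InvalidInputError(
            f"expected a channels x samples array with >= 2 channels, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("multichannel data contain non-finite values")
    return arr


def _resolve_estimator(estimator):
    if callable(estimator):
        return getattr(estimator, "__name__", "custom"), estimator
    if estimator not in PAIR_ESTIMATORS:
        raise InvalidParameterError(
            f"unknown estimator {estimator!r}; available: {sorted(PAIR_ESTIMATORS)}"
        )
    return estimator, PAIR_ESTIMATORS[estimator]


def fc_matrix(data, estimator="mdc3", grid: FrequencyGrid | None = None,
              cfg: DetrendConfig = DetrendConfig(), labels=None) -> FCMatrix:
    """Estimate the connectivity matrix of a channels x samples recording.

    ``estimator`` is a name from :data:`PAIR_ESTIMATORS` or any callable
    ``(x, y, grid, cfg) -> CouplingResult``. Undirected estimators fill both
    triangles symmetrically with unit diagonal; directed estimators place the
    i-leading value at (i, j) (and, by the leading/lagging duality, the
    j-leading value at (j, i)) with zero diagonal.
    """
    arr = _as_channels(data)
    n = arr.shape[0]
    if labels is None:
        labels = tuple(f"ch{i}" for i in range(n))
    elif len(labels) != n:
        raise InvalidInputError(f"{len(labels)} labels for {n} channels")
    name, fn = _resolve_estimator(estimator)

    weights = np.zeros((n, n))
    directed: bool | None = None
    for i in range(n):
        for j in range(i + 1, n):
            res = fn(arr[i], arr[j], grid, cfg)
            if directed is None:
                directed = res.directed
            if res.directed:
                weights[i, j] = res.leading
                weights[j, i] = res.lagging
            else:
                weights[i, j] = weights[j, i] = res.value
    directed = bool(directed)
    np.fill_diagonal(weights, 0.0 if directed else 1.0)
    return FCMatrix(labels=tuple(labels), weights=weights,
                    estimator_name=name, directed=directed)


def node_strength(fc: FCMatrix, absolute: bool = False) -> np.ndarray:
    """Signed strength of every node: sum of incident edge weights.

    The diagonal is excluded. For a directed matrix this is in-strength plus
    out-strength (row sum + column sum); for an undirected one the row sum.
    Weights keep their sign so anticorrelations subtract, unless ``absolute``.
    """
    w = fc.weights.copy()
    np.fill_diagonal(w, 0.0)
    if absolute:
        w = np.abs(w)
    if fc.directed:
        return w.sum(axis=1) + w.sum(axis=0)
    return w.sum(axis=1)


def fisher_average(matrices) -> FCMatrix:
    """Entrywise Fisher-z average of correlation-valued matrices.

    Each entry is clipped just inside (-1, 1), atanh-transformed, averaged
    across matrices and mapped back with tanh. The unit diagonal of
    undirected inputs survives within clip tolerance.
    """
    matrices = list(matrices)
    if not matrices:
        raise InvalidInputError("need at least one matrix to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.weights.shape != first.weights.shape or m.labels != first.labels:
            raise InvalidInputError("matrices must share shape and labels")
        if m.directed != first.directed:
            raise InvalidInputError("cannot mix directed and undirected matrices")
    stack = np.stack([m.weights for m in matrices])
    if np.any(np.abs(stack) > 1):
        raise InvalidInputError("Fisher averaging requires entries in [-1, 1]")
    z = np.arctanh(np.clip(stack, -1 + core.FISHER_CLIP, 1 - core.FISHER_CLIP))
    avg = np.tanh(z.mean(axis=0))
    return FCMatrix(labels=first.labels, weights=avg,
                    estimator_name=first.estimator_name, directed=first.directed)


def segment_and_estimate(data, plan: SegmentPlan, estimator="mdc3",
                         grid: FrequencyGrid | None = None,
                         cfg: DetrendConfig = DetrendConfig(),
                         labels=None, absolute: bool = False) -> np.ndarray:
    """Across-segment mean node strength of a multichannel recording.

    The recording is cut into consecutive non-overlapping segments (trailing
    remainder discarded), a connectivity matrix and its node strengths are
    computed per segment, and the per-node mean over segments is returned.
    """
    arr = _as_channels(data)
    n_seg = plan.n_segments(arr.shape[1])
    if n_seg < 1:
        raise InvalidInputError(
            f"no full segment of {plan.segment_length} samples fits in "
            f"{arr.shape[1]}"
        )
    strengths = []
    for k in range(n_seg):
        seg = arr[:, k * plan.segment_length: (k + 1) * plan.segment_length]
        fc = fc_matrix(seg, estimator, grid, cfg, labels=labels)
        strengths.append(node_strength(fc, absolute=absolute))
    return np.mean(strengths, axis=0)
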
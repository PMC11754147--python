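"""Comparison classifiers: single-feature 1NN and 1NN over DTW distances.

The DTW route encodes each recording as a variable-length sequence of
fixation vectors — either ``XYL`` (x, y centre and duration) or ``XYLDxDy``
(adding per-axis dispersion) — and compares subjects with classic
unconstrained dynamic time warping using a Euclidean local cost.  A test
subject inherits the label of its nearest training subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit

from .events import Recording, extract_features

DIMS = {"XYL": 3, "XYLDxDy": 5}


@dataclass
class FixSequence:
    """Temporally ordered fixation vectors of one recording.

    ``scaling`` records the per-dimension affine parameters (mean, std) that
    were applied, or ``None`` for raw values.
    """

    items: np.ndarray
    dims: str
    scaling: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.items = np.asarray(self.items, dtype=np.float64)
        if self.dims not in DIMS:
            raise ValueError(f"dims must be one of {sorted(DIMS)}")
        if self.items.ndim != 2 or self.items.shape[1] != DIMS[self.dims]:
            raise ValueError(
                f"{self.dims} sequence items must have {DIMS[self.dims]} dimensions"
            )

    def __len__(self) -> int:
        return len(self.items)


def to_sequence(
    recording: Recording,
    dims: str = "XYL",
    scaling: tuple[np.ndarray, np.ndarray] | None = None,
) -> FixSequence:
    """Encode a recording's fixations as a (n_fixations, d) sequence."""
    if dims not in DIMS:
        raise ValueError(f"dims must be one of {sorted(DIMS)}")
    rows = []
    for f in recording.fixations:
        row = [f.pos_x, f.pos_y, f.duration_ms]
        if dims == "XYLDxDy":
            if f.disp_x is None or f.disp_y is None:
                raise ValueError(
                    "XYLDxDy encoding requires dispersion on every fixation"
                )
            row += [f.disp_x, f.disp_y]
        rows.append(row)
    items = np.asarray(rows, dtype=np.float64).reshape(len(rows), DIMS[dims])
    if scaling is not None:
        mean, std = (np.asarray(a, dtype=np.float64) for a in scaling)
        items = (items - mean) / std
    return FixSequence(items=items, dims=dims, scaling=scaling)


def fit_standardiser(
    sequences: Sequence[FixSequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension mean/std over all items of a training pool.

    Zero-variance dimensions get std 1 so they pass through centred.
    """
    stacked = np.concatenate([s.items for s in sequences], axis=0)
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)
    std[std == 0.0] = 1.0
    return mean, std


@njit(cache=False)
def _dtw_kernel(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = 0.0
            for k in range(a.shape[1]):
                diff = a[i - 1, k] - b[j - 1, k]
                s += diff * diff
            d = np.sqrt(s)
            best = acc[i - 1, j - 1]
            if acc[i - 1, j] < best:
                best = acc[i - 1, j]
            if acc[i, j - 1] < best:
                best = acc[i, j - 1]
            acc[i, j] = d + best
    return acc[n, m]


def dtw_distance(a: FixSequence, b: FixSequence) -> float:
    """Unconstrained DTW distance with Euclidean local cost.

    Cumulative cost ``D(i,j) = d(a_i, b_j) + min(D(i-1,j), D(i,j-1),
    D(i-1,j-1))``; the returned value is ``D(len(a), len(b))``.  No warping
    window is applied; the sequences here are short enough (hundreds of
    fixations) that the full alignment lattice is cheap.
    """
    if a.dims != b.dims:
        raise ValueError(f"dimension mismatch: {a.dims} vs {b.dims}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("DTW requires sequences of length >= 1")
    return float(_dtw_kernel(a.items, b.items))


def nn1_classify(
    train: Sequence[tuple[object, str]],
    test_item: object,
    distance: Callable[[object, object], float],
) -> str:
    """Label of the nearest training item; ties go to the earliest item.

    Works for scalar features with ``lambda x, y: abs(x - y)`` as well as
    for sequences under :func:`dtw_distance`.
    """
    if not train:
        raise ValueError("1NN requires a non-empty training set")
    best_label, best_dist = None, np.inf
    for item, label in train:
        d = distance(item, test_item)
        if d < best_dist:
            best_label, best_dist = label, d
    return best_label


class FeatureNN1Classifier:
    """1NN on one scalar gaze feature (fit/predict over Recordings)."""

    def __init__(self, feature: str):
        self.feature = feature
        self._train: list[tuple[float, str]] = []

    def fit(self, recordings: Sequence[Recording], labels: Sequence[str]) -> None:
        self._train = [
            (extract_features(r)[self.feature], y)
            for r, y in zip(recordings, labels)
        ]

    def predict(self, recordings: Sequence[Recording]) -> list[str]:
        return [
            nn1_classify(
                self._train,
                extract_features(r)[self.feature],
                lambda x, y: abs(x - y),
            )
            for r in recordings
        ]


class DtwNN1Classifier:
    """1NN with DTW distance over fixation sequences.

    When ``standardise`` is on (default) each dimension is centred and
    scaled by mean/std computed on the training pool only, so screen pixels
    and milliseconds contribute comparably to the Euclidean local cost.
    """

    def __init__(self, dims: str = "XYL", standardise: bool = True):
        self.dims = dims
        self.standardise = standardise
        self._train: list[tuple[FixSequence, str]] = []
        self._scaling: tuple[np.ndarray, np.ndarray] | None = None

    def fit(self, recordings: Sequence[Recording], labels: Sequence[str]) -> None:
        raw = [to_sequence(r, self.dims) for r in recordings]
        self._scaling = fit_standardiser(raw) if self.standardise else None
        self._train = [
            (to_sequence(r, self.dims, self._scaling), y)
            for r, y in zip(recordings, labels)
        ]

    def predict(self, recordings: Sequence[Recording]) -> list[str]:
        return [
            nn1_classify(
                self._train,
                to_sequence(r, self.dims, self._scaling),
                dtw_distance,
            )
            for r in recordings
        ]


def distance_matrix(
    sequences: Sequence[FixSequence],
) -> np.ndarray:
    """Square symmetric DTW distance matrix (useful for inspection/export)."""
    n = len(sequences)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = dtw_distance(sequences[i], sequences[j])
    return mat
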
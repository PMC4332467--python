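"""Reduced feature representations of gait patterns.

Two alternatives to feeding the classifier the full 101-point pattern:

* the six discrete gait parameters of the vertical GRF curve — the two
  force peaks ``Fz1`` (loading response) and ``Fz3`` (push-off), the
  mid-stance valley ``Fz2``, and their occurrence times ``Tz1``, ``Tz2``,
  ``Tz3`` in % of stance;
* principal-component scores of the pattern, keeping the smallest number of
  components whose cumulative explained-variance fraction reaches a target
  (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, DimensionError, ExtractionError, FitError
from .grf import GaitDataset, GaitPattern, N_PATTERN_POINTS

PARAM_NAMES = ("fz1", "tz1", "fz2", "tz2", "fz3", "tz3")

#: default search windows (% stance, inclusive) for the two force peaks
PEAK1_WINDOW = (5, 40)
PEAK2_WINDOW = (60, 95)


@dataclass(frozen=True)
class DiscreteGaitParams:
    """The six scalars extracted from one M-shaped gait pattern.

    Forces in %BW, times in % of stance; ``tz1 < tz2 < tz3`` and the valley
    ``fz2`` does not exceed either peak.
    """

    fz1: float
    tz1: float
    fz2: float
    tz2: float
    fz3: float
    tz3: float
    subject_id: str = ""
    side: str = ""
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.tz1 < self.tz2 < self.tz3 <= 100):
            raise ExtractionError(
                f"times must satisfy 0 <= tz1 < tz2 < tz3 <= 100, got "
                f"({self.tz1}, {self.tz2}, {self.tz3})"
            )
        if self.fz2 > self.fz1 or self.fz2 > self.fz3:
            raise ExtractionError(
                f"valley fz2={self.fz2} exceeds a peak (fz1={self.fz1}, fz3={self.fz3})"
            )

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)


def extract_discrete_params(
    pattern: GaitPattern,
    peak1_window: tuple[int, int] = PEAK1_WINDOW,
    peak2_window: tuple[int, int] = PEAK2_WINDOW,
) -> DiscreteGaitParams:
    """Locate the two peaks and the valley of a gait pattern.

    ``fz1``/``fz3`` are the maxima inside the two search windows, ``fz2`` the
    minimum strictly between their times.  Ties break to the earliest index.
    A curve with no valley between two distinct peaks (e.g. a single bump)
    raises :class:`ExtractionError`.
    """
    v = pattern.values
    lo1, hi1 = int(peak1_window[0]), int(peak1_window[1])
    lo2, hi2 = int(peak2_window[0]), int(peak2_window[1])
    if not (0 <= lo1 <= hi1 < N_PATTERN_POINTS and 0 <= lo2 <= hi2 < N_PATTERN_POINTS):
        raise ExtractionError(f"invalid search windows {peak1_window}, {peak2_window}")
    if hi1 < lo1 or hi2 < lo2:
        raise ExtractionError("empty peak search window")

    i1 = lo1 + int(np.argmax(v[lo1 : hi1 + 1]))
    i3 = lo2 + int(np.argmax(v[lo2 : hi2 + 1]))
    if i3 - i1 < 2:
        raise ExtractionError(
            f"pattern {pattern.key()}: no room for a valley between peaks at {i1} and {i3}"
        )
    i2 = i1 + 1 + int(np.argmin(v[i1 + 1 : i3]))
    try:
        return DiscreteGaitParams(
            fz1=float(v[i1]),
            tz1=float(i1),
            fz2=float(v[i2]),
            tz2=float(i2),
            fz3=float(v[i3]),
            tz3=float(i3),
            subject_id=pattern.subject_id,
            side=pattern.side,
            trial_id=pattern.trial_id,
        )
    except ExtractionError as err:
        raise ExtractionError(f"pattern {pattern.key()} is not M-shaped: {err}") from None


def discrete_params_frame(
    dataset: GaitDataset,
    peak1_window: tuple[int, int] = PEAK1_WINDOW,
    peak2_window: tuple[int, int] = PEAK2_WINDOW,
) -> pd.DataFrame:
    """Extract the six parameters for every pattern of a dataset.

    Returns a DataFrame with columns ``subject_id, side, trial_id, fz1, tz1,
    fz2, tz2, fz3, tz3``.  If any pattern fails extraction the error lists
    all offending trials.
    """
    rows, failures = [], []
    for p in dataset.patterns:
        try:
            d = extract_discrete_params(p, peak1_window, peak2_window)
        except ExtractionError as err:
            failures.append(f"{p.key()}: {err}")
            continue
        rows.append((p.subject_id, p.side, p.trial_id, *(getattr(d, n) for n in PARAM_NAMES)))
    if failures:
        raise ExtractionError(
            f"{len(failures)} pattern(s) failed parameter extraction:\n  " + "\n  ".join(failures)
        )
    return pd.DataFrame(rows, columns=["subject_id", "side", "trial_id", *PARAM_NAMES])


def write_discrete_params(frame: pd.DataFrame, path: str | Path) -> None:
    """Export a discrete-parameter table (units: %BW and % stance)."""
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PCA features
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    """A fitted PCA basis for gait patterns.

    ``components`` holds the full orthonormal basis (rows); the feature
    vector returned by :func:`transform_pca` uses the first
    ``n_components_kept`` of them.
    """

    mean_vector: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components_kept: int
    variance_fraction: float


def _as_matrix(patterns) -> np.ndarray:
    if isinstance(patterns, GaitDataset):
        return np.vstack([p.values for p in patterns.patterns])
    if isinstance(patterns, np.ndarray):
        return np.asarray(patterns, dtype=float)
    return np.vstack([np.asarray(p.values if isinstance(p, GaitPattern) else p, dtype=float) for p in patterns])


def fit_pca(training_patterns, variance_fraction: float = 0.95) -> PcaModel:
    """Fit PCA on training patterns and pick how many components to keep.

    Mean-centering followed by an eigendecomposition of the sample
    covariance (n-1 denominator); ``n_components_kept`` is the smallest k
    whose cumulative explained-variance fraction reaches
    ``variance_fraction``.  Fit this on training folds only — the basis must
    not see test data.
    """
    if not 0 < variance_fraction <= 1:
        raise FitError(f"variance_fraction must be in (0, 1], got {variance_fraction}")
    X = _as_matrix(training_patterns)
    if X.ndim != 2 or X.shape[0] < 2:
        raise FitError(f"PCA needs at least 2 training patterns, got shape {X.shape}")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateDataError("training patterns have zero variance; PCA is undefined")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    ratio = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(ratio), variance_fraction - 1e-12) + 1)
    k = min(k, ratio.size)
    return PcaModel(
        mean_vector=pca.mean_,
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=ratio,
        n_components_kept=k,
        variance_fraction=variance_fraction,
    )


def transform_pca(model: PcaModel, pattern) -> np.ndarray:
    """Project mean-centered pattern(s) onto the kept components.

    Accepts a :class:`GaitPattern`, a 1-D vector, or an (n, d) matrix;
    returns features of length ``n_components_kept`` (or an (n, k) matrix).
    """
    x = pattern.values if isinstance(pattern, GaitPattern) else np.asarray(pattern, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.mean_vector.size:
        raise DimensionError(
            f"pattern length {X.shape[1]} does not match PCA dimension {model.mean_vector.size}"
        )
    F = (X - model.mean_vector) @ model.components[: model.n_components_kept].T
    return F[0] if single else F
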
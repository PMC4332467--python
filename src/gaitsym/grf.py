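"""Data model, I/O and preprocessing for stance-phase vertical ground-reaction forces.

A force platform records the vertical ground-reaction force (GRF) of one
isolated step at a fixed sampling rate.  This module turns such recordings
into *gait patterns*: the force expressed in percent bodyweight (%BW),
resampled onto 101 equally spaced points covering 0..100 % of stance
duration (1 % spacing, endpoints included).  The 101-sample pattern is the
unit of analysis for both the symmetry-index protocol and the left/right
classifier.

File formats
------------
Trials travel as a "long" CSV with columns ``subject_id, side, trial_id,
sample_index, force_n, bodyweight_n, sampling_rate_hz`` (side tokens
``left|L|l`` / ``right|R|r``; bodyweight constant per subject, sampling rate
constant per file).  Patterns travel as a wide CSV with columns
``subject_id, side, trial_id, label, v000..v100``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    EmptyStanceError,
    FormatError,
    IntegrityError,
    ParseError,
    TooShortError,
)

N_PATTERN_POINTS = 101
#: columns of the long trial CSV dialect, in canonical order
TRIAL_COLUMNS = (
    "subject_id",
    "side",
    "trial_id",
    "sample_index",
    "force_n",
    "bodyweight_n",
    "sampling_rate_hz",
)

_SIDE_TOKENS = {"left": "left", "l": "left", "right": "right", "r": "right"}


def canonical_side(token: str) -> str:
    """Map an accepted side token (``left|L|l|right|R|r``) to ``left``/``right``."""
    try:
        return _SIDE_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise FormatError(f"unrecognized side token {token!r}; accepted: left|L|l|right|R|r")


@dataclass(frozen=True)
class ForceTrial:
    """One raw stance-phase vertical GRF recording.

    ``samples`` are vertical forces, in Newtons for raw recordings or in %BW
    after :func:`normalize_bodyweight` (tracked by ``units``).
    """

    subject_id: str
    side: str
    trial_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    bodyweight_n: float
    units: str = "N"

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", canonical_side(self.side))
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise DomainError(
                f"trial {self.key()} needs a one-dimensional sample sequence, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise DomainError(f"trial {self.key()} contains non-finite force samples")
        if not self.sampling_rate_hz > 0:
            raise DomainError(f"sampling_rate_hz must be positive, got {self.sampling_rate_hz}")
        if not self.bodyweight_n > 0:
            raise DomainError(f"bodyweight_n must be positive, got {self.bodyweight_n}")

    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.side, self.trial_id)


@dataclass(frozen=True)
class GaitPattern:
    """A 101-sample normalized stance curve (%BW at each 1 % of stance).

    The class label used throughout the package is +1 for right-side and
    -1 for left-side patterns.
    """

    subject_id: str
    side: str
    trial_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "side", canonical_side(self.side))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (N_PATTERN_POINTS,):
            raise DomainError(
                f"gait pattern must have exactly {N_PATTERN_POINTS} values, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise DomainError(f"pattern {self.key()} contains non-finite values")
        if np.any(values < 0):
            raise DomainError(f"pattern {self.key()} contains negative %BW values")

    @property
    def label(self) -> int:
        """+1 for right, -1 for left."""
        return 1 if self.side == "right" else -1

    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.side, self.trial_id)


@dataclass
class GaitDataset:
    """A collection of gait patterns with unique (subject, side, trial) keys."""

    patterns: list[GaitPattern]
    provenance: str = ""

    def __post_init__(self) -> None:
        keys = [p.key() for p in self.patterns]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise IntegrityError(f"duplicate (subject, side, trial) keys: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.patterns)

    def matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (values array n x 101, labels ±1, subject ids) in pattern order."""
        X = np.vstack([p.values for p in self.patterns])
        y = np.array([p.label for p in self.patterns], dtype=float)
        subjects = np.array([p.subject_id for p in self.patterns], dtype=object)
        return X, y, subjects


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_trials(path: str | Path) -> list[ForceTrial]:
    """Read force trials from the long-CSV dialect.

    Raises :class:`FormatError` for a missing column or bad side token,
    :class:`ParseError` (with row number) for a non-numeric value, and
    :class:`IntegrityError` for duplicate sample rows or inconsistent
    per-subject bodyweight / per-file sampling rate.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    numeric = {}
    for col in ("sample_index", "force_n", "bodyweight_n", "sampling_rate_hz"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric {col} value {df[col][bad.idxmax()]!r} at row {row}")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise ParseError(f"{path}: empty {col} value at row {row}")
        numeric[col] = parsed
    df = df.assign(**numeric)
    df["side"] = df["side"].map(canonical_side)

    dup = df.duplicated(subset=["subject_id", "side", "trial_id", "sample_index"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise IntegrityError(f"{path}: duplicate (subject, side, trial, sample_index) at row {row}")
    if df["sampling_rate_hz"].nunique() != 1:
        raise IntegrityError(f"{path}: sampling_rate_hz must be constant per file")
    for subj, grp in df.groupby("subject_id"):
        if grp["bodyweight_n"].nunique() != 1:
            raise IntegrityError(f"{path}: bodyweight_n not constant for subject {subj!r}")

    trials = []
    for (subj, side, trial), grp in df.groupby(["subject_id", "side", "trial_id"], sort=True):
        grp = grp.sort_values("sample_index")
        trials.append(
            ForceTrial(
                subject_id=str(subj),
                side=str(side),
                trial_id=str(trial),
                samples=grp["force_n"].to_numpy(dtype=float),
                sampling_rate_hz=float(grp["sampling_rate_hz"].iloc[0]),
                bodyweight_n=float(grp["bodyweight_n"].iloc[0]),
            )
        )
    return trials


def write_trials(trials: Iterable[ForceTrial], path: str | Path) -> None:
    """Write trials in the long-CSV dialect (inverse of :func:`read_trials`)."""
    rows = []
    for t in trials:
        for i, f in enumerate(t.samples):
            rows.append((t.subject_id, t.side, t.trial_id, i, f, t.bodyweight_n, t.sampling_rate_hz))
    df = pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
    df.to_csv(path, index=False)


PATTERN_VALUE_COLUMNS = tuple(f"v{i:03d}" for i in range(N_PATTERN_POINTS))


def write_patterns(dataset: GaitDataset, path: str | Path) -> None:
    """Write a pattern CSV: subject_id, side, trial_id, label, v000..v100."""
    rows = []
    for p in dataset.patterns:
        rows.append([p.subject_id, p.side, p.trial_id, p.label, *p.values])
    df = pd.DataFrame(rows, columns=["subject_id", "side", "trial_id", "label", *PATTERN_VALUE_COLUMNS])
    df.to_csv(path, index=False)


def read_patterns(path: str | Path) -> GaitDataset:
    """Read a pattern CSV written by :func:`write_patterns`."""
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "side": str, "trial_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in ("subject_id", "side", "trial_id", *PATTERN_VALUE_COLUMNS) if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing[0]} (+{len(missing) - 1} more)")
    patterns = []
    for _, row in df.iterrows():
        patterns.append(
            GaitPattern(
                subject_id=str(row["subject_id"]),
                side=str(row["side"]),
                trial_id=str(row["trial_id"]),
                values=row[list(PATTERN_VALUE_COLUMNS)].to_numpy(dtype=float),
            )
        )
    return GaitDataset(patterns, provenance=f"read from {path}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def normalize_bodyweight(trial: ForceTrial) -> ForceTrial:
    """Express forces in percent bodyweight: 100 * F / bodyweight."""
    if not trial.bodyweight_n > 0:
        raise DomainError(f"bodyweight must be positive, got {trial.bodyweight_n}")
    return replace(trial, samples=100.0 * trial.samples / trial.bodyweight_n, units="%BW")


def clip_negative(trial: ForceTrial) -> ForceTrial:
    """Clip negative force readings (sensor noise) to zero."""
    return replace(trial, samples=np.maximum(trial.samples, 0.0))


def segment_stance(trial: ForceTrial, threshold_pct_bw: float = 5.0) -> ForceTrial:
    """Crop a bodyweight-normalized trial to its stance phase.

    Stance is the longest contiguous run of samples at or above the threshold,
    extended by one sample on each side when available (so the curve re-enters
    the near-zero flanks).  Sub-threshold padding before/after stance does not
    affect the result.
    """
    if threshold_pct_bw <= 0:
        raise DomainError(f"threshold_pct_bw must be positive, got {threshold_pct_bw}")
    s = trial.samples
    above = s >= threshold_pct_bw
    if not above.any():
        raise EmptyStanceError(f"trial {trial.key()}: no sample reaches {threshold_pct_bw} %BW")
    # contiguous runs of True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    starts, stops = edges[0::2], edges[1::2]
    best = int(np.argmax(stops - starts))
    lo = max(starts[best] - 1, 0)
    hi = min(stops[best] + 1, s.size)
    if hi - lo < 4:
        raise TooShortError(f"trial {trial.key()}: stance segment of {hi - lo} samples is too short")
    return replace(trial, samples=s[lo:hi])


def time_normalize(trial: ForceTrial) -> GaitPattern:
    """Resample a stance-cropped, %BW trial onto 101 points over 0..100 % stance.

    Piecewise-linear interpolation; the values at 0 % and 100 % equal the
    first and last stance sample exactly.
    """
    s = trial.samples
    if not np.all(np.isfinite(s)):
        raise DomainError(f"trial {trial.key()} contains non-finite samples")
    if s.size < 4:
        raise TooShortError(f"trial {trial.key()}: {s.size} samples < 4")
    grid = np.linspace(0.0, 100.0, N_PATTERN_POINTS)
    support = np.linspace(0.0, 100.0, s.size)
    values = np.interp(grid, support, s)
    return GaitPattern(trial.subject_id, trial.side, trial.trial_id, values)


def preprocess_trial(
    trial: ForceTrial,
    threshold_pct_bw: float = 5.0,
    clip_negatives: bool = True,
) -> GaitPattern:
    """Raw Newtons trial -> 101-point %BW gait pattern.

    Pipeline: bodyweight normalization, optional clipping of negative
    readings, stance segmentation at ``threshold_pct_bw``, time
    normalization.
    """
    t = normalize_bodyweight(trial)
    if clip_negatives:
        t = clip_negative(t)
    t = segment_stance(t, threshold_pct_bw=threshold_pct_bw)
    return time_normalize(t)


def preprocess_trials(
    trials: Iterable[ForceTrial],
    threshold_pct_bw: float = 5.0,
    clip_negatives: bool = True,
    provenance: str = "",
) -> GaitDataset:
    """Apply :func:`preprocess_trial` to every trial and collect a dataset."""
    patterns = [
        preprocess_trial(t, threshold_pct_bw=threshold_pct_bw, clip_negatives=clip_negatives)
        for t in trials
    ]
    return GaitDataset(patterns, provenance=provenance)


def subject_mean_patterns(dataset: GaitDataset) -> GaitDataset:
    """Average each subject/side's trial patterns into one mean pattern.

    This is the default classification unit: one pattern per subject per
    side, so a 60-subject cohort yields 120 patterns (60 right, 60 left).
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for p in dataset.patterns:
        groups.setdefault((p.subject_id, p.side), []).append(p.values)
    patterns = [
        GaitPattern(subj, side, "mean", np.mean(vals, axis=0))
        for (subj, side), vals in sorted(groups.items())
    ]
    return GaitDataset(patterns, provenance=f"subject means of: {dataset.provenance}")
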
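"""The classical symmetry-index protocol for discrete gait parameters.

For each of the six vertical-GRF parameters this module computes, per side,
the trial-to-trial coefficient of variation (CV = SD/mean x 100, repeatable
when CV <= 12.5 %), Robinson's absolute symmetry index
SI = 2|X_R - X_L| / (X_R + X_L) x 100 (acceptable when SI < 10 %), and a
paired two-sided t-test of the left-right difference across subjects
(significant when p <= 0.05).  Sample standard deviations use the n-1
denominator throughout; p-values are probabilities in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, DomainError, ReportError
from .features import PARAM_NAMES

logger = logging.getLogger(__name__)

CV_ACCEPTABLE_PCT = 12.5
SI_ACCEPTABLE_PCT = 10.0
SIGNIFICANCE_LEVEL = 0.05


def coefficient_of_variation(values: Sequence[float]) -> float:
    """CV in percent: 100 * sample SD / mean (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError(f"CV needs at least 2 values, got {v.size}")
    m = v.mean()
    if m == 0:
        raise DomainError("CV is undefined for zero-mean values")
    return float(100.0 * v.std(ddof=1) / m)


def symmetry_index(x_right: float, x_left: float) -> float:
    """Absolute symmetry index in percent: 2|X_R - X_L| / (X_R + X_L) x 100."""
    denom = x_right + x_left
    if denom == 0:
        raise DomainError("symmetry index is undefined when X_R + X_L = 0")
    return float(200.0 * abs(x_right - x_left) / denom)


def paired_t_test(left_values: Sequence[float], right_values: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test of right - left differences.

    Returns ``(t, p)`` with ``p`` in [0, 1].  Identical sequences give
    ``(0, 1)``; constant nonzero differences raise
    :class:`DegenerateVarianceError` (the statistic diverges).
    """
    left = np.asarray(left_values, dtype=float)
    right = np.asarray(right_values, dtype=float)
    if left.shape != right.shape:
        raise DomainError(f"paired samples must have equal length, got {left.shape} vs {right.shape}")
    n = left.size
    if n < 2:
        raise DomainError(f"paired t-test needs n >= 2, got {n}")
    d = right - left
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        raise DegenerateVarianceError(
            f"differences are constant ({d[0]}) with zero variance; t statistic diverges"
        )
    res = stats.ttest_rel(right, left)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ParamSummary:
    """Per-parameter row of the symmetry report (one line of the classical table)."""

    parameter_name: str
    left_mean: float
    right_mean: float
    left_cv_pct: float
    right_cv_pct: float
    si_pct: float
    p_value: float

    @property
    def cv_acceptable(self) -> bool:
        return self.left_cv_pct <= CV_ACCEPTABLE_PCT and self.right_cv_pct <= CV_ACCEPTABLE_PCT

    @property
    def si_acceptable(self) -> bool:
        return self.si_pct < SI_ACCEPTABLE_PCT

    @property
    def significant_difference(self) -> bool:
        return self.p_value <= SIGNIFICANCE_LEVEL


@dataclass
class SiReport:
    """The full six-parameter symmetry report."""

    summaries: list[ParamSummary]
    n_subjects: int
    aggregation: str

    def __post_init__(self) -> None:
        names = [s.parameter_name for s in self.summaries]
        if len(set(names)) != len(names):
            raise ReportError(f"duplicate parameter names in report: {names}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": s.parameter_name,
                    "left_cv_pct": s.left_cv_pct,
                    "left_mean": s.left_mean,
                    "right_cv_pct": s.right_cv_pct,
                    "right_mean": s.right_mean,
                    "si_pct": s.si_pct,
                    "p_value": s.p_value,
                    "cv_acceptable": s.cv_acceptable,
                    "si_acceptable": s.si_acceptable,
                    "significant_difference": s.significant_difference,
                }
                for s in self.summaries
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def render_text(self) -> str:
        lines = [
            f"Symmetry report ({self.n_subjects} subjects, aggregation: {self.aggregation})",
            f"{'param':<6} {'L CV%':>7} {'L mean':>8} {'R CV%':>7} {'R mean':>8} "
            f"{'SI%':>7} {'p':>8}  flags",
        ]
        for s in self.summaries:
            flags = []
            flags.append("CV:ok" if s.cv_acceptable else "CV:high")
            flags.append("SI:ok" if s.si_acceptable else "SI:high")
            flags.append("p:sig" if s.significant_difference else "p:ns")
            lines.append(
                f"{s.parameter_name:<6} {s.left_cv_pct:>7.2f} {s.left_mean:>8.2f} "
                f"{s.right_cv_pct:>7.2f} {s.right_mean:>8.2f} {s.si_pct:>7.2f} "
                f"{s.p_value:>8.4f}  {' '.join(flags)}"
            )
        return "\n".join(lines)


def build_si_report(
    params: pd.DataFrame,
    aggregation: str = "per_subject_then_mean",
    parameter_names: Sequence[str] = PARAM_NAMES,
) -> SiReport:
    """Build the classical symmetry report from a discrete-parameter table.

    ``params`` has one row per trial with columns ``subject_id, side`` plus
    the parameter columns (see
    :func:`gaitsym.features.discrete_params_frame`).  Per subject and side,
    trials are averaged; the CV is computed per subject/side over trials and
    then averaged across subjects; the paired t-test runs on subject-level
    side means.

    ``aggregation`` controls the SI column: ``per_subject_then_mean``
    (default) averages each subject's own SI; ``si_of_group_means`` applies
    the SI formula once to the group means.

    Subjects missing one side are excluded with a logged warning; at least
    two complete subjects are required.
    """
    if aggregation not in ("per_subject_then_mean", "si_of_group_means"):
        raise ReportError(f"unknown aggregation {aggregation!r}")
    required = {"subject_id", "side", *parameter_names}
    missing = required - set(params.columns)
    if missing:
        raise ReportError(f"parameter table is missing columns: {sorted(missing)}")

    sides_per_subject = params.groupby("subject_id")["side"].agg(lambda s: frozenset(s))
    complete = sorted(sides_per_subject.index[sides_per_subject == frozenset({"left", "right"})])
    dropped = sorted(set(sides_per_subject.index) - set(complete))
    if dropped:
        logger.warning("excluding %d subject(s) missing one side: %s", len(dropped), dropped)
    if len(complete) < 2:
        raise ReportError(f"need >= 2 subjects with both sides, got {len(complete)}")
    data = params[params["subject_id"].isin(complete)]

    summaries = []
    for name in parameter_names:
        grouped = data.groupby(["subject_id", "side"])[name]
        means = grouped.mean().unstack("side").loc[complete]
        n_trials = grouped.size()
        if (n_trials < 2).any():
            bad = n_trials.index[n_trials < 2].tolist()
            raise ReportError(f"CV needs >= 2 trials per subject/side; too few for {bad[:5]}")
        cvs = grouped.agg(coefficient_of_variation).unstack("side").loc[complete]

        if aggregation == "per_subject_then_mean":
            si = float(
                np.mean([symmetry_index(r, l) for l, r in zip(means["left"], means["right"])])
            )
        else:
            si = symmetry_index(float(means["right"].mean()), float(means["left"].mean()))
        _, p = paired_t_test(means["left"].to_numpy(), means["right"].to_numpy())
        summaries.append(
            ParamSummary(
                parameter_name=name,
                left_mean=float(means["left"].mean()),
                right_mean=float(means["right"].mean()),
                left_cv_pct=float(cvs["left"].mean()),
                right_cv_pct=float(cvs["right"].mean()),
                si_pct=si,
                p_value=p,
            )
        )
    return SiReport(summaries=summaries, n_subjects=len(complete), aggregation=aggregation)
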
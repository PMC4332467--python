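"""Synthetic stance-phase vertical GRF cohorts with controllable asymmetry.

The generator emulates the statistical structure of a healthy-walking force
platform study: M-shaped vertical GRF curves parameterized by the six
discrete gait parameters (loading-response peak Fz1, mid-stance valley Fz2,
push-off peak Fz3, and their times Tz1 < Tz2 < Tz3 in % stance),
between-subject variation of those parameters, multiplicative
within-subject trial-to-trial jitter at the coefficient-of-variation scale
reported for such parameters (roughly 4-10 %), additive measurement noise
in Newtons, and a per-parameter multiplicative left-right asymmetry delta
applied to the right side.

Defaults are a 60-subject cohort, 10 trials per side, 400 Hz sampling,
population means 114 / 75 / 110 %BW at 23 / 49 / 77 % stance.

The waveform family is a monotone cubic (PCHIP) interpolant through the
knots (0, 0), (Tz1, Fz1), (Tz2, Fz2), (Tz3, Fz3), (100, 0).  Because the
interpolant is monotone between knots, its interior local extrema sit
*exactly* at the three (time, force) pairs, so the generator's truth maps
one-to-one onto what discrete-parameter extraction should recover.  The
curve is smooth and M-shaped but not physiological beyond its extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from ._random import substream
from .errors import GeneratorError
from .features import PARAM_NAMES
from .grf import ForceTrial, GaitDataset, preprocess_trials

DEFAULT_PARAM_MEANS = {"fz1": 114.0, "tz1": 23.0, "fz2": 75.0, "tz2": 49.0, "fz3": 110.0, "tz3": 77.0}
#: within-subject trial-to-trial CVs (fractions), per parameter
DEFAULT_WITHIN_CV = {"fz1": 0.087, "tz1": 0.092, "fz2": 0.069, "tz2": 0.054, "fz3": 0.086, "tz3": 0.044}
#: between-subject spread at the same relative scale
DEFAULT_BETWEEN_CV = dict(DEFAULT_WITHIN_CV)


@dataclass(frozen=True)
class CurveParams:
    """True parameters of one M-shaped stance curve (forces %BW, times % stance)."""

    fz1: float
    tz1: float
    fz2: float
    tz2: float
    fz3: float
    tz3: float
    stance_duration_s: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.tz1 < self.tz2 < self.tz3 < 100):
            raise GeneratorError(
                f"times must satisfy 0 < tz1 < tz2 < tz3 < 100, got "
                f"({self.tz1}, {self.tz2}, {self.tz3})"
            )
        if min(self.fz1, self.fz2, self.fz3) <= 0:
            raise GeneratorError("force amplitudes must be positive")
        if self.fz2 >= min(self.fz1, self.fz3):
            raise GeneratorError(
                f"valley fz2={self.fz2} must lie below both peaks ({self.fz1}, {self.fz3})"
            )
        if not self.stance_duration_s > 0:
            raise GeneratorError("stance duration must be positive")

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}


def curve(params: CurveParams, t) -> np.ndarray:
    """Evaluate the noiseless %BW curve at stance percentages ``t`` in [0, 100].

    Zero at both ends of stance; local extrema exactly at
    (tz1, fz1), (tz2, fz2), (tz3, fz3).
    """
    knots_t = np.array([0.0, params.tz1, params.tz2, params.tz3, 100.0])
    knots_v = np.array([0.0, params.fz1, params.fz2, params.fz3, 0.0])
    interp = PchipInterpolator(knots_t, knots_v)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 100):
        raise GeneratorError("stance percentage must lie in [0, 100]")
    v = np.asarray(interp(t), dtype=float)
    # the interpolant is exact at the knots up to float noise; pin the closure
    return np.where((t == 0.0) | (t == 100.0), 0.0, v)


@dataclass(frozen=True)
class CohortConfig:
    """Study-scale configuration of a synthetic cohort.

    ``asymmetry`` maps parameter names to multiplicative deltas applied to
    the right side (e.g. ``{"fz1": 0.05}`` makes the right first peak 5 %
    higher); deltas must exceed -1.  All CVs are fractions, not percent.
    """

    n_subjects: int = 60
    trials_per_side: int = 10
    param_means: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_MEANS))
    between_subject_cv: dict = field(default_factory=lambda: dict(DEFAULT_BETWEEN_CV))
    within_trial_cv: dict = field(default_factory=lambda: dict(DEFAULT_WITHIN_CV))
    asymmetry: dict = field(default_factory=dict)
    bodyweight_mean_n: float = 700.0
    bodyweight_sd_n: float = 70.0
    sampling_rate_hz: float = 400.0
    stance_mean_s: float = 0.7
    stance_sd_s: float = 0.05
    noise_n: float = 3.0
    pad_s: float = 0.05
    force_correlation: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name, d in (("between_subject_cv", self.between_subject_cv),
                        ("within_trial_cv", self.within_trial_cv)):
            if any(v < 0 for v in d.values()):
                raise GeneratorError(f"{name} entries must be >= 0")
        if any(v <= -1 for v in self.asymmetry.values()):
            raise GeneratorError("asymmetry deltas must be > -1")
        unknown = set(self.asymmetry) - set(PARAM_NAMES)
        if unknown:
            raise GeneratorError(f"unknown asymmetry parameter(s): {sorted(unknown)}")
        if self.n_subjects < 1 or self.trials_per_side < 1:
            raise GeneratorError("cohort needs at least one subject and one trial per side")
        if not 0 <= self.force_correlation <= 1:
            raise GeneratorError("force_correlation must lie in [0, 1]")


_TIME_MARGIN = 2.0  # % stance kept between ordered time parameters when clamping
_VALLEY_RATIO = 0.98  # valley forced below this fraction of the lower peak


def _clamp_params(raw: dict[str, float]) -> tuple[dict[str, float], bool]:
    """Force a parameter draw back into the valid M-shape region.

    Returns the (possibly adjusted) parameters and whether anything moved.
    """
    p = dict(raw)
    for name in ("fz1", "fz2", "fz3"):
        p[name] = max(p[name], 1.0)
    lo = _TIME_MARGIN
    for name in ("tz1", "tz2", "tz3"):
        p[name] = max(p[name], lo)
        lo = p[name] + _TIME_MARGIN
    if p["tz3"] > 100 - _TIME_MARGIN:
        p["tz3"] = 100 - _TIME_MARGIN
        p["tz2"] = min(p["tz2"], p["tz3"] - _TIME_MARGIN)
        p["tz1"] = min(p["tz1"], p["tz2"] - _TIME_MARGIN)
    peak_floor = min(p["fz1"], p["fz3"]) * _VALLEY_RATIO
    p["fz2"] = min(p["fz2"], peak_floor)
    clamped = any(abs(p[n] - raw[n]) > 1e-12 for n in p)
    return p, clamped


def _jitter(
    rng: np.random.Generator,
    base: dict[str, float],
    cv: dict[str, float],
    force_correlation: float,
) -> tuple[dict[str, float], bool]:
    """One multiplicative parameter draw around ``base``.

    The three force amplitudes share a common loading factor with pairwise
    correlation ``force_correlation`` (vertical-GRF peaks and valley rise
    and fall together with loading and speed); each parameter's marginal CV
    is exactly the configured one.  Times are drawn independently.
    """
    z_common = rng.standard_normal()
    w_common = np.sqrt(force_correlation)
    w_indep = np.sqrt(1.0 - force_correlation)
    drawn = {}
    for n in PARAM_NAMES:
        z = rng.standard_normal()
        if n.startswith("fz"):
            z = w_common * z_common + w_indep * z
        drawn[n] = base[n] * (1.0 + cv.get(n, 0.0) * z)
    return _clamp_params(drawn)


def sample_cohort(config: CohortConfig) -> tuple[list[ForceTrial], pd.DataFrame]:
    """Draw a full cohort of raw force trials plus the ground-truth table.

    Per subject: subject-level parameters are drawn around the population
    means (between-subject CV), the right side applies the asymmetry deltas,
    and every trial jitters each parameter multiplicatively (within-subject
    CV), renders the curve at the sampling rate over a drawn stance
    duration, converts %BW to Newtons via the subject's bodyweight, adds
    white measurement noise, and pads both ends with noise-only samples.

    Each subject consumes an independent random sub-stream, so enlarging the
    cohort never changes earlier subjects' draws.
    """
    trials: list[ForceTrial] = []
    truth_rows = []
    n_draws = 0
    n_clamped = 0
    for s in range(config.n_subjects):
        rng = substream(config.seed, "cohort", s)
        subject_id = f"S{s:03d}"
        bw = float(rng.normal(config.bodyweight_mean_n, config.bodyweight_sd_n))
        bw = max(bw, 0.3 * config.bodyweight_mean_n)
        base, clamped = _jitter(rng, config.param_means, config.between_subject_cv, config.force_correlation)
        n_draws += 1
        n_clamped += clamped
        for side in ("left", "right"):
            if side == "right":
                shifted = {
                    n: base[n] * (1.0 + config.asymmetry.get(n, 0.0)) for n in PARAM_NAMES
                }
                side_params, clamped = _clamp_params(shifted)
                n_clamped += clamped
                n_draws += 1
            else:
                side_params = base
            for trial in range(config.trials_per_side):
                trial_params, clamped = _jitter(rng, side_params, config.within_trial_cv, config.force_correlation)
                n_draws += 1
                n_clamped += clamped
                duration = max(float(rng.normal(config.stance_mean_s, config.stance_sd_s)), 0.2)
                cp = CurveParams(**trial_params, stance_duration_s=duration)
                n_samples = max(int(round(duration * config.sampling_rate_hz)), 4)
                pct = curve(cp, np.linspace(0.0, 100.0, n_samples))
                force = pct * bw / 100.0
                n_pad = int(round(config.pad_s * config.sampling_rate_hz))
                samples = np.concatenate((np.zeros(n_pad), force, np.zeros(n_pad)))
                if config.noise_n > 0:
                    samples = samples + rng.normal(0.0, config.noise_n, samples.size)
                trials.append(
                    ForceTrial(
                        subject_id=subject_id,
                        side=side,
                        trial_id=f"T{trial:02d}",
                        samples=samples,
                        sampling_rate_hz=config.sampling_rate_hz,
                        bodyweight_n=bw,
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": subject_id,
                        "side": side,
                        "trial_id": f"T{trial:02d}",
                        "bodyweight_n": bw,
                        "stance_duration_s": duration,
                        **{f"true_{n}": trial_params[n] for n in PARAM_NAMES},
                        **{f"delta_{n}": config.asymmetry.get(n, 0.0) for n in PARAM_NAMES},
                    }
                )
    # clamps cluster on subjects whose base draw landed near a boundary, so a
    # raw >1 % rate fires spuriously in small cohorts; require volume too
    if n_clamped > 0.01 * n_draws and n_clamped >= 10:
        warnings.warn(
            f"{n_clamped}/{n_draws} parameter draws needed clamping; "
            "configured spreads may be too wide for a valid M-shape",
            stacklevel=2,
        )
    return trials, pd.DataFrame(truth_rows)


def simulate_patterns(config: CohortConfig, threshold_pct_bw: float = 5.0) -> tuple[GaitDataset, pd.DataFrame]:
    """Convenience: draw a cohort and run the full preprocessing pipeline."""
    trials, truth = sample_cohort(config)
    dataset = preprocess_trials(
        trials,
        threshold_pct_bw=threshold_pct_bw,
        provenance=f"synthetic cohort (seed={config.seed}, n={config.n_subjects})",
    )
    return dataset, truth
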
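"""Per-finger calibration from unimanual force-hold trials.

Each unimanual trial asks a participant to hold one finger at a target
force for ~7 s while force is sampled at ~200 Hz.  From a session of such
trials we estimate, per finger:

* the coefficient of variation ``k`` — the slope of a no-intercept robust
  regression of within-trial force SD on within-trial mean force
  (signal-dependent noise: ``sigma(x) = k * u`` passes through the
  origin), and
* the maximum voluntary contraction (MVC) — the highest target level the
  finger could actually maintain over the analysis window.

The analysis window defaults to the middle of the trial (drop the first
~1.5 s ramp-up and the final ~0.5 s), expressed as fractions of the
recording so it adapts to any duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "TrialRecording",
    "TrialSummary",
    "AssociationResult",
    "DEFAULT_WINDOW",
    "trial_summary",
    "estimate_cv",
    "estimate_mvc",
    "cv_mvc_association",
]

# middle 5 s of a nominal 7 s trial: skip 1.5 s ramp, drop final 0.5 s
DEFAULT_WINDOW: Tuple[float, float] = (1.5 / 7.0, 6.5 / 7.0)

BISQUARE_TUNING = 4.685  # 95% efficiency under Gaussian errors
IRLS_TOL = 1e-8
IRLS_MAXITER = 100


class CalibrationError(ValueError):
    """Raised when trial data cannot support the requested estimate."""


@dataclass(frozen=True)
class TrialRecording:
    """One unimanual force hold: a sampled force series at a target level."""

    finger_id: str
    target_g: float
    samples: np.ndarray
    rate: float = 200.0
    participant_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.size == 0:
            raise ValueError("samples must be non-empty")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class TrialSummary:
    """Windowed mean and SD of one trial's force samples."""

    target_g: float
    mean_force: float
    sd_force: float
    n_samples: int


def trial_summary(
    rec: TrialRecording, window: Tuple[float, float] = DEFAULT_WINDOW
) -> TrialSummary:
    """Mean and SD (ddof=1) of the samples inside the analysis window.

    ``window`` is a ``(start, end)`` pair of fractions of the recording.
    """
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"window must satisfy 0 <= start < end <= 1, got {window}")
    n = rec.samples.size
    i0, i1 = int(math.floor(lo * n)), int(math.ceil(hi * n))
    kept = rec.samples[i0:i1]
    if kept.size < 2:
        raise CalibrationError("analysis window retains fewer than 2 samples")
    return TrialSummary(
        target_g=rec.target_g,
        mean_force=float(np.mean(kept)),
        sd_force=float(np.std(kept, ddof=1)),
        n_samples=int(kept.size),
    )


def estimate_cv(summaries: Sequence[TrialSummary]) -> float:
    """Coefficient of variation: robust no-intercept slope of SD on mean.

    Iteratively re-weighted least squares with a bisquare (Tukey biweight)
    weighting function, through the origin.  Falls back to the plain
    least-squares slope when the fit is exact (zero residuals leave the
    robust scale undefined).
    """
    summaries = list(summaries)
    if len(summaries) < 3:
        raise CalibrationError("need >= 3 force levels to estimate k")
    mean = np.array([s.mean_force for s in summaries])
    sd = np.array([s.sd_force for s in summaries])
    if len(np.unique(np.round(mean, 12))) < 3:
        raise CalibrationError("need >= 3 distinct mean forces")
    if np.allclose(mean, 0.0):
        raise CalibrationError("all mean forces are zero")

    ols_slope = float(mean @ sd / (mean @ mean))
    resid = sd - ols_slope * mean
    scale = np.max(np.abs(sd)) if np.any(sd != 0) else 1.0
    if np.max(np.abs(resid)) <= 1e-12 * max(scale, 1.0):
        return ols_slope

    rlm = sm.RLM(sd, mean[:, None], M=sm.robust.norms.TukeyBiweight(BISQUARE_TUNING))
    fit = rlm.fit(conv="coefs", tol=IRLS_TOL, maxiter=IRLS_MAXITER)
    return float(fit.params[0])


def estimate_mvc(
    recs: Sequence[TrialRecording],
    threshold: float = 0.95,
    window: Tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """MVC as the highest target whose windowed mean reaches the target.

    A trial counts as maintained when its windowed mean force is at least
    ``threshold`` times the target level.
    """
    recs = list(recs)
    if not recs:
        raise CalibrationError("need at least one trial")
    maintained = [
        r.target_g
        for r in recs
        if trial_summary(r, window).mean_force >= threshold * r.target_g
    ]
    if not maintained:
        raise CalibrationError("no trial satisfied the maintained-force criterion")
    return float(max(maintained))


@dataclass(frozen=True)
class AssociationResult:
    """OLS association between k and MVC across fingers and participants."""

    slope: float
    intercept: float
    t_stat: float
    df: int
    p_value: float
    r: float


def cv_mvc_association(
    k: Sequence[float], mvc: Sequence[float]
) -> AssociationResult:
    """Least-squares fit of k on MVC with slope t-test and Pearson r.

    The regression has an intercept; the slope's t statistic carries
    ``n - 2`` degrees of freedom.
    """
    k = np.asarray(k, dtype=float)
    mvc = np.asarray(mvc, dtype=float)
    if k.shape != mvc.shape or k.ndim != 1:
        raise ValueError("k and mvc must be 1-d arrays of equal length")
    if k.size < 3:
        raise ValueError("need >= 3 points")
    if np.ptp(mvc) == 0:
        raise ValueError("MVC values are constant; association undefined")
    res = stats.linregress(mvc, k)
    n = k.size
    return AssociationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        t_stat=float(res.slope / res.stderr),
        df=n - 2,
        p_value=float(res.pvalue),
        r=float(res.rvalue),
    )
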
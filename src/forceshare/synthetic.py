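"""Synthetic study generator: populations, force-hold trials, share data.

Everything the analysis pipeline consumes can be generated here from
known ground truth, emulating a bimanual force-sharing study:

* a population of participants, each with a weak-finger/strong-finger
  profile (coefficient of variation ``k`` and MVC) drawn from truncated
  normals whose defaults match published group statistics for the left
  little finger (k 2.38 +/- 1.2 %, MVC 12.71 +/- 2.30 N) and right index
  finger (k 1.62 +/- 0.59 %, MVC 23.29 +/- 5.18 N) of 14 adults;
* unimanual force-hold recordings with signal-dependent Gaussian noise
  (``sigma = k * u``), a 1.5 s linear ramp, and failure plateaus at MVC
  for targets beyond the finger's strength;
* bimanual share observations ``y = c* + noise`` where ``c*`` is the
  optimal share implied by ground-truth cost weights and the noise is
  Gaussian on the share scale, truncated to (0, 1).

All generators are pure functions of their spec and RNG: identical seeds
give identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .calibration import TrialRecording
from .mcmc import ShareDataset
from .model import CostWeights, FingerProfile, NormConstants, normalization_constants, share_for_pair

__all__ = [
    "FingerSpec",
    "PopulationSpec",
    "ScenarioSpec",
    "DEFAULT_LEVELS",
    "sample_population",
    "simulate_unimanual",
    "simulate_share_data",
    "trend_scenario",
]

DEFAULT_LEVELS: Tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0)


@dataclass(frozen=True)
class FingerSpec:
    """Population distribution of one finger's profile.

    ``k`` moments are dimensionless fractions (0.0238 == 2.38%); MVC
    moments are Newtons.  Draws are truncated at zero.
    """

    label: str
    k_mean: float
    k_sd: float
    mvc_mean: float
    mvc_sd: float

    def __post_init__(self) -> None:
        if self.k_mean <= 0 or self.mvc_mean <= 0:
            raise ValueError("means must be > 0")
        if self.k_sd < 0 or self.mvc_sd < 0:
            raise ValueError("SDs must be >= 0")


# group statistics for the finger pair with the largest strength asymmetry:
# weak = left little, strong = right index
LEFT_LITTLE = FingerSpec("left_little", k_mean=0.0238, k_sd=0.012, mvc_mean=12.71, mvc_sd=2.30)
RIGHT_INDEX = FingerSpec("right_index", k_mean=0.0162, k_sd=0.0059, mvc_mean=23.29, mvc_sd=5.18)


@dataclass(frozen=True)
class PopulationSpec:
    """How many participants to draw and from which finger distributions.

    ``k_mvc_corr`` optionally couples each finger's k and MVC draws
    through a Gaussian copula before truncation (negative values emulate
    the weak empirical association between noise and strength).
    """

    n_participants: int = 14
    finger_weak: FingerSpec = LEFT_LITTLE
    finger_strong: FingerSpec = RIGHT_INDEX
    k_mvc_corr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if not -1.0 < self.k_mvc_corr < 1.0:
            raise ValueError("k_mvc_corr must lie in (-1, 1)")


def _draw_finger(
    spec: FingerSpec, n: int, corr: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Positive (k, mvc) draws, optionally correlated, truncated at 0."""
    if spec.k_sd == 0 and spec.mvc_sd == 0:
        return np.full(n, spec.k_mean), np.full(n, spec.mvc_mean)
    k = np.empty(n)
    mvc = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        z1 = rng.standard_normal(todo.size)
        z2 = corr * z1 + np.sqrt(1.0 - corr**2) * rng.standard_normal(todo.size)
        k[todo] = spec.k_mean + spec.k_sd * z1
        mvc[todo] = spec.mvc_mean + spec.mvc_sd * z2
        todo = todo[(k[todo] <= 0) | (mvc[todo] <= 0)]
    return k, mvc


def sample_population(
    spec: PopulationSpec, rng: np.random.Generator
) -> List[Tuple[FingerProfile, FingerProfile]]:
    """Draw a population of (weak, strong) finger-profile pairs."""
    n = spec.n_participants
    k_w, mvc_w = _draw_finger(spec.finger_weak, n, spec.k_mvc_corr, rng)
    k_s, mvc_s = _draw_finger(spec.finger_strong, n, spec.k_mvc_corr, rng)
    return [
        (
            FingerProfile(spec.finger_weak.label, float(k_w[m]), float(mvc_w[m])),
            FingerProfile(spec.finger_strong.label, float(k_s[m]), float(mvc_s[m])),
        )
        for m in range(n)
    ]


def simulate_unimanual(
    profile: FingerProfile,
    targets: Sequence[float],
    rng: np.random.Generator,
    rate: float = 200.0,
    duration: float = 7.0,
    ramp: float = 1.5,
    participant_id: str = "",
) -> List[TrialRecording]:
    """Simulate force-hold trials at each target level for one finger.

    The mean force ramps linearly to the commanded level over ``ramp``
    seconds, then holds; samples are independent Gaussians with SD
    ``k * u(t)``.  Targets beyond the finger's MVC plateau at MVC (the
    participant cannot maintain them), so such trials fail a
    maintained-force criterion.
    """
    targets = list(targets)
    if not targets:
        raise ValueError("need at least one target level")
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be > 0")
    n = int(round(rate * duration))
    t = np.arange(n) / rate
    out = []
    for g in targets:
        level = min(float(g), profile.mvc)
        mean = np.where(t < ramp, level * t / max(ramp, 1.0 / rate), level)
        mean = np.minimum(mean, level)
        samples = mean + profile.k * mean * rng.standard_normal(n)
        out.append(
            TrialRecording(
                finger_id=profile.finger_id,
                target_g=float(g),
                samples=samples,
                rate=rate,
                participant_id=participant_id,
            )
        )
    return out


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for a bimanual share experiment.

    One set of cost weights per force level; ``n_obs`` share observations
    per participant per level; per-(level, participant) noise SDs drawn
    from a truncated normal so participants differ in reliability (set
    ``noise_sd_sd = 0`` for homogeneous noise).
    """

    levels: Tuple[float, ...] = DEFAULT_LEVELS
    weights: Tuple[CostWeights, ...] = ()
    n_obs: int = 50
    noise_sd_mean: float = 0.05
    noise_sd_sd: float = 0.015
    noise_sd_min: float = 0.005

    def __post_init__(self) -> None:
        if not self.levels:
            raise ValueError("need at least one force level")
        weights = tuple(self.weights) or tuple(
            trend_weights(g, self.levels) for g in self.levels
        )
        if len(weights) != len(self.levels):
            raise ValueError("need one CostWeights per level")
        object.__setattr__(self, "weights", weights)
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        # noise_sd_mean == 0 is allowed (noiseless shares, useful for checks)
        if self.noise_sd_mean < 0 or self.noise_sd_min <= 0 or self.noise_sd_sd < 0:
            raise ValueError("noise scales must be non-negative")


def trend_weights(g: float, levels: Sequence[float]) -> CostWeights:
    """Level-dependent ground truth: effort emphasis shifts with force.

    At the lowest level the absolute-effort weight dominates
    (lam = 0.75); it declines linearly to 0.30 at the highest level while
    the normalized-effort weight mu rises to take up the slack and the
    error weight stays at nu = 0.10 — the qualitative pattern reported
    for human force sharing as targets grow.
    """
    lo, hi = min(levels), max(levels)
    frac = 0.0 if hi == lo else (g - lo) / (hi - lo)
    nu = 0.10
    lam = 0.75 - 0.45 * frac
    return CostWeights(nu=nu, lam=lam, mu=1.0 - nu - lam)


def trend_scenario(
    levels: Sequence[float] = DEFAULT_LEVELS, n_obs: int = 50
) -> ScenarioSpec:
    """Default scenario with the lam-to-mu crossing built in."""
    levels = tuple(float(g) for g in levels)
    return ScenarioSpec(
        levels=levels,
        weights=tuple(trend_weights(g, levels) for g in levels),
        n_obs=n_obs,
    )


def simulate_share_data(
    profiles: Sequence[Tuple[FingerProfile, FingerProfile]],
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    consts: Optional[NormConstants] = None,
    participant_ids: Optional[Sequence[str]] = None,
) -> List[ShareDataset]:
    """Generate one ShareDataset per force level from ground-truth weights.

    Each observation is the participant's optimal share ``c*`` plus
    Gaussian noise on the share scale, redrawn (truncated) if it falls
    outside (0, 1).  Warns if truncation alters more than 0.1% of draws.
    """
    profiles = list(profiles)
    if consts is None:
        consts = normalization_constants(profiles)
    if participant_ids is None:
        participant_ids = [f"P{m + 1:02d}" for m in range(len(profiles))]
    n_redraw = 0
    n_draw = 0
    datasets = []
    for g, weights in zip(scenario.levels, scenario.weights):
        ys = []
        for p_i, p_j in profiles:
            c = share_for_pair(weights, consts, p_i, p_j)
            if scenario.noise_sd_sd > 0:
                sd = max(
                    scenario.noise_sd_min,
                    rng.normal(scenario.noise_sd_mean, scenario.noise_sd_sd),
                )
            else:
                sd = scenario.noise_sd_mean
            y = c + sd * rng.standard_normal(scenario.n_obs)
            n_draw += scenario.n_obs
            bad = (y <= 0.0) | (y >= 1.0)
            while np.any(bad):
                n_redraw += int(bad.sum())
                y[bad] = c + sd * rng.standard_normal(int(bad.sum()))
                bad = (y <= 0.0) | (y >= 1.0)
            ys.append(y)
        datasets.append(
            ShareDataset(
                level_g=g,
                participant_ids=list(participant_ids),
                y=ys,
                profiles=profiles,
            )
        )
    if n_draw and n_redraw / n_draw > 1e-3:
        warnings.warn(
            f"(0,1) truncation altered {n_redraw / n_draw:.2%} of share draws; "
            "noise scale may be too large for the shares being simulated",
            stacklevel=2,
        )
    return datasets
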
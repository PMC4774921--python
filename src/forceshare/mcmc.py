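"""Bayesian estimation of the cost weights by Metropolis-within-Gibbs.

For one force level ``l`` the data are observed force shares
``y_lm(n) in (0,1)`` — the weaker finger's fraction of the total force —
for participants ``m = 1..M``.  The model is

    y_lm(n) ~ Normal(c*_lm, sigma2_lm),

where ``c*_lm`` is the participant's optimal share implied by the cost
weights (nu, lam, mu) and the participant's finger profiles.  The weights
live on the unit simplex, which is awkward to sample directly, so the
sampler works in the stick-breaking reparametrization

    nu = w,   lam = (1 - w) * z,   mu = (1 - w) * (1 - z),

with independent U(0,1) priors on ``w`` and ``z``.  Per-participant noise
variances get the scale-invariant prior ``pi(sigma2) ~ 1/sigma2``
(inverse-gamma InvGa(0,0)); a flat-prior variant is available.  One
sampler cycle is:

1. adaptive random-walk Metropolis update of ``w`` (logit scale),
2. adaptive random-walk Metropolis update of ``z`` (logit scale),
3. deterministic ``mu = (1 - w)(1 - z)``,
4. exact Gibbs draw of each ``sigma2_lm`` from its inverse-gamma
   conditional.

Reduced models fix a subset of the weights at zero by pinning ``w`` and/or
``z``; force levels are always fitted independently of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import CostWeights, FingerProfile, NormConstants

__all__ = [
    "ShareDataset",
    "ModelSpec",
    "AdaptState",
    "PosteriorChain",
    "ParamSummary",
    "reparam_forward",
    "reparam_inverse",
    "log_likelihood",
    "variance_gibbs_update",
    "rwmh_step",
    "run_chain",
    "posterior_summary",
    "FULL_MODEL",
    "ALL_WEIGHT_SUBSETS",
]

DEFAULT_T = 90_000
DEFAULT_BURN_IN = 40_000

ADAPT_BATCH = 50
ADAPT_TARGET = 0.44  # optimal acceptance for a one-dimensional random walk

FULL_MODEL = frozenset({"nu", "lam", "mu"})
ALL_WEIGHT_SUBSETS: Tuple[frozenset, ...] = (
    frozenset({"nu", "lam", "mu"}),
    frozenset({"lam", "mu"}),
    frozenset({"nu", "mu"}),
    frozenset({"nu", "lam"}),
    frozenset({"mu"}),
    frozenset({"lam"}),
    frozenset({"nu"}),
)


# ---------------------------------------------------------------------------
# data containers


class ShareDataset:
    """Observed force shares at one force level, with finger profiles.

    Parameters
    ----------
    level_g
        Target force level in Newtons.
    participant_ids, y, profiles
        Parallel sequences: for each participant, an id, a 1-d array of
        shares in the open interval (0, 1), and the ``(weak, strong)``
        finger-profile pair used to compute the participant's predicted
        optimal share.
    """

    def __init__(
        self,
        level_g: float,
        participant_ids: Sequence[str],
        y: Sequence[np.ndarray],
        profiles: Sequence[Tuple[FingerProfile, FingerProfile]],
    ) -> None:
        if not (len(participant_ids) == len(y) == len(profiles)):
            raise ValueError("participant_ids, y and profiles must be parallel")
        if len(participant_ids) == 0:
            raise ValueError("dataset has no participants")
        self.level_g = float(level_g)
        self.participant_ids = list(participant_ids)
        self.y = [np.asarray(v, dtype=float).ravel() for v in y]
        self.profiles = list(profiles)
        for pid, v in zip(self.participant_ids, self.y):
            if v.size == 0:
                raise ValueError(f"participant {pid}: no observations")
            if not np.all((v > 0.0) & (v < 1.0)):
                raise ValueError(f"participant {pid}: shares must lie in (0, 1)")
        # per-participant sufficient statistics and profile arrays
        self.n_obs = np.array([v.size for v in self.y], dtype=float)
        self.sum_y = np.array([v.sum() for v in self.y])
        self.sum_y2 = np.array([(v**2).sum() for v in self.y])
        self.k2_i = np.array([p_i.k**2 for p_i, _ in self.profiles])
        self.k2_j = np.array([p_j.k**2 for _, p_j in self.profiles])
        self.invmvc2_i = np.array([1.0 / p_i.mvc**2 for p_i, _ in self.profiles])
        self.invmvc2_j = np.array([1.0 / p_j.mvc**2 for _, p_j in self.profiles])

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    @property
    def n_total(self) -> float:
        """Total number of observations at this level."""
        return float(self.n_obs.sum())


@dataclass(frozen=True)
class ModelSpec:
    """Which weights are free and how noise variances are structured.

    ``free_terms`` is a non-empty subset of {"nu", "lam", "mu"}; the
    remaining weights are fixed at zero.  ``variance_structure`` is
    "per_participant" (one sigma2 per participant per level) or "pooled"
    (one sigma2 per level).  ``prior`` selects the variance prior:
    "invgamma00" for pi(s2) ~ 1/s2, "flat" for pi(s2) ~ 1.
    """

    free_terms: frozenset = FULL_MODEL
    variance_structure: str = "per_participant"
    prior: str = "invgamma00"

    def __post_init__(self) -> None:
        terms = frozenset(self.free_terms)
        object.__setattr__(self, "free_terms", terms)
        if not terms or not terms <= {"nu", "lam", "mu"}:
            raise ValueError("free_terms must be a non-empty subset of nu/lam/mu")
        if self.variance_structure not in ("per_participant", "pooled"):
            raise ValueError("variance_structure must be per_participant or pooled")
        if self.prior not in ("invgamma00", "flat"):
            raise ValueError("prior must be invgamma00 or flat")

    @property
    def n_free_weights(self) -> int:
        return len(self.free_terms) - 1

    def stick_constraints(self) -> Tuple[Optional[float], Optional[float]]:
        """Fixed (w, z) values implied by the zero weights; None = sampled."""
        t = self.free_terms
        if t == {"nu", "lam", "mu"}:
            return (None, None)
        if t == {"lam", "mu"}:
            return (0.0, None)
        if t == {"nu", "mu"}:
            return (None, 0.0)
        if t == {"nu", "lam"}:
            return (None, 1.0)
        if t == {"mu"}:
            return (0.0, 0.0)
        if t == {"lam"}:
            return (0.0, 1.0)
        if t == {"nu"}:
            return (1.0, 0.5)
        raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# reparametrization


def reparam_forward(w: float, z: float) -> CostWeights:
    """Map stick-breaking coordinates (w, z) to simplex weights.

    ``nu = w``, ``lam = (1-w) z``, ``mu = (1-w)(1-z)``; the weights sum to
    1 by construction.
    """
    if not (0.0 <= w <= 1.0 and 0.0 <= z <= 1.0):
        raise ValueError("w and z must lie in [0, 1]")
    lam = (1.0 - w) * z
    return CostWeights(nu=w, lam=lam, mu=1.0 - w - lam)


def reparam_inverse(weights: CostWeights) -> Tuple[float, float]:
    """Recover (w, z) from simplex weights; undefined at nu == 1."""
    if weights.nu >= 1.0:
        raise ValueError("z is undefined when nu == 1")
    return (weights.nu, weights.lam / (1.0 - weights.nu))


# ---------------------------------------------------------------------------
# likelihood


def _shares_for(
    data: ShareDataset, weights: CostWeights, consts: NormConstants
) -> np.ndarray:
    """Predicted optimal share of the weak finger, per participant."""
    nu_t, lam_t, mu_t = consts.tilded(weights)
    a_i = nu_t * data.k2_i + lam_t + mu_t * data.invmvc2_i
    a_j = nu_t * data.k2_j + lam_t + mu_t * data.invmvc2_j
    return a_j / (a_i + a_j)


def _rss_per_participant(data: ShareDataset, c: np.ndarray) -> np.ndarray:
    """Sum of squared residuals per participant via sufficient statistics."""
    return data.sum_y2 - 2.0 * c * data.sum_y + data.n_obs * c**2


def log_likelihood(
    data: ShareDataset,
    weights: CostWeights,
    variances: np.ndarray | float,
    consts: NormConstants,
) -> float:
    """Gaussian log-likelihood of the shares given weights and variances.

    ``variances`` is a length-M array (per participant) or a scalar
    (pooled across participants).
    """
    var = np.broadcast_to(np.asarray(variances, dtype=float), (data.n_participants,))
    if np.any(var <= 0.0):
        raise ValueError("variances must be > 0")
    c = _shares_for(data, weights, consts)
    rss = _rss_per_participant(data, c)
    return float(
        -0.5 * data.n_total * math.log(2.0 * math.pi)
        - 0.5 * np.sum(data.n_obs * np.log(var))
        - 0.5 * np.sum(rss / var)
    )


# ---------------------------------------------------------------------------
# samplers


def _invgamma_shape_offset(prior: str) -> float:
    # InvGa(0,0) prior adds nothing; flat prior pi(s2) ~ 1 is InvGa(-1, 0)
    return 0.0 if prior == "invgamma00" else -1.0


def variance_gibbs_update(
    residuals: np.ndarray,
    rng: np.random.Generator,
    prior: str = "invgamma00",
) -> float:
    """One exact draw of a participant's noise variance.

    Under the scale-invariant prior the conditional is
    ``InvGa(N/2, RSS/2)`` with ``N`` observations and residual sum of
    squares ``RSS``; the flat prior shifts the shape to ``N/2 - 1``.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    n = residuals.size
    if n < 1:
        raise ValueError("need at least one residual")
    rss = float(residuals @ residuals)
    if rss <= 0.0:
        raise ValueError("all residuals are zero: variance conditional is improper")
    shape = n / 2.0 + _invgamma_shape_offset(prior)
    if shape <= 0.0:
        raise ValueError(f"prior {prior!r} needs more observations (shape <= 0)")
    return (rss / 2.0) / rng.gamma(shape)


@dataclass
class AdaptState:
    """Diminishing-adaptation state for one random-walk proposal scale.

    The proposal SD (stored as ``log_sd``, logit scale) is nudged after
    every batch of ``batch_size`` proposals: up if the batch acceptance
    rate exceeded the target, down otherwise, by ``min(0.01, 1/sqrt(b))``
    at batch ``b`` so adaptation vanishes asymptotically.
    """

    log_sd: float = 0.0
    batch_size: int = ADAPT_BATCH
    target: float = ADAPT_TARGET
    batch_index: int = 0
    _in_batch: int = 0
    _accepted: int = 0
    trace: List[float] = field(default_factory=list)

    def record(self, accepted: bool) -> None:
        self._in_batch += 1
        self._accepted += int(accepted)
        if self._in_batch >= self.batch_size:
            self.batch_index += 1
            step = min(0.01, self.batch_index**-0.5)
            rate = self._accepted / self._in_batch
            self.log_sd += step if rate > self.target else -step
            self.trace.append(self.log_sd)
            self._in_batch = 0
            self._accepted = 0


def _logit(x: float) -> float:
    return math.log(x) - math.log1p(-x)


def rwmh_step(
    x: float,
    log_target: Callable[[float], float],
    adapt: AdaptState,
    rng: np.random.Generator,
    curr_lp: Optional[float] = None,
) -> Tuple[float, bool, float]:
    """One adaptive random-walk Metropolis step on (0, 1).

    The proposal is a Gaussian step on the logit scale; the acceptance
    ratio carries the Jacobian ``x (1 - x)`` of the transform so the chain
    targets ``log_target`` on the original scale.  Returns
    ``(new_x, accepted, log_target(new_x))``.
    """
    if curr_lp is None:
        curr_lp = log_target(x)
    step = math.exp(adapt.log_sd) * rng.standard_normal()
    x_new = 1.0 / (1.0 + math.exp(-(_logit(x) + step)))
    accepted = False
    new_lp = curr_lp
    if 0.0 < x_new < 1.0:  # guard against floating saturation at the boundary
        prop_lp = log_target(x_new)
        log_ratio = (
            prop_lp
            - curr_lp
            + math.log(x_new * (1.0 - x_new))
            - math.log(x * (1.0 - x))
        )
        if log_ratio >= 0.0 or rng.random() < math.exp(log_ratio):
            accepted = True
            x, new_lp = x_new, prop_lp
    adapt.record(accepted)
    return (x, accepted, new_lp)


# ---------------------------------------------------------------------------
# the full per-level chain


@dataclass
class PosteriorChain:
    """MCMC output for one force level.

    Arrays hold every iteration, including burn-in; ``retained`` slices
    off the burn-in.  ``sigma2`` has one column per participant, or a
    single column for the pooled variance structure.
    """

    w: np.ndarray
    z: np.ndarray
    nu: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    participant_ids: List[str]
    burn_in: int
    seed: int
    spec: ModelSpec
    level_g: float
    accept_rate_w: float
    accept_rate_z: float
    adapt_trace_w: np.ndarray
    adapt_trace_z: np.ndarray

    @property
    def n_iter(self) -> int:
        return self.w.size

    def retained(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        return arr[self.burn_in :]


def _initial_variances(data: ShareDataset) -> np.ndarray:
    pooled = float(np.var(np.concatenate(data.y), ddof=0))
    out = np.empty(data.n_participants)
    for m, v in enumerate(data.y):
        if v.size >= 2:
            s2 = float(np.var(v, ddof=1))
            out[m] = s2 if s2 > 0 else max(pooled, 1e-6)
        else:
            out[m] = max(pooled, 1e-6)
    return out


def run_chain(
    data: ShareDataset,
    spec: ModelSpec,
    consts: NormConstants,
    T: int = DEFAULT_T,
    burn_in: int = DEFAULT_BURN_IN,
    seed: int = 0,
) -> PosteriorChain:
    """Run the Metropolis-within-Gibbs sampler for one force level.

    Each cycle updates ``w`` then ``z`` by adaptive random-walk Metropolis
    (skipping any coordinate pinned by the model's zero-weight
    constraints), recomputes ``mu`` deterministically, and draws every
    noise variance exactly from its inverse-gamma conditional.  The run
    is a pure function of ``(data, spec, consts, T, burn_in, seed)``.
    """
    if not (T > burn_in >= 0):
        raise ValueError("need T > burn_in >= 0")
    for pid, v in zip(data.participant_ids, data.y):
        if v.size >= 2 and np.ptp(v) == 0.0:
            raise ValueError(
                f"participant {pid}: constant shares make the variance "
                "conditional improper; cannot fit"
            )
    rng = np.random.default_rng(seed)
    M = data.n_participants
    pooled = spec.variance_structure == "pooled"
    shape_off = _invgamma_shape_offset(spec.prior)
    if pooled:
        gibbs_shape = data.n_total / 2.0 + shape_off
    else:
        gibbs_shape = data.n_obs / 2.0 + shape_off
    if np.any(np.atleast_1d(gibbs_shape) <= 0.0):
        raise ValueError("flat variance prior needs more observations per unit")

    w_fix, z_fix = spec.stick_constraints()
    w = 0.5 if w_fix is None else w_fix
    z = 0.5 if z_fix is None else z_fix

    b_nu, b_lam, b_mu = consts.b_nu, consts.b_lam, consts.b_mu
    k2_i, k2_j = data.k2_i, data.k2_j
    iv_i, iv_j = data.invmvc2_i, data.invmvc2_j
    n_obs, sum_y, sum_y2 = data.n_obs, data.sum_y, data.sum_y2

    def rss_vec(w_: float, z_: float) -> np.ndarray:
        nu_t = w_ / b_nu
        lam_t = (1.0 - w_) * z_ / b_lam
        mu_t = (1.0 - w_) * (1.0 - z_) / b_mu
        a_i = nu_t * k2_i + lam_t + mu_t * iv_i
        a_j = nu_t * k2_j + lam_t + mu_t * iv_j
        c = a_j / (a_i + a_j)
        return sum_y2 - 2.0 * c * sum_y + n_obs * c**2

    var = _initial_variances(data)
    if pooled:
        var = np.full(M, float(np.mean(var)))

    def exponent(w_: float, z_: float) -> float:
        return float(-0.5 * np.sum(rss_vec(w_, z_) / var))

    lp = exponent(w, z)
    if not math.isfinite(lp):
        raise ValueError("log posterior not finite at initialization")

    out_w = np.empty(T)
    out_z = np.empty(T)
    out_s2 = np.empty((T, 1 if pooled else M))
    adapt_w = AdaptState()
    adapt_z = AdaptState()
    acc_w = 0
    acc_z = 0

    for t in range(T):
        if w_fix is None:
            w, ok, lp = rwmh_step(w, lambda x: exponent(x, z), adapt_w, rng, lp)
            acc_w += ok
        if z_fix is None:
            z, ok, lp = rwmh_step(z, lambda x: exponent(w, x), adapt_z, rng, lp)
            acc_z += ok

        rss = rss_vec(w, z)
        if pooled:
            total = float(rss.sum())
            if total <= 0.0:
                raise ValueError("zero residual sum: variance conditional improper")
            s2 = (total / 2.0) / rng.gamma(gibbs_shape)
            var[:] = s2
            out_s2[t, 0] = s2
        else:
            if np.any(rss <= 0.0):
                raise ValueError("zero residual sum: variance conditional improper")
            var = (rss / 2.0) / rng.gamma(gibbs_shape)
            out_s2[t] = var
        lp = float(-0.5 * np.sum(rss / var))
        out_w[t] = w
        out_z[t] = z

    nu = out_w
    lam = (1.0 - out_w) * out_z
    mu = (1.0 - out_w) * (1.0 - out_z)
    return PosteriorChain(
        w=out_w,
        z=out_z,
        nu=nu,
        lam=lam,
        mu=mu,
        sigma2=out_s2,
        participant_ids=list(data.participant_ids),
        burn_in=burn_in,
        seed=seed,
        spec=spec,
        level_g=data.level_g,
        accept_rate_w=(acc_w / T) if w_fix is None else math.nan,
        accept_rate_z=(acc_z / T) if z_fix is None else math.nan,
        adapt_trace_w=np.array(adapt_w.trace),
        adapt_trace_z=np.array(adapt_z.trace),
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class ParamSummary:
    median: float
    lo95: float
    hi95: float


def posterior_summary(chain: PosteriorChain) -> Dict[str, ParamSummary]:
    """Posterior medians and equal-tailed 95% credible intervals.

    Keys are ``nu``, ``lam``, ``mu`` and ``sigma2[<participant>]`` (or
    ``sigma2`` for the pooled structure).  Marginal medians of the three
    weights need not themselves sum to 1.
    """
    if chain.burn_in >= chain.n_iter:
        raise ValueError("no post-burn-in samples")
    out: Dict[str, ParamSummary] = {}

    def summarize(arr: np.ndarray) -> ParamSummary:
        med, lo, hi = np.quantile(arr, [0.5, 0.025, 0.975])
        return ParamSummary(float(med), float(lo), float(hi))

    for name in ("nu", "lam", "mu"):
        out[name] = summarize(chain.retained(name))
    s2 = chain.retained("sigma2")
    if s2.shape[1] == 1:
        out["sigma2"] = summarize(s2[:, 0])
    else:
        for m, pid in enumerate(chain.participant_ids):
            out[f"sigma2[{pid}]"] = summarize(s2[:, m])
    return out
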
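"""Static optimal-control model of two-finger isometric force sharing.

A target force ``g`` (Newtons) is produced jointly by two fingers, one per
hand.  Each finger's force is a noisy realization of its motor command
``u``: signal-dependent noise with standard deviation ``k*u``, where ``k``
is the finger's coefficient of variation.  The central nervous system is
modelled as minimizing a weighted sum of three costs:

* expected squared error of the total force (weight ``nu``),
* absolute effort ``u_i**2 + u_j**2`` (weight ``lam``),
* normalized effort ``(u_i/MVC_i)**2 + (u_j/MVC_j)**2`` (weight ``mu``),

where ``MVC`` is the finger's maximum voluntary contraction.  The weights
live on the unit simplex (``nu + lam + mu = 1``) and each is divided by a
population normalization constant so that equal weights mean equal
influence on the optimum.  Expanding the expectation, the cost is a
quadratic in ``(u_i, u_j)``,

    J = nu_t * (u_i + u_j - g)**2 + a_i * u_i**2 + a_j * u_j**2,

with effective coefficients ``a = nu_t*k**2 + lam_t + mu_t/MVC**2`` (the
tilde/``_t`` marks a normalized weight).  The minimizer is closed-form, and
the optimal share of finger i, ``c* = a_j / (a_i + a_j)``, is independent
of the target force and of any common rescaling of the weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

__all__ = [
    "FingerProfile",
    "CostWeights",
    "NormConstants",
    "EffectiveCoefficients",
    "normalization_constants",
    "effective_coefficient",
    "effective_coefficients",
    "optimal_command",
    "optimal_share",
    "share_for_pair",
    "cost",
]

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class FingerProfile:
    """Noise and strength characteristics of one finger.

    Parameters
    ----------
    finger_id
        Hand + digit label, e.g. ``"left_little"``.
    k
        Coefficient of variation of force, a dimensionless fraction
        (``sigma(x) = k * u``).  Tables in the literature often report
        percent; convert before constructing.
    mvc
        Maximum voluntary contraction in Newtons.
    """

    finger_id: str
    k: float
    mvc: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and > 0, got {self.k!r}")
        if not (math.isfinite(self.mvc) and self.mvc > 0):
            raise ValueError(f"mvc must be finite and > 0, got {self.mvc!r}")


@dataclass(frozen=True)
class CostWeights:
    """Simplex-constrained cost weights (nu, lam, mu).

    ``nu`` weights the expected squared error of total force, ``lam`` the
    absolute effort, ``mu`` the MVC-normalized effort.  The constructor
    enforces ``nu + lam + mu == 1`` (to 1e-9) and each weight in [0, 1].
    """

    nu: float
    lam: float
    mu: float

    def __post_init__(self) -> None:
        for name, v in (("nu", self.nu), ("lam", self.lam), ("mu", self.mu)):
            if not (math.isfinite(v) and -_SIMPLEX_TOL <= v <= 1 + _SIMPLEX_TOL):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        s = self.nu + self.lam + self.mu
        if abs(s - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"weights must sum to 1, got {s!r}")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.nu, self.lam, self.mu)


@dataclass(frozen=True)
class NormConstants:
    """Population normalization constants for the three cost terms.

    ``b_nu`` is the population mean of ``k_i**2 + k_j**2`` over the
    analyzed participants, ``b_lam`` is the constant 2, and ``b_mu`` the
    mean of ``1/MVC_i**2 + 1/MVC_j**2``.  Dividing each raw weight by its
    constant puts the three cost terms on a comparable scale, so equal
    weights mean equal influence on the optimal solution.
    """

    b_nu: float
    b_mu: float
    b_lam: float = 2.0

    def __post_init__(self) -> None:
        for name, v in (("b_nu", self.b_nu), ("b_lam", self.b_lam), ("b_mu", self.b_mu)):
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")

    def tilded(self, weights: CostWeights) -> Tuple[float, float, float]:
        """Return the normalized weights (nu_t, lam_t, mu_t)."""
        return (weights.nu / self.b_nu, weights.lam / self.b_lam, weights.mu / self.b_mu)


@dataclass(frozen=True)
class EffectiveCoefficients:
    """Quadratic penalties on each command plus the normalized error weight."""

    a_i: float
    a_j: float
    nu_tilde: float


def normalization_constants(
    pairs: Sequence[Tuple[FingerProfile, FingerProfile]],
) -> NormConstants:
    """Compute normalization constants from participant finger-pair profiles.

    Parameters
    ----------
    pairs
        One ``(profile_i, profile_j)`` tuple per participant for the
        designated finger pair.

    Returns
    -------
    NormConstants
        ``b_nu`` = mean of ``k_i**2 + k_j**2``; ``b_lam`` = 2;
        ``b_mu`` = mean of ``1/MVC_i**2 + 1/MVC_j**2``.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one participant's profile pair")
    b_nu = sum(p_i.k**2 + p_j.k**2 for p_i, p_j in pairs) / len(pairs)
    b_mu = sum(1.0 / p_i.mvc**2 + 1.0 / p_j.mvc**2 for p_i, p_j in pairs) / len(pairs)
    return NormConstants(b_nu=b_nu, b_mu=b_mu)


def effective_coefficient(
    weights: CostWeights, consts: NormConstants, profile: FingerProfile
) -> float:
    """Effective quadratic penalty ``a = nu_t*k**2 + lam_t + mu_t/MVC**2``."""
    if weights.nu == 0 and weights.lam == 0 and weights.mu == 0:
        raise ValueError("all weights zero: effective coefficient undefined")
    nu_t, lam_t, mu_t = consts.tilded(weights)
    return nu_t * profile.k**2 + lam_t + mu_t / profile.mvc**2


def effective_coefficients(
    weights: CostWeights,
    consts: NormConstants,
    profile_i: FingerProfile,
    profile_j: FingerProfile,
) -> EffectiveCoefficients:
    """Both fingers' effective coefficients plus the normalized error weight."""
    return EffectiveCoefficients(
        a_i=effective_coefficient(weights, consts, profile_i),
        a_j=effective_coefficient(weights, consts, profile_j),
        nu_tilde=weights.nu / consts.b_nu,
    )


def optimal_command(
    a_i: float, a_j: float, nu_tilde: float, g: float
) -> Tuple[float, float]:
    """Cost-minimizing motor commands ``(u_i*, u_j*)`` for target force ``g``.

    Solves the stationarity conditions of the quadratic cost:
    ``u_i* = g * a_j / (a_i + a_j + a_i*a_j/nu_tilde)`` and
    ``u_j* = (a_i / a_j) * u_i*``.  The total generally undershoots ``g``
    because effort and noise penalties trade off against accuracy; it
    approaches ``g`` as ``nu_tilde`` grows.
    """
    if a_i <= 0 or a_j <= 0:
        raise ValueError("effective coefficients must be > 0")
    if nu_tilde <= 0:
        raise ValueError("nu_tilde must be > 0 (no accuracy term, commands vanish)")
    if g < 0:
        raise ValueError("target force must be >= 0")
    u_i = g * a_j / (a_i + a_j + a_i * a_j / nu_tilde)
    u_j = (a_i / a_j) * u_i
    return (u_i, u_j)


def optimal_share(a_i: float, a_j: float) -> float:
    """Optimal fraction of the total force carried by finger i.

    ``c* = a_j / (a_i + a_j)``: the finger with the *smaller* effective
    penalty takes the larger share.  Independent of the target force and
    of common rescaling of the raw weights.
    """
    if a_i <= 0 or a_j <= 0:
        raise ValueError("effective coefficients must be > 0")
    return a_j / (a_i + a_j)


def share_for_pair(
    weights: CostWeights,
    consts: NormConstants,
    profile_i: FingerProfile,
    profile_j: FingerProfile,
) -> float:
    """Optimal share of finger i for one participant's finger pair."""
    eff = effective_coefficients(weights, consts, profile_i, profile_j)
    return optimal_share(eff.a_i, eff.a_j)


def cost(
    u_i: float,
    u_j: float,
    g: float,
    weights: CostWeights,
    consts: NormConstants,
    profile_i: FingerProfile,
    profile_j: FingerProfile,
) -> float:
    """Expected cost of commands ``(u_i, u_j)`` at target ``g``.

    Uses the expanded quadratic form; under signal-dependent Gaussian
    noise ``x ~ N(u, k*u)`` it equals the expectation form
    ``nu_t * E[(x_i + x_j - g)**2] + lam_t*(u_i**2 + u_j**2)
    + mu_t*((u_i/MVC_i)**2 + (u_j/MVC_j)**2)``.
    """
    nu_t, lam_t, mu_t = consts.tilded(weights)
    a_i = nu_t * profile_i.k**2 + lam_t + mu_t / profile_i.mvc**2
    a_j = nu_t * profile_j.k**2 + lam_t + mu_t / profile_j.mvc**2
    return nu_t * (u_i + u_j - g) ** 2 + a_i * u_i**2 + a_j * u_j**2
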
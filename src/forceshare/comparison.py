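"""Model comparison across weight subsets and variance structures.

Seven candidate models arise from keeping a non-empty subset of the cost
weights (nu, lam, mu) and fixing the rest at zero; each can be fitted
with per-participant noise variances or a single pooled variance per
force level.  Models are compared by

* the data log-likelihood averaged over posterior samples (a model-fit
  score; the original analysis labels this quantity a "marginal"
  log-likelihood, but it is a posterior average, not an integrated
  likelihood — we keep the computation as defined),
* log Bayes factors, taken as differences of those averaged
  log-likelihoods, and
* AIC = -2 * max log-likelihood + 2 d, with the maximum taken over the
  posterior samples and d counting free weight parameters plus variance
  parameters across levels.

Force levels are fitted independently; whole-dataset quantities sum the
per-level ones (per-level parameters are disjoint, so per-level maxima
sum to the joint maximum).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mcmc import (
    ALL_WEIGHT_SUBSETS,
    ModelSpec,
    PosteriorChain,
    ShareDataset,
    posterior_summary,
    run_chain,
)
from .model import CostWeights, FingerProfile, NormConstants, effective_coefficients, optimal_command

__all__ = [
    "ComparisonTable",
    "model_label",
    "loglik_samples",
    "averaged_loglik",
    "max_loglik",
    "log_bayes_factor",
    "aic",
    "fit_all_models",
    "predict_forces",
]

_TERM_ORDER = ("nu", "lam", "mu")


def model_label(free_terms: frozenset) -> str:
    """Canonical label, e.g. ``"nu+lam+mu"`` for the full model."""
    return "+".join(t for t in _TERM_ORDER if t in free_terms)


def loglik_samples(
    chain: PosteriorChain, data: ShareDataset, consts: NormConstants
) -> np.ndarray:
    """Eq-7-style log-likelihood evaluated at every retained sample."""
    nu = chain.retained("nu")
    lam = chain.retained("lam")
    mu = chain.retained("mu")
    s2 = chain.retained("sigma2")  # (T, M) or (T, 1)
    if nu.size == 0:
        raise ValueError("chain has no post-burn-in samples")

    nu_t = (nu / consts.b_nu)[:, None]
    lam_t = (lam / consts.b_lam)[:, None]
    mu_t = (mu / consts.b_mu)[:, None]
    a_i = nu_t * data.k2_i + lam_t + mu_t * data.invmvc2_i
    a_j = nu_t * data.k2_j + lam_t + mu_t * data.invmvc2_j
    c = a_j / (a_i + a_j)  # (T, M)
    rss = data.sum_y2 - 2.0 * c * data.sum_y + data.n_obs * c**2
    const = -0.5 * data.n_total * np.log(2.0 * np.pi)
    return const - 0.5 * np.sum(data.n_obs * np.log(s2) + rss / s2, axis=1)


def averaged_loglik(
    chain: PosteriorChain, data: ShareDataset, consts: NormConstants
) -> float:
    """Posterior-averaged log-likelihood (mean over retained samples)."""
    return float(np.mean(loglik_samples(chain, data, consts)))


def max_loglik(
    chain: PosteriorChain, data: ShareDataset, consts: NormConstants
) -> float:
    """Maximum log-likelihood over retained samples (no optimizer pass)."""
    return float(np.max(loglik_samples(chain, data, consts)))


def log_bayes_factor(ll_a: float, ll_b: float) -> float:
    """Log Bayes factor of model a over model b from their log-likelihood scores."""
    if not (np.isfinite(ll_a) and np.isfinite(ll_b)):
        raise ValueError("log-likelihoods must be finite")
    return float(ll_a - ll_b)


def aic(max_ll: float, d: int) -> float:
    """Akaike information criterion: ``-2 * max_ll + 2 * d``."""
    if d < 0:
        raise ValueError("free-parameter count must be >= 0")
    return -2.0 * max_ll + 2.0 * d


@dataclass
class ComparisonTable:
    """Per-model fit scores over the whole dataset.

    ``table`` has one row per (model, variance_structure) with columns
    ``avg_loglik``, ``max_loglik``, ``d`` and ``aic``; the AIC column is
    exactly ``-2 * max_loglik + 2 * d``.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        """Wide layout: one column per model, log-likelihood and AIC rows."""
        lines = []
        for structure, sub in self.table.groupby("variance_structure", sort=False):
            lines.append(f"variance structure: {structure}")
            header = ["Model"] + list(sub["model"])
            ll = ["Log-likelihood"] + [f"{v:.2f}" for v in sub["avg_loglik"]]
            ai = ["AIC"] + [f"{v:.2f}" for v in sub["aic"]]
            widths = [max(len(r[i]) for r in (header, ll, ai)) for i in range(len(header))]
            for row in (header, ll, ai):
                lines.append("  ".join(s.rjust(w) for s, w in zip(row, widths)))
            lines.append("")
        return "\n".join(lines)


def _variance_param_count(spec: ModelSpec, data: ShareDataset) -> int:
    return 1 if spec.variance_structure == "pooled" else data.n_participants


def fit_all_models(
    datasets: Sequence[ShareDataset],
    consts: NormConstants,
    T: int,
    burn_in: int,
    seed: int,
    variance_structures: Sequence[str] = ("per_participant", "pooled"),
    prior: str = "invgamma00",
    subsets: Sequence[frozenset] = ALL_WEIGHT_SUBSETS,
) -> ComparisonTable:
    """Fit every weight-subset model at every level and tabulate scores.

    Per model: chains run independently per force level with seeds derived
    deterministically from ``seed``; per-level averaged and maximum
    log-likelihoods are summed over levels, and ``d`` counts free weight
    parameters plus variance parameters, again summed over levels.
    """
    rows = []
    for structure in variance_structures:
        for subset in subsets:
            spec = ModelSpec(
                free_terms=subset, variance_structure=structure, prior=prior
            )
            avg_total = 0.0
            max_total = 0.0
            d_total = 0
            for data in datasets:
                child = _level_seed(seed, model_label(subset), structure, data.level_g)
                chain = run_chain(data, spec, consts, T=T, burn_in=burn_in, seed=child)
                ll = loglik_samples(chain, data, consts)
                avg_total += float(np.mean(ll))
                max_total += float(np.max(ll))
                d_total += spec.n_free_weights + _variance_param_count(spec, data)
            rows.append(
                {
                    "model": model_label(subset),
                    "variance_structure": structure,
                    "avg_loglik": avg_total,
                    "max_loglik": max_total,
                    "d": d_total,
                    "aic": aic(max_total, d_total),
                }
            )
    return ComparisonTable(pd.DataFrame(rows))


def _level_seed(seed: int, label: str, structure: str, level_g: float) -> int:
    """Deterministic child seed for one (model, structure, level) chain."""
    key = [seed, abs(hash_stable(label)), abs(hash_stable(structure)), int(round(level_g * 1000))]
    return int(np.random.SeedSequence(key).generate_state(1)[0])


def hash_stable(s: str) -> int:
    """Process-independent 31-bit hash of a short string."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


def predict_forces(
    weights: CostWeights,
    consts: NormConstants,
    profiles: Sequence[Tuple[FingerProfile, FingerProfile]],
    g: float,
) -> List[Tuple[float, float]]:
    """Fitted optimal commands ``(u_i*, u_j*)`` per participant at target g.

    Evaluated at the supplied weights (typically per-level posterior
    medians, renormalized onto the simplex); pairs directly with observed
    mean forces for fitted-versus-produced scatter plots.
    """
    out = []
    for p_i, p_j in profiles:
        eff = effective_coefficients(weights, consts, p_i, p_j)
        out.append(optimal_command(eff.a_i, eff.a_j, eff.nu_tilde, g))
    return out
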
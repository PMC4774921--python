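"""End-to-end orchestration: simulate -> calibrate -> fit -> compare -> report.

A run is driven by a :class:`RunConfig` (loadable from YAML) and writes
every artifact under one output directory together with a manifest
(seed, config hash, package and library versions) sufficient to
reproduce it exactly.  Stages can be run individually through the CLI or
all at once with :func:`run_pipeline`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    TrialRecording,
    cv_mvc_association,
    estimate_cv,
    estimate_mvc,
    trial_summary,
)
from .comparison import (
    ComparisonTable,
    fit_all_models,
    model_label,
    predict_forces,
)
from .io import (
    read_profiles_csv,
    read_share_csv,
    read_trials_csv,
    write_chain,
    write_profiles_csv,
    write_share_csv,
    write_trials_csv,
)
from .mcmc import (
    FULL_MODEL,
    ModelSpec,
    PosteriorChain,
    posterior_summary,
    run_chain,
)
from .model import CostWeights, FingerProfile, NormConstants, normalization_constants
from .synthetic import (
    DEFAULT_LEVELS,
    PopulationSpec,
    ScenarioSpec,
    sample_population,
    simulate_share_data,
    simulate_unimanual,
    trend_scenario,
)

__all__ = ["RunConfig", "run_pipeline", "report_weights"]

log = logging.getLogger("forceshare")


@dataclass
class MCMCConfig:
    T: int = 9000
    burn_in: int = 4000
    seed: int = 0
    prior: str = "invgamma00"
    variance_structure: str = "per_participant"

    def __post_init__(self) -> None:
        if not (self.T > self.burn_in >= 0):
            raise ValueError("need T > burn_in >= 0")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    outdir: str = "forceshare_run"
    n_participants: int = 14
    levels: Tuple[float, ...] = DEFAULT_LEVELS
    n_obs: int = 50
    noise_sd_mean: float = 0.05
    noise_sd_sd: float = 0.015
    weights: Optional[List[List[float]]] = None  # per level (nu, lam, mu)
    finger_weak: str = "left_little"
    finger_strong: str = "right_index"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)

    def __post_init__(self) -> None:
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        self.levels = tuple(float(g) for g in self.levels)
        if self.finger_weak == self.finger_strong:
            raise ValueError("the designated pair must use two distinct fingers")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["levels"] = list(self.levels)
        return d

    def scenario(self) -> ScenarioSpec:
        if self.weights is not None:
            weights = tuple(CostWeights(*w) for w in self.weights)
        else:
            weights = ()
        return ScenarioSpec(
            levels=self.levels,
            weights=weights,
            n_obs=self.n_obs,
            noise_sd_mean=self.noise_sd_mean,
            noise_sd_sd=self.noise_sd_sd,
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(outdir: Path, config: RunConfig, artifacts: Sequence[str]) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.mcmc.seed,
        "versions": {
            "forceshare": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": sys.version.split()[0],
        },
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


class _Stage:
    """Context manager logging stage duration to stderr."""

    def __init__(self, name: str) -> None:
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.1fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.1fs (%s)", self.name, dt, exc)
        return False


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: RunConfig, outdir: Path) -> List[str]:
    """Draw a population and write trials, true profiles and share data."""
    rng = np.random.default_rng(np.random.SeedSequence([config.mcmc.seed, 1]))
    pop = PopulationSpec(
        n_participants=config.n_participants,
        finger_weak=_finger_spec(config.finger_weak),
        finger_strong=_finger_spec(config.finger_strong),
    )
    pairs = sample_population(pop, rng)
    pids = [f"P{m + 1:02d}" for m in range(len(pairs))]
    profiles = dict(zip(pids, pairs))

    recs: List[TrialRecording] = []
    for pid, pair in profiles.items():
        for prof in pair:
            targets = np.arange(2.0, prof.mvc + 4.0, 2.0)
            recs.extend(
                simulate_unimanual(prof, targets, rng, participant_id=pid)
            )
    scenario = config.scenario()
    datasets = simulate_share_data(
        pairs, scenario, rng, participant_ids=pids
    )
    write_trials_csv(recs, outdir / "trials.csv")
    write_profiles_csv(profiles, outdir / "true_profiles.csv")
    write_share_csv(datasets, outdir / "shares.csv")
    truth = pd.DataFrame(
        {
            "level_g": scenario.levels,
            "nu": [w.nu for w in scenario.weights],
            "lam": [w.lam for w in scenario.weights],
            "mu": [w.mu for w in scenario.weights],
        }
    )
    truth.to_csv(outdir / "true_weights.csv", index=False)
    return ["trials.csv", "true_profiles.csv", "shares.csv", "true_weights.csv"]


def _finger_spec(label: str):
    from . import synthetic

    known = {
        "left_little": synthetic.LEFT_LITTLE,
        "right_index": synthetic.RIGHT_INDEX,
    }
    if label in known:
        return known[label]
    raise ValueError(
        f"no built-in population statistics for finger {label!r}; "
        "supply profiles directly via calibrate"
    )


def calibrate_stage(config: RunConfig, outdir: Path) -> List[str]:
    """Estimate k and MVC per finger from the trials file."""
    recs = read_trials_csv(outdir / "trials.csv")
    by_unit: Dict[Tuple[str, str], List[TrialRecording]] = {}
    for rec in recs:
        by_unit.setdefault((rec.participant_id, rec.finger_id), []).append(rec)

    rows = []
    for (pid, fid), unit in sorted(by_unit.items()):
        mvc = estimate_mvc(unit)
        summaries = [
            trial_summary(r) for r in unit if r.target_g <= mvc
        ]
        k = estimate_cv(summaries)
        rows.append({"participant_id": pid, "finger_id": fid, "k": k, "mvc": mvc})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "profiles.csv", index=False)

    assoc = cv_mvc_association(df["k"].to_numpy(), df["mvc"].to_numpy())
    (outdir / "association.json").write_text(
        json.dumps(asdict(assoc), indent=2) + "\n"
    )
    return ["profiles.csv", "association.json"]


def fit_stage(config: RunConfig, outdir: Path) -> List[str]:
    """Fit the full model per force level; write chains and summaries."""
    profiles = read_profiles_csv(
        outdir / "profiles.csv", config.finger_weak, config.finger_strong
    )
    datasets = read_share_csv(outdir / "shares.csv", profiles)
    consts = normalization_constants(list(profiles.values()))
    spec = ModelSpec(
        free_terms=FULL_MODEL,
        variance_structure=config.mcmc.variance_structure,
        prior=config.mcmc.prior,
    )
    artifacts = []
    summaries = {}
    for data in datasets:
        seed = _level_seed(config.mcmc.seed, data.level_g)
        chain = run_chain(
            data, spec, consts, T=config.mcmc.T, burn_in=config.mcmc.burn_in, seed=seed
        )
        stem = f"chain_level_{data.level_g:g}"
        write_chain(chain, outdir / f"{stem}.csv", outdir / f"{stem}.json")
        artifacts += [f"{stem}.csv", f"{stem}.json"]
        summaries[data.level_g] = posterior_summary(chain)
    table = report_weights(summaries)
    table.to_csv(outdir / "weight_summaries.csv", index=False)
    artifacts.append("weight_summaries.csv")
    return artifacts


def _level_seed(seed: int, level_g: float) -> int:
    return int(
        np.random.SeedSequence([seed, 2, int(round(level_g * 1000))]).generate_state(1)[0]
    )


def report_weights(
    summaries: Dict[float, Dict[str, "ParamSummary"]],
) -> pd.DataFrame:
    """Tidy per-level weight summaries: level_g, parameter, median, lo95, hi95.

    Medians are marginal, so per level the three medians need not sum
    exactly to 1.
    """
    if not summaries:
        raise ValueError("no fitted levels")
    rows = []
    for g in sorted(summaries):
        for name in ("nu", "lam", "mu"):
            s = summaries[g][name]
            rows.append(
                {
                    "level_g": g,
                    "parameter": name,
                    "median": s.median,
                    "lo95": s.lo95,
                    "hi95": s.hi95,
                }
            )
    return pd.DataFrame(rows)


def compare_stage(config: RunConfig, outdir: Path) -> List[str]:
    """Fit all weight-subset models and both variance structures."""
    profiles = read_profiles_csv(
        outdir / "profiles.csv", config.finger_weak, config.finger_strong
    )
    datasets = read_share_csv(outdir / "shares.csv", profiles)
    consts = normalization_constants(list(profiles.values()))
    table = fit_all_models(
        datasets,
        consts,
        T=config.mcmc.T,
        burn_in=config.mcmc.burn_in,
        seed=config.mcmc.seed,
        prior=config.mcmc.prior,
    )
    table.to_csv(outdir / "comparison.csv")
    (outdir / "comparison.txt").write_text(table.to_text())
    return ["comparison.csv", "comparison.txt"]


def report_stage(config: RunConfig, outdir: Path) -> List[str]:
    """Figure-style outputs: association scatter, weights vs level, forces."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    artifacts = []

    prof_df = pd.read_csv(outdir / "profiles.csv", float_precision="round_trip")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(prof_df["mvc"], prof_df["k"] * 100, c="k", s=18)
    coef = np.polyfit(prof_df["mvc"], prof_df["k"] * 100, 1)
    xs = np.linspace(prof_df["mvc"].min(), prof_df["mvc"].max(), 50)
    ax.plot(xs, np.polyval(coef, xs), "k--")
    ax.set_xlabel("MVC (N)")
    ax.set_ylabel("k (%)")
    fig.tight_layout()
    fig.savefig(outdir / "fig_association.png", dpi=120)
    plt.close(fig)
    artifacts.append("fig_association.png")

    wdf = pd.read_csv(outdir / "weight_summaries.csv")
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, color in (("nu", "C2"), ("lam", "C0"), ("mu", "C1")):
        sub = wdf[wdf["parameter"] == name].sort_values("level_g")
        ax.plot(sub["level_g"], sub["median"], "-o", color=color, label=name)
        ax.plot(sub["level_g"], sub["lo95"], "--", color=color, lw=0.8)
        ax.plot(sub["level_g"], sub["hi95"], "--", color=color, lw=0.8)
    ax.set_xlabel("force level g (N)")
    ax.set_ylabel("posterior weight")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_weights.png", dpi=120)
    plt.close(fig)
    artifacts.append("fig_weights.png")

    # fitted versus produced forces at the posterior-median weights
    profiles = read_profiles_csv(
        outdir / "profiles.csv", config.finger_weak, config.finger_strong
    )
    datasets = read_share_csv(outdir / "shares.csv", profiles)
    consts = normalization_constants(list(profiles.values()))
    rows = []
    for data in datasets:
        sub = wdf[wdf["level_g"] == data.level_g].set_index("parameter")["median"]
        total = sub.sum()
        weights = CostWeights(
            nu=sub["nu"] / total, lam=sub["lam"] / total, mu=sub["mu"] / total
        )
        pairs = [profiles[pid] for pid in data.participant_ids]
        fitted = predict_forces(weights, consts, pairs, data.level_g)
        for pid, (u_i, u_j), y in zip(data.participant_ids, fitted, data.y):
            mean_share = float(np.mean(y))
            rows.append(
                {
                    "level_g": data.level_g,
                    "participant_id": pid,
                    "fitted_weak": u_i,
                    "fitted_strong": u_j,
                    "produced_weak": mean_share * data.level_g,
                    "produced_strong": (1 - mean_share) * data.level_g,
                }
            )
    fdf = pd.DataFrame(rows)
    fdf.to_csv(outdir / "forces.csv", index=False)
    artifacts.append("forces.csv")

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(fdf["fitted_weak"], fdf["produced_weak"], s=16, label="weak finger")
    ax.scatter(fdf["fitted_strong"], fdf["produced_strong"], s=16, label="strong finger")
    lim = max(fdf[["fitted_strong", "produced_strong"]].max())
    ax.plot([0, lim], [0, lim], "k:", lw=1)
    ax.set_xlabel("fitted force (N)")
    ax.set_ylabel("produced force (N)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "fig_forces.png", dpi=120)
    plt.close(fig)
    artifacts.append("fig_forces.png")
    return artifacts


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage in order and write the manifest; returns outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: List[str] = []
    stages = [
        ("simulate", simulate_stage),
        ("calibrate", calibrate_stage),
        ("fit", fit_stage),
        ("compare", compare_stage),
        ("report", report_stage),
    ]
    for name, fn in stages:
        with _Stage(name):
            artifacts += fn(config, outdir)
    _write_manifest(outdir, config, artifacts)
    return outdir
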
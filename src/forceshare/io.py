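"""CSV/JSON serialization for trials, profiles, shares and chains.

All tabular artifacts are plain CSV in long format so they round-trip
through pandas at full float precision:

* trials:   participant_id, finger_id, target_g, t, force
* profiles: participant_id, finger_id, k, mvc   (k as a fraction)
* shares:   level_g, participant_id, y
* chains:   one row per iteration, columns for every sampled parameter,
            plus a JSON sidecar with seed, lengths and acceptance rates.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .calibration import TrialRecording
from .mcmc import ModelSpec, PosteriorChain, ShareDataset
from .model import FingerProfile

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_share_csv",
    "read_share_csv",
    "write_chain",
    "read_chain",
]

def write_trials_csv(recs: Sequence[TrialRecording], path) -> None:
    frames = []
    for rec in recs:
        n = rec.samples.size
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": rec.participant_id,
                    "finger_id": rec.finger_id,
                    "target_g": rec.target_g,
                    "t": np.arange(n) / rec.rate,
                    "force": rec.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path) -> List[TrialRecording]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for (pid, fid, g), grp in df.groupby(
        ["participant_id", "finger_id", "target_g"], sort=True
    ):
        t = grp["t"].to_numpy()
        rate = 1.0 / np.median(np.diff(t)) if t.size > 1 else 200.0
        out.append(
            TrialRecording(
                finger_id=str(fid),
                target_g=float(g),
                samples=grp["force"].to_numpy(),
                rate=float(rate),
                participant_id=str(pid),
            )
        )
    return out


def write_profiles_csv(
    profiles: Dict[str, Tuple[FingerProfile, FingerProfile]], path
) -> None:
    rows = []
    for pid, pair in profiles.items():
        for prof in pair:
            rows.append(
                {
                    "participant_id": pid,
                    "finger_id": prof.finger_id,
                    "k": prof.k,
                    "mvc": prof.mvc,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(
    path, finger_weak: str, finger_strong: str
) -> Dict[str, Tuple[FingerProfile, FingerProfile]]:
    """Profiles keyed by participant, ordered (weak finger, strong finger)."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: Dict[str, Tuple[FingerProfile, FingerProfile]] = {}
    for pid, grp in df.groupby("participant_id", sort=True):
        by_finger = {
            str(r.finger_id): FingerProfile(str(r.finger_id), float(r.k), float(r.mvc))
            for r in grp.itertuples()
        }
        if finger_weak not in by_finger or finger_strong not in by_finger:
            raise ValueError(
                f"participant {pid}: missing profile for designated pair "
                f"({finger_weak}, {finger_strong})"
            )
        out[str(pid)] = (by_finger[finger_weak], by_finger[finger_strong])
    return out


def write_share_csv(datasets: Sequence[ShareDataset], path) -> None:
    frames = []
    for data in datasets:
        for pid, y in zip(data.participant_ids, data.y):
            frames.append(
                pd.DataFrame({"level_g": data.level_g, "participant_id": pid, "y": y})
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_share_csv(
    path, profiles: Dict[str, Tuple[FingerProfile, FingerProfile]]
) -> List[ShareDataset]:
    df = pd.read_csv(path, float_precision="round_trip")
    datasets = []
    for g, lvl in df.groupby("level_g", sort=True):
        pids = []
        ys = []
        pairs = []
        for pid, grp in lvl.groupby("participant_id", sort=True):
            pid = str(pid)
            if pid not in profiles:
                raise ValueError(f"no finger profiles for participant {pid}")
            pids.append(pid)
            ys.append(grp["y"].to_numpy())
            pairs.append(profiles[pid])
        datasets.append(
            ShareDataset(level_g=float(g), participant_ids=pids, y=ys, profiles=pairs)
        )
    return datasets


def write_chain(chain: PosteriorChain, csv_path, json_path) -> None:
    cols = {
        "iteration": np.arange(chain.n_iter),
        "w": chain.w,
        "z": chain.z,
        "nu": chain.nu,
        "lam": chain.lam,
        "mu": chain.mu,
    }
    if chain.sigma2.shape[1] == 1:
        cols["sigma2"] = chain.sigma2[:, 0]
    else:
        for m, pid in enumerate(chain.participant_ids):
            cols[f"sigma2[{pid}]"] = chain.sigma2[:, m]
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    meta = {
        "level_g": chain.level_g,
        "seed": chain.seed,
        "T": chain.n_iter,
        "burn_in": chain.burn_in,
        "free_terms": sorted(chain.spec.free_terms),
        "variance_structure": chain.spec.variance_structure,
        "prior": chain.spec.prior,
        "accept_rate_w": None if math.isnan(chain.accept_rate_w) else chain.accept_rate_w,
        "accept_rate_z": None if math.isnan(chain.accept_rate_z) else chain.accept_rate_z,
        "participant_ids": chain.participant_ids,
    }
    Path(json_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_chain(csv_path, json_path) -> PosteriorChain:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(Path(json_path).read_text())
    pids = list(meta["participant_ids"])
    if "sigma2" in df.columns:
        sigma2 = df[["sigma2"]].to_numpy()
    else:
        sigma2 = df[[f"sigma2[{pid}]" for pid in pids]].to_numpy()
    spec = ModelSpec(
        free_terms=frozenset(meta["free_terms"]),
        variance_structure=meta["variance_structure"],
        prior=meta["prior"],
    )
    nan = float("nan")
    return PosteriorChain(
        w=df["w"].to_numpy(),
        z=df["z"].to_numpy(),
        nu=df["nu"].to_numpy(),
        lam=df["lam"].to_numpy(),
        mu=df["mu"].to_numpy(),
        sigma2=sigma2,
        participant_ids=pids,
        burn_in=int(meta["burn_in"]),
        seed=int(meta["seed"]),
        spec=spec,
        level_g=float(meta["level_g"]),
        accept_rate_w=meta["accept_rate_w"] if meta["accept_rate_w"] is not None else nan,
        accept_rate_z=meta["accept_rate_z"] if meta["accept_rate_z"] is not None else nan,
        adapt_trace_w=np.array([]),
        adapt_trace_z=np.array([]),
    )
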
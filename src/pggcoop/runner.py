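"""Multi-generation, multi-replicate experiment driver.

A *replicate* is one full run of the model from a fresh random population;
an *experiment* is a set of replicates differing only in seed (replicate r
uses ``base_seed + r``, each with its own generator stream, so replicates
can run in any order with identical results).  ``run_grid`` sweeps the
Cartesian product of altruist-fraction, noise and stubbornness values and
summarizes each cell, with an optional on-disk cache keyed by a parameter
digest.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import INFINITE, PopulationState, SimParams, init_population
from .evolve import step_generation, update_population
from . import metrics as _metrics

__all__ = [
    "Trajectory",
    "SweepResult",
    "PROFILES",
    "apply_profile",
    "params_digest",
    "run_replicate",
    "run_experiment",
    "run_grid",
]

#: Guard against accidental huge runs (agents x generations).
MAX_AGENT_GENERATIONS = 2_000_000_000

#: Named run profiles: generations, replicates, asymptotic window.
PROFILES = {
    "full": {"generations": 20_000, "replicates": 30, "window": 5_000},
    "scaled": {"generations": 5_000, "replicates": 10, "window": 1_000},
}


def apply_profile(params: SimParams, profile: str) -> tuple[SimParams, int]:
    """Return (params with the profile's run lengths, asymptotic window)."""
    try:
        p = PROFILES[profile.lower()]
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
        ) from None
    return (
        params.with_(generations=p["generations"], replicates=p["replicates"]),
        p["window"],
    )


@dataclass
class Trajectory:
    """One replicate's cooperation-level time series and final strategies."""

    params_digest: str
    replicate_index: int
    coop_levels: np.ndarray  # float, length = generations
    final_ccc: np.ndarray  # int, length N
    final_is_altruist: np.ndarray  # bool, length N


@dataclass
class SweepResult:
    """Summary table over a (alpha, beta, w) grid."""

    rows: pd.DataFrame

    def cell(self, alpha: float, beta: float, w: float) -> pd.Series:
        df = self.rows
        beta_match = (
            np.isinf(df["beta"]) if math.isinf(beta) else df["beta"] == beta
        )
        sel = df[(df["alpha"] == alpha) & beta_match & (df["w"] == w)]
        if len(sel) != 1:
            raise KeyError(f"no unique grid cell ({alpha}, {beta}, {w})")
        return sel.iloc[0]


def params_digest(params: SimParams) -> str:
    """Stable short hash of every field that affects simulation output."""
    payload = {
        k: (repr(v) if not isinstance(v, (int, float, str, type(None))) else v)
        for k, v in vars(params).items()
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:16]


def run_replicate(params: SimParams, seed: int) -> Trajectory:
    """Run one replicate: initialise from ``seed`` and iterate the model for
    the configured number of generations, recording the cooperation level of
    every generation (the first being the conventional initial round)."""
    if params.n_agents * params.generations > MAX_AGENT_GENERATIONS:
        raise RuntimeError(
            f"run of {params.generations} generations x {params.n_agents} "
            f"agents exceeds the resource guard "
            f"({MAX_AGENT_GENERATIONS} agent-generations); split the run "
            "or raise pggcoop.runner.MAX_AGENT_GENERATIONS"
        )
    rng = np.random.default_rng(seed)
    state = init_population(params, rng)
    levels = np.empty(params.generations, dtype=float)
    levels[0] = state.cooperation_level()
    # generation 1's strategy update uses its conventional payoffs
    state = update_population(state, params, rng)
    for g in range(1, params.generations):
        state, rec = step_generation(state, params, rng)
        levels[g] = rec.coop_level
    return Trajectory(
        params_digest=params_digest(params),
        replicate_index=seed - params.base_seed,
        coop_levels=levels,
        final_ccc=state.ccc.copy(),
        final_is_altruist=state.is_altruist.copy(),
    )


def run_experiment(params: SimParams) -> list[Trajectory]:
    """Run all configured replicates with seeds base_seed, base_seed+1, ..."""
    return [
        run_replicate(params, params.base_seed + r)
        for r in range(params.replicates)
    ]


def _cache_path(cache_dir: Path, digest: str) -> Path:
    return Path(cache_dir) / f"summary_{digest}.json"


def run_grid(
    base: SimParams,
    alphas: Sequence[float],
    betas: Sequence[float],
    ws: Sequence[float],
    window: int | None = None,
    cache_dir: str | Path | None = None,
) -> SweepResult:
    """Summarize every cell of the (alpha, beta, w) grid.

    Each cell runs a full experiment over ``base`` with the three swept
    fields replaced, then reduces it with
    :func:`pggcoop.metrics.summarize`.  With ``cache_dir`` set, cell
    summaries are persisted as JSON keyed by the parameter digest and reused
    on rerun.
    """
    for name, vals in (("alpha", alphas), ("beta", betas), ("w", ws)):
        if len(vals) == 0:
            raise ValueError(f"empty grid list for {name}")
    for b in betas:
        if (not math.isinf(b)) and (b < 0 or math.isnan(b)):
            raise ValueError(f"invalid beta grid value {b}")
    for a in alphas:
        if not (0 <= a <= 1):
            raise ValueError(f"invalid alpha grid value {a}")
    for w in ws:
        if not (0 <= w <= 1):
            raise ValueError(f"invalid w grid value {w}")

    if window is None:
        window = min(5_000, base.generations)
    rows = []
    for a in alphas:
        for b in betas:
            for w in ws:
                cell = base.with_(
                    altruist_fraction=a, noise=b, stubbornness=w
                )
                digest = params_digest(cell)
                cached = None
                if cache_dir is not None:
                    path = _cache_path(Path(cache_dir), digest)
                    if path.exists():
                        cached = json.loads(path.read_text())
                if cached is None:
                    trajectories = run_experiment(cell)
                    stats = _metrics.summarize(trajectories, window)
                    cached = {
                        "alpha": a,
                        "beta": b,
                        "w": w,
                        "digest": digest,
                        "asymptotic_coop": stats.asymptotic_coop,
                        "asymptotic_sd": stats.asymptotic_sd,
                        "frac_ccc_zero": stats.frac_ccc_zero,
                        "frac_ccc_gt50": stats.frac_ccc_gt50,
                    }
                    if cache_dir is not None:
                        Path(cache_dir).mkdir(parents=True, exist_ok=True)
                        _cache_path(Path(cache_dir), digest).write_text(
                            json.dumps(
                                {
                                    k: ("inf" if isinstance(v, float)
                                        and math.isinf(v) else v)
                                    for k, v in cached.items()
                                }
                            )
                        )
                else:
                    if cached.get("beta") == "inf":
                        cached["beta"] = INFINITE
                rows.append(cached)
    return SweepResult(rows=pd.DataFrame(rows))
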
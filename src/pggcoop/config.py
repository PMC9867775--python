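"""Run configuration: YAML loading, validation, and tabular output writing.

Configs are flat key/value YAML documents whose keys mirror
:class:`pggcoop.core.SimParams`, plus run-level keys (output directory,
profile, thinning, grid lists, verbosity).  The string ``"inf"`` parses to
the infinite-noise-free limit of beta.  Unknown keys are rejected so typos
fail loudly before any simulation starts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import INFINITE, SimParams, UNSET
from .metrics import SummaryStats

__all__ = ["RunConfig", "load_config", "parse_beta", "write_outputs"]

_PARAM_KEYS = {
    "n_agents",
    "endowment",
    "contribution_cost",
    "enhancement",
    "altruist_fraction",
    "noise",
    "stubbornness",
    "mutation_rate",
    "mutation_sd",
    "mutation_bound",
    "generations",
    "replicates",
    "imitation_rule",
    "mutation_scope",
    "zero_ccc_rule",
    "initial_coop_fraction",
    "base_seed",
}
_RUN_KEYS = {
    "output_dir",
    "thinning",
    "profile",
    "alpha_grid",
    "beta_grid",
    "w_grid",
    "verbosity",
}

#: RNG-consumption-order contract version; bump if the per-generation draw
#: order ever changes, so determinism breaks are detectable downstream.
RNG_ORDER_VERSION = 1


def parse_beta(value) -> float:
    """Parse a noise value; the strings 'inf'/'infinity' (any case) map to
    the infinite limit."""
    if isinstance(value, str):
        if value.strip().lower() in {"inf", "infinity", "∞"}:
            return INFINITE
        value = float(value)
    value = float(value)
    if math.isnan(value) or value < 0:
        raise ValueError(f"noise must be >= 0 or 'inf', got {value}")
    return value


@dataclass
class RunConfig:
    """Validated run configuration: model parameters plus run-level I/O."""

    params: SimParams = field(default_factory=SimParams)
    output_dir: str = "pggcoop_out"
    thinning: int = 1
    profile: str | None = None
    alpha_grid: list = field(default_factory=list)
    beta_grid: list = field(default_factory=list)
    w_grid: list = field(default_factory=list)
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d["imitation_rule"] = self.params.imitation_rule.value
        d["mutation_scope"] = self.params.mutation_scope.value
        d["zero_ccc_rule"] = self.params.zero_ccc_rule.value
        if math.isinf(d["noise"]):
            d["noise"] = "inf"
        for key in _RUN_KEYS:
            val = getattr(self, key)
            if key == "beta_grid":
                val = ["inf" if isinstance(b, float) and math.isinf(b) else b
                       for b in val]
            d[key] = val
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_config(path: str | Path | None = None, overrides: dict | None = None
                ) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` (e.g. CLI flags) win
    over file values.  An empty or missing-keys config yields the default
    parameterization (N=100, e=10, u=0.5, h=1.5, 5% mutation with sd 5 and
    bound 50, 20,000 generations, 30 replicates)."""
    raw: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        try:
            loaded = yaml.safe_load(p.read_text())
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed YAML in {p}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {p} must be a mapping of keys to values")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    param_kwargs = {k: raw[k] for k in _PARAM_KEYS & set(raw)}
    if "noise" in param_kwargs:
        param_kwargs["noise"] = parse_beta(param_kwargs["noise"])
    if param_kwargs.get("initial_coop_fraction") in ("unset", "none"):
        param_kwargs["initial_coop_fraction"] = UNSET
    try:
        params = SimParams(**param_kwargs)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid parameter value: {exc}") from exc

    run_kwargs = {k: raw[k] for k in _RUN_KEYS & set(raw)}
    if "beta_grid" in run_kwargs:
        run_kwargs["beta_grid"] = [parse_beta(b) for b in run_kwargs["beta_grid"]]
    cfg = RunConfig(params=params, **run_kwargs)
    if cfg.thinning < 1:
        raise ValueError("thinning must be a positive integer")
    if cfg.profile is not None and cfg.profile.lower() not in {"full", "scaled"}:
        raise ValueError(f"profile must be 'full' or 'scaled', got {cfg.profile}")
    return cfg


def _fmt(x: float) -> float:
    """Round to 6 significant digits for machine-readable summaries."""
    return float(f"{x:.6g}")


def write_outputs(
    trajectories,
    summary: SummaryStats,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict[str, Path]:
    """Write the three run artifacts and return their paths.

    - ``trajectories.csv``: tidy per-generation cooperation levels
      (replicate, generation, coop_level), keeping every
      ``config.thinning``-th generation.
    - ``final_ccc.csv``: replicate, agent_index, agent_type, ccc at the
      final generation (R x N rows).
    - ``summary.json``: asymptotic statistics, full parameter echo, seeds
      and code version, numbers at 6 significant digits.
    """
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    k = config.thinning
    rows = []
    for t in trajectories:
        idx = np.arange(0, len(t.coop_levels), k)
        for g in idx:
            rows.append((t.replicate_index, int(g) + 1, t.coop_levels[g]))
    traj_df = pd.DataFrame(
        rows, columns=["replicate", "generation", "coop_level"]
    )
    traj_path = out / "trajectories.csv"
    traj_df.to_csv(traj_path, index=False, float_format="%.6g")

    ccc_rows = []
    for t in trajectories:
        for i, (alt, ccc) in enumerate(zip(t.final_is_altruist, t.final_ccc)):
            ccc_rows.append(
                (
                    t.replicate_index,
                    i,
                    "altruist" if alt else "conditional",
                    int(ccc),
                )
            )
    ccc_df = pd.DataFrame(
        ccc_rows, columns=["replicate", "agent_index", "agent_type", "ccc"]
    )
    ccc_path = out / "final_ccc.csv"
    ccc_df.to_csv(ccc_path, index=False)

    summary_doc = {
        "asymptotic_coop": _fmt(summary.asymptotic_coop),
        "asymptotic_sd": _fmt(summary.asymptotic_sd),
        "frac_ccc_zero": _fmt(summary.frac_ccc_zero),
        "frac_ccc_gt50": _fmt(summary.frac_ccc_gt50),
        "params": config.to_dict(),
        "replicate_seeds": [
            config.params.base_seed + r
            for r in range(len(trajectories))
        ],
        "code_version": __version__,
        "rng_order_version": RNG_ORDER_VERSION,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary_doc, indent=2))
    return {
        "trajectories": traj_path,
        "final_ccc": ccc_path,
        "summary": summary_path,
    }
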
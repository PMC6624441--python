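"""Delimited-text input/output for trial tables, draws, summaries and configs."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import PosteriorDraws, SamplerConfig
from .model import ModelConfig

__all__ = [
    "read_trials",
    "read_covariates",
    "write_draws",
    "read_draws",
    "write_truth",
    "read_truth",
    "load_config",
    "write_manifest",
]

_TRIAL_COLUMNS = ["person_id", "session", "trial_type", "rt"]

_CONFIG_KEYS = {
    "form",
    "beta_scale",
    "delta_scale",
    "sigma_scale",
    "correlated_effects",
    "standardize",
    "min_rt",
    "max_rt",
    "max_rt_policy",
    "rt_unit",
    "n_chains",
    "n_iterations",
    "n_burnin",
    "seed",
    "design",
    "truth",
    "n_rep",
    "n_persons",
    "trials_per_cell",
}

_DESIGN_KEYS = {
    "n_persons",
    "runs_per_session",
    "trials_per_run",
    "frequent_go_fraction",
    "reward_run_fraction",
    "rt_window",
    "window_enabled",
}


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trial columns {sorted(missing)}")
    return df


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "person_id" not in df.columns:
        raise ValueError(f"{path}: covariate table needs a person_id column")
    return df


def write_draws(draws: PosteriorDraws, path) -> None:
    """Persist draws as long-format CSV (chain, iteration, parameter, value)."""
    df = draws.to_dataframe()
    meta_keys = dict(
        form=draws.model_config.form,
        n_chains=draws.config.n_chains,
        n_iterations=draws.config.n_iterations,
        n_burnin=draws.config.n_burnin,
        person_ids=",".join(map(str, draws.person_ids)),
        covariate_names=",".join(draws.covariate_names),
    )
    path = Path(path)
    with path.open("w") as fh:
        for k, v in meta_keys.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_draws(path) -> PosteriorDraws:
    path = Path(path)
    meta = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            skip += 1
            k, _, v = line[2:].partition(":")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=skip)
    names = list(dict.fromkeys(df["parameter"]))
    n_chains = int(df["chain"].max()) + 1
    n_iter = int(df["iteration"].max()) + 1
    arr = (
        df.set_index(["chain", "iteration", "parameter"])["value"]
        .unstack("parameter")[names]
        .to_numpy()
        .reshape(n_chains, n_iter, len(names))
    )
    scfg = SamplerConfig(
        n_chains=int(meta.get("n_chains", n_chains)),
        n_iterations=int(meta.get("n_iterations", n_iter)),
        n_burnin=int(meta.get("n_burnin", 0)),
    )
    mcfg = ModelConfig(form=meta.get("form", "direct"))
    return PosteriorDraws(
        samples=arr,
        names=names,
        config=scfg,
        model_config=mcfg,
        person_ids=meta.get("person_ids", "").split(",") if meta.get("person_ids") else [],
        covariate_names=meta.get("covariate_names", "").split(",")
        if meta.get("covariate_names")
        else [],
    )


def write_truth(truth, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(truth.as_dict(), fh, indent=2)


def read_truth(path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)


def load_config(path) -> dict:
    """Load a YAML run config, rejecting unknown keys."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    design = cfg.get("design") or {}
    bad = set(design) - _DESIGN_KEYS
    if bad:
        raise ValueError(f"{path}: unknown design keys: {sorted(bad)}")
    return cfg


def write_manifest(out_dir, command: str, seed, config: dict, paths: dict) -> Path:
    """One manifest per run: command, settings snapshot, artifact paths."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "paths": {k: str(v) for k, v in paths.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    with path.open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
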
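"""Configuration files, tabular writers, and run manifests.

Configs are JSON or YAML key-value documents validated against a strict
schema (unknown keys are rejected, offending key named). Rates may be given
either directly (``parameters``) or as per-species life-history blocks
(``life_history``) from which they are derived. Units are fixed: years and
individuals per km^2; output headers echo them.

Outputs are plain text: CSV for tabular results (trajectories, sweeps,
ensemble records), JSON for structured ones (equilibria, bifurcation
points), plus a ``manifest.json`` carrying the package version, the
config hash and the file checksums so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError
from .params import (
    PARAM_NAMES,
    LifeHistory,
    Parameters,
    parameters_from_life_histories,
)

__all__ = ["RunConfig", "load_config", "write_outputs", "DEFAULT_SEED"]

logger = logging.getLogger("hyperpredation")

DEFAULT_SEED = 0

_TOP_KEYS = {"parameters", "life_history", "hunting", "init", "t_end", "seed",
             "sweep", "ensemble", "output_dir"}
_LIFE_KEYS = {"mean_lifespan", "annual_multiplication", "carrying_capacity"}
_SWEEP_KEYS = {"parameter", "start", "stop", "n_grid"}
_ENSEMBLE_KEYS = {"n", "semiwidth", "jitter_hunting"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration with defaults resolved."""

    parameters: Parameters
    init: tuple[float, float, float]
    t_end: float
    seed: int
    sweep: dict | None
    ensemble: dict | None
    output_dir: str
    defaulted: tuple[str, ...] = field(default=())
    source_text: str = field(default="", repr=False)


def _reject_unknown(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _positive_number(value, key: str, nonnegative: bool = False):
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"key {key!r} must be a number, got {value!r}")
    if nonnegative and value < 0:
        raise ConfigError(f"key {key!r} must be nonnegative, got {value}")
    if not nonnegative and value <= 0:
        raise ConfigError(f"key {key!r} must be positive, got {value}")
    return float(value)


def _parse_parameters(doc: dict) -> Parameters:
    has_raw = "parameters" in doc
    has_lh = "life_history" in doc
    if has_raw == has_lh:
        raise ConfigError("config must contain exactly one of 'parameters' or 'life_history'")
    hunting = doc.get("hunting", {})
    _reject_unknown(hunting, {"a", "b"}, "'hunting'")
    a = _positive_number(hunting["a"], "hunting.a", nonnegative=True) if "a" in hunting else None
    b = _positive_number(hunting["b"], "hunting.b", nonnegative=True) if "b" in hunting else None

    if has_raw:
        block = doc["parameters"]
        _reject_unknown(block, set(PARAM_NAMES), "'parameters'")
        for key, value in block.items():
            _positive_number(value, f"parameters.{key}", nonnegative=True)
        merged = dict(block)
        if a is not None:
            merged["a"] = a
        if b is not None:
            merged["b"] = b
        try:
            return Parameters.from_dict(merged)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    block = doc["life_history"]
    _reject_unknown(block, {"fox", "cottontail", "hare", "e"}, "'life_history'")
    species = {}
    for name in ("fox", "cottontail", "hare"):
        if name not in block:
            raise ConfigError(f"life_history block is missing species {name!r}")
        sub = block[name]
        _reject_unknown(sub, _LIFE_KEYS, f"'life_history.{name}'")
        for key in _LIFE_KEYS:
            if key not in sub:
                raise ConfigError(f"life_history.{name} is missing key {key!r}")
            _positive_number(sub[key], f"life_history.{name}.{key}")
        species[name] = LifeHistory(**sub)
    e = block.get("e", 0.91)
    params = parameters_from_life_histories(
        species["fox"], species["cottontail"], species["hare"], e=e, a=a, b=b
    )
    logger.info("derived rates from life histories: %s", params.to_dict())
    return params


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Defaults (logged with provenance): init (0.4, 1, 3) per km^2,
    t_end 500 years, seed 0, output_dir 'results'.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    _reject_unknown(doc, _TOP_KEYS, "config root")

    parameters = _parse_parameters(doc)

    defaulted: list[str] = []

    def get(key: str, default):
        if key in doc:
            return doc[key]
        defaulted.append(key)
        logger.info("config key %r defaulted to %r", key, default)
        return default

    init = get("init", [0.4, 1.0, 3.0])
    if not (isinstance(init, (list, tuple)) and len(init) == 3):
        raise ConfigError(f"key 'init' must be a list of three densities, got {init!r}")
    init = tuple(_positive_number(x, "init", nonnegative=True) for x in init)
    t_end = _positive_number(get("t_end", 500.0), "t_end")
    seed = get("seed", DEFAULT_SEED)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"key 'seed' must be an integer, got {seed!r}")

    sweep_block = doc.get("sweep")
    if sweep_block is not None:
        _reject_unknown(sweep_block, _SWEEP_KEYS, "'sweep'")
        for key in _SWEEP_KEYS:
            if key not in sweep_block:
                raise ConfigError(f"sweep block is missing key {key!r}")
    ensemble_block = doc.get("ensemble")
    if ensemble_block is not None:
        _reject_unknown(ensemble_block, _ENSEMBLE_KEYS, "'ensemble'")

    return RunConfig(
        parameters=parameters,
        init=init,
        t_end=t_end,
        seed=seed,
        sweep=sweep_block,
        ensemble=ensemble_block,
        output_dir=str(get("output_dir", "results")),
        defaulted=tuple(defaulted),
        source_text=text,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        if np.iscomplexobj(obj):
            return [[float(z.real), float(z.imag)] for z in obj]
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, complex):
        return [obj.real, obj.imag]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_outputs(results: dict, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Write results to ``out_dir`` and return the manifest.

    DataFrames go to ``<name>.csv``, everything else JSON-serializable to
    ``<name>.json``. The manifest records each file's sha256, the package
    version, the seed and the config hash.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for name, payload in results.items():
        if isinstance(payload, pd.DataFrame):
            target = out / f"{name}.csv"
            payload.to_csv(target, index=False)
        else:
            target = out / f"{name}.json"
            target.write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))
        files[target.name] = hashlib.sha256(target.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "files": files,
        "seed": config.seed if config is not None else None,
        "config_sha256": hashlib.sha256(config.source_text.encode()).hexdigest()
        if config is not None
        else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("wrote %d result files to %s", len(files), out)
    return manifest
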
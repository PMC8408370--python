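"""File formats and run manifests.

Observation matrices travel as CSV with a header row of series names, one
row per time point and one column per spatial dimension.  Thinned chains are
written in long format (time, k, n, value) so they round-trip through plain
pandas; skeleton replays can also be dumped to a compact ``.npz`` container
(arrays ``times``, ``samples``, scalar ``delta``).  Every sampler run emits
a JSON manifest recording the configuration, seed and model fingerprint.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diagnostics import DiscretizedChain
from .errors import ParameterError, ShapeError

__all__ = [
    "read_observations_csv",
    "write_observations_csv",
    "write_chain_csv",
    "read_chain_csv",
    "write_chain_npz",
    "read_chain_npz",
    "write_event_log_csv",
    "write_manifest",
    "load_config",
    "validate_config",
]


def read_observations_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a d x N observation matrix from CSV (rows = time, cols = space).

    Returns (y, column names) with y transposed to the package's (d, N)
    convention.  Ragged rows or non-numeric cells raise :class:`ShapeError`.
    """
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ShapeError(f"could not parse observation CSV {path}: {exc}") from exc
    if frame.empty:
        raise ShapeError(f"observation CSV {path} has no rows")
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ShapeError(f"observation CSV {path} contains non-finite values")
    return values.T.copy(), list(frame.columns)


def write_observations_csv(path, y: np.ndarray, names: list[str] | None = None) -> None:
    y = np.asarray(y, dtype=float)
    d = y.shape[0]
    names = names or [f"series_{k}" for k in range(d)]
    pd.DataFrame(y.T, columns=names).to_csv(path, index=False)


def write_chain_csv(path, chain: DiscretizedChain) -> None:
    """Long-format dump: one row per (time, k, n, value)."""
    n, d, N = chain.samples.shape
    kk, nn = np.meshgrid(np.arange(d), np.arange(N), indexing="ij")
    frame = pd.DataFrame(
        {
            "time": np.repeat(chain.times, d * N),
            "k": np.tile(kk.ravel(), n),
            "n": np.tile(nn.ravel(), n),
            "value": chain.samples.reshape(n, -1).ravel(),
        }
    )
    frame.to_csv(path, index=False)


def read_chain_csv(path) -> DiscretizedChain:
    frame = pd.read_csv(path)
    required = {"time", "k", "n", "value"}
    if set(frame.columns) != required:
        raise ShapeError(f"chain CSV must have columns {sorted(required)}")
    times = np.sort(frame["time"].unique())
    d = int(frame["k"].max()) + 1
    N = int(frame["n"].max()) + 1
    samples = (
        frame.sort_values(["time", "k", "n"])["value"]
        .to_numpy()
        .reshape(len(times), d, N)
    )
    delta = float(times[1] - times[0]) if len(times) > 1 else float(times[0] or 1.0)
    return DiscretizedChain(times=times, samples=samples, delta=delta)


def write_chain_npz(path, chain: DiscretizedChain) -> None:
    """Compact binary container: arrays ``times`` (n,), ``samples`` (n,d,N),
    scalar ``delta``; written with numpy's uncompressed .npz layout."""
    np.savez(path, times=chain.times, samples=chain.samples, delta=chain.delta)


def read_chain_npz(path) -> DiscretizedChain:
    with np.load(path) as data:
        return DiscretizedChain(
            times=data["times"], samples=data["samples"], delta=float(data["delta"])
        )


def write_event_log_csv(path, skeleton) -> None:
    frame = skeleton.event_log_frame()
    frame.to_csv(path, index=False)


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path, *, config: dict, seed: int, model_desc: dict,
                   counters: dict | None = None) -> None:
    manifest = {
        "config": config,
        "seed": seed,
        "model": model_desc,
        "config_hash": _config_hash({"config": config, "model": model_desc}),
        "counters": counters or {},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_MODEL_KEYS = {
    "lgssm": {"name", "d", "N", "sigma2", "psi"},
    "sv": {"name", "d", "N", "nu"},
}
_SAMPLER_KEYS = {
    "sampler", "width", "overlap", "s_width", "t_width", "s_overlap",
    "t_overlap", "theta", "gamma", "horizon", "delta", "seed",
}


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration and validate its schema."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema check; raises :class:`ParameterError` listing offending keys."""
    if not isinstance(cfg, dict):
        raise ParameterError("config must be a mapping")
    if "model" not in cfg:
        raise ParameterError("config is missing required key: 'model'")
    model = cfg["model"]
    if not isinstance(model, dict) or "name" not in model:
        raise ParameterError("config 'model' block must be a mapping with a 'name'")
    name = model["name"]
    if name not in _MODEL_KEYS:
        raise ParameterError(
            f"unknown model name {name!r}; expected one of {sorted(_MODEL_KEYS)}"
        )
    unknown = set(model) - _MODEL_KEYS[name]
    if unknown:
        raise ParameterError(
            f"unknown keys in 'model' block: {sorted(unknown)}"
        )
    missing = _MODEL_KEYS[name] - set(model)
    if missing:
        raise ParameterError(f"missing keys in 'model' block: {sorted(missing)}")
    sampler = cfg.get("sampler", {})
    if not isinstance(sampler, dict):
        raise ParameterError("config 'sampler' block must be a mapping")
    unknown = set(sampler) - _SAMPLER_KEYS
    if unknown:
        raise ParameterError(f"unknown keys in 'sampler' block: {sorted(unknown)}")
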
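"""JSON model configuration and reference fixtures.

Schema (all physical parameters in the units of the field equation)::

    {
      "p": 1, "period": 6.2832, "N": 64,
      "leak": 1.0 | [l_1, ...],
      "c": 1.0, "sigma": 1.0, "h": 0.0, "s1": 0.25, "centered": true,
      "kernel": {"type": "cosine", "coeffs": [[0, -1.0], [2, 1.5]]}
              | {"type": "matrix", "values": [[...]]},
      "delay": {"type": "ring"} | {"type": "matrix", "values": [[...]]},
      "I_ext": 0.0 | [[...]]
    }

Unknown keys are rejected; loading is deterministic.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import (
    CosineKernel,
    DelaySpec,
    MatrixKernel,
    NeuralFieldModel,
    SigmoidSpec,
    SpatialGrid,
)

__all__ = ["ConfigError", "load_config", "save_config", "model_from_config",
           "model_to_config", "make_fixtures"]

_KNOWN_KEYS = {
    "p", "period", "N", "leak", "c", "sigma", "h", "s1", "centered",
    "kernel", "delay", "I_ext", "schema_version",
}
_DEFAULTS = {
    "p": 1,
    "period": 2 * np.pi,
    "N": 64,
    "leak": 1.0,
    "c": 0.0,
    "sigma": 1.0,
    "h": 0.0,
    "s1": 0.25,
    "centered": True,
    "delay": {"type": "ring"},
    "I_ext": 0.0,
    "schema_version": 1,
}


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> dict:
    """Load and validate a model config, filling defaults."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a JSON object")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = dict(_DEFAULTS)
    cfg.update(raw)
    if "kernel" not in cfg:
        raise ConfigError("config must define 'kernel'")
    for key in ("period", "sigma", "s1"):
        if not cfg[key] > 0:
            raise ConfigError(f"'{key}' must be positive")
    if cfg["c"] < 0:
        raise ConfigError("'c' must be >= 0")
    leak = np.atleast_1d(np.asarray(cfg["leak"], dtype=float))
    if np.any(leak <= 0):
        raise ConfigError("'leak' rates must be positive")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg, indent=1, sort_keys=True) + "\n")


def model_from_config(cfg: dict) -> NeuralFieldModel:
    grid = SpatialGrid.uniform_ring(int(cfg["N"]), float(cfg["period"]))
    kspec = cfg["kernel"]
    if kspec.get("type") == "cosine":
        kernel = CosineKernel([(float(w), float(a)) for w, a in kspec["coeffs"]],
                              period=grid.period)
    elif kspec.get("type") == "matrix":
        kernel = MatrixKernel(np.asarray(kspec["values"], dtype=float))
    else:
        raise ConfigError("kernel.type must be 'cosine' or 'matrix'")
    dspec = cfg["delay"]
    if dspec.get("type") == "ring":
        delay = DelaySpec(c=float(cfg["c"]))
    elif dspec.get("type") == "matrix":
        delay = DelaySpec(c=float(cfg["c"]),
                          matrix_values=np.asarray(dspec["values"], dtype=float))
    else:
        raise ConfigError("delay.type must be 'ring' or 'matrix'")
    sig = SigmoidSpec(
        gain=float(cfg["sigma"]),
        threshold=float(cfg["h"]),
        s1=float(cfg["s1"]),
        centered=bool(cfg["centered"]),
    )
    i_ext = cfg["I_ext"]
    if isinstance(i_ext, list):
        i_ext = np.asarray(i_ext, dtype=float)
    return NeuralFieldModel(
        grid=grid,
        leak=np.atleast_1d(np.asarray(cfg["leak"], dtype=float)),
        kernel=kernel,
        delay=delay,
        sigmoid=sig,
        populations=int(cfg["p"]),
        i_ext=i_ext,
    )


def model_to_config(model: NeuralFieldModel) -> dict:
    if isinstance(model.kernel, CosineKernel):
        kernel = {"type": "cosine", "coeffs": [[w, a] for w, a in model.kernel.coeffs]}
    else:
        kernel = {"type": "matrix", "values": model.kernel.values.tolist()}
    delay = ({"type": "ring"} if model.delay.ring
             else {"type": "matrix", "values": model.delay.matrix_values.tolist()})
    i_ext = model.i_ext
    if isinstance(i_ext, np.ndarray):
        i_ext = i_ext.tolist()
    elif callable(i_ext):
        raise ConfigError("callable external currents cannot be serialized")
    return {
        "p": model.populations,
        "period": model.grid.period,
        "N": model.n,
        "leak": model.leak.tolist() if model.leak.size > 1 else float(model.leak[0]),
        "c": model.delay.c,
        "sigma": model.sigmoid.gain,
        "h": model.sigmoid.threshold,
        "s1": model.sigmoid.s1,
        "centered": model.sigmoid.centered,
        "kernel": kernel,
        "delay": delay,
        "I_ext": i_ext,
        "schema_version": 1,
    }


# ---------------------------------------------------------------------------
# fixtures: the printed reference models
# ---------------------------------------------------------------------------

def make_fixtures(outdir: str | Path) -> list[Path]:
    """Write the reference model configs used throughout the package.

    * ``fig1.json`` — scalar ring, unit leak, ``J(x) = -1 + 1.5 cos(2x)``,
      saw delay at ``c = 1``: the eigenvalue-accumulation example.
    * ``fig2.json`` — same model with ``c`` and ``sigma`` as sweep
      placeholders for the two-parameter bifurcation diagram.
    * ``toy0.json`` — zero connectivity (pure leak) sanity model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = {
        "p": 1,
        "period": 2 * np.pi,
        "N": 64,
        "leak": 1.0,
        "h": 0.0,
        "s1": 0.25,
        "centered": True,
        "kernel": {"type": "cosine", "coeffs": [[0, -1.0], [2, 1.5]]},
        "delay": {"type": "ring"},
        "I_ext": 0.0,
        "schema_version": 1,
    }
    fig1 = dict(base, c=1.0, sigma=1.0)
    fig2 = dict(base, c=1.0, sigma=1.0)  # c, sigma swept by the caller
    toy0 = dict(base, c=0.0, sigma=1.0)
    toy0["kernel"] = {"type": "cosine", "coeffs": []}
    paths = []
    for name, cfg in [("fig1.json", fig1), ("fig2.json", fig2), ("toy0.json", toy0)]:
        p = outdir / name
        save_config(cfg, p)
        paths.append(p)
    return paths
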
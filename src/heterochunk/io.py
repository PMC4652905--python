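"""Configuration files, state serialization and run manifests.

Configs are YAML with sections ``model``, ``plasticity``, ``stimulus``,
``init`` and top-level run keys; every omitted key takes the package default
(the shipped ``defaults.yaml`` records them).  Weight sets and network
states round-trip through HDF5; matrices are additionally exportable as CSV
for weight-matrix snapshots.  A manifest (JSON) captures the full config,
the seed and checksums of produced files, and is sufficient to re-execute a
run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ModelParams, NetworkState
from .experiment import InitSpec, RunConfig, StimulusSpec
from .plasticity import PlasticityParams, TraceState, WeightSet

__all__ = [
    "load_config", "save_config", "config_to_dict", "config_from_dict",
    "save_state", "load_state", "export_weights_csv", "write_manifest",
]

_SECTIONS = {
    "model": ModelParams,
    "plasticity": PlasticityParams,
    "stimulus": StimulusSpec,
    "init": InitSpec,
}
_SKIP_FIELDS = {"b_z_fn"}  # callables are code, not config


def _fill(cls, d: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)} - _SKIP_FIELDS
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown key '{section}.{sorted(unknown)[0]}'")
    try:
        return cls(**d)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid section '{section}': {exc}") from exc


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _fill(cls, d.pop(name, {}) or {}, name)
    run_names = {f.name for f in dataclasses.fields(RunConfig)} - set(_SECTIONS)
    unknown = set(d) - run_names
    if unknown:
        raise ValueError(f"unknown key '{sorted(unknown)[0]}'")
    try:
        return RunConfig(**kwargs, **d)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc


def config_to_dict(config: RunConfig) -> dict:
    out = {}
    for name in _SECTIONS:
        sec = dataclasses.asdict(getattr(config, name))
        for k in list(sec):
            if k in _SKIP_FIELDS:
                del sec[k]
            elif isinstance(sec[k], np.ndarray):
                sec[k] = sec[k].tolist()
        out[name] = sec
    for f in dataclasses.fields(RunConfig):
        if f.name not in _SECTIONS:
            out[f.name] = getattr(config, f.name)
    return out


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (defaults filled in)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return config_from_dict(d)


def save_config(config: RunConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def save_state(path, weights: WeightSet, state: NetworkState = None):
    """Lossless HDF5 round-trip of weights (and optionally network state)."""
    import h5py

    with h5py.File(path, "w") as fh:
        g = fh.create_group("weights")
        for name in ("P", "V", "W", "Q", "R"):
            g.create_dataset(name, data=getattr(weights, name))
        if state is not None:
            g2 = fh.create_group("state")
            for name in ("x", "y", "z"):
                g2.create_dataset(name, data=getattr(state, name))
            g2.attrs["t"] = state.t
            g2.create_dataset("a_x", data=state.traces.a_x)
            g2.create_dataset("a_y", data=state.traces.a_y)


def load_state(path):
    """Inverse of :func:`save_state`; returns ``(weights, state_or_None)``."""
    import h5py

    with h5py.File(path, "r") as fh:
        g = fh["weights"]
        weights = WeightSet(*(np.asarray(g[n]) for n in ("P", "V", "W", "Q", "R")))
        state = None
        if "state" in fh:
            g2 = fh["state"]
            state = NetworkState(
                np.asarray(g2["x"]), np.asarray(g2["y"]), np.asarray(g2["z"]),
                float(g2.attrs["t"]),
                TraceState(np.asarray(g2["a_x"]), np.asarray(g2["a_y"])),
            )
    return weights, state


def export_weights_csv(weights: WeightSet, out_dir, prefix: str = ""):
    """Write each coupling matrix as CSV (weight-matrix snapshots)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("P", "V", "W", "Q", "R"):
        p = out_dir / f"{prefix}{name}.csv"
        np.savetxt(p, getattr(weights, name), delimiter=",", fmt="%.10g")
        paths[name] = p
    return paths


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(out_dir, config: RunConfig, seed: int, files=(),
                   summary: dict = None):
    """JSON manifest: config snapshot, seed, code version, file checksums.

    An artifact directory can be regenerated from its manifest alone (the
    config and seed fully determine every output).
    """
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config": config_to_dict(config),
        "files": {
            str(Path(f).name): _sha256(f) for f in files if Path(f).exists()
        },
    }
    if summary:
        manifest["summary"] = summary
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return path
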
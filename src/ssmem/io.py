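"""Run configuration (TOML), chain serialization and manifests.

A run is fully reproducible from (config, seed): the serialized config has
every default materialised, and the chain directory carries a manifest with
the config hash, seeds, package version and per-file checksums.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .filters import PFConfig
from .gibbs import InferenceConfig, PosteriorSamples

__all__ = ["RunConfig", "load_config", "dump_config", "save_chains", "load_chains"]

_SCHEMA = {
    "run": {"benchmark": "ou", "dataset": "", "output_dir": "chains", "seed": 1},
    "inference": {
        "n_iterations": 1000, "burn_in": 0.2, "thinning": 1, "mode": "perturbed",
        "delta": 0.1, "eta_kind": "conjugate_niw", "proposal_kind": "RAM",
        "target_accept": 0.234, "proposal_beta": 0.66, "sigma0": 0.1,
    },
    "pf": {
        "n_particles": 50, "kind": "bootstrap", "integrator": "langevin",
        "dt": 0.1, "rho": 0.0, "ess_threshold": 0.5,
    },
}


@dataclass
class RunConfig:
    """Fully-resolved run configuration (all defaults explicit)."""

    run: dict = field(default_factory=lambda: dict(_SCHEMA["run"]))
    inference: dict = field(default_factory=lambda: dict(_SCHEMA["inference"]))
    pf: dict = field(default_factory=lambda: dict(_SCHEMA["pf"]))

    def inference_config(self) -> InferenceConfig:
        pf_kwargs = dict(self.pf)
        n = pf_kwargs.pop("n_particles")
        if isinstance(n, list):
            n = max(int(v) for v in n)  # engine cap; per-individual list validated upstream
        return InferenceConfig(pf=PFConfig(n_particles=int(n), **pf_kwargs), **self.inference)

    def to_dict(self) -> dict:
        return {"run": dict(self.run), "inference": dict(self.inference), "pf": dict(self.pf)}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _validate_section(name: str, given: dict, schema: dict) -> dict:
    unknown = sorted(set(given) - set(schema))
    if unknown:
        raise ValueError(f"unknown config keys in [{name}]: {', '.join(unknown)}")
    out = dict(schema)
    out.update(given)
    return out


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load and resolve a TOML run configuration; unknown keys are rejected
    and cross-field constraints are checked."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = sorted(set(raw) - set(_SCHEMA))
    if unknown:
        raise ValueError(f"unknown config sections: {', '.join(unknown)}")
    cfg = RunConfig(
        run=_validate_section("run", raw.get("run", {}), _SCHEMA["run"]),
        inference=_validate_section("inference", raw.get("inference", {}), _SCHEMA["inference"]),
        pf=_validate_section("pf", raw.get("pf", {}), _SCHEMA["pf"]),
    )
    if isinstance(cfg.pf["n_particles"], list) and cfg.inference["mode"] != "perturbed":
        raise ValueError("per-individual particle counts require mode = 'perturbed'")
    cfg.inference_config()  # surface value errors early
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, list):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return json.dumps(str(v))


def dump_config(cfg: RunConfig, path: Union[str, Path]) -> None:
    """Write a config back to TOML with every default explicit (lossless
    round-trip through :func:`load_config`)."""
    lines = []
    for section, values in cfg.to_dict().items():
        lines.append(f"[{section}]")
        for k, v in values.items():
            lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

_BLOCKS = ("c", "kappa", "xi", "mu", "omega")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_chains(
    samples: PosteriorSamples,
    out_dir: Union[str, Path],
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write posterior chains as delimited text (one file per block) plus a
    binary container and a checksummed manifest; returns the manifest."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "chains.npz", **{b: getattr(samples, b) for b in _BLOCKS})
    n = samples.n_save
    frames = {
        "c": pd.DataFrame(samples.c.reshape(n, -1),
                          columns=[f"cell{i}_c{k}" for i in range(samples.c.shape[1])
                                   for k in range(samples.c.shape[2])]),
        "kappa": pd.DataFrame(samples.kappa, columns=[f"kappa{k}" for k in range(samples.kappa.shape[1])]),
        "xi": pd.DataFrame(samples.xi, columns=[f"xi{k}" for k in range(samples.xi.shape[1])]),
        "mu": pd.DataFrame(samples.mu, columns=[f"mu{k}" for k in range(samples.mu.shape[1])]),
        "omega": pd.DataFrame(samples.omega.reshape(n, -1),
                              columns=[f"omega{i}{j}" for i in range(samples.omega.shape[1])
                                       for j in range(samples.omega.shape[2])]),
    }
    for name, df in frames.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "n_save": n,
        "seed": seed,
        "config_hash": config.config_hash() if config is not None else None,
        "accept_rates": samples.accept_rates,
        "checksums": {f.name: _sha256(f) for f in sorted(out.glob("*.tsv"))},
        "checksums_binary": {"chains.npz": _sha256(out / "chains.npz")},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if config is not None:
        dump_config(config, out / "config.toml")
    return manifest


def load_chains(chain_dir: Union[str, Path]) -> PosteriorSamples:
    """Exact inverse of :func:`save_chains` (reads the binary container and
    verifies manifest checksums; a truncated/modified block is reported by
    name)."""
    cd = Path(chain_dir)
    manifest = json.loads((cd / "manifest.json").read_text())
    for fname, digest in {**manifest["checksums"], **manifest["checksums_binary"]}.items():
        path = cd / fname
        if not path.exists() or _sha256(path) != digest:
            raise IOError(f"chain block {fname!r} is missing or corrupted (checksum mismatch)")
    with np.load(cd / "chains.npz") as z:
        return PosteriorSamples(
            c=z["c"], kappa=z["kappa"], xi=z["xi"], mu=z["mu"], omega=z["omega"],
            accept_rates=manifest.get("accept_rates", {}),
        )
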
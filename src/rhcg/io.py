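"""Run configuration, ensemble file formats and run manifests.

Ensembles are written as a multi-model PDB plus a CSV weights sidecar
(chain_id, log_p_bias, w0, w) and the fragment-index table; configs are
YAML key-value files echoed into every output directory together with a
JSON manifest recording seeds, the config hash and package version.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants as K
from .growth import Ensemble
from .struct import read_models, write_models

__all__ = ["RunConfig", "write_ensemble", "read_ensemble", "write_manifest"]


@dataclass
class RunConfig:
    """Growth / reweighting parameters; defaults mirror the tau K18 study."""

    sequence: str = K.TAU_K18_PAD_SEQUENCE
    fragment_length: int = 5
    overlap_length: int = 2
    n_pad_residues: int = 1
    clash_cutoff: float = K.DEFAULT_CLASH_CUTOFF
    pool_size: int = K.DEFAULT_POOL_SIZE
    n_chains: int = K.DEFAULT_N_CHAINS
    theta: float = K.DEFAULT_THETA
    theta_f: float = K.DEFAULT_THETA_F
    seed: int = 0
    max_attempts: int = 10000
    n_conformers: int = 100
    residue_offset: int = 0     # construct index 1 -> author numbering
    observable_errors: dict = field(
        default_factory=lambda: dict(K.FORWARD_ERROR_DEFAULTS)
    )
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        numeric = {
            "fragment_length": self.fragment_length,
            "overlap_length": self.overlap_length,
            "clash_cutoff": self.clash_cutoff,
            "pool_size": self.pool_size,
            "n_chains": self.n_chains,
            "theta": self.theta,
            "theta_f": self.theta_f,
            "max_attempts": self.max_attempts,
            "n_conformers": self.n_conformers,
        }
        for name, value in numeric.items():
            if value is None:
                raise ValueError(f"config field {name} is missing")
            if value <= 0:
                raise ValueError(f"config field {name} must be positive (got {value})")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_ensemble(ensemble: Ensemble, prefix, residue_offset: int = 0) -> None:
    """Write ``<prefix>.pdb`` (multi-model) plus ``<prefix>.weights.csv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_models(
        f"{prefix}.pdb",
        [ensemble.template.with_coords(c) for c in ensemble.coords],
        offset=residue_offset,
    )
    c = len(ensemble)
    uniform = np.full(c, 1.0 / c)
    table = pd.DataFrame(
        {
            "chain_id": np.arange(c),
            "log_p_bias": ensemble.log_p_bias,
            "w0": ensemble.w0 if ensemble.w0 is not None else uniform,
            "w": ensemble.w if ensemble.w is not None else uniform,
        }
    )
    for n, pos in enumerate(range(ensemble.fragment_indices.shape[1])):
        table[f"frag_{n + 1}"] = ensemble.fragment_indices[:, pos]
    table.to_csv(f"{prefix}.weights.csv", index=False, float_format="%.12g")


def read_ensemble(prefix, residue_offset: int = 0) -> Ensemble:
    """Inverse of :func:`write_ensemble`; a missing sidecar loads uniform
    weights with a warning."""
    import logging

    prefix = Path(prefix)
    models = read_models(f"{prefix}.pdb", offset=residue_offset)
    coords = np.stack([m.coords for m in models])
    c = len(models)
    sidecar = Path(f"{prefix}.weights.csv")
    if sidecar.exists():
        table = pd.read_csv(sidecar)
        if len(table) != c:
            raise ValueError(
                f"{sidecar}: {len(table)} weight rows for {c} models"
            )
        for col in ("w0", "w"):
            if abs(table[col].sum() - 1.0) > 1e-6:
                raise ValueError(f"{sidecar}: column {col} does not sum to 1")
        frag_cols = [col for col in table.columns if col.startswith("frag_")]
        frag = table[frag_cols].to_numpy(dtype=int)
        log_p = table["log_p_bias"].to_numpy()
        w0 = table["w0"].to_numpy()
        w = table["w"].to_numpy()
    else:
        logging.getLogger(__name__).warning(
            "%s: no weights sidecar, assuming uniform weights", prefix
        )
        frag = np.zeros((c, 0), dtype=int)
        log_p = np.zeros(c)
        w0 = w = np.full(c, 1.0 / c)
    return Ensemble(
        template=models[0],
        coords=coords,
        fragment_indices=frag,
        log_p_bias=log_p,
        w0=w0,
        w=w,
    )


def write_manifest(path, config: RunConfig, stage: str, extra: dict | None = None) -> None:
    from . import __version__

    manifest = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
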
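"""Stage orchestration: configuration, seeding, manifests.

A run is described by a YAML-class config (stages + per-stage parameters +
global seed).  Unknown keys are rejected before anything executes; every run
persists the resolved config, a seed record and a manifest listing each
artifact with its SHA-256 content hash, so identical (config, seed) runs
produce byte-identical manifests.

The single global seed is expanded into independent per-stage streams with
``numpy`` SeedSequence spawn keys indexed by a fixed stage table, so adding
a stage never perturbs the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

log = logging.getLogger(__name__)

#: fixed stage -> stream index table (append-only; order never changes)
STAGE_STREAMS = {
    "simulate": 0,
    "scan": 1,
    "rank": 2,
    "exclude": 3,
    "tree": 4,
    "clock": 5,
    "rates": 6,
    "quantify": 7,
    "hertz": 8,
    "spearman": 9,
}

STAGE_ORDER = list(STAGE_STREAMS)

_KNOWN_KEYS = {"stages", "seed", "out_dir", "params", "log_level"}


class ConfigError(ValueError):
    pass


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent per-stage random stream from the global seed."""
    if stage not in STAGE_STREAMS:
        raise ConfigError(f"unknown stage {stage!r}")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGE_STREAMS[stage],)))


def stage_seed(seed: int, stage: str) -> int:
    """A 31-bit integer seed derived from the per-stage stream."""
    return int(stage_rng(seed, stage).integers(0, 2**31 - 1))


@dataclass
class RunConfig:
    stages: list[str]
    seed: int = 0
    out_dir: Path = Path("runs")
    params: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "stages" not in raw or not raw["stages"]:
            raise ConfigError("config must list at least one stage")
        bad = [s for s in raw["stages"] if s not in STAGE_STREAMS]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        return cls(
            stages=list(raw["stages"]),
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "runs")),
            params=dict(raw.get("params", {})),
            log_level=str(raw.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "params": self.params,
            "log_level": self.log_level,
        }


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest.

    Stage implementations live in :mod:`itamorigins.stages`; each receives
    the config params, its derived seed and the output directory, and
    returns the list of files it wrote.  A failing stage aborts the run with
    its name; artifacts written so far stay on disk and are flagged partial.
    """
    from . import stages as stage_impls

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    resolved = out_dir / "config.resolved.yaml"
    with resolved.open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    (out_dir / "seed.json").write_text(
        json.dumps({"seed": config.seed, "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages}}, sort_keys=True)
    )

    ordered = [s for s in STAGE_ORDER if s in config.stages]
    manifest: dict = {"seed": config.seed, "stages": ordered, "artifacts": {}, "complete": False}
    for stage in ordered:
        func = getattr(stage_impls, f"stage_{stage}", None)
        if func is None:
            raise ConfigError(f"stage {stage!r} has no implementation")
        log.info("running stage %s", stage)
        try:
            written = func(
                params=config.params.get(stage, {}),
                seed=stage_seed(config.seed, stage),
                out_dir=out_dir,
            )
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(out_dir, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        for p in written:
            manifest["artifacts"][str(Path(p).relative_to(out_dir))] = sha256_file(p)
    manifest["complete"] = True
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
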
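"""Configuration schema and run manifests.

A single top-level YAML config drives the pipeline; one declared root
seed feeds every source of randomness.  Each pipeline output is
accompanied by a JSON manifest (config snapshot, seeds, package version,
SHA-256 digests of the files written) sufficient to re-run it
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from droughtmob.scenarios import SCENARIOS

__all__ = ["PipelineConfig", "RunManifest", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """A config file violated the schema."""


_ABM_KEYS = {"scenario", "n_sims"}
_MEXICO_KEYS = {"n_communities", "n_states", "n_persons", "years", "planted"}
_TOP_KEYS = {"seed", "stage", "abm", "mexico"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    stage: str = "all"  # "abm" | "mexico" | "all"
    scenario: str = "base_case"
    n_sims: int = 1000
    n_communities: int = 93
    n_states: int = 22
    n_persons: int = 7500
    years: tuple[int, int] = (1991, 2018)
    planted: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stage": self.stage,
            "abm": {"scenario": self.scenario, "n_sims": self.n_sims},
            "mexico": {
                "n_communities": self.n_communities,
                "n_states": self.n_states,
                "n_persons": self.n_persons,
                "years": list(self.years),
                "planted": dict(self.planted),
            },
        }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(source) -> PipelineConfig:
    """Load and validate a YAML config (path or mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")
    cfg = PipelineConfig()
    cfg.seed = int(raw.get("seed", 0))
    cfg.stage = raw.get("stage", "all")
    if cfg.stage not in ("abm", "mexico", "all"):
        raise ConfigError(f"stage must be abm|mexico|all, got {cfg.stage!r}")
    abm = raw.get("abm", {}) or {}
    _check_keys(abm, _ABM_KEYS, "abm")
    cfg.scenario = abm.get("scenario", cfg.scenario)
    if cfg.scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {cfg.scenario!r}; valid names: {sorted(SCENARIOS)}"
        )
    cfg.n_sims = int(abm.get("n_sims", cfg.n_sims))
    if cfg.n_sims < 1:
        raise ConfigError("abm.n_sims must be >= 1")
    mex = raw.get("mexico", {}) or {}
    _check_keys(mex, _MEXICO_KEYS, "mexico")
    cfg.n_communities = int(mex.get("n_communities", cfg.n_communities))
    cfg.n_states = int(mex.get("n_states", cfg.n_states))
    cfg.n_persons = int(mex.get("n_persons", cfg.n_persons))
    years = mex.get("years", list(cfg.years))
    if len(years) != 2 or years[0] > years[1]:
        raise ConfigError("mexico.years must be [first, last]")
    cfg.years = (int(years[0]), int(years[1]))
    planted = mex.get("planted", {}) or {}
    if not isinstance(planted, dict):
        raise ConfigError("mexico.planted must be a mapping of coefficient names")
    cfg.planted = {str(k): float(v) for k, v in planted.items()}
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: dict
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    timestamp: str = ""

    @classmethod
    def create(cls, config: PipelineConfig, output_paths: list[str | Path]) -> "RunManifest":
        from droughtmob import __version__

        return cls(
            config=config.to_dict(),
            seed=config.seed,
            version=__version__,
            outputs={str(p): _sha256(Path(p)) for p in output_paths},
            timestamp=datetime.now(timezone.utc).isoformat(),
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "version": self.version,
                    "outputs": self.outputs,
                    "timestamp": self.timestamp,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=d["config"],
            seed=d["seed"],
            version=d["version"],
            outputs=d["outputs"],
            timestamp=d.get("timestamp", ""),
        )

    def verify(self) -> dict[str, bool]:
        """Check that every recorded output still matches its digest."""
        return {
            p: Path(p).exists() and _sha256(Path(p)) == digest
            for p, digest in self.outputs.items()
        }
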
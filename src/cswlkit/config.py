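"""Pipeline configuration: YAML/JSON file with dotted-path CLI overrides,
deterministic per-stage sub-seeds, and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    # paths
    lexicon: Optional[str] = None  # None -> bundled toy lexicon
    inventory: Optional[str] = None
    out_dir: str = "cswl_out"
    # phonotactics
    aggregation: str = "sum"
    # pseudoword search
    template: str = "CVCV"
    k: int = 6
    floor: float = 0.75
    recombination_mode: str = "syllable"
    max_shared_biphones: Optional[int] = 0
    max_onset_reuse: Optional[int] = 3
    # design
    pairs_per_set: int = 6
    exposures_per_pair: int = 6
    test_repetitions: int = 2
    interleave_policy: str = "random_max_run"
    counterbalance_version: str = "A"
    # simulation
    n_participants: int = 30
    learner: str = "glmm_generative"
    beta0: float = 2.03
    delta_pp_plus: float = 0.17
    tau_participant: float = 1.53
    tau_stimulus: float = 0.46
    contamination_rate: float = 0.02
    # analysis
    exclusion_k: float = 3.0
    exclusion_scope: str = "global"
    n_boot: int = 2000
    run_bayes: bool = True
    mcmc_warmup: int = 400
    mcmc_draws: int = 600
    mcmc_chains: int = 4
    # global
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed fanned out from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int(np.frombuffer(digest[:8], dtype=np.uint64)[0] % 2**31)


_VALID = {f for f in PipelineConfig.__dataclass_fields__}


def load_config(path: Optional[str] = None, overrides: Optional[dict[str, Any]] = None) -> PipelineConfig:
    """Load YAML (JSON is valid YAML) and apply overrides; unknown keys and
    invalid values are reported with their field path."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(raw)
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val
    unknown = set(data) - _VALID
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = PipelineConfig(**data)
    _validate(cfg)
    return cfg


def _validate(cfg: PipelineConfig) -> None:
    checks = [
        (cfg.aggregation in ("sum", "mean"), "aggregation"),
        (set(cfg.template) <= {"C", "V"} and len(cfg.template) >= 2, "template"),
        (cfg.k >= 1, "k"),
        (0 < cfg.floor <= 1, "floor"),
        (cfg.recombination_mode in ("syllable", "biphone"), "recombination_mode"),
        (cfg.n_participants >= 1, "n_participants"),
        (cfg.learner in ("guesser", "associative", "glmm_generative"), "learner"),
        (cfg.tau_participant >= 0 and cfg.tau_stimulus >= 0, "tau_*"),
        (0 <= cfg.contamination_rate <= 1, "contamination_rate"),
        (cfg.exclusion_k > 0, "exclusion_k"),
        (cfg.exclusion_scope in ("global", "per_participant"), "exclusion_scope"),
        (cfg.n_boot >= 1, "n_boot"),
        (cfg.mcmc_chains >= 2, "mcmc_chains"),
        (cfg.seed >= 0, "seed"),
    ]
    bad = [name for ok, name in checks if not ok]
    if bad:
        raise ConfigError(f"invalid config fields: {bad}")


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, stage: str, cfg: PipelineConfig, outputs: list[Path]) -> Path:
    import cswlkit

    manifest = {
        "stage": stage,
        "seed": cfg.seed,
        "stage_seed": cfg.stage_seed(stage),
        "config": asdict(cfg),
        "versions": {
            "cswlkit": cswlkit.__version__,
            "numpy": np.__version__,
        },
        "outputs": {
            str(p.relative_to(out_dir)): sha256_of(p) for p in outputs if p.exists()
        },
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
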
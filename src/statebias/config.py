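"""Layered run configuration: CLI flags > config file > protocol defaults.

The defaults encode the benchmark protocol: GPCR runs use a shallow MSA of
8 cluster + 16 extra sequences, the top 4 state-matching templates, 50
models and no recycling, with same-subfamily templates excluded; kinase
runs use 20 templates and no subfamily exclusion. A resolved config
serializes to a single mapping that fully reproduces a run.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .msa import SubsampleSpec
from .selection import StateQuery


class ConfigError(ValueError):
    """Unknown or conflicting configuration keys."""


#: keys accepted from config files and CLI overrides
_KNOWN_KEYS = {
    "mode",
    "gpcr_state",
    "dfg",
    "ac_helix",
    "salt_bridge",
    "num_templates",
    "exclude_subfamily",
    "shuffle_templates",
    "min_rank_score",
    "min_seq_identity",
    "num_clusters",
    "num_extra",
    "msa_mode",
    "speach_window",
    "speach_stride",
    "num_models",
    "recycles",
    "seed",
    "predictor",
    "plddt_floor",
    "rg_ceiling",
    "noise_sigma",
}

_GPCR_DEFAULTS: dict[str, Any] = {
    "mode": "gpcr",
    "gpcr_state": "Active",
    "dfg": "all",
    "ac_helix": "all",
    "salt_bridge": "all",
    "num_templates": 4,
    "exclude_subfamily": True,
    "shuffle_templates": False,
    "min_rank_score": 0.0,
    "min_seq_identity": 0.0,
    "num_clusters": 8,
    "num_extra": 16,
    "msa_mode": "shallow",
    "speach_window": 10,
    "speach_stride": None,
    "num_models": 50,
    "recycles": 0,
    "seed": 0,
    "predictor": "mock",
    "plddt_floor": 40.0,
    "rg_ceiling": 2.5,
    "noise_sigma": 0.5,
}

_KINASE_DEFAULTS = {
    **_GPCR_DEFAULTS,
    "mode": "kinase",
    "gpcr_state": None,
    "num_templates": 20,
    "exclude_subfamily": False,
}

MSA_MODES = ("shallow", "none", "speach", "full")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved parameters of one ensemble run."""

    query: StateQuery
    subsample: SubsampleSpec
    msa_mode: str = "shallow"
    speach_window: int = 10
    speach_stride: int | None = None
    n_models: int = 50
    recycles: int = 0
    seed: int = 0
    predictor: str = "mock"
    plddt_floor: float = 40.0
    rg_ceiling: float = 2.5
    noise_sigma: float = 0.5
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.msa_mode not in MSA_MODES:
            raise ConfigError(
                f"unknown msa_mode {self.msa_mode!r} (choose from {MSA_MODES})"
            )
        if self.n_models < 1:
            raise ConfigError("num_models must be >= 1")
        if self.recycles < 0:
            raise ConfigError("recycles must be >= 0")

    def to_mapping(self) -> dict[str, Any]:
        """Flat mapping that, fed back through resolve_config, reproduces the run."""
        return dict(self.raw)

    def to_manifest_entry(self) -> dict[str, Any]:
        return {
            "config": self.to_mapping(),
            "query": asdict(self.query),
            "subsample": asdict(self.subsample),
        }


def resolve_config(
    cli_args: Mapping[str, Any] | None = None,
    config_file: str | Path | None = None,
    mode: str | None = None,
) -> RunConfig:
    """Merge CLI overrides, a YAML/JSON config file and protocol defaults.

    Precedence: CLI > file > defaults. ``mode`` (``gpcr``/``kinase``) picks
    the default block; it may also come from the file or CLI. Unknown keys
    are rejected by name.
    """
    cli_args = {k: v for k, v in (cli_args or {}).items() if v is not None}
    file_args: dict[str, Any] = {}
    if config_file is not None:
        text = Path(config_file).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {config_file} must hold a mapping")
        file_args = loaded
    for label, mapping in (("config file", file_args), ("CLI", cli_args)):
        unknown = sorted(set(mapping) - _KNOWN_KEYS)
        if unknown:
            raise ConfigError(f"unknown {label} keys: {', '.join(unknown)}")
    resolved_mode = (
        cli_args.get("mode") or file_args.get("mode") or mode or "gpcr"
    )
    if resolved_mode not in ("gpcr", "kinase"):
        raise ConfigError(f"unknown mode {resolved_mode!r}")
    defaults = _GPCR_DEFAULTS if resolved_mode == "gpcr" else _KINASE_DEFAULTS
    merged = {**defaults, **file_args, **cli_args, "mode": resolved_mode}
    query = StateQuery(
        mode=resolved_mode,
        gpcr_state=merged["gpcr_state"] if resolved_mode == "gpcr" else None,
        dfg=merged["dfg"],
        ac_helix=merged["ac_helix"],
        salt_bridge=merged["salt_bridge"],
        k=int(merged["num_templates"]),
        exclude_same_subfamily=bool(merged["exclude_subfamily"]),
        randomize=bool(merged["shuffle_templates"]),
        min_rank_score=float(merged["min_rank_score"]),
        min_seq_identity=float(merged["min_seq_identity"]),
        seed=int(merged["seed"]),
    )
    subsample = SubsampleSpec(
        n_clusters=int(merged["num_clusters"]),
        n_extra=int(merged["num_extra"]),
        seed=int(merged["seed"]),
    )
    return RunConfig(
        query=query,
        subsample=subsample,
        msa_mode=str(merged["msa_mode"]),
        speach_window=int(merged["speach_window"]),
        speach_stride=(
            None
            if merged["speach_stride"] in (None, "none")
            else int(merged["speach_stride"])
        ),
        n_models=int(merged["num_models"]),
        recycles=int(merged["recycles"]),
        seed=int(merged["seed"]),
        predictor=str(merged["predictor"]),
        plddt_floor=float(merged["plddt_floor"]),
        rg_ceiling=float(merged["rg_ceiling"]),
        noise_sigma=float(merged["noise_sigma"]),
        raw=merged,
    )


def write_manifest(path: str | Path, payload: Mapping[str, Any]) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, default=str) + "\n")
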
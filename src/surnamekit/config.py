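"""YAML run configuration: strict keys, defaults, deterministic hashing.

One file configures every stage.  Section names mirror the modules:

.. code-block:: yaml

    seed: 42
    log_level: INFO
    dialects:
      vital: {LAST_NAME: surname, POB: birthplace}
      registry: {}
    linkage: {match_threshold: 0.95, review_low: 0.85}
    filter: {min_length: 5, long_name_exempt_length: 12}
    build: {target_birthplace: Armenia}
    evaluate: {match_mode: exact}
    simulate: {n_target_stems: 300}

Unknown keys anywhere are rejected by name, so typos fail loudly instead
of silently running on defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml

from .construction import BuildConfig
from .filters import FilterConfig
from .linkage import LinkageConfig
from .synthetic_data import WorldConfig

__all__ = ["ConfigError", "RunConfig", "load_config"]

_TOP_LEVEL_KEYS = {
    "seed",
    "log_level",
    "dialects",
    "linkage",
    "filter",
    "build",
    "evaluate",
    "simulate",
}
_EVALUATE_KEYS = {"match_mode", "truncation_length", "target_birthplace"}
_BUILD_KEYS = {
    "target_birthplace",
    "harvest_father_surname",
    "emit_truncated_reference",
    "collapse_punctuation_variants",
}


class ConfigError(ValueError):
    """Invalid or unknown configuration content; message names the key."""


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {', '.join(sorted(unknown))}")


def _dataclass_from(section: str, cls, given: Mapping[str, Any], **extra):
    allowed = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, given, allowed)
    try:
        return cls(**{**dict(given), **extra})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{section}' config: {exc}") from exc


@dataclass
class RunConfig:
    """Fully materialized configuration for a pipeline run."""

    seed: int = 0
    log_level: str = "INFO"
    dialects: dict[str, dict[str, str]] = field(default_factory=dict)
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    build: BuildConfig = field(default_factory=BuildConfig)
    evaluate: dict[str, Any] = field(
        default_factory=lambda: {"match_mode": "exact", "truncation_length": 10}
    )
    simulate: WorldConfig = field(default_factory=WorldConfig)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "RunConfig":
        data = dict(data or {})
        _check_keys("top level", data, _TOP_LEVEL_KEYS)
        seed = int(data.get("seed", 0))

        linkage = _dataclass_from("linkage", LinkageConfig, data.get("linkage", {}) or {})
        filter_cfg = _dataclass_from("filter", FilterConfig, _coerce_suffixes(data.get("filter", {}) or {}))

        build_raw = dict(data.get("build", {}) or {})
        _check_keys("build", build_raw, _BUILD_KEYS)
        build = BuildConfig(linkage=linkage, filter=filter_cfg, **build_raw)

        evaluate = dict(data.get("evaluate", {}) or {})
        _check_keys("evaluate", evaluate, _EVALUATE_KEYS)
        evaluate.setdefault("match_mode", "exact")
        evaluate.setdefault("truncation_length", linkage.truncation_length)

        simulate = _dataclass_from(
            "simulate", WorldConfig, data.get("simulate", {}) or {}, seed=seed
        )

        dialects = {k: dict(v or {}) for k, v in (data.get("dialects", {}) or {}).items()}
        _check_keys("dialects", dialects, {"vital", "registry"})

        return cls(
            seed=seed,
            log_level=str(data.get("log_level", "INFO")),
            dialects=dialects,
            linkage=linkage,
            filter=filter_cfg,
            build=build,
            evaluate=evaluate,
            simulate=simulate,
        )

    def digest(self) -> str:
        """Stable short hash of the configuration, for run logs."""
        payload = json.dumps(_jsonable(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _coerce_suffixes(section: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(section)
    for key in ("armenian_suffixes", "russian_suffixes"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def load_config(path: Optional[str | Path]) -> RunConfig:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return RunConfig.from_mapping({})
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping")
    return RunConfig.from_mapping(raw)
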
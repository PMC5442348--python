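"""Engine configuration: thresholds, score weights and lexicon overrides.

All knobs the extraction pipeline exposes, with their defaults.  Loadable
from a YAML mapping; unknown keys and out-of-range values are hard errors so
misconfigured runs fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["EngineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


_UNIT = ("theta_sim", "tau_conf", "tau_rule", "w_sim")


@dataclass
class EngineConfig:
    #: cosine threshold for similarity-based sentence selection
    theta_sim: float = 0.25
    #: confidence threshold for accepting candidate values
    tau_conf: float = 0.5
    #: coverage threshold at which an induced reject rule triggers
    tau_rule: float = 0.9
    #: minimum instances before a rule may trigger
    min_support: int = 5
    #: weight of the sentence score in the combined confidence (chunk gets 1-w)
    w_sim: float = 0.5
    #: tokens of left context scanned for negation/uncertainty triggers
    scope_window: int = 6
    #: tokens of context scanned for vocabulary negative indicators
    #: (None = whole sentence)
    indicator_window: int | None = None
    #: rolling window (documents) for the accrued-accuracy display
    accuracy_window: int = 10
    #: extra negation / certainty trigger phrases (merged with defaults)
    extra_negation_triggers: list[str] = field(default_factory=list)
    extra_certainty_triggers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in _UNIT:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError("%s must be in [0,1], got %r" % (name, v))
        if self.min_support < 1:
            raise ConfigError("min_support must be >= 1")
        if self.scope_window < 1:
            raise ConfigError("scope_window must be >= 1")

    @staticmethod
    def from_dict(data: dict) -> "EngineConfig":
        known = {f.name for f in fields(EngineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError("unknown config keys: %s" % ", ".join(sorted(unknown)))
        return EngineConfig(**data)

    @staticmethod
    def load(path: str | Path) -> "EngineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file %s: expected a mapping" % path)
        return EngineConfig.from_dict(data)
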
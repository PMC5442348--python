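"""Attribute schema: the data elements an extraction run targets.

Each attribute (data element) has a name, a cardinality (single- or
multi-valued), an optional value-domain constraint (numeric range or
enumeration), optional section constraints, and a flag controlling whether
accepted values are generalized to their vocabulary hypernym.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ValueDomain", "AttributeSpec", "AttributeSchema", "SchemaError"]


class SchemaError(ValueError):
    pass


_NUM_RE = re.compile(r"[+-]?\d+(?:\.\d+)?")


@dataclass(frozen=True)
class ValueDomain:
    """Numeric closed-interval range or casefolded enumeration."""

    kind: str  # "range" | "enum"
    low: float | None = None
    high: float | None = None
    values: frozenset[str] = frozenset()

    @staticmethod
    def numeric_range(low: float, high: float) -> "ValueDomain":
        if low > high:
            raise SchemaError("range low %r > high %r" % (low, high))
        return ValueDomain(kind="range", low=low, high=high)

    @staticmethod
    def enumeration(values) -> "ValueDomain":
        return ValueDomain(kind="enum", values=frozenset(v.casefold() for v in values))

    def contains(self, surface: str) -> bool:
        if self.kind == "range":
            m = _NUM_RE.search(surface)
            if not m:
                return False
            x = float(m.group())
            return self.low <= x <= self.high
        return surface.casefold() in self.values


@dataclass
class AttributeSpec:
    name: str
    cardinality: str = "multi"  # "single" | "multi"
    domain: ValueDomain | None = None
    sections: list[str] = field(default_factory=list)       # restrict to these
    skip_sections: list[str] = field(default_factory=list)  # never search these
    generalize: bool = False

    def __post_init__(self) -> None:
        if self.cardinality not in ("single", "multi"):
            raise SchemaError(
                "attribute %r: cardinality must be 'single' or 'multi', got %r"
                % (self.name, self.cardinality)
            )


@dataclass
class AttributeSchema:
    attributes: dict[str, AttributeSpec]

    def __iter__(self):
        return iter(self.attributes.values())

    def __contains__(self, name: str) -> bool:
        return name in self.attributes

    def __getitem__(self, name: str) -> AttributeSpec:
        return self.attributes[name]

    @property
    def names(self) -> list[str]:
        return list(self.attributes)

    @staticmethod
    def from_specs(specs: list[AttributeSpec]) -> "AttributeSchema":
        return AttributeSchema({s.name: s for s in specs})

    @staticmethod
    def from_dict(data: dict) -> "AttributeSchema":
        specs = []
        for name, cfg in data.items():
            cfg = cfg or {}
            domain = None
            if "range" in cfg:
                lo, hi = cfg["range"]
                domain = ValueDomain.numeric_range(float(lo), float(hi))
            elif "enum" in cfg:
                domain = ValueDomain.enumeration(cfg["enum"])
            specs.append(
                AttributeSpec(
                    name=name,
                    cardinality=cfg.get("cardinality", "multi"),
                    domain=domain,
                    sections=list(cfg.get("sections", [])),
                    skip_sections=list(cfg.get("skip_sections", [])),
                    generalize=bool(cfg.get("generalize", False)),
                )
            )
        return AttributeSchema.from_specs(specs)

    @staticmethod
    def load(path: str | Path) -> "AttributeSchema":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise SchemaError("schema file %s: expected a mapping of attributes" % path)
        return AttributeSchema.from_dict(data)

    def to_dict(self) -> dict:
        out: dict = {}
        for s in self:
            cfg: dict = {"cardinality": s.cardinality}
            if s.domain is not None:
                if s.domain.kind == "range":
                    cfg["range"] = [s.domain.low, s.domain.high]
                else:
                    cfg["enum"] = sorted(s.domain.values)
            if s.sections:
                cfg["sections"] = list(s.sections)
            if s.skip_sections:
                cfg["skip_sections"] = list(s.skip_sections)
            if s.generalize:
                cfg["generalize"] = True
            out[s.name] = cfg
        return out

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
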
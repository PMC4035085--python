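"""Pipeline configuration: one YAML document covering every tunable knob.

Sections mirror the pipeline stages (scan, descriptor, polya, tsd, classify)
plus a global ``rng_seed``.  Unknown keys are rejected so typos fail loudly,
and the fully resolved configuration can be dumped into a run manifest for
provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .annotate import AnnotateConfig, ClassifyConfig, PolyAConfig, TSDConfig
from .errors import InputError
from .fold import DEFAULT_DESCRIPTOR, RibozymeDescriptor
from .scan import ScanParams


def _replace_from_dict(obj, section: str, data: dict):
    allowed = {f.name for f in dataclasses.fields(obj)}
    unknown = set(data) - allowed
    if unknown:
        raise InputError(f"unknown {section} config keys: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return dataclasses.replace(obj, **coerced)
    except (TypeError, ValueError) as exc:
        raise InputError(f"invalid {section} config: {exc}") from exc


def descriptor_from_dict(data: dict) -> RibozymeDescriptor:
    """Build a descriptor from a config mapping; helix entries are nested
    mappings (min_len/max_len/wobble_allowed)."""
    helices = {}
    flat = {}
    for k, v in data.items():
        if k in {"p1", "p11", "p2", "p3", "p4"} and isinstance(v, dict):
            base = getattr(DEFAULT_DESCRIPTOR, k)
            helices[k] = _replace_from_dict(base, f"descriptor.{k}", v)
        else:
            flat[k] = v
    return _replace_from_dict(
        dataclasses.replace(DEFAULT_DESCRIPTOR, **helices) if helices else DEFAULT_DESCRIPTOR,
        "descriptor", flat,
    )


@dataclass(frozen=True)
class PipelineConfig:
    scan: ScanParams = field(default_factory=ScanParams)
    descriptor: RibozymeDescriptor = DEFAULT_DESCRIPTOR
    polya: PolyAConfig = field(default_factory=PolyAConfig)
    tsd: TSDConfig = field(default_factory=TSDConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    max_scan_rounds: int = 5
    rng_seed: int = 0

    def annotate_config(self) -> AnnotateConfig:
        return AnnotateConfig(
            scan=self.scan, polya=self.polya, tsd=self.tsd,
            classify=self.classify, descriptor=self.descriptor,
            max_scan_rounds=self.max_scan_rounds,
        )

    def to_manifest(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: unpack(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return unpack(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        base = cls()
        known = {"scan", "descriptor", "polya", "tsd", "classify", "max_scan_rounds", "rng_seed"}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        if "scan" in data:
            kwargs["scan"] = _replace_from_dict(base.scan, "scan", data["scan"])
        if "descriptor" in data:
            kwargs["descriptor"] = descriptor_from_dict(data["descriptor"])
        if "polya" in data:
            kwargs["polya"] = _replace_from_dict(base.polya, "polya", data["polya"])
        if "tsd" in data:
            kwargs["tsd"] = _replace_from_dict(base.tsd, "tsd", data["tsd"])
        if "classify" in data:
            kwargs["classify"] = _replace_from_dict(base.classify, "classify", data["classify"])
        for k in ("max_scan_rounds", "rng_seed"):
            if k in data:
                kwargs[k] = int(data[k])
        return dataclasses.replace(base, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise InputError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise InputError(f"config {path} must be a mapping")
        return cls.from_dict(data)
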
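"""YAML configuration plumbing for the pipeline.

A config file holds the hammerhead descriptor, the junction-box
consensus strings, annotation thresholds, folding weights and the
synthetic-genome spec.  Only keys that are present override defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .annotate import AnnotationConfig, BoxConsensus
from .descriptor import HHRDescriptor
from .fold import DEFAULT_WEIGHTS
from .simulate import SyntheticSpec

__all__ = ["PipelineConfig", "load_config"]

_TUPLE_FIELDS = {
    "helix1_len", "helix2_len", "helix3_len", "loop_len", "topologies",
    "monomer_bounds", "tsd_lens", "solo_context", "internal_length",
    "monomer_length",
}


def _build(cls, data: dict | None):
    data = dict(data or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    for k in list(data):
        if k in _TUPLE_FIELDS and isinstance(data[k], list):
            data[k] = tuple(data[k])
    return cls(**data)


@dataclasses.dataclass
class PipelineConfig:
    descriptor: HHRDescriptor = dataclasses.field(default_factory=HHRDescriptor)
    boxes: BoxConsensus = dataclasses.field(default_factory=BoxConsensus)
    annotation: AnnotationConfig = dataclasses.field(default_factory=AnnotationConfig)
    fold_weights: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    min_loop: int = 3
    synthetic: SyntheticSpec = dataclasses.field(default_factory=SyntheticSpec)

    def to_yaml(self, path) -> None:
        def clean(obj):
            d = dataclasses.asdict(obj)
            return {k: list(v) if isinstance(v, tuple) else v
                    for k, v in d.items()}

        payload = {
            "descriptor": clean(self.descriptor),
            "boxes": clean(self.boxes),
            "annotation": clean(self.annotation),
            "fold_weights": dict(self.fold_weights),
            "min_loop": self.min_loop,
            "synthetic": clean(self.synthetic),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path=None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig(
        descriptor=_build(HHRDescriptor, data.get("descriptor")),
        boxes=_build(BoxConsensus, data.get("boxes")),
        annotation=_build(AnnotationConfig, data.get("annotation")),
        fold_weights=dict(data.get("fold_weights") or DEFAULT_WEIGHTS),
        min_loop=int(data.get("min_loop", 3)),
        synthetic=_build(SyntheticSpec, data.get("synthetic")),
    )
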
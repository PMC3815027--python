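"""Pipeline configuration: one document tying all stage parameters together.

The configuration round-trips losslessly through JSON, and its canonical
hash is recorded in every output so a run can be traced back to its exact
settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .metrics import MeasureConfig
from .segmentation import SegmentationConfig
from .synthetic import PopulationParams

__all__ = ["PipelineConfig", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of a generate → segment → measure → compare run."""

    seed: int = 0
    n_control: int = 20
    n_carrier: int = 20
    carrier_fraction: float = 0.5
    out_dir: str = "out"
    spacing_override: tuple[float, float, float] | None = None
    save_stacks: bool = True
    save_labels: bool = True
    generator: PopulationParams = field(default_factory=PopulationParams)
    measure: MeasureConfig = field(default_factory=MeasureConfig)

    def to_dict(self) -> dict:
        return _to_jsonable(dataclasses.asdict(self))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        gen = doc.pop("generator", {})
        meas = dict(doc.pop("measure", {}))
        seg = meas.pop("segmentation", {})
        if "spacing_override" in doc and doc["spacing_override"] is not None:
            doc["spacing_override"] = tuple(doc["spacing_override"])
        return cls(
            generator=_params_from_dict(gen),
            measure=MeasureConfig(
                segmentation=SegmentationConfig(**_tupled(seg)),
                **_tupled(meas),
            ),
            **doc,
        )

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


_TUPLE_FIELDS = {
    "grid_shape", "spacing", "channels", "semi_axes", "psf_sigma",
    "control_pair_probs", "ssc13_ap", "ssc13_ml", "ssc17_ap",
    "ssc17_ml_uniform", "spot_channels", "association_channels", "paint_pair",
}

_WEIGHT_FIELDS = {
    "telomere_cluster_size_weights", "ac6_cluster_count_weights",
    "ac6_cluster_count_weights_fused", "sscrs2a_cluster_count_weights",
    "association_count_weights",
}

# dict-valued fields whose values are (mean, sd) tuples
_DICT_TUPLE_FIELDS = {"gonosome_ap", "gonosome_ml"}


def _tupled(doc: dict) -> dict:
    out = {}
    for k, v in doc.items():
        if v is not None and k in _TUPLE_FIELDS:
            out[k] = tuple(v)
        elif v is not None and k in _WEIGHT_FIELDS:
            out[k] = tuple((int(a), float(b)) for a, b in v)
        elif v is not None and k in _DICT_TUPLE_FIELDS:
            out[k] = {kk: tuple(vv) for kk, vv in v.items()}
        else:
            out[k] = v
    return out


def _params_from_dict(doc: dict) -> PopulationParams:
    return PopulationParams(**_tupled(doc))


def config_hash(config: PipelineConfig) -> str:
    """Short stable hash of the analysis-relevant settings.

    Output location and artifact-persistence flags are excluded: two runs
    that differ only in where results are written produce identical
    measurements and share a hash.
    """
    doc = config.to_dict()
    for key in ("out_dir", "save_stacks", "save_labels"):
        doc.pop(key, None)
    canonical = json.dumps(doc, indent=2, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
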
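"""Run configuration: design + generator + stereology + output options,
with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .config import ParameterError, StereologyConfig
from .simulate import CohortDesign, GeneratorParams, GroupParams, default_cohort_params

__all__ = ["OutputOptions", "RunConfig"]

_FORMATS = ("csv", "tsv", "markdown")


def _plain(obj):
    """Recursively coerce numpy scalars/containers to plain Python types so
    the config serializes with safe YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


@dataclass
class OutputOptions:
    format: str = "csv"
    decimals: int = 2

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ParameterError(f"format must be one of {_FORMATS}")
        if self.decimals < 0:
            raise ParameterError("decimals must be >= 0")


@dataclass
class RunConfig:
    """Everything one run needs: cohort design, generator parameters,
    stereological constants and output options."""

    design: CohortDesign = field(default_factory=CohortDesign)
    generator: GeneratorParams = field(default_factory=default_cohort_params)
    stereology: StereologyConfig = field(default_factory=StereologyConfig)
    output: OutputOptions = field(default_factory=OutputOptions)

    def to_dict(self) -> dict:
        d = {
            "design": asdict(self.design),
            "generator": asdict(self.generator),
            "stereology": asdict(self.stereology),
            "output": asdict(self.output),
        }
        d["design"]["labels"] = list(self.design.labels)
        for gp in d["generator"]["groups"].values():
            for key in ("body_mass_g", "testis_mass_g", "tubule_diameter_um",
                        "epithelium_height_um", "compartment_weights"):
                gp[key] = list(gp[key])
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        design_d = dict(d.get("design", {}))
        if "labels" in design_d:
            design_d["labels"] = tuple(design_d["labels"])
        gen_d = dict(d.get("generator", {}))
        groups = {}
        for label, gp in gen_d.pop("groups", {}).items():
            gp = dict(gp)
            for key in ("body_mass_g", "testis_mass_g", "tubule_diameter_um",
                        "epithelium_height_um", "compartment_weights"):
                if key in gp:
                    gp[key] = tuple(gp[key])
            groups[label] = GroupParams(**gp)
        generator = (
            GeneratorParams(groups=groups, **gen_d) if groups else default_cohort_params()
        )
        return cls(
            design=CohortDesign(**design_d),
            generator=generator,
            stereology=StereologyConfig(**d.get("stereology", {})),
            output=OutputOptions(**d.get("output", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
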
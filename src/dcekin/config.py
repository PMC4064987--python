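"""YAML-backed analysis configuration.

The config carries the acquisition constants, two-stage settings, IO
paths, and the simulation design/noise blocks, and round-trips exactly
through parse -> emit -> parse.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .aif import AIFParams
from .gkm import GKMParams
from .relaxometry import AcquisitionConstants
from .synthetic import ExperimentDesign, NoiseModel


@dataclass(frozen=True)
class TwoStageSettings:
    split_min: float = 20.0
    smoothing: str = "fourier5"
    n_resample: int = 40
    stage2_mode: str = "global_offset"


@dataclass(frozen=True)
class IOSettings:
    input: str | None = None
    input_kind: str = "signal"      # signal | concentration
    output_dir: str = "."


@dataclass(frozen=True)
class AnalysisConfig:
    acquisition: AcquisitionConstants = field(default_factory=AcquisitionConstants)
    two_stage: TwoStageSettings = field(default_factory=TwoStageSettings)
    io: IOSettings = field(default_factory=IOSettings)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    noise: NoiseModel = field(default_factory=NoiseModel)
    mode: str = "gkm"               # gkm | two_stage
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "acquisition": asdict(self.acquisition),
            "two_stage": asdict(self.two_stage),
            "io": asdict(self.io),
            "design": asdict(self.design),
            "noise": asdict(self.noise),
            "mode": self.mode,
            "log_level": self.log_level,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d or {})
        design_d = dict(d.get("design") or {})
        if isinstance(design_d.get("truth_aif"), dict):
            design_d["truth_aif"] = AIFParams(**design_d["truth_aif"])
        for key in ("truth_stage1", "truth_stage2"):
            if isinstance(design_d.get(key), dict):
                design_d[key] = GKMParams(**design_d[key])
        return cls(
            acquisition=AcquisitionConstants(**(d.get("acquisition") or {})),
            two_stage=TwoStageSettings(**(d.get("two_stage") or {})),
            io=IOSettings(**(d.get("io") or {})),
            design=ExperimentDesign(**design_d),
            noise=NoiseModel(**(d.get("noise") or {})),
            mode=d.get("mode", "gkm"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "AnalysisConfig":
        path = Path(source)
        if path.exists():
            text = path.read_text()
        else:
            text = str(source)
        return cls.from_dict(yaml.safe_load(text) or {})
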
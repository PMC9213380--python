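"""Run configuration: one YAML document describing a full experiment.

A :class:`RunConfig` resolves every knob of the pipeline — the factorial
design, tissue-class parameters, emulator parameters, extraction
settings and evaluation thresholds — and round-trips losslessly through
YAML. Every pipeline run writes its resolved configuration next to its
outputs so a run is regenerable from the output directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import ExtractionSettings
from .phantom import (
    AcquisitionDesign,
    EmulatorParams,
    TissueClassSpec,
    default_class_specs,
)
from .pipeline import EvaluationThresholds

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    design: AcquisitionDesign = field(default_factory=AcquisitionDesign)
    class_specs: tuple[TissueClassSpec, ...] = field(
        default_factory=default_class_specs)
    emulator: EmulatorParams = field(default_factory=EmulatorParams)
    extraction: ExtractionSettings = field(default_factory=ExtractionSettings)
    thresholds: EvaluationThresholds = field(default_factory=EvaluationThresholds)
    shape: tuple[int, int, int] = (4, 128, 128)

    def small(self) -> "RunConfig":
        """Reduced design for tests: 4 doses x 5 repeats x 4 modes."""
        return dataclasses.replace(self, design=self.design.small())

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, design=dataclasses.replace(self.design, master_seed=int(seed)))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "design": {
                "doses": list(self.design.doses),
                "n_repeats": self.design.n_repeats,
                "recon_modes": list(self.design.recon_modes),
                "master_seed": self.design.master_seed,
            },
            "class_specs": [dataclasses.asdict(sp) for sp in self.class_specs],
            "emulator": dataclasses.asdict(self.emulator),
            "extraction": dataclasses.asdict(self.extraction),
            "thresholds": dataclasses.asdict(self.thresholds),
            "shape": list(self.shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        if "design" in d:
            des = dict(d["design"])
            if "doses" in des:
                des["doses"] = tuple(des["doses"])
            if "recon_modes" in des:
                des["recon_modes"] = tuple(des["recon_modes"])
            kwargs["design"] = AcquisitionDesign(**des)
        if "class_specs" in d:
            kwargs["class_specs"] = tuple(
                TissueClassSpec(**sp) for sp in d["class_specs"])
        if "emulator" in d:
            kwargs["emulator"] = EmulatorParams(**d["emulator"])
        if "extraction" in d:
            kwargs["extraction"] = ExtractionSettings(**d["extraction"])
        if "thresholds" in d:
            kwargs["thresholds"] = EvaluationThresholds(**d["thresholds"])
        if "shape" in d:
            kwargs["shape"] = tuple(int(v) for v in d["shape"])
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls.from_dict(d or {})
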
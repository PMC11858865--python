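"""YAML run configuration: validation and conversion to domain objects.

The config file mirrors the model structure in sections — ``compound``
(disposition), ``formulation`` (particles, solubilities, DLM scalars),
``protocol`` (media gradient), ``physiology`` (GI regions), ``trial`` (study
design) — plus the dissolution input ``mode`` (``"profile"`` or ``"dlm"``).
Unknown keys are rejected with their location; omitted values fall back to
the documented defaults.  The bundled ``data/default_config.yaml`` reproduces
the default media gradient and media properties exactly.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .adam import GIRegion, default_regions
from .dlm import FormulationModel
from .media import (DEFAULT_REGION_MAP, DissolutionProtocol, GI_REGIONS,
                    Medium, ProtocolSegment)
from .pbpk import CompoundDisposition
from .synthetic import StudySpec
from .usp4 import ConfigurationError

__all__ = ["RunConfig", "load_config", "save_config", "default_config"]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MediumConfig(_Model):
    pH: float
    buffer_total: float = 0.0
    buffer_pka1: float | None = None
    buffer_pka2: float | None = None
    bile_salt: float = 0.0
    solubility: float


class SegmentConfig(_Model):
    medium: str
    start: float
    duration: float
    flow_rate: float


class ProtocolConfig(_Model):
    cell_volume: float = 20.0
    media: dict[str, MediumConfig]
    segments: list[SegmentConfig]
    region_map: dict[str, list[str]] = Field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_REGION_MAP.items()}
    )

    @model_validator(mode="after")
    def _segments_reference_media(self):
        for i, seg in enumerate(self.segments):
            if seg.medium not in self.media:
                raise ValueError(f"protocol.segments[{i}].medium: unknown medium {seg.medium!r}")
        return self


class FormulationConfig(_Model):
    label: str = "formulation"
    dose: float = 5.0
    density: float = 1.3
    diffusivity: float = 5e-6
    radius_um: float = 10.0
    hmax: float = 30.0
    solubility: dict[str, float] = Field(default_factory=dict)  # per medium, mg/mL
    dlm_scalars: dict[str, float] = Field(default_factory=dict)  # per medium and/or region


class CompoundConfig(_Model):
    Vc: float = 700.0
    Vp: float = 2400.0
    Q_dist: float = 150.0
    CLint_3A4: float = 6000.0
    CLint_3A5: float = 0.0
    fu_plasma: float = 0.01
    Q_h: float = 90.0
    Peff: float = 1.5
    bp_max: float = 35.0
    bp_c50: float = 2.0
    gut_clint_3a4: float = 6.0
    gut_clint_3a5: float = 0.0
    ent_kout: float = 5.0
    hematocrit: float = 0.45


class RegionConfig(_Model):
    name: str
    transit_rate: float
    fluid_volume: float
    radius: float
    solubility: float
    dlm_scalar: float | None = None
    cyp3a_abundance: float = 0.0
    perm_scale: float = 1.0


class PhysiologyConfig(_Model):
    regions: list[RegionConfig] | None = None  # None -> fasted defaults


class TrialConfig(_Model):
    n_subjects: int = 12
    dose: float = 5.0
    variability_cv: dict[str, float] = Field(default_factory=lambda: {
        "CLint_3A4": 0.35, "Vc": 0.25, "Peff": 0.20, "Q_dist": 0.15,
    })
    residual_cv: float = 0.10
    sample_times_h: list[float] = Field(default_factory=lambda: [
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0,
        16.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0,
    ])


class RunConfig(_Model):
    mode: Literal["profile", "dlm"] = "dlm"
    compound: CompoundConfig = Field(default_factory=CompoundConfig)
    formulation: FormulationConfig = Field(default_factory=FormulationConfig)
    protocol: ProtocolConfig
    physiology: PhysiologyConfig = Field(default_factory=PhysiologyConfig)
    trial: TrialConfig = Field(default_factory=TrialConfig)

    @model_validator(mode="after")
    def _mode_inputs_present(self):
        if self.mode == "dlm":
            media = {s.medium for s in self.protocol.segments}
            for m in sorted(media):
                if m not in self.formulation.solubility and m not in self.protocol.media:
                    raise ValueError(f"formulation.solubility: missing entry for protocol medium {m!r} (dlm mode)")
        return self

    # ---- converters to domain objects -------------------------------------

    def to_protocol(self) -> DissolutionProtocol:
        media = {
            name: Medium(name=name, pH=mc.pH, buffer_total=mc.buffer_total,
                         buffer_pka1=mc.buffer_pka1, buffer_pka2=mc.buffer_pka2,
                         bile_salt=mc.bile_salt,
                         solubility=self.formulation.solubility.get(name, mc.solubility))
            for name, mc in self.protocol.media.items()
        }
        segments = [ProtocolSegment(media[s.medium], s.start, s.duration, s.flow_rate)
                    for s in self.protocol.segments]
        return DissolutionProtocol(
            segments, cell_volume=self.protocol.cell_volume,
            region_map={k: tuple(v) for k, v in self.protocol.region_map.items()},
        )

    def to_formulation(self) -> FormulationModel:
        f = self.formulation
        solubility = {name: f.solubility.get(name, mc.solubility)
                      for name, mc in self.protocol.media.items()}
        return FormulationModel.monodisperse(
            dose=f.dose, radius_um=f.radius_um, density=f.density,
            diffusivity=f.diffusivity, hmax=f.hmax, label=f.label,
            solubility_by_medium=solubility, dlm_scalars=dict(f.dlm_scalars),
        )

    def to_disposition(self) -> CompoundDisposition:
        return CompoundDisposition(**self.compound.model_dump())

    def to_regions(self) -> list[GIRegion]:
        scalars = {k: v for k, v in self.formulation.dlm_scalars.items()
                   if k in GI_REGIONS}
        if self.physiology.regions is None:
            media_sol = {name: self.formulation.solubility.get(name, mc.solubility)
                         for name, mc in self.protocol.media.items()}
            region_map = {k: tuple(v) for k, v in self.protocol.region_map.items()}
            return default_regions(media_sol, scalars, region_map)
        out = []
        for rc in self.physiology.regions:
            kw = rc.model_dump()
            if kw["name"] in scalars:
                kw["dlm_scalar"] = scalars[kw["name"]]
            out.append(GIRegion(**kw))
        return out

    def to_study_spec(self, seed: int = 0) -> StudySpec:
        t = self.trial
        return StudySpec(n_subjects=t.n_subjects, dose=t.dose,
                         variability_cv=dict(t.variability_cv),
                         residual_cv=t.residual_cv, seed=seed,
                         sample_times_h=tuple(t.sample_times_h))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return RunConfig.model_validate(raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)


def default_config() -> RunConfig:
    """The bundled default configuration (default media gradient, fasted
    physiology, tacrolimus-like illustrative compound parameters)."""
    text = importlib.resources.files("tacivive").joinpath("data/default_config.yaml").read_text()
    return RunConfig.model_validate(yaml.safe_load(text))
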
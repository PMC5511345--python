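"""Run configuration: YAML-backed, schema-validated (unknown keys rejected),
resolved config written next to every run's outputs."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .chase import ChaseThresholds
from .geometry import CellGeometry, CellShape
from .optics import OpticsConfig
from .simulate import (BleachEvent, FluorophorePool, Mechanism, SeededSheath,
                       SimulationConfig)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryBlock(_Strict):
    shape: CellShape = CellShape.SPHEROPLAST
    diameter_um: float = 5.0
    length_um: float | None = None
    center_um: tuple[float, float] = (0.0, 0.0)

    def build(self) -> CellGeometry:
        return CellGeometry(self.shape, self.diameter_um, self.length_um,
                            self.center_um)


class BleachBlock(_Strict):
    t_bleach_s: float
    line_start_um: tuple[float, float]
    line_end_um: tuple[float, float]
    footprint_fwhm_um: float = 0.8
    polymer_survival: float = 0.0
    pool_survival: float = 0.4
    saturation: float = 4.0

    def build(self) -> BleachEvent:
        return BleachEvent(**self.model_dump())


class SeededSheathBlock(_Strict):
    t_nucleation_s: float
    anchor_um: tuple[float, float]
    direction: tuple[float, float]
    v_a_nm_per_s: float
    target_length_um: float | None = None
    t_contract_s: float | None = None
    initial_length_um: float = 0.0

    def build(self) -> SeededSheath:
        return SeededSheath(**self.model_dump())


class SimulationBlock(_Strict):
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    mechanism: Mechanism = Mechanism.DISTAL
    v_a_mean_nm_per_s: float = 38.0
    v_a_sd_nm_per_s: float = 5.0
    contraction_fraction: float = 0.5
    contraction_jitter_sd: float = 0.03
    nucleation_rate_per_min: float = 0.0
    extended_dwell_s: float | None = 10.0
    disassembly_delay_s: float = 20.0
    disassembly_tau_s: float = 15.0
    frame_interval_s: float = 2.0
    duration_s: float = 120.0
    bleach: BleachBlock | None = None
    seeded_sheaths: list[SeededSheathBlock] = Field(default_factory=list)
    pool_brightness: float = 1.0
    pool_size: int | None = None

    def build(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            geometry=self.geometry.build(), seed=seed,
            mechanism=self.mechanism,
            v_a_mean_nm_per_s=self.v_a_mean_nm_per_s,
            v_a_sd_nm_per_s=self.v_a_sd_nm_per_s,
            contraction_fraction=self.contraction_fraction,
            contraction_jitter_sd=self.contraction_jitter_sd,
            nucleation_rate_per_min=self.nucleation_rate_per_min,
            extended_dwell_s=self.extended_dwell_s,
            disassembly_delay_s=self.disassembly_delay_s,
            disassembly_tau_s=self.disassembly_tau_s,
            frame_interval_s=self.frame_interval_s,
            duration_s=self.duration_s,
            bleach=self.bleach.build() if self.bleach else None,
            seeded_sheaths=[s.build() for s in self.seeded_sheaths],
            pool=FluorophorePool(self.pool_brightness, self.pool_size),
        )


class OpticsBlock(_Strict):
    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 110.0
    photons_per_ring: float = 60.0
    cytosol_background: float = 20.0
    read_noise_sd: float = 2.0
    camera_offset: float = 100.0
    shot_noise: bool = True

    def build(self, seed: int | None) -> OpticsConfig:
        return OpticsConfig(seed=seed, **self.model_dump())


class AnalysisBlock(_Strict):
    k_front: float = 3.0
    bleached_k: float = 2.0
    bright_floor: float = 0.7
    min_span_bins: int = 2
    drift_tol_fraction: float = 0.2
    width_tol: float = 0.3
    intensity_rise_min_pct: float = 5.0
    intensity_recovery_pct: float = 20.0
    bleached_floor_frac: float = 0.15
    classify_window_s: float = 8.0
    edge_trim_bins: int = 3
    profile_halfwidth_frames: int = 2

    def build(self) -> ChaseThresholds:
        return ChaseThresholds(**self.model_dump())


class RunConfig(_Strict):
    seed: int
    outdir: str = "out"
    log_level: str = "INFO"
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    optics: OpticsBlock = Field(default_factory=OpticsBlock)
    analysis: AnalysisBlock = Field(default_factory=AnalysisBlock)

    @field_validator("log_level")
    @classmethod
    def _level(cls, v: str) -> str:
        if v.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ValueError("log_level must be DEBUG/INFO/WARNING/ERROR")
        return v.upper()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
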
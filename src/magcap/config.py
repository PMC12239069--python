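"""Replication configurations: validated JSON bundles of all model inputs.

A :class:`ReplicationConfig` names one experimental condition — magnet field
model, capsule composition, fluid, acquisition design, analysis parameters
(binning, linking gates, observation window) and the master seed — with SI
units suffixed on every numeric key. Validation is strict: unknown keys are
rejected and all violations are reported together, not just the first.

Three packaged conditions (5-, 10- and 20-nm nanoparticle loadings at
500 ppm) live under ``magcap/data`` and carry effective susceptibilities
calibrated against reported mean transport speeds — annotated
"calibrated, not measured" in the files themselves.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import constants
from .capsule import CapsuleSpec, FluidMedium
from .errors import ConfigError
from .field import MagnetFieldModel
from .synth import ExperimentDesign

__all__ = [
    "ReplicationConfig",
    "load_config",
    "save_config",
    "packaged_config",
    "packaged_config_names",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FieldConfig(_Strict):
    surface_field_T: float = Field(gt=0)
    decay_length_m: float = Field(gt=0)
    origin_m: float = 0.0

    def to_model(self) -> MagnetFieldModel:
        return MagnetFieldModel(self.surface_field_T, self.decay_length_m, self.origin_m)


class CapsuleConfig(_Strict):
    diameter_m: float = Field(gt=0)
    np_diameter_m: float = Field(gt=0)
    loading_ppm: float = Field(ge=0, lt=1e6)
    intrinsic_susceptibility: float
    np_density_kg_m3: float = Field(default=constants.MAGNETITE_DENSITY, gt=0)
    matrix_density_kg_m3: float = Field(default=constants.PDMS_DENSITY, gt=0)
    demag_factor: float = Field(default=constants.SPHERE_DEMAG_FACTOR, ge=0, le=1)

    def to_spec(self) -> CapsuleSpec:
        return CapsuleSpec(
            diameter=self.diameter_m,
            np_diameter=self.np_diameter_m,
            loading_ppm=self.loading_ppm,
            intrinsic_susceptibility=self.intrinsic_susceptibility,
            np_density=self.np_density_kg_m3,
            matrix_density=self.matrix_density_kg_m3,
            demag_factor=self.demag_factor,
        )


class FluidConfig(_Strict):
    viscosity_Pa_s: float = Field(default=constants.WATER_VISCOSITY, gt=0)
    susceptibility: float = constants.WATER_SUSCEPTIBILITY
    density_kg_m3: float = Field(default=constants.WATER_DENSITY, gt=0)

    def to_medium(self) -> FluidMedium:
        return FluidMedium(self.viscosity_Pa_s, self.susceptibility, self.density_kg_m3)


class DesignConfig(_Strict):
    n_tracks: int = Field(ge=1)
    frame_rate_fps: float = Field(default=24.0, gt=0)
    duration_s: float = Field(default=60.0, gt=0)
    field_of_view_m: tuple[float, float] = (6e-3, 2e-3)
    start_x_min_m: float = Field(default=5e-4, ge=0)
    start_x_max_m: float = Field(default=5e-3, gt=0)
    start_sampler: str = "stratified"
    localization_noise_sd_m: float = Field(default=5e-7, ge=0)
    detection_dropout_prob: float = Field(default=0.0, ge=0, lt=1)

    def to_design(self, seed: int) -> ExperimentDesign:
        return ExperimentDesign(
            n_tracks=self.n_tracks,
            frame_rate=self.frame_rate_fps,
            duration=self.duration_s,
            field_of_view=tuple(self.field_of_view_m),
            start_x_min=self.start_x_min_m,
            start_x_max=self.start_x_max_m,
            start_sampler=self.start_sampler,
            localization_noise_sd=self.localization_noise_sd_m,
            detection_dropout_prob=self.detection_dropout_prob,
            seed=seed,
        )


class AnalysisConfig(_Strict):
    bin_width_m: float = Field(default=1e-4, gt=0)
    window_min_m: float = Field(default=5e-4, ge=0)
    window_max_m: float = Field(default=5e-3, gt=0)
    max_displacement_m: Optional[float] = Field(default=None, gt=0)
    max_gap_frames: int = Field(default=2, ge=0)

    @property
    def window(self) -> tuple[float, float]:
        return (self.window_min_m, self.window_max_m)


class CalibrationConfig(_Strict):
    """Anchors the condition to a reported mean transport speed.

    ``target_mean_speed_m_s`` is the mean approach speed over the analysis
    window that the capsule's effective susceptibility was calibrated to
    reproduce; ``average`` is the window-averaging convention used
    ("observed" = expected pooled frame-sampled mean). ``note`` documents
    provenance of the stored susceptibility.
    """

    target_mean_speed_m_s: Optional[float] = Field(default=None, gt=0)
    average: str = "observed"
    note: str = ""


class ReplicationConfig(_Strict):
    name: str
    seed: int = Field(ge=0, lt=2**31)
    field: FieldConfig
    capsule: CapsuleConfig
    fluid: FluidConfig = FluidConfig()
    design: DesignConfig
    analysis: AnalysisConfig = AnalysisConfig()
    calibration: CalibrationConfig = CalibrationConfig()

    @model_validator(mode="after")
    def _cross_checks(self):
        problems = []
        if self.design.start_x_max_m <= self.design.start_x_min_m:
            problems.append("design.start_x_max_m must exceed design.start_x_min_m")
        if self.analysis.window_max_m <= self.analysis.window_min_m:
            problems.append("analysis.window_max_m must exceed analysis.window_min_m")
        if self.design.start_x_min_m <= self.capsule.diameter_m / 2:
            problems.append("design.start_x_min_m must exceed the capsule radius")
        if problems:
            raise ValueError("; ".join(problems))
        return self

    # -- conversions to domain objects ------------------------------------
    def field_model(self) -> MagnetFieldModel:
        return self.field.to_model()

    def capsule_spec(self) -> CapsuleSpec:
        return self.capsule.to_spec()

    def fluid_medium(self) -> FluidMedium:
        return self.fluid.to_medium()

    def experiment_design(self, seed: Optional[int] = None) -> ExperimentDesign:
        return self.design.to_design(self.seed if seed is None else seed)

    def to_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.model_dump(mode="json"), sort_keys=True).encode()
        ).hexdigest()[:12]


def _format_validation_error(exc: ValidationError) -> str:
    lines = [f"configuration failed validation with {exc.error_count()} problem(s):"]
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  - {loc}: {err['msg']}")
    return "\n".join(lines)


def load_config(path: str | Path) -> ReplicationConfig:
    """Load and fully validate a replication config.

    All violations are reported together in the raised
    :class:`ConfigError`, naming each offending key.
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    try:
        return ReplicationConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: ReplicationConfig, path: str | Path) -> None:
    from .io import atomic_write_text

    atomic_write_text(path, config.to_json())


def packaged_config_names() -> list[str]:
    """Names of the replication configs shipped with the package."""
    pkg = resources.files("magcap") / "data"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))


def packaged_config(name: str) -> ReplicationConfig:
    """Load a packaged replication config, e.g. ``"replication_10nm"``."""
    pkg = resources.files("magcap") / "data" / f"{name}.json"
    try:
        raw = json.loads(pkg.read_text())
    except FileNotFoundError as exc:
        raise ConfigError(
            f"no packaged config named {name!r}; available: {packaged_config_names()}"
        ) from exc
    try:
        return ReplicationConfig.model_validate(raw)
    except ValidationError as exc:  # pragma: no cover - packaged files are valid
        raise ConfigError(_format_validation_error(exc)) from exc
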
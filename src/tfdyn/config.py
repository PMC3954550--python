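"""Experiment configuration: schema, validation, YAML round-trip.

An experiment config fully describes one synthetic condition: the
generating motion model, the single-molecule imaging regime, the FRAP
geometry/protocol, the grid-search plan, and seeds.  Unknown keys are
rejected; invariants (fraction sums, residence-time ordering, positive
counts) are checked at load time with named errors.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .conditions import get_condition
from .frap import FrapProtocol, NucleusGeometry
from .frapfit import SearchSpace
from .kinetics import MotionModel
from .motion import ImagingRegime
from .pics import PicsConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MotionBlock(_Strict):
    fraction_free: float = Field(ge=0, le=1)
    fraction_short: float = Field(ge=0, le=1)
    fraction_long: float = Field(ge=0, le=1)
    d_free: float = Field(gt=0, description="µm²/s")
    d_bound: float = Field(default=0.03, ge=0)
    tau_short: float = Field(default=0.7, gt=0)
    tau_long: float = Field(default=2.3, gt=0)

    @model_validator(mode="after")
    def _invariants(self):
        total = self.fraction_free + self.fraction_short + self.fraction_long
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"invariant 'fraction sum = 1' violated (sum={total})")
        if (
            self.fraction_short > 0
            and self.fraction_long > 0
            and self.tau_short > self.tau_long
        ):
            raise ValueError("invariant 'tau_short <= tau_long' violated")
        if self.d_bound > self.d_free:
            raise ValueError("invariant 'd_bound <= d_free' violated")
        return self

    def to_model(self) -> MotionModel:
        f = [self.fraction_free, self.fraction_short, self.fraction_long]
        s = sum(f)

        def _tau(t: float) -> float:
            # YAML has no clean inf literal; huge values mean "permanent"
            return math.inf if t >= 1e8 else t

        return MotionModel(
            fraction_free=f[0] / s,
            fraction_short=f[1] / s,
            fraction_long=f[2] / s,
            d_free=self.d_free,
            d_bound=self.d_bound,
            tau_short=_tau(self.tau_short),
            tau_long=_tau(self.tau_long),
        )


class RegimeBlock(_Strict):
    frame_lag_ms: float = Field(default=6.25, gt=0)
    second_lag_ms: float | None = Field(default=12.5, gt=0)
    frames_per_series: int = Field(default=8, ge=2)
    series_per_cell: int = Field(default=180, gt=0)
    n_cells: int = Field(default=20, gt=0)
    roi_pixels: int = Field(default=50, gt=0)
    pixel_size_um: float = Field(default=0.220, gt=0)
    localization_sigma_um: float = Field(default=0.040, ge=0)
    mean_peaks_per_frame: float = Field(default=1.5, gt=0)
    blink_off_rate: float = Field(default=0.0, ge=0)
    blink_on_rate: float = Field(default=0.0, ge=0)
    bleach_rate: float = Field(default=0.0, ge=0)
    axial_extent_um: float = Field(default=1.0, gt=0)
    detection_slab_um: float | None = None  # None = unbounded (wide-field)

    def to_regime(self, seed: int) -> ImagingRegime:
        return ImagingRegime(
            frame_lag=self.frame_lag_ms * 1e-3,
            frames_per_series=self.frames_per_series,
            series_per_cell=self.series_per_cell,
            n_cells=self.n_cells,
            roi_pixels=self.roi_pixels,
            pixel_size=self.pixel_size_um,
            localization_sigma=self.localization_sigma_um,
            mean_peaks_per_frame=self.mean_peaks_per_frame,
            blink_off_rate=self.blink_off_rate,
            blink_on_rate=self.blink_on_rate,
            bleach_rate=self.bleach_rate,
            axial_extent=self.axial_extent_um,
            detection_slab=self.detection_slab_um or math.inf,
            rng_seed=seed,
        )


class FrapGeometryBlock(_Strict):
    a_um: float = Field(default=6.0, gt=0)
    b_um: float = Field(default=4.0, gt=0)
    c_um: float = Field(default=2.5, gt=0)
    strip_width_um: float = Field(default=1.0, gt=0)

    def to_geometry(self) -> NucleusGeometry:
        return NucleusGeometry(self.a_um, self.b_um, self.c_um, self.strip_width_um)


class FrapProtocolBlock(_Strict):
    n_prescans: int = Field(default=40, ge=1)
    scan_interval_s: float = Field(default=0.1, gt=0)
    bleach_duration_s: float = Field(default=0.1, gt=0)
    recovery_duration_s: float = Field(default=55.0, gt=0)
    bleach_survival: float = Field(default=0.16, ge=0, le=1)
    n_cells: int = Field(default=30, gt=0)
    n_particles: int = Field(default=20_000, gt=0)
    sim_timestep_s: float = Field(default=0.05, gt=0)
    n_bleach_substeps: int = Field(default=5, ge=1)

    def to_protocol(self, seed: int) -> FrapProtocol:
        return FrapProtocol(
            n_prescans=self.n_prescans,
            scan_interval=self.scan_interval_s,
            bleach_duration=self.bleach_duration_s,
            recovery_duration=self.recovery_duration_s,
            bleach_survival=self.bleach_survival,
            n_cells=self.n_cells,
            n_particles=self.n_particles,
            sim_timestep=self.sim_timestep_s,
            n_bleach_substeps=self.n_bleach_substeps,
            rng_seed=seed,
        )


class SearchBlock(_Strict):
    n_fraction: int = Field(default=10, ge=2)
    n_tau_short: int = Field(default=5, ge=2)
    n_tau_long: int = Field(default=8, ge=2)
    refine_passes: int = Field(default=1, ge=0)
    candidate_particles: int = Field(default=3000, gt=0)
    final_particles: int = Field(default=120_000, gt=0)
    stage2_pool: int = Field(default=15, gt=0)
    polish_pool: int = Field(default=10, gt=0)

    def to_space(self) -> SearchSpace:
        return SearchSpace(
            n_fraction=self.n_fraction,
            n_tau_short=self.n_tau_short,
            n_tau_long=self.n_tau_long,
            refine_passes=self.refine_passes,
        )


class PicsBlock(_Strict):
    max_lag_ms: float = Field(default=37.5, gt=0)
    background_window_um2: tuple[float, float] = (1.0, 4.0)
    min_pairs: int = Field(default=50, gt=0)
    n_groups: int = Field(default=3, ge=1)

    def to_config(self, roi_size: float) -> PicsConfig:
        return PicsConfig(
            max_lag=self.max_lag_ms * 1e-3,
            roi_size=roi_size,
            background_window=self.background_window_um2,
            min_pairs=self.min_pairs,
        )


class ExperimentConfig(_Strict):
    """Complete description of one synthetic condition."""

    condition: str = "custom"
    seed: int = 0
    profile: Literal["full", "reduced"] = "full"
    motion: MotionBlock
    frap_model: MotionBlock | None = None
    regime: RegimeBlock = RegimeBlock()
    frap_geometry: FrapGeometryBlock = FrapGeometryBlock()
    frap_protocol: FrapProtocolBlock = FrapProtocolBlock()
    search: SearchBlock = SearchBlock()
    pics: PicsBlock = PicsBlock()

    def effective(self) -> "ExperimentConfig":
        """Resolve the scale profile into concrete block values."""
        if self.profile == "full":
            return self
        upd = self.model_copy(deep=True)
        upd.regime.n_cells = min(upd.regime.n_cells, 5)
        upd.regime.series_per_cell = min(upd.regime.series_per_cell, 60)
        upd.frap_protocol.n_cells = min(upd.frap_protocol.n_cells, 5)
        upd.frap_protocol.n_particles = min(upd.frap_protocol.n_particles, 2000)
        upd.frap_protocol.n_prescans = min(upd.frap_protocol.n_prescans, 10)
        upd.frap_protocol.sim_timestep_s = max(
            upd.frap_protocol.sim_timestep_s, 0.1
        )
        upd.search.n_fraction = min(upd.search.n_fraction, 5)
        upd.search.n_tau_short = min(upd.search.n_tau_short, 3)
        upd.search.n_tau_long = min(upd.search.n_tau_long, 4)
        upd.search.candidate_particles = min(upd.search.candidate_particles, 800)
        upd.search.final_particles = min(upd.search.final_particles, 4000)
        upd.search.stage2_pool = min(upd.search.stage2_pool, 25)
        upd.pics.n_groups = min(upd.pics.n_groups, 3)
        return upd

    def frap_generating_model(self) -> MotionModel:
        block = self.frap_model or self.motion
        m = block.to_model()
        # FRAP treats bound molecules as strictly immobile
        return MotionModel(
            m.fraction_free,
            m.fraction_short,
            m.fraction_long,
            m.d_free,
            0.0,
            m.tau_short,
            m.tau_long,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            self.model_dump(exclude_none=False), sort_keys=False
        )


def validate_and_load(path: str | Path) -> ExperimentConfig:
    """Load, default-fill and schema-check a YAML experiment config."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return ExperimentConfig.model_validate(raw)
    except Exception as exc:  # re-raise with the file name attached
        raise ValueError(f"{path}: {exc}") from exc


def config_for_condition(
    key: str, seed: int = 0, profile: str = "full"
) -> ExperimentConfig:
    """Build a config whose ground truth is a catalogued condition."""
    c = get_condition(key)
    smm = c.smm_ground_truth()
    frap = c.frap_ground_truth()

    def _block(m: MotionModel) -> MotionBlock:
        return MotionBlock(
            fraction_free=m.fraction_free,
            fraction_short=m.fraction_short,
            fraction_long=m.fraction_long,
            d_free=m.d_free,
            d_bound=m.d_bound,
            tau_short=m.tau_short,
            tau_long=min(m.tau_long, 1e9),  # YAML-safe stand-in for inf
        )

    return ExperimentConfig(
        condition=key, seed=seed, profile=profile,
        motion=_block(smm), frap_model=_block(frap),
    )
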
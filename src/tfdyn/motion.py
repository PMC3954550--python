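"""Synthetic single-molecule motion and localization tables.

Ground truth for the displacement analysis: molecules switch between free
3D diffusion and slow chromatin-bound motion according to the three-state
chain of :mod:`tfdyn.kinetics`, are imaged as short series of frames in a
square region of interest, and are observed as 2D-projected positions with
Gaussian localization error.  Series are statistically independent (the real
experiment bleaches between series), so displacement correlations exist only
within one series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import MotionModel, rates_from_fractions, transition_matrix

LOCALIZATION_COLUMNS = ["cell", "series", "frame", "x_um", "y_um", "photons"]


@dataclass(frozen=True)
class ImagingRegime:
    """Acquisition geometry and timing of the single-molecule experiment.

    Defaults mirror the stroboscopic wide-field protocol: series of 8 frames
    at a 6.25 ms (or 12.5 ms) lag, a 50x50 pixel region of interest with
    220 nm pixels, ~40 nm localization error and ~1.5 detected peaks per
    frame.

    ``detection_slab`` is the axial thickness within which a molecule is
    counted as visible; the default is unbounded (all molecules in the
    imaged volume are detectable), since at lags <= 37.5 ms axial diffusion
    lengths (~0.3 µm) are far below the wide-field depth of detection.  Set
    it to a finite value to stress-test the axial-escape bias.
    """

    frame_lag: float = 6.25e-3  # s
    frames_per_series: int = 8
    series_per_cell: int = 180
    n_cells: int = 20
    roi_pixels: int = 50
    pixel_size: float = 0.220  # µm
    localization_sigma: float = 0.040  # µm per axis
    mean_peaks_per_frame: float = 1.5
    blink_off_rate: float = 0.0  # 1/s
    blink_on_rate: float = 0.0  # 1/s
    bleach_rate: float = 0.0  # 1/s
    axial_extent: float = 1.0  # µm, thickness of the simulated volume
    detection_slab: float = math.inf  # µm, axial visibility window
    lateral_margin: float = 1.0  # µm simulated beyond the ROI on each side
    mean_photons: float = 100.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_lag <= 0:
            raise ValueError("frame_lag must be positive")
        if self.localization_sigma < 0:
            raise ValueError("localization_sigma must be non-negative")
        if self.frames_per_series < 2:
            raise ValueError("a series needs at least 2 frames")
        if min(self.series_per_cell, self.n_cells, self.roi_pixels) <= 0:
            raise ValueError("counts must be positive")

    @property
    def roi_size(self) -> float:
        """Side of the square field of view, µm."""
        return self.roi_pixels * self.pixel_size

    @property
    def visible_fraction(self) -> float:
        """Probability that a uniformly placed molecule is detectable."""
        lat = self.roi_size / (self.roi_size + 2 * self.lateral_margin)
        axial = min(self.detection_slab, self.axial_extent) / self.axial_extent
        return lat * lat * axial


@dataclass
class TrajectorySet:
    """Ground-truth 3D trajectories with state labels and emission flags.

    Arrays are indexed (molecule, frame); positions additionally carry the
    axis (x, y, z) in µm with the lateral origin at the ROI corner.
    """

    positions: np.ndarray  # (n_mol, n_frames, 3)
    states: np.ndarray  # (n_mol, n_frames) int8
    emitting: np.ndarray  # (n_mol, n_frames) bool
    cell: np.ndarray  # (n_mol,)
    series: np.ndarray  # (n_mol,)
    regime: ImagingRegime

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0]


def _evolve_states(
    rng: np.random.Generator,
    p0: np.ndarray,
    tmat: np.ndarray,
    n_mol: int,
    n_frames: int,
) -> np.ndarray:
    states = np.empty((n_mol, n_frames), dtype=np.int8)
    states[:, 0] = rng.choice(3, size=n_mol, p=p0)
    cum = np.cumsum(tmat, axis=1)
    for t in range(1, n_frames):
        u = rng.random(n_mol)
        prev = states[:, t - 1]
        rows = cum[prev]
        states[:, t] = (u[:, None] > rows).sum(axis=1)
    return states


def simulate_trajectories(
    model: MotionModel,
    regime: ImagingRegime,
    rng: np.random.Generator | None = None,
) -> TrajectorySet:
    """Simulate ground-truth trajectories for every cell and series.

    Molecules are placed uniformly in a volume extending ``lateral_margin``
    beyond the ROI and ``axial_extent`` axially; their number per series is
    Poisson, calibrated so the expected number of *visible* molecules per
    frame equals ``mean_peaks_per_frame``.  The mobility state evolves by the
    exact per-lag transition matrix of the three-state chain (initialized at
    stationarity, i.e. at the model fractions) and each frame-to-frame
    displacement is Gaussian per axis with variance ``2 D dt`` at the
    diffusion coefficient of the state occupied at the start of the step.
    """
    rates = rates_from_fractions(model)
    tmat = transition_matrix(rates, regime.frame_lag)
    p0 = model.fractions
    d_of_state = model.diffusion_of_state()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(regime.rng_seed))

    mean_mols = regime.mean_peaks_per_frame / regime.visible_fraction
    size = regime.roi_size
    lo, hi = -regime.lateral_margin, size + regime.lateral_margin
    f = regime.frames_per_series
    dt = regime.frame_lag

    pos_parts, state_parts, emit_parts, cell_parts, series_parts = [], [], [], [], []
    for cell in range(regime.n_cells):
        counts = rng.poisson(mean_mols, size=regime.series_per_cell)
        m = int(counts.sum())
        if m == 0:
            continue
        series_ids = np.repeat(np.arange(regime.series_per_cell), counts)

        states = _evolve_states(rng, p0, tmat, m, f)
        pos = np.empty((m, f, 3))
        pos[:, 0, 0] = rng.uniform(lo, hi, m)
        pos[:, 0, 1] = rng.uniform(lo, hi, m)
        pos[:, 0, 2] = rng.uniform(
            -regime.axial_extent / 2, regime.axial_extent / 2, m
        )
        # per-step sigma set by the state at the start of the step
        sigmas = np.sqrt(2.0 * d_of_state[states[:, :-1]] * dt)  # (m, f-1)
        steps = rng.standard_normal((m, f - 1, 3)) * sigmas[:, :, None]
        pos[:, 1:, :] = pos[:, :1, :] + np.cumsum(steps, axis=1)

        emitting = np.ones((m, f), dtype=bool)
        if regime.blink_off_rate > 0 or regime.bleach_rate > 0:
            p_off = 1.0 - math.exp(-regime.blink_off_rate * dt)
            p_on = 1.0 - math.exp(-regime.blink_on_rate * dt)
            p_bleach = 1.0 - math.exp(-regime.bleach_rate * dt)
            on = np.ones(m, dtype=bool)
            alive = np.ones(m, dtype=bool)
            for t in range(1, f):
                u = rng.random(m)
                on = np.where(on, u >= p_off, u < p_on)
                alive &= rng.random(m) >= p_bleach
                emitting[:, t] = on & alive

        pos_parts.append(pos)
        state_parts.append(states)
        emit_parts.append(emitting)
        cell_parts.append(np.full(m, cell))
        series_parts.append(series_ids)

    return TrajectorySet(
        positions=np.concatenate(pos_parts) if pos_parts else np.empty((0, f, 3)),
        states=np.concatenate(state_parts) if state_parts else np.empty((0, f), np.int8),
        emitting=np.concatenate(emit_parts) if emit_parts else np.empty((0, f), bool),
        cell=np.concatenate(cell_parts) if cell_parts else np.empty(0, int),
        series=np.concatenate(series_parts) if series_parts else np.empty(0, int),
        regime=regime,
    )


def observe(
    trajectories: TrajectorySet,
    regime: ImagingRegime | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Turn ground-truth trajectories into an observed localization table.

    The axial coordinate is dropped (2D projection), independent Gaussian
    localization noise of SD ``localization_sigma`` is added per axis, and
    molecules outside the ROI, outside the detection slab, or not emitting
    are omitted.  Deterministic for a given ``rng_seed``.
    """
    if regime is None:
        regime = trajectories.regime
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([regime.rng_seed, 1]))

    pos = trajectories.positions
    n_mol, n_frames, _ = pos.shape
    size = regime.roi_size
    half_slab = regime.detection_slab / 2

    noisy = pos[:, :, :2]
    if regime.localization_sigma > 0:
        noisy = noisy + rng.normal(0.0, regime.localization_sigma, noisy.shape)

    visible = (
        trajectories.emitting
        & (pos[:, :, 0] >= 0)
        & (pos[:, :, 0] <= size)
        & (pos[:, :, 1] >= 0)
        & (pos[:, :, 1] <= size)
        & (np.abs(pos[:, :, 2]) <= half_slab)
    )
    mol_idx, frame_idx = np.nonzero(visible)
    photons = rng.poisson(regime.mean_photons, size=mol_idx.size)
    table = pd.DataFrame(
        {
            "cell": trajectories.cell[mol_idx],
            "series": trajectories.series[mol_idx],
            "frame": frame_idx,
            "x_um": noisy[mol_idx, frame_idx, 0],
            "y_um": noisy[mol_idx, frame_idx, 1],
            "photons": photons,
        }
    )
    return table.sort_values(["cell", "series", "frame"], kind="stable").reset_index(
        drop=True
    )


def simulate_localizations(model: MotionModel, regime: ImagingRegime) -> pd.DataFrame:
    """Convenience: ground-truth simulation followed by observation."""
    return observe(simulate_trajectories(model, regime), regime)


def simulate_two_lag_experiment(
    model: MotionModel, regime: ImagingRegime, second_lag: float = 12.5e-3
) -> dict[float, pd.DataFrame]:
    """Simulate the paired-lag protocol: one table per frame lag.

    Returns a mapping frame_lag -> localization table, with independent
    series at each lag (seeds derived from the regime seed).
    """
    regime2 = replace(regime, frame_lag=second_lag, rng_seed=regime.rng_seed + 1)
    return {
        regime.frame_lag: simulate_localizations(model, regime),
        second_lag: simulate_localizations(model, regime2),
    }


def write_localizations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=LOCALIZATION_COLUMNS)


def read_localizations(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(LOCALIZATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    return table
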
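"""Motion simulator: step statistics, observation model, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tfdyn import (
    ImagingRegime,
    MotionModel,
    observe,
    simulate_localizations,
    simulate_trajectories,
)
from tfdyn.kinetics import FREE


def test_free_step_sd_matches_gaussian_rule():
    """Per-axis true step SD of free molecules is sqrt(2 D dt) = 0.1280 µm."""
    model = MotionModel(1.0, 0.0, 0.0, d_free=1.31)
    regime = ImagingRegime(series_per_cell=150, n_cells=4, rng_seed=1)
    traj = simulate_trajectories(model, regime)
    steps = np.diff(traj.positions, axis=1)  # all molecules are free
    sd = steps.std()
    assert sd == pytest.approx(math.sqrt(2 * 1.31 * 0.00625), rel=0.02)
    assert sd == pytest.approx(0.1280, abs=0.003)


def test_all_bound_zero_d_trajectories_constant():
    model = MotionModel(0.0, 0.0, 1.0, d_free=1.0, d_bound=0.0, tau_long=math.inf)
    regime = ImagingRegime(series_per_cell=20, n_cells=2, rng_seed=2)
    traj = simulate_trajectories(model, regime)
    assert np.all(traj.positions == traj.positions[:, :1, :])


def test_state_occupancy_matches_fractions(agonist_model):
    """Long-run frame occupancy per state is within 3 SE of the fractions."""
    regime = ImagingRegime(series_per_cell=380, n_cells=16, rng_seed=14)
    traj = simulate_trajectories(agonist_model, regime)
    states = traj.states.ravel()
    n = states.size
    assert n > 1e5
    for s, f in enumerate(agonist_model.fractions):
        occ = np.mean(states == s)
        # frames within a molecule are correlated; use molecule count for SE
        n_eff = traj.states.shape[0]
        se = math.sqrt(f * (1 - f) / n_eff)
        assert abs(occ - f) < 3.5 * se


def test_mixture_msd_closed_form(agonist_model):
    """Observed 2D MSD at one lag = 4[aD_f+(1-a)D_b]dt + 4 sigma_loc^2."""
    regime = ImagingRegime(series_per_cell=400, n_cells=8, rng_seed=3)
    traj = simulate_trajectories(agonist_model, regime)
    table = observe(traj, regime)
    # pair consecutive frames of the same molecule via the ground truth:
    noisy_like = traj.positions[:, :, :2]
    rng = np.random.default_rng(0)
    noisy = noisy_like + rng.normal(0, regime.localization_sigma, noisy_like.shape)
    d2 = ((noisy[:, 1:, :] - noisy[:, :-1, :]) ** 2).sum(axis=2).ravel()
    m = agonist_model
    alpha = m.fraction_free
    expected = (
        4 * (alpha * m.d_free + (1 - alpha) * m.d_bound) * regime.frame_lag
        + 4 * regime.localization_sigma**2
    )
    se = d2.std() / math.sqrt(len(d2))
    assert abs(d2.mean() - expected) < 3.5 * se
    assert len(table) > 0  # the observed table was produced alongside


def test_observe_noiseless_is_bijection_onto_roi(agonist_model, small_regime):
    regime = replace(small_regime, localization_sigma=0.0)
    traj = simulate_trajectories(agonist_model, regime)
    table = observe(traj, regime)
    pos = traj.positions
    size = regime.roi_size
    in_roi = (
        (pos[:, :, 0] >= 0)
        & (pos[:, :, 0] <= size)
        & (pos[:, :, 1] >= 0)
        & (pos[:, :, 1] <= size)
    )
    assert len(table) == int(in_roi.sum())
    # observed positions equal true positions exactly
    got = np.sort(table["x_um"].to_numpy())
    want = np.sort(pos[:, :, 0][in_roi])
    np.testing.assert_allclose(got, want, atol=0)


def test_immobile_observed_msd_is_4_sigma_sq():
    """Noise-only squared displacement of an immobile molecule: 4 sigma^2."""
    from tfdyn.motion import TrajectorySet

    regime = ImagingRegime(localization_sigma=0.040, rng_seed=4)
    n_mol, f = 3000, regime.frames_per_series
    positions = np.tile([5.5, 5.5, 0.0], (n_mol, f, 1))
    traj = TrajectorySet(
        positions=positions,
        states=np.full((n_mol, f), 2, dtype=np.int8),
        emitting=np.ones((n_mol, f), dtype=bool),
        cell=np.zeros(n_mol, dtype=int),
        series=np.arange(n_mol),
        regime=regime,
    )
    table = observe(traj, regime)
    xy = table.sort_values(["series", "frame"])[["x_um", "y_um"]].to_numpy()
    xy = xy.reshape(n_mol, f, 2)
    d2 = ((xy[:, 1:, :] - xy[:, :-1, :]) ** 2).sum(axis=2).ravel()
    se = d2.std() / math.sqrt(len(d2))
    assert abs(d2.mean() - 4 * 0.040**2) < 3.5 * se


def test_observation_deterministic_under_seed(agonist_model, small_regime):
    t1 = simulate_localizations(agonist_model, small_regime)
    t2 = simulate_localizations(agonist_model, small_regime)
    assert t1.equals(t2)


def test_mean_peaks_per_frame_calibration(agonist_model, small_regime):
    table = simulate_localizations(agonist_model, small_regime)
    frames_total = (
        small_regime.n_cells
        * small_regime.series_per_cell
        * small_regime.frames_per_series
    )
    rate = len(table) / frames_total
    assert rate == pytest.approx(small_regime.mean_peaks_per_frame, rel=0.1)


def test_blinking_reduces_observations(agonist_model, small_regime):
    blinky = replace(small_regime, blink_off_rate=40.0, blink_on_rate=10.0)
    base = simulate_localizations(agonist_model, small_regime)
    dimmed = simulate_localizations(agonist_model, blinky)
    assert len(dimmed) < 0.8 * len(base)


def test_finite_detection_slab_drops_out_of_focus(agonist_model, small_regime):
    """The same trajectories observed through a thin axial slab yield
    roughly slab/extent as many localizations (density calibration aside)."""
    sliced = replace(small_regime, detection_slab=0.4)
    traj = simulate_trajectories(agonist_model, small_regime)
    full = observe(traj, small_regime)
    thin = observe(traj, sliced)
    ratio = len(thin) / len(full)
    assert 0.25 < ratio < 0.55  # ~0.4 with axial diffusion in and out


def test_trajectory_states_all_free_when_pure_diffusion():
    model = MotionModel(1.0, 0.0, 0.0, d_free=2.0)
    regime = ImagingRegime(series_per_cell=10, n_cells=1, rng_seed=5)
    traj = simulate_trajectories(model, regime)
    assert np.all(traj.states == FREE)
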
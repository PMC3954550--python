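"""Strip-FRAP Monte Carlo: conservation, limits, discretization, ordering."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tfdyn import FrapCurve, FrapProtocol, MotionModel, NucleusGeometry, simulate_frap
from tfdyn.frap import simulate_candidate_curves, reduced_protocol


FIXED_CELL = MotionModel(0.0, 0.0, 1.0, d_free=1.31, d_bound=0.0, tau_long=math.inf)
PURE_DIFFUSION = MotionModel(1.0, 0.0, 0.0, d_free=1.31, d_bound=0.0)


def test_geometry_strip_volume_fraction():
    geom = NucleusGeometry(a=6.0, b=4.0, c=2.5, strip_width=1.0)
    # closed form (3h - h^3)/2 with h = 1/12; cross-check by quadrature
    h = 0.5 / 6.0
    xs = np.linspace(-0.5, 0.5, 20001)
    num = np.trapezoid(1 - (xs / 6.0) ** 2, xs) / (4.0 / 3.0 * 6.0)
    assert geom.strip_volume_fraction() == pytest.approx((3 * h - h**3) / 2, abs=1e-12)
    assert geom.strip_volume_fraction() == pytest.approx(num, abs=1e-6)


def test_fluorescence_conserved_outside_bleach(agonist_model, geometry, tiny_frap_protocol):
    frap_model = replace_bound_immobile(agonist_model)
    curve = simulate_frap(frap_model, geometry, tiny_frap_protocol)
    totals = curve.total_fluorescent
    pre = totals[curve.phase == "pre"]
    rec = totals[curve.phase == "recovery"]
    n = tiny_frap_protocol.n_particles * tiny_frap_protocol.n_cells
    assert np.all(pre == n)  # exact: nothing bleaches before the pulse
    assert np.all(rec == rec[0])  # exact: nothing bleaches afterwards
    assert rec[0] < n


def replace_bound_immobile(m: MotionModel) -> MotionModel:
    return MotionModel(
        m.fraction_free, m.fraction_short, m.fraction_long, m.d_free, 0.0,
        m.tau_short, m.tau_long,
    )


def test_prebleach_baseline_is_one(agonist_model, geometry):
    proto = FrapProtocol(
        n_prescans=20, recovery_duration=2.0, n_cells=4, n_particles=4000,
        sim_timestep=0.1, rng_seed=9,
    )
    curve = simulate_frap(replace_bound_immobile(agonist_model), geometry, proto)
    pre = curve.intensity[curve.phase == "pre"]
    assert pre.mean() == pytest.approx(1.0, abs=1e-12)  # normalization identity
    n_strip = proto.n_particles * proto.n_cells * geometry.strip_volume_fraction()
    se = 1.0 / math.sqrt(n_strip * len(pre))
    assert abs(pre.mean() - 1.0) < 3 * se  # and statistically consistent


def test_fixed_cell_curve_flat_after_bleach(geometry):
    """Immobile-limit control: no recovery and no further loss for 6 s."""
    proto = FrapProtocol(
        n_prescans=10, recovery_duration=6.0, n_cells=3, n_particles=5000,
        sim_timestep=0.1, rng_seed=5,
    )
    curve = simulate_frap(FIXED_CELL, geometry, proto)
    rec = curve.intensity[curve.phase == "recovery"]
    assert np.all(rec == rec[0])  # bound molecules cannot move: exactly flat
    assert rec[0] == pytest.approx(proto.bleach_survival, abs=0.05)


def test_pure_diffusion_plateau_particle_conservation(geometry):
    """Long-time level equals the surviving fluorescent fraction."""
    proto = FrapProtocol(
        n_prescans=10, recovery_duration=30.0, n_cells=4, n_particles=5000,
        sim_timestep=0.1, rng_seed=6,
    )
    curve = simulate_frap(PURE_DIFFUSION, geometry, proto)
    n = proto.n_particles * proto.n_cells
    surviving = curve.total_fluorescent[-1] / n
    rec = curve.intensity[curve.phase == "recovery"]
    plateau = rec[-80:].mean()
    assert plateau == pytest.approx(surviving, abs=0.03)


def test_more_long_binding_never_accelerates_recovery(geometry):
    """Pointwise ordering (within noise) as fraction_long grows."""
    proto = FrapProtocol(
        n_prescans=5, recovery_duration=12.0, n_cells=6, n_particles=6000,
        sim_timestep=0.1, rng_seed=7,
    )
    curves = []
    for f_long in (0.0, 0.3, 0.6):
        m = MotionModel(1.0 - f_long, 0.0, f_long, 1.31, 0.0, tau_long=8.0)
        c = simulate_frap(m, geometry, replace(proto, rng_seed=7))
        curves.append(c.intensity[c.phase == "recovery"])
    # compare smoothed curves to suppress counting noise
    k = np.ones(10) / 10

    def smooth(y):
        return np.convolve(y, k, mode="valid")

    assert np.all(smooth(curves[0]) >= smooth(curves[1]) - 0.05)
    assert np.all(smooth(curves[1]) >= smooth(curves[2]) - 0.05)


def test_timestep_halving_within_replicate_scatter(agonist_model, geometry):
    """dt -> dt/2 changes the curve less than the replicate-to-replicate SD."""
    base = FrapProtocol(
        n_prescans=5, recovery_duration=8.0, n_cells=4, n_particles=6000,
        sim_timestep=0.1, rng_seed=8,
    )
    m = replace_bound_immobile(agonist_model)

    def rec(proto):
        c = simulate_frap(m, geometry, proto)
        return c.intensity[c.phase == "recovery"]

    coarse = rec(base)
    fine = rec(replace(base, sim_timestep=0.05))
    rep_sd = np.std(
        [rec(replace(base, rng_seed=s)) for s in (18, 28, 38)], axis=0
    ).mean()
    assert np.abs(coarse - fine).mean() < 2.0 * rep_sd


def test_deterministic_under_seed(agonist_model, geometry, tiny_frap_protocol):
    m = replace_bound_immobile(agonist_model)
    c1 = simulate_frap(m, geometry, tiny_frap_protocol)
    c2 = simulate_frap(m, geometry, tiny_frap_protocol)
    np.testing.assert_array_equal(c1.intensity, c2.intensity)


def test_unsimulable_model_rejected(geometry, tiny_frap_protocol):
    bad = MotionModel(0.0, 0.5, 0.5, 1.0, 0.0, tau_short=0.5, tau_long=2.0)
    with pytest.raises(ValueError):
        simulate_frap(bad, geometry, tiny_frap_protocol)


def test_protocol_validation():
    with pytest.raises(ValueError):
        FrapProtocol(sim_timestep=0.3)  # larger than the scan interval
    with pytest.raises(ValueError):
        FrapProtocol(bleach_survival=1.2)


def test_curve_csv_round_trip(tmp_path, agonist_model, geometry, tiny_frap_protocol):
    c = simulate_frap(replace_bound_immobile(agonist_model), geometry, tiny_frap_protocol)
    path = tmp_path / "curve.csv"
    c.write_csv(path)
    back = FrapCurve.read_csv(path)
    np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-12)
    assert list(back.phase[:3]) == ["pre"] * 3


def test_batch_simulator_matches_ensemble_statistically(agonist_model, geometry):
    """CRN batch engine and the ensemble engine agree on the mean curve."""
    m = replace_bound_immobile(agonist_model)
    proto = FrapProtocol(
        n_prescans=5, recovery_duration=10.0, n_cells=5, n_particles=8000,
        sim_timestep=0.1, rng_seed=12,
    )
    ens = simulate_frap(m, geometry, proto)
    ens_rec = ens.intensity[ens.phase == "recovery"]
    cp = replace(
        reduced_protocol(proto, n_particles=40_000, n_cells=1, n_prescans=0),
        rng_seed=77,
    )
    bat = simulate_candidate_curves([m, m], geometry, cp)
    np.testing.assert_array_equal(bat[0], bat[1])  # identical under CRN
    assert np.abs(bat[0] - ens_rec).mean() < 0.02


def test_batch_requires_shared_d_free(geometry, tiny_frap_protocol):
    m1 = MotionModel(1.0, 0.0, 0.0, 1.0)
    m2 = MotionModel(1.0, 0.0, 0.0, 2.0)
    with pytest.raises(ValueError, match="d_free"):
        simulate_candidate_curves([m1, m2], geometry, tiny_frap_protocol)
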
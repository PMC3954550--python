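"""PICS: pair correlation, background correction, population fits, MSD fits."""

import math

import numpy as np
import pandas as pd
import pytest

from tfdyn import MotionModel, ImagingRegime, simulate_localizations
from tfdyn.pics import (
    PcumCurve,
    PicsAnalysis,
    PicsConfig,
    correlate,
    default_l2_grid,
    fit_populations,
    group_sem,
    msd_vs_lag,
    partition_cells,
    pair_squared_displacements,
    pcum_two_population,
    pooled_curves,
)


def brute_force_counts(table, lag_frames, l2_grid):
    """Independent oracle: all-pairs counting with explicit loops."""
    counts = np.zeros(len(l2_grid), dtype=int)
    n_ref = 0
    for (_, _), sub in table.groupby(["cell", "series"]):
        by_frame = {
            int(f): g[["x_um", "y_um"]].to_numpy() for f, g in sub.groupby("frame")
        }
        for t, a in by_frame.items():
            later = [f for f in by_frame if f > t + lag_frames]
            b = by_frame.get(t + lag_frames)
            if b is None and not later:
                continue
            n_ref += len(a)
            if b is None:
                continue
            for ax, ay in a:
                for bx, by in b:
                    d2 = (ax - bx) ** 2 + (ay - by) ** 2
                    counts += d2 <= l2_grid
    return counts, n_ref


def make_table(rows):
    return pd.DataFrame(rows, columns=["cell", "series", "frame", "x_um", "y_um"])


class TestCorrelate:
    def test_four_point_configuration(self):
        """Two molecules each moving ~0.1 µm: C(l²=0.04) = 1 per molecule."""
        table = make_table(
            [
                (0, 0, 0, 1.0, 1.0),
                (0, 0, 0, 8.0, 8.0),
                (0, 0, 1, 1.1, 1.0),
                (0, 0, 1, 8.0, 8.1),
            ]
        )
        grid = np.array([0.001, 0.04, 1.0])
        curve = correlate(table, 1, grid, min_pairs=1)
        assert curve.n_pairs == 2
        assert curve.raw_c[1] == pytest.approx(1.0)

    def test_matches_brute_force_exactly(self, small_table):
        """Vectorized pair counting equals the explicit double loop."""
        sub = small_table[small_table["cell"] < 2].reset_index(drop=True)
        grid = default_l2_grid()
        for lag in (1, 3):
            curve = correlate(sub, lag, grid, min_pairs=1)
            counts, n_ref = brute_force_counts(sub, lag, grid)
            np.testing.assert_array_equal(curve.raw_counts.astype(int), counts)
            assert curve.n_pairs == n_ref

    def test_pair_displacements_within_series_only(self):
        table = make_table(
            [(0, 0, 0, 1.0, 1.0), (0, 1, 1, 1.0, 1.0)]  # different series
        )
        d2, n_ref = pair_squared_displacements(table, 1)
        assert d2.size == 0 and n_ref == 0

    def test_empty_frames_flagged(self):
        table = make_table([(0, 0, 0, 1.0, 1.0)])
        curve = correlate(table, 1, np.array([0.01, 1.0, 2.0]))
        assert curve.flagged

    def test_shuffled_frames_have_no_correlated_plateau(self, rng):
        """Permutation oracle: uncorrelated uniform molecules leave nothing
        after background correction (plateau ~ 0)."""
        rows = []
        for series in range(300):
            for frame in range(2):
                for _ in range(rng.poisson(3) + 1):
                    rows.append(
                        (0, series, frame, rng.uniform(0, 11), rng.uniform(0, 11))
                    )
        table = make_table(rows)
        curve = correlate(table, 1, default_l2_grid(), min_pairs=10)
        assert curve.flagged or curve.plateau < 0.08

    def test_pcum_monotone_and_bounded(self, small_table):
        curves = pooled_curves({6.25e-3: small_table}, min_pairs=10)
        assert len(curves) >= 3
        for c in curves:
            if c.flagged:
                continue
            assert np.all(np.diff(c.pcum) >= 0)
            assert c.pcum.min() >= 0.0 and c.pcum.max() <= 1.0


class TestFitPopulations:
    def test_closed_form_value_and_exact_refit(self):
        """P_cum(0.01 | 0.55, 0.033, 0.002) = 0.591; refit recovers exactly."""
        alpha, m1, m2 = 0.55, 0.033, 0.002
        # independently computed closed form
        expected = 1.0 - (
            alpha * math.exp(-0.01 / m1) + (1 - alpha) * math.exp(-0.01 / m2)
        )
        assert pcum_two_population(np.array([0.01]), alpha, m1, m2)[
            0
        ] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.591, abs=5e-4)

        grid = default_l2_grid()
        curve = PcumCurve(
            lag=0.00625,
            l2_grid=grid,
            pcum=pcum_two_population(grid, alpha, m1, m2),
            n_pairs=10_000,
            raw_counts=np.zeros_like(grid),
            density_correction=0.0,
            plateau=1.0,
        )
        fit = fit_populations(curve, order=2)
        assert fit.alpha == pytest.approx(alpha, abs=1e-6)
        assert fit.msd_fast == pytest.approx(m1, abs=1e-6)
        assert fit.msd_slow == pytest.approx(m2, abs=1e-6)
        assert fit.residual_norm < 1e-8

    def test_single_population_identity(self):
        """1 - 1/e at l² = MSD for a single population, and the order-2 fit
        degenerates gracefully on one-population data."""
        msd = 0.05
        grid = default_l2_grid()
        pcum = 1.0 - np.exp(-grid / msd)
        assert np.interp(msd, grid, pcum) == pytest.approx(1 - 1 / math.e, abs=1e-3)
        curve = PcumCurve(0.00625, grid, pcum, 1000, np.zeros_like(grid), 0.0, 1.0)
        fit2 = fit_populations(curve, order=2)
        # either alpha -> 1 or both MSDs agree
        assert fit2.alpha > 0.99 or fit2.msd_fast == pytest.approx(
            fit2.msd_slow, rel=0.05
        )

    def test_nested_model_residuals(self, small_table):
        """The two-population fit never fits worse than one population."""
        curves = [
            c
            for c in pooled_curves({6.25e-3: small_table}, min_pairs=10)
            if not c.flagged
        ]
        for curve in curves:
            r1 = fit_populations(curve, order=1).residual_norm
            r2 = fit_populations(curve, order=2).residual_norm
            assert r2 <= r1 + 1e-12

    def test_invalid_order(self, small_table):
        curve = pooled_curves({6.25e-3: small_table}, min_pairs=10)[0]
        with pytest.raises(ValueError):
            fit_populations(curve, order=4)


class TestMsdVsLag:
    def test_exact_linear_input(self):
        """MSD = 4·1.31·dt + 0.0064 exactly -> D = 1.31, intercept 0.0064."""
        lags = np.array([6.25e-3, 12.5e-3, 25e-3, 37.5e-3])
        from tfdyn.pics import TwoPopFit

        fits = [
            TwoPopFit(0.5, 4 * 1.31 * t + 0.0064, 4 * 0.03 * t + 0.0064, 0.0, 2, t)
            for t in lags
        ]
        fast, slow, alpha, _ = msd_vs_lag(fits, lags)
        assert fast.d == pytest.approx(1.31, abs=1e-9)
        assert fast.intercept == pytest.approx(0.0064, abs=1e-9)
        assert slow.d == pytest.approx(0.03, abs=1e-9)
        assert alpha == pytest.approx(0.5)

    def test_constant_msd_gives_zero_d(self):
        lags = np.array([6.25e-3, 12.5e-3, 25e-3])
        from tfdyn.pics import TwoPopFit

        fits = [TwoPopFit(0.5, 0.02, 0.02, 0.0, 2, t) for t in lags]
        fast, slow, *_ = msd_vs_lag(fits, lags)
        assert fast.d == pytest.approx(0.0, abs=1e-12)
        assert slow.d == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_clipped_and_flagged(self):
        lags = np.array([1e-3, 2e-3, 3e-3])
        from tfdyn.pics import TwoPopFit

        fits = [TwoPopFit(0.5, 0.03 - 5 * t, 0.01, 0.0, 2, t) for t in lags]
        fast, *_ = msd_vs_lag(fits, lags)
        assert fast.d == 0.0 and fast.flagged

    def test_too_few_lags(self):
        from tfdyn.pics import TwoPopFit

        fits = [TwoPopFit(0.5, 0.1, 0.01, 0.0, 2, t) for t in (1e-3, 2e-3)]
        with pytest.raises(ValueError):
            msd_vs_lag(fits, [1e-3, 2e-3])


class TestGroupSem:
    def test_partition_sizes_20_cells(self):
        groups = partition_cells(np.arange(20), 3)
        assert sorted(len(g) for g in groups) == [6, 7, 7]

    def test_sem_arithmetic(self):
        """Group estimates {1.2, 1.3, 1.4} -> SEM = 0.0577."""
        vals = np.array([1.2, 1.3, 1.4])
        sem = vals.std(ddof=1) / math.sqrt(3)
        assert sem == pytest.approx(0.05774, abs=1e-4)
        calls = iter(vals)

        def analysis(tables):
            return {"x": float(next(calls))}

        table = make_table(
            [(c, 0, 0, 1.0, 1.0) for c in range(6)]
        )
        sems, _ = group_sem({6.25e-3: table}, analysis, n_groups=3)
        assert sems["x"] == pytest.approx(sem, abs=1e-9)

    def test_identical_groups_zero_sem(self):
        def analysis(tables):
            return {"x": 0.3}

        table = make_table([(c, 0, 0, 1.0, 1.0) for c in range(6)])
        sems, _ = group_sem({6.25e-3: table}, analysis, n_groups=3)
        assert sems["x"] == 0.0

    def test_failed_group_marked_unavailable(self):
        state = {"n": 0}

        def analysis(tables):
            state["n"] += 1
            if state["n"] > 1:
                raise ValueError("no usable curves")
            return {"x": 1.0}

        table = make_table([(c, 0, 0, 1.0, 1.0) for c in range(6)])
        sems, _ = group_sem({6.25e-3: table}, analysis, n_groups=3)
        assert math.isnan(sems["x"])


def test_full_analysis_recovers_two_population_structure(agonist_model):
    """Moderate-scale end-to-end PICS run: fractions and D in the right
    neighbourhood (tight recovery is covered by the acceptance suite)."""
    regime = ImagingRegime(series_per_cell=120, n_cells=9, rng_seed=21)
    table = simulate_localizations(agonist_model, regime)
    res = PicsAnalysis({regime.frame_lag: table}).fit(n_groups=3)
    assert 0.40 < res.alpha < 0.70
    assert 0.9 < res.fast.d < 1.7
    assert res.slow.d < 0.12
    assert "diffusing fraction" in res.summary()
    d = res.to_dict()
    assert set(d) >= {"diffusing_fraction_pct", "d_fast_um2_s", "per_lag"}
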
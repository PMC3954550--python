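"""FRAP grid search: scoring, ranking, averaging, sensitivity analysis."""

import math
from dataclasses import replace

import numpy as np
import pytest

from tfdyn import (
    FrapCurve,
    FrapGridSearch,
    FrapProtocol,
    MotionModel,
    NucleusGeometry,
    SearchSpace,
    sensitivity_dfast,
    simulate_frap,
)
from tfdyn.frapfit import candidate_model, score

TINY_SPACE = SearchSpace(n_fraction=3, n_tau_short=2, n_tau_long=2, refine_passes=0)


def flat_target(value=1.0, n=550):
    t = np.arange(1, n + 1) * 0.1
    return FrapCurve(
        time=t,
        intensity=np.full(n, float(value)),
        phase=np.full(n, "recovery", dtype=object),
    )


@pytest.fixture(scope="module")
def small_target(agonist_model, geometry):
    m = MotionModel(0.44, 0.33, 0.23, 1.31, 0.0, 0.7, 2.3)
    proto = FrapProtocol(
        n_prescans=5, recovery_duration=20.0, n_cells=6, n_particles=5000,
        sim_timestep=0.1, rng_seed=31,
    )
    return simulate_frap(m, geometry, proto), proto


class TestSearchSpace:
    def test_bounds_are_the_stated_ones(self):
        s = SearchSpace()
        cand = s.base_candidates()
        assert cand[:, 0].max() <= 0.90 and cand[:, 1].max() <= 0.90
        assert np.all(cand[:, 0] + cand[:, 1] <= 0.90 + 1e-9)
        assert cand[:, 2].min() == pytest.approx(0.1)
        assert cand[:, 2].max() == pytest.approx(1.0)
        assert cand[:, 3].min() == pytest.approx(1.0)
        assert cand[:, 3].max() == pytest.approx(300.0)

    def test_tau_long_sampled_logarithmically(self):
        v = SearchSpace(n_tau_long=8).tau_long_values()
        ratios = v[1:] / v[:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_local_candidates_respect_bounds(self):
        s = SearchSpace()
        local = s.local_candidates(np.array([0.9, 0.0, 0.1, 1.0]))
        assert np.all(local[:, 0] + local[:, 1] <= 0.90 + 1e-9)
        assert local[:, 2].min() >= 0.1 and local[:, 3].min() >= 1.0


class TestScore:
    def test_identical_candidate_zero_sse(self, geometry):
        """Scoring the generator of the target with its own seed gives 0."""
        m = MotionModel(0.5, 0.3, 0.2, 1.31, 0.0, 0.7, 2.3)
        proto = FrapProtocol(
            n_prescans=5, recovery_duration=5.0, n_cells=1, n_particles=1000,
            sim_timestep=0.1, rng_seed=13,
        )
        target = simulate_frap(m, geometry, proto)
        assert score(m, target, geometry, proto) == 0.0

    def test_flat_zero_candidate_vs_unit_target(self, geometry):
        """A fully bleached immobile candidate against a target == 1 over
        550 samples scores exactly 550."""
        m = MotionModel(0.0, 0.0, 1.0, 1.31, 0.0, tau_long=math.inf)
        proto = FrapProtocol(
            n_prescans=0, recovery_duration=55.0, n_cells=1, n_particles=500,
            sim_timestep=0.1, bleach_survival=0.0, rng_seed=1,
        )
        sse = score(m, flat_target(1.0), geometry, proto)
        assert sse == pytest.approx(550.0, abs=1e-9)

    def test_tau_long_discrimination(self, small_target, geometry):
        """A fast-recovering target prefers tau_long = 2 s over 200 s."""
        target, proto = small_target
        cp = replace(proto, n_particles=20_000, n_cells=1, n_prescans=0, rng_seed=91)
        s2 = score(candidate_model(0.33, 0.23, 0.7, 2.0, 1.31), target, geometry, cp)
        s200 = score(candidate_model(0.33, 0.23, 0.7, 200.0, 1.31), target, geometry, cp)
        assert s2 < s200

    def test_disjoint_time_grids_rejected(self, geometry):
        target = flat_target(n=10)  # 1 s of recovery only
        m = MotionModel(1.0, 0.0, 0.0, 1.31)
        proto = FrapProtocol(
            n_prescans=0, recovery_duration=55.0, n_cells=1, n_particles=100,
            sim_timestep=0.1, rng_seed=1,
        )
        with pytest.raises(ValueError, match="time grids"):
            score(m, target, geometry, proto)


class TestFit:
    def test_ranking_deterministic_and_consistent(self, small_target, geometry):
        target, proto = small_target
        kw = dict(
            candidate_particles=600, final_particles=1500, stage2_pool=12,
            polish_pool=4, seed=17,
        )
        r1 = FrapGridSearch(target, 1.31, geometry, proto, TINY_SPACE, **kw).fit()
        r2 = FrapGridSearch(target, 1.31, geometry, proto, TINY_SPACE, **kw).fit()
        assert r1.ranked.equals(r2.ranked)
        assert np.all(np.diff(r1.ranked["sse"].to_numpy()) >= 0)  # total order
        # top-n averaging identities
        for c in ["fraction_free", "fraction_short", "tau_long"]:
            assert r1.params[c] == pytest.approx(float(r1.top[c].mean()))
            assert r1.sems[c] == pytest.approx(
                float(r1.top[c].std(ddof=1) / math.sqrt(len(r1.top)))
            )
        assert r1.n_averaged == min(10, len(r1.ranked))

    def test_widening_space_never_increases_best_sse(self, small_target, geometry):
        """With nested grids and every candidate scored at final fidelity,
        the wider space's best SSE cannot be worse."""
        target, proto = small_target
        narrow = SearchSpace(n_fraction=3, n_tau_short=2, n_tau_long=2, refine_passes=0)
        wide = SearchSpace(n_fraction=5, n_tau_short=3, n_tau_long=3, refine_passes=0)
        # n=5 fraction grid contains the n=3 one; same for the tau grids
        assert set(np.round(narrow.fraction_values(), 9)) <= set(
            np.round(wide.fraction_values(), 9)
        )
        kw = dict(
            candidate_particles=500, final_particles=500, stage2_pool=10_000,
            polish_pool=1, seed=23,
        )
        best_narrow = FrapGridSearch(target, 1.31, geometry, proto, narrow, **kw).fit()
        best_wide = FrapGridSearch(target, 1.31, geometry, proto, wide, **kw).fit()
        assert best_wide.best_sse <= best_narrow.best_sse + 1e-12

    def test_degenerate_target_rejected(self, geometry):
        with pytest.raises(ValueError, match="degenerate"):
            FrapGridSearch(flat_target(1.0), 1.31, geometry)

    def test_nonpositive_d_rejected(self, geometry):
        with pytest.raises(ValueError):
            FrapGridSearch(flat_target(0.5), 0.0, geometry)

    def test_summary_and_serialization(self, small_target, geometry):
        target, proto = small_target
        res = FrapGridSearch(
            target, 1.31, geometry, proto, TINY_SPACE,
            candidate_particles=500, final_particles=800, stage2_pool=8,
            polish_pool=2, seed=3,
        ).fit()
        s = res.summary()
        assert "diffusing fraction" in s and "tau" in s
        d = res.to_dict()
        assert set(d["params"]) == {
            "fraction_free", "fraction_short", "fraction_long",
            "tau_short", "tau_long",
        }
        assert len(res.fitted_curve.recovery.intensity) == len(
            res.target.recovery.intensity
        )


class TestSensitivity:
    def test_identical_d_values_identical_results(self, small_target, geometry):
        target, proto = small_target
        results, spread = sensitivity_dfast(
            target, (1.31, 1.31, 1.31), geometry, proto, TINY_SPACE,
            candidate_particles=400, final_particles=400, stage2_pool=6,
            polish_pool=2, seed=5,
        )
        assert len(results) == 3
        for c, v in spread.items():
            assert v == 0.0

    def test_zero_d_rejected(self, small_target, geometry):
        target, proto = small_target
        with pytest.raises(ValueError):
            sensitivity_dfast(target, (0.0, 1.31, 1.44), geometry, proto)
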
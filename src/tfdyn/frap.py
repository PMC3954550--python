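"""Kinetic Monte Carlo simulation of strip-FRAP in an ellipsoidal nucleus.

Particles populate an ellipsoid uniformly and follow the three-population
model: a freely diffusing state taking Gaussian 3D steps (variance 2·D·dt
per axis, reflecting boundary) and two strictly immobile bound states with
exponential residence times.  A narrow strip through the centre, spanning
the full nucleus cross-section, is both the bleach and the detection
region.  During the bleach window fluorescent particles inside the strip
are bleached per sub-step, so molecules moving through the strip receive a
dose proportional to their residence.  The observable is the fluorescent
count inside the strip normalized to its pre-bleach mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .kinetics import FREE, MotionModel, rates_from_fractions


@dataclass(frozen=True)
class NucleusGeometry:
    """Ellipsoidal nucleus with a central bleach/detection strip.

    The strip is a slab |x| <= strip_width/2 oriented normal to the longest
    semi-axis, spanning the full cross-section of the nucleus.
    """

    a: float = 6.0  # µm, semi-axis along the strip normal
    b: float = 4.0  # µm
    c: float = 2.5  # µm
    strip_width: float = 1.0  # µm

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("semi-axes must be positive")
        if not 0 < self.strip_width < 2 * self.a:
            raise ValueError("strip_width must lie in (0, 2a)")

    def strip_volume_fraction(self) -> float:
        """Exact fraction of the ellipsoid volume inside the strip."""
        h = min(self.strip_width / 2.0, self.a) / self.a
        # integral of the elliptic cross-section over |x| <= h·a
        return (3.0 * h - h**3) / 2.0


@dataclass(frozen=True)
class FrapProtocol:
    """Timing, bleach depth and replication of the strip-FRAP experiment.

    ``bleach_survival`` is the probability that a fluorophore resident in
    the strip for the whole bleach window stays fluorescent.  The default is
    calibrated so that, for the reference agonist-bound receptor condition,
    the first recovery sample lands at ~30% of baseline (molecules moving
    through the strip receive only a partial dose, so the full-residence
    survival is lower than the observed depth).
    """

    n_prescans: int = 40
    scan_interval: float = 0.1  # s
    bleach_duration: float = 0.1  # s
    recovery_duration: float = 55.0  # s
    bleach_survival: float = 0.16
    n_cells: int = 30
    n_particles: int = 20_000  # per replicate cell
    sim_timestep: float = 0.05  # s
    n_bleach_substeps: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_timestep <= 0 or self.sim_timestep > self.scan_interval + 1e-12:
            raise ValueError("sim_timestep must be positive and <= scan_interval")
        if not 0.0 <= self.bleach_survival <= 1.0:
            raise ValueError("bleach_survival must be a probability")
        if self.n_particles <= 0 or self.n_cells <= 0:
            raise ValueError("particle and cell counts must be positive")

    @property
    def steps_per_scan(self) -> int:
        n = round(self.scan_interval / self.sim_timestep)
        if abs(n * self.sim_timestep - self.scan_interval) > 1e-9:
            raise ValueError("scan_interval must be a multiple of sim_timestep")
        return int(n)

    @property
    def n_recovery(self) -> int:
        return int(round(self.recovery_duration / self.scan_interval))


@dataclass
class FrapCurve:
    """Normalized strip fluorescence versus time (t = 0 at bleach end)."""

    time: np.ndarray  # s
    intensity: np.ndarray  # / pre-bleach baseline
    phase: np.ndarray  # 'pre' | 'recovery'
    total_fluorescent: np.ndarray | None = None  # diagnostic, per sample
    n_particles: int = 0

    @property
    def recovery(self) -> "FrapCurve":
        m = self.phase == "recovery"
        return FrapCurve(
            self.time[m],
            self.intensity[m],
            self.phase[m],
            None if self.total_fluorescent is None else self.total_fluorescent[m],
            self.n_particles,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "intensity": self.intensity, "phase": self.phase}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FrapCurve":
        return cls(
            time=df["time_s"].to_numpy(dtype=float),
            intensity=df["intensity"].to_numpy(dtype=float),
            phase=df["phase"].to_numpy(dtype=object)
            if "phase" in df
            else np.where(df["time_s"].to_numpy() < 0, "pre", "recovery"),
        )

    @classmethod
    def read_csv(cls, path) -> "FrapCurve":
        return cls.from_frame(pd.read_csv(path))

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, self.intensity, **kwargs)
        ax.set_xlabel("time after bleach (s)")
        ax.set_ylabel("normalized strip intensity")
        return ax


def _sample_ellipsoid(
    rng: np.random.Generator, n: int, geom: NucleusGeometry
) -> np.ndarray:
    """Uniform points in the ellipsoid by rejection from the bounding box."""
    out = np.empty((n, 3))
    filled = 0
    axes = np.array([geom.a, geom.b, geom.c])
    while filled < n:
        m = int(1.91 * (n - filled)) + 16  # 1/volume-ratio ≈ π/6
        cand = rng.uniform(-1.0, 1.0, (m, 3))
        keep = (cand**2).sum(axis=1) <= 1.0
        take = cand[keep][: n - filled]
        out[filled : filled + take.shape[0]] = take * axes
        filled += take.shape[0]
    return out


def _outside(pos: np.ndarray, geom: NucleusGeometry) -> np.ndarray:
    u = pos / np.array([geom.a, geom.b, geom.c])
    return (u * u).sum(axis=-1) > 1.0


def _switch_probabilities(rates, dt: float) -> tuple[float, float, float, float]:
    """Per-step switching probabilities, 1 − exp(−k·dt).

    The free-state exit channels share one uniform draw, so their
    probabilities are split proportionally to the rates.
    """
    k_out = rates.k_free_short + rates.k_free_long
    p_out = -np.expm1(-k_out * dt)
    if np.ndim(k_out) == 0 and k_out == 0:
        p_fs = p_fl = 0.0
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(k_out > 0, rates.k_free_short / np.maximum(k_out, 1e-300), 0.0)
        p_fs = p_out * share
        p_fl = p_out - p_fs
    p_sf = -np.expm1(-rates.k_short_free * dt)
    p_lf = -np.expm1(-rates.k_long_free * dt)
    return p_fs, p_fl, p_sf, p_lf


class _Ensemble:
    """Mutable particle state shared by the simulation phases."""

    def __init__(
        self,
        model: MotionModel,
        geom: NucleusGeometry,
        n: int,
        rng: np.random.Generator,
    ) -> None:
        self.geom = geom
        # float32 positions: micron-scale coordinates need ~1e-3 µm at most
        self.pos = _sample_ellipsoid(rng, n, geom).astype(np.float32)
        self.states = rng.choice(3, size=n, p=model.fractions).astype(np.int8)
        self.fluor = np.ones(n, dtype=bool)
        rates = rates_from_fractions(model)
        self.k = rates
        self.d_free = model.d_free
        self.rng = rng

    def step(self, dt: float) -> None:
        rng, n = self.rng, self.pos.shape[0]
        # state transitions (one uniform per particle; exact exponential
        # switching probabilities per state)
        u = rng.random(n)
        s = self.states
        free = s == FREE
        p_fs, p_fl, p_sf, p_lf = _switch_probabilities(self.k, dt)
        to_short = free & (u < p_fs)
        to_long = free & (u >= p_fs) & (u < p_fs + p_fl)
        from_short = (s == 1) & (u < p_sf)
        from_long = (s == 2) & (u < p_lf)
        # displacement uses the state at the start of the step; steps that
        # would exit the nucleus are rejected (symmetric proposal with a
        # uniform target, so the uniform stationary density is preserved
        # exactly — a zero-flux boundary without reflection geometry)
        sigma = math.sqrt(2.0 * self.d_free * dt)
        steps = rng.standard_normal((n, 3)).astype(np.float32)
        steps *= np.where(free, np.float32(sigma), np.float32(0.0))[:, None]
        newpos = self.pos + steps
        bad = _outside(newpos, self.geom)
        newpos[bad] = self.pos[bad]
        self.pos = newpos
        s[to_short] = 1
        s[to_long] = 2
        s[from_short | from_long] = FREE

    def in_strip(self) -> np.ndarray:
        return np.abs(self.pos[:, 0]) <= self.geom.strip_width / 2.0

    def strip_fluor_count(self) -> int:
        return int(np.count_nonzero(self.fluor & self.in_strip()))


def simulate_frap(
    model: MotionModel,
    geom: NucleusGeometry | None = None,
    proto: FrapProtocol | None = None,
    rng: np.random.Generator | None = None,
    *,
    with_diagnostics: bool = True,
    baseline: str = "auto",
) -> FrapCurve:
    """Simulate the averaged strip-FRAP experiment for one condition.

    Replicate cells are pooled into one ensemble of
    ``n_particles * n_cells`` particles (cells are independent and
    identically distributed, so pooled counting equals averaging replicate
    curves).  Deterministic under the protocol seed.  The random-number
    consumption per step is independent of the model parameters, so two
    simulations from the same seed are driven by common random numbers —
    which makes least-squares comparisons between candidate parameter sets
    low-variance.

    ``baseline`` selects the normalization: ``"simulated"`` uses the mean of
    the pre-bleach scans (the experimental procedure), ``"expected"`` uses
    the exact expectation ``n_particles_total * strip volume fraction``
    (noise-free; used for candidate curves during fitting), and ``"auto"``
    picks "expected" when there are no pre-bleach scans.
    """
    geom = geom or NucleusGeometry()
    proto = proto or FrapProtocol()
    rates = rates_from_fractions(model)  # validates simulability
    del rates
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(proto.rng_seed))

    n = proto.n_particles * proto.n_cells
    ens = _Ensemble(model, geom, n, rng)
    dt = proto.sim_timestep
    spscan = proto.steps_per_scan

    times, intens, phases, totals = [], [], [], []

    # --- pre-bleach scans (stationary dynamics, all fluorescent)
    pre_counts = []
    for i in range(proto.n_prescans):
        t = -proto.bleach_duration - (proto.n_prescans - 1 - i) * proto.scan_interval
        pre_counts.append(ens.strip_fluor_count())
        times.append(t)
        phases.append("pre")
        totals.append(int(ens.fluor.sum()))
        if i < proto.n_prescans - 1:
            for _ in range(spscan):
                ens.step(dt)
    if baseline == "auto":
        baseline = "simulated" if pre_counts else "expected"
    if baseline == "simulated":
        if not pre_counts:
            raise ValueError("simulated baseline requires pre-bleach scans")
        baseline_value = float(np.mean(pre_counts))
    elif baseline == "expected":
        baseline_value = n * geom.strip_volume_fraction()
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")

    # --- bleach window: move + bleach per sub-step
    nsub = max(proto.n_bleach_substeps, 1)
    dt_b = proto.bleach_duration / nsub
    survive_sub = proto.bleach_survival ** (1.0 / nsub)
    for _ in range(nsub):
        ens.step(dt_b)
        u = rng.random(n)
        hit = ens.in_strip() & ens.fluor & (u >= survive_sub)
        ens.fluor[hit] = False

    # --- recovery
    rec_counts = np.empty(proto.n_recovery, dtype=float)
    for j in range(proto.n_recovery):
        for _ in range(spscan):
            ens.step(dt)
        rec_counts[j] = ens.strip_fluor_count()
        times.append((j + 1) * proto.scan_interval)
        phases.append("recovery")
        totals.append(int(ens.fluor.sum()))
    intens = (
        np.concatenate([np.asarray(pre_counts, float), rec_counts]) / baseline_value
    )

    return FrapCurve(
        time=np.asarray(times),
        intensity=intens,
        phase=np.asarray(phases, dtype=object),
        total_fluorescent=np.asarray(totals) if with_diagnostics else None,
        n_particles=n,
    )


def simulate_candidate_curves(
    models: list[MotionModel],
    geom: NucleusGeometry,
    proto: FrapProtocol,
    *,
    return_variance: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Recovery curves for a batch of candidate models, common random numbers.

    All candidates must share ``d_free`` (it is a fixed parameter of the
    grid search).  One set of random draws — initial positions, step
    proposals and switching uniforms — is shared by every candidate, so
    differences between the returned curves are purely parameter-driven.
    Bleaching is Rao-Blackwellized (particles carry survival probabilities
    rather than sampled flags) and no pre-bleach scans are simulated;
    curves are normalized by the exact expected baseline (particle count
    times strip volume fraction).  Returns (n_candidates, n_recovery).

    With ``return_variance=True`` an unbiased estimate of the per-sample
    Monte Carlo variance of each curve is returned alongside, computed from
    the between-subgroup scatter of 8 equal particle subgroups.  The
    variance of a curve depends on its own parameters — deeply bleached
    (high-bound) candidates are intrinsically less noisy — so least-squares
    comparisons between candidates must subtract it to be unbiased.
    """
    if not models:
        return np.empty((0, proto.n_recovery))
    d_free = models[0].d_free
    if any(abs(m.d_free - d_free) > 1e-12 for m in models):
        raise ValueError("batched candidates must share d_free")
    k_count = len(models)
    n = proto.n_particles * proto.n_cells
    rng = np.random.default_rng(np.random.SeedSequence(proto.rng_seed))
    half_w = geom.strip_width / 2.0

    pos0 = _sample_ellipsoid(rng, n, geom)
    u0 = rng.random(n)
    fractions = np.array([m.fractions for m in models])  # (K, 3)
    cum = fractions.cumsum(axis=1)
    states = (u0[None, :] >= cum[:, 0:1]).astype(np.int8)
    states += u0[None, :] >= cum[:, 1:2]
    # float32 positions: localization at strip scale needs ~1e-3 µm at most
    pos = np.repeat(pos0[None, :, :].astype(np.float32), k_count, axis=0)
    # Rao-Blackwellized fluorescence: each particle carries its survival
    # probability (product of per-sub-step strip doses) instead of a
    # sampled fluorescent/bleached flag — identical expectation, but the
    # bleach-sampling noise is integrated out analytically
    fluor = np.ones((k_count, n))
    inv_axes = (1.0 / np.array([geom.a, geom.b, geom.c])).astype(np.float32)
    newpos = np.empty_like(pos)
    r2 = np.empty((k_count, n), dtype=np.float32)

    rate_list = [rates_from_fractions(m) for m in models]

    class _Rates:
        k_free_short = np.array([r.k_free_short for r in rate_list])[:, None]
        k_free_long = np.array([r.k_free_long for r in rate_list])[:, None]
        k_short_free = np.array([r.k_short_free for r in rate_list])[:, None]
        k_long_free = np.array([r.k_long_free for r in rate_list])[:, None]

    probs_cache: dict[float, tuple] = {}

    def step(dt: float) -> None:
        u = rng.random(n)[None, :]
        z = (rng.standard_normal((n, 3)) * math.sqrt(2.0 * d_free * dt)).astype(
            np.float32
        )
        free = states == FREE
        np.multiply(free[:, :, None], z[None, :, :], out=newpos)
        np.add(newpos, pos, out=newpos)
        np.square(newpos[:, :, 0] * inv_axes[0], out=r2)
        np.add(r2, np.square(newpos[:, :, 1] * inv_axes[1]), out=r2)
        np.add(r2, np.square(newpos[:, :, 2] * inv_axes[2]), out=r2)
        ok = r2 <= 1.0
        np.copyto(pos, newpos, where=ok[:, :, None])
        if dt not in probs_cache:
            probs_cache[dt] = _switch_probabilities(_Rates, dt)
        p_fs, p_fl, p_sf, p_lf = probs_cache[dt]
        to_short = free & (u < p_fs)
        to_long = free & (u >= p_fs) & (u < p_fs + p_fl)
        from_short = (states == 1) & (u < p_sf)
        from_long = (states == 2) & (u < p_lf)
        states[to_short] = 1
        states[to_long] = 2
        states[from_short | from_long] = FREE

    # bleach window
    nsub = max(proto.n_bleach_substeps, 1)
    survive_sub = proto.bleach_survival ** (1.0 / nsub)
    for _ in range(nsub):
        step(proto.bleach_duration / nsub)
        in_strip = np.abs(pos[:, :, 0]) <= half_w
        fluor[in_strip] *= survive_sub

    baseline = n * geom.strip_volume_fraction()
    out = np.empty((k_count, proto.n_recovery))
    var = np.empty((k_count, proto.n_recovery)) if return_variance else None
    n_groups = 8
    m = (n // n_groups) * n_groups
    group_baseline = baseline * (m / n_groups) / n
    for j in range(proto.n_recovery):
        for _ in range(proto.steps_per_scan):
            step(proto.sim_timestep)
        in_strip = np.abs(pos[:, :, 0]) <= half_w
        weights = np.where(in_strip, fluor, 0.0)
        out[:, j] = weights.sum(axis=1) / baseline
        if var is not None:
            # between-subgroup scatter of independent particle subgroups
            per_group = (
                weights[:, :m].reshape(k_count, n_groups, -1).sum(axis=2)
                / group_baseline
            )
            var[:, j] = per_group.var(axis=1, ddof=1) / n_groups
    if return_variance:
        return out, var
    return out


def reduced_protocol(
    proto: FrapProtocol,
    *,
    n_particles: int | None = None,
    n_cells: int = 1,
    n_prescans: int = 5,
) -> FrapProtocol:
    """Light-weight variant of a protocol for candidate-curve simulation."""
    return replace(
        proto,
        n_particles=n_particles or proto.n_particles,
        n_cells=n_cells,
        n_prescans=n_prescans,
    )
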
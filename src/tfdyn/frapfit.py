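"""Fitting FRAP curves by searching the three-population parameter space.

The model curve for a candidate parameter set (short/long bound fraction,
short/long residence time; the free diffusion coefficient is fixed at the
value measured by single-molecule analysis) is generated by the Monte Carlo
simulator and compared to the target curve by ordinary least squares over
the recovery phase.  Candidates come from a bounded grid — fractions 0–90%
(sum ≤ 90%), tau_short 0.1–1 s linear, tau_long 1–300 s logarithmic —
augmented by common-random-number pattern descents that walk the
least-squares valley off-grid.  The parameters of the ten best-fitting
curves are averaged (± SEM) to represent the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frap import (
    FrapCurve,
    FrapProtocol,
    NucleusGeometry,
    reduced_protocol,
    simulate_candidate_curves,
    simulate_frap,
)
from .kinetics import MotionModel

PARAM_COLUMNS = ["fraction_short", "fraction_long", "tau_short", "tau_long"]


@dataclass(frozen=True)
class SearchSpace:
    """Bounded sampling plan of the four free FRAP parameters."""

    fraction_max: float = 0.90
    n_fraction: int = 10
    tau_short_bounds: tuple[float, float] = (0.1, 1.0)
    n_tau_short: int = 5
    tau_long_bounds: tuple[float, float] = (1.0, 300.0)
    n_tau_long: int = 8
    refine_passes: int = 1  # 0 = pure pre-simulated library mode
    refine_factor: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.fraction_max <= 0.90:
            raise ValueError("fraction bounds are 0-90%")
        if self.tau_short_bounds != (0.1, 1.0) or self.tau_long_bounds != (1.0, 300.0):
            # other windows are allowed but must stay ordered and positive
            ts, tl = self.tau_short_bounds, self.tau_long_bounds
            if not (0 < ts[0] < ts[1] <= tl[0] < tl[1]):
                raise ValueError("residence-time bounds must be ordered")

    def fraction_values(self) -> np.ndarray:
        return np.linspace(0.0, self.fraction_max, self.n_fraction)

    def tau_short_values(self) -> np.ndarray:
        return np.linspace(*self.tau_short_bounds, self.n_tau_short)

    def tau_long_values(self) -> np.ndarray:
        return np.geomspace(*self.tau_long_bounds, self.n_tau_long)

    def base_candidates(self) -> np.ndarray:
        """All (f_short, f_long, tau_short, tau_long) grid points."""
        fs, fl, ts, tl = np.meshgrid(
            self.fraction_values(),
            self.fraction_values(),
            self.tau_short_values(),
            self.tau_long_values(),
            indexing="ij",
        )
        cand = np.column_stack([v.ravel() for v in (fs, fl, ts, tl)])
        return cand[cand[:, 0] + cand[:, 1] <= self.fraction_max + 1e-12]

    def local_candidates(self, center: np.ndarray) -> np.ndarray:
        """Refinement grid around ``center`` at ``refine_factor``x finer spacing."""
        k = self.refine_factor
        offsets = np.array([-2, -1, 0, 1, 2]) / k

        def around(values: np.ndarray, x: float, log: bool = False) -> np.ndarray:
            v = np.log(values) if log else values
            step = (v[-1] - v[0]) / (len(v) - 1)
            c = math.log(x) if log else x
            out = c + offsets * step
            out = np.clip(out, v[0], v[-1])
            return np.exp(out) if log else out

        fs = around(self.fraction_values(), center[0])
        fl = around(self.fraction_values(), center[1])
        ts = around(self.tau_short_values(), center[2])
        tl = around(self.tau_long_values(), center[3], log=True)
        g = np.meshgrid(fs, fl, ts, tl, indexing="ij")
        cand = np.column_stack([v.ravel() for v in g])
        cand = cand[cand[:, 0] + cand[:, 1] <= self.fraction_max + 1e-12]
        return np.unique(np.round(cand, 9), axis=0)


def candidate_model(
    f_short: float, f_long: float, tau_short: float, tau_long: float, d_free: float
) -> MotionModel:
    """Three-population model for one candidate (bound states immobile)."""
    return MotionModel(
        fraction_free=max(1.0 - f_short - f_long, 0.0),
        fraction_short=f_short,
        fraction_long=f_long,
        d_free=d_free,
        d_bound=0.0,
        tau_short=tau_short,
        tau_long=tau_long,
    )


def score(
    model: MotionModel,
    target: FrapCurve,
    geom: NucleusGeometry,
    proto: FrapProtocol,
    *,
    return_curve: bool = False,
):
    """Sum of squared differences to the target over the recovery phase.

    The candidate simulation uses the fixed protocol seed (common random
    numbers across candidates).  The target is resampled onto the simulated
    time grid by linear interpolation; a mismatch beyond the simulated time
    span raises.
    """
    sim = simulate_frap(model, geom, proto, with_diagnostics=False)
    sim_rec = sim.recovery
    tgt_rec = target.recovery
    if tgt_rec.time.size == 0:
        raise ValueError("target curve has no recovery samples")
    if (
        sim_rec.time[0] < tgt_rec.time[0] - proto.scan_interval / 2
        or sim_rec.time[-1] > tgt_rec.time[-1] + proto.scan_interval / 2
    ):
        raise ValueError("target and simulated time grids do not overlap")
    tgt = np.interp(sim_rec.time, tgt_rec.time, tgt_rec.intensity)
    sse = float(np.sum((sim_rec.intensity - tgt) ** 2))
    if return_curve:
        return sse, sim
    return sse


@dataclass
class FrapFitResults:
    """Ranked grid-search result with top-10 averages and the fitted curve."""

    ranked: pd.DataFrame  # candidates sorted by SSE (ascending); the SSE is
    # corrected for each candidate's own Monte Carlo variance and can dip
    # slightly below zero at the noise floor
    top: pd.DataFrame  # the averaged best candidates (normally 10)
    params: dict  # top-10 means
    sems: dict  # top-10 SEMs (SD/sqrt(n))
    fitted_curve: FrapCurve  # mean of the top candidate curves
    target: FrapCurve
    d_free: float
    n_averaged: int
    flagged_short_search: bool  # fewer than 10 candidates were available

    @property
    def best_sse(self) -> float:
        return float(self.ranked["sse"].iloc[0])

    @property
    def fraction_free(self) -> float:
        return self.params["fraction_free"]

    @property
    def bound_fraction(self) -> float:
        return self.params["fraction_short"] + self.params["fraction_long"]

    def residuals(self) -> np.ndarray:
        tgt = np.interp(
            self.fitted_curve.recovery.time,
            self.target.recovery.time,
            self.target.recovery.intensity,
        )
        return self.fitted_curve.recovery.intensity - tgt

    def to_dict(self) -> dict:
        return {
            "d_free_um2_s": self.d_free,
            "n_averaged": self.n_averaged,
            "best_sse": self.best_sse,
            "params": dict(self.params),
            "sems": dict(self.sems),
            "top": self.top.to_dict(orient="list"),
        }

    def summary(self) -> str:
        p, s = self.params, self.sems
        lines = [
            "FRAP three-population grid-search fit "
            f"(top {self.n_averaged} average, D_free = {self.d_free:.2f} um^2/s)",
            "-" * 66,
            f"diffusing fraction : {100 * p['fraction_free']:6.1f} "
            f"+/- {100 * s['fraction_free']:.1f} %",
            f"short bound        : {100 * p['fraction_short']:6.1f} "
            f"+/- {100 * s['fraction_short']:.1f} %   "
            f"tau = {p['tau_short']:.2f} +/- {s['tau_short']:.2f} s",
            f"long bound         : {100 * p['fraction_long']:6.1f} "
            f"+/- {100 * s['fraction_long']:.1f} %   "
            f"tau = {p['tau_long']:.2f} +/- {s['tau_long']:.2f} s",
            f"best SSE           : {self.best_sse:.4g} "
            f"over {self.target.recovery.time.size} recovery samples",
        ]
        if self.flagged_short_search:
            lines.append("warning: fewer than 10 candidates were averaged")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(
            self.target.recovery.time,
            self.target.recovery.intensity,
            "k-",
            lw=0.8,
            label="target",
        )
        ax.plot(
            self.fitted_curve.recovery.time,
            self.fitted_curve.recovery.intensity,
            "r-",
            lw=1.2,
            label=f"top-{self.n_averaged} fit",
        )
        ax.set_xlabel("time after bleach (s)")
        ax.set_ylabel("normalized strip intensity")
        ax.legend()
        return ax


class FrapGridSearch:
    """Model object: fit a target FRAP curve by simulated-curve search.

    Parameters
    ----------
    target :
        Baseline-normalized FRAP curve to fit.
    d_free :
        Fixed diffusion coefficient of the free population (µm²/s), taken
        from the single-molecule analysis.
    geom, proto :
        Nucleus geometry and acquisition protocol.  Candidate curves are
        simulated with a reduced variant of ``proto``
        (``candidate_particles`` particles, one replicate, analytic
        baseline) but identical timing, so target and candidates share any
        residual time-discretization bias.
    space :
        :class:`SearchSpace`; the stated bounds are the defaults.
    seed :
        Seed of the common-random-numbers stream shared by all candidates.
    """

    def __init__(
        self,
        target: FrapCurve,
        d_free: float,
        geom: NucleusGeometry | None = None,
        proto: FrapProtocol | None = None,
        space: SearchSpace | None = None,
        *,
        candidate_particles: int = 3000,
        final_particles: int = 120_000,
        stage2_pool: int = 15,
        polish_pool: int = 10,
        band_pool: int = 2,
        n_polish: int = 3,
        descent_particles: int | None = None,
        fit_window: float | None = None,
        ultra_pool: int = 0,
        ultra_particles: int | None = None,
        seed: int = 1234,
    ) -> None:
        if d_free <= 0:
            raise ValueError("d_free must be positive")
        rec = target.recovery.intensity
        if rec.size == 0 or np.allclose(rec, rec[0]):
            raise ValueError("degenerate target curve (no recovery variation)")
        self.target = target
        self.d_free = float(d_free)
        self.geom = geom or NucleusGeometry()
        proto = proto or FrapProtocol()
        self.proto = proto
        from dataclasses import replace as _replace

        # candidates may be simulated/compared over a shorter window than
        # the full protocol: at Monte Carlo signal-to-noise the long flat
        # tail contributes noise-dominated samples that dilute the
        # informative early recovery
        window = min(fit_window or proto.recovery_duration, proto.recovery_duration)
        self.candidate_proto = _replace(
            reduced_protocol(
                proto, n_particles=candidate_particles, n_cells=1, n_prescans=0
            ),
            recovery_duration=window,
            rng_seed=seed,
        )
        self.final_proto = _replace(self.candidate_proto, n_particles=final_particles)
        self.stage2_pool = stage2_pool
        self.polish_pool = polish_pool
        self.band_pool = band_pool
        self.n_polish = n_polish
        self.descent_proto = _replace(
            self.candidate_proto,
            n_particles=descent_particles or max(final_particles // 3, 10_000),
        )
        # optional highest-fidelity re-ranking of the leading candidates
        self.ultra_pool = ultra_pool
        self.ultra_proto = _replace(
            self.candidate_proto,
            n_particles=ultra_particles or 5 * final_particles,
        )
        self._ultra: dict[tuple, float] = {}
        self.space = space or SearchSpace()
        self._screen: dict[tuple, float] = {}  # stage-1 (screening) SSE
        self._final: dict[tuple, float] = {}  # stage-2 (final) SSE
        self._final_curves: dict[tuple, np.ndarray] = {}
        self._rec_times = (
            np.arange(1, self.candidate_proto.n_recovery + 1)
            * self.candidate_proto.scan_interval
        )
        tgt_rec = target.recovery
        if (
            self._rec_times[0] < tgt_rec.time[0] - proto.scan_interval / 2
            or self._rec_times[-1] > tgt_rec.time[-1] + proto.scan_interval / 2
        ):
            raise ValueError("target and simulated time grids do not overlap")
        self._tgt = np.interp(self._rec_times, tgt_rec.time, tgt_rec.intensity)

    def _key(self, c) -> tuple:
        # canonicalize so regenerated grid points (tiny float noise from
        # the log/linear interpolation) merge with base points, and so
        # physically equivalent candidates (a residence time of an
        # unpopulated state is meaningless) collapse to one entry — without
        # this, identical curves can fill several top-10 slots.  Rounding
        # happens first so that a fraction of 1e-12 and exactly 0 agree.
        fs, fl, ts, tl = (round(float(v), 5) for v in c)
        if fs == 0.0:
            ts = round(self.space.tau_short_bounds[0], 5)
        if fl == 0.0:
            tl = round(self.space.tau_long_bounds[0], 5)
        return (fs, fl, ts, tl)

    def _batch(
        self, candidates: np.ndarray, proto: FrapProtocol, store: dict,
        keep_curves: bool = False, max_rows: int = 4_000_000,
    ) -> None:
        todo = [self._key(c) for c in candidates]
        todo = [k for k in dict.fromkeys(todo) if k not in store]
        if not todo:
            return
        chunk = max(1, max_rows // (proto.n_particles * proto.n_cells))
        for i in range(0, len(todo), chunk):
            batch = todo[i : i + chunk]
            models = [candidate_model(*k, self.d_free) for k in batch]
            curves, variances = simulate_candidate_curves(
                models, self.geom, proto, return_variance=True
            )
            # subtract the candidate's own Monte Carlo variance: the raw SSE
            # floor scales with the candidate's intensity level, which would
            # otherwise systematically favour deeply bleached (high-bound)
            # candidates under noise-limited ranking
            sses = ((curves - self._tgt[None, :]) ** 2).sum(axis=1) - variances.sum(
                axis=1
            )
            for k, sse, cur in zip(batch, sses, curves):
                store[k] = float(sse)
                if keep_curves:
                    self._final_curves[k] = cur

    def score(self, f_short, f_long, tau_short, tau_long) -> float:
        """Final-fidelity SSE of one candidate (common random numbers)."""
        key = self._key((f_short, f_long, tau_short, tau_long))
        if key not in self._final:
            self._batch(np.array([key]), self.final_proto, self._final, True)
        return self._final[key]

    def _descend(
        self, start: tuple, proto: FrapProtocol, store: dict, max_iter: int = 4
    ) -> list[tuple]:
        """Pattern search from ``start`` at the fidelity of ``proto``.

        Common random numbers make the noise of neighbouring candidates
        nearly identical, so local comparisons are reliable well below the
        particle count needed for global ones.  Moves: exchange weight
        between the two bound states (total preserved), shift the total
        bound fraction (split preserved), and step each residence time
        (tau_long in log space).  The step starts at the base grid spacing
        and halves whenever no move improves.  Returns the visited
        candidates sorted by score.
        """
        space = self.space
        fv, tsv, tlv = (
            space.fraction_values(),
            space.tau_short_values(),
            np.log(space.tau_long_values()),
        )
        step = np.array(
            [
                fv[1] - fv[0] if len(fv) > 1 else 0.1,
                tsv[1] - tsv[0] if len(tsv) > 1 else 0.2,
                tlv[1] - tlv[0] if len(tlv) > 1 else 0.8,
            ]
        )

        def clip(y: np.ndarray) -> tuple | None:
            y = y.copy()
            y[0] = np.clip(y[0], 0.0, space.fraction_max)
            y[1] = np.clip(y[1], 0.0, space.fraction_max)
            y[2] = np.clip(y[2], *space.tau_short_bounds)
            y[3] = np.clip(y[3], *space.tau_long_bounds)
            if y[0] + y[1] > space.fraction_max + 1e-12:
                return None
            return self._key(y)

        x = np.array(start, float)
        self._batch(np.array([x]), proto, store)
        fx = store[self._key(x)]
        visited = {self._key(x)}
        for _ in range(max_iter):
            moves = []
            for s in (-1, 1):  # exchange between the bound states,
                y = x.copy()  # preserving their total exactly
                m = min(step[0], y[1] if s > 0 else y[0])
                y[0] += s * m
                y[1] -= s * m
                if m > 0:
                    moves.append(y)
            for s in (-1, 1):  # shift the total, preserving the split
                y = x.copy()
                y[0] += s * step[0] / 2
                y[1] += s * step[0] / 2
                moves.append(y)
            for s in (-1, 1):
                y = x.copy()
                y[2] += s * step[1]
                moves.append(y)
            for s in (-1, 1):
                y = x.copy()
                y[3] = math.exp(math.log(y[3]) + s * step[2])
                moves.append(y)
            keys = [k for k in (clip(y) for y in moves) if k is not None]
            if not keys:
                break
            self._batch(np.array(keys), proto, store)
            visited.update(keys)
            best_key = min(keys, key=lambda k: store[k])
            if store[best_key] < fx:
                x, fx = np.array(best_key), store[best_key]
            else:
                step = step / 2.0
                if step[0] < 0.01:
                    break
        return sorted(visited, key=lambda k: store[k])

    def fit(self, top_n: int = 10) -> FrapFitResults:
        """Staged search: screen, adjudicate a diverse pool, polish, rank.

        Stage 1 scores every grid candidate at the screening particle
        count.  Screening orders candidates only coarsely — the model has
        a soft direction (a larger short-bound fraction with a residence
        time near the scan interval mimics free diffusion), and screening
        noise is correlated with the bound fraction — so diversity is
        preserved deliberately: the best ``stage2_pool`` candidates plus
        the best ``band_pool`` of every total-bound band are re-simulated
        at the final particle count.  Pattern descents (common random
        numbers, intermediate fidelity) then polish the best
        ``n_polish`` band-distinct final candidates, and each descent's
        leaders are re-simulated at the final count.  The ranking, top-10
        averages and fitted curve come exclusively from final-fidelity
        scores.  With ``refine_passes = 0`` the polish stage is skipped
        and the fit reduces to a pure pre-simulated-library search.
        """
        self._batch(self.space.base_candidates(), self.candidate_proto, self._screen)
        pool = sorted(self._screen.items(), key=lambda kv: (kv[1], kv[0]))
        pool_keys = [k for k, _ in pool[: self.stage2_pool]]
        fv = self.space.fraction_values()
        band_width = fv[1] - fv[0] if len(fv) > 1 else 1.0
        per_band: dict[int, int] = {}
        for k, _ in pool:
            band = int(round((k[0] + k[1]) / band_width))
            if per_band.get(band, 0) < self.band_pool:
                per_band[band] = per_band.get(band, 0) + 1
                if k not in pool_keys:
                    pool_keys.append(k)
        if self.space.refine_passes > 0:
            # band centres: even split at mid residence times, tau_long at
            # the geometric middle of its identifiable range (binding longer
            # than about half the observation window looks permanent)
            ts_mid = float(np.median(self.space.tau_short_values()))
            tl_lo, tl_hi = self.space.tau_long_bounds
            ident_hi = min(tl_hi, max(self.candidate_proto.recovery_duration / 2,
                                      2 * tl_lo))
            tl_mid = math.sqrt(tl_lo * ident_hi)
            for b in fv:
                k = self._key((b / 2, b / 2, ts_mid, tl_mid))
                if k not in pool_keys:
                    pool_keys.append(k)
        self._batch(np.array(pool_keys), self.final_proto, self._final, keep_curves=True)

        if self.space.refine_passes > 0:
            # polish the best band-distinct incumbents: local descents at
            # intermediate fidelity, leaders re-scored at final fidelity
            ranked1 = sorted(self._final.items(), key=lambda kv: (kv[1], kv[0]))
            centers: list[tuple] = []
            for k, _ in ranked1:
                if all(
                    abs((k[0] + k[1]) - (c[0] + c[1])) >= band_width - 1e-9
                    for c in centers
                ):
                    centers.append(k)
                if len(centers) >= self.n_polish:
                    break
            store: dict[tuple, float] = {}
            promote: list[tuple] = []
            for c in centers:
                leaders = self._descend(
                    c, self.descent_proto, store,
                    max_iter=2 + 2 * self.space.refine_passes,
                )
                promote.extend(leaders[: self.polish_pool])
            self._batch(
                np.array(list(dict.fromkeys(promote))),
                self.final_proto,
                self._final,
                keep_curves=True,
            )

        scores = self._final
        if self.ultra_pool > 0:
            # re-rank the leaders at the highest fidelity: near-degenerate
            # parameter families are separated only by sub-1e-2 SSE margins
            leaders = sorted(self._final.items(), key=lambda kv: (kv[1], kv[0]))
            keys = np.array([k for k, _ in leaders[: self.ultra_pool]])
            self._batch(keys, self.ultra_proto, self._ultra, keep_curves=True)
            # surround the highest-fidelity winner with a symmetric local
            # neighbourhood so the top-10 average reflects the landscape
            # around it rather than the composition of the search pool
            best = min(self._ultra.items(), key=lambda kv: (kv[1], kv[0]))[0]
            nbrs = []
            dfrac = (fv[1] - fv[0]) / 3 if len(fv) > 1 else 0.03
            tsv = self.space.tau_short_values()
            dts = (tsv[1] - tsv[0]) / 3 if len(tsv) > 1 else 0.1
            dtl = math.log(self.space.tau_long_bounds[1] /
                           self.space.tau_long_bounds[0]) / (
                3 * max(self.space.n_tau_long - 1, 1))
            x = np.array(best)
            for delta in (
                (+dfrac, -dfrac, 0, 0), (-dfrac, +dfrac, 0, 0),
                (+dfrac / 2, +dfrac / 2, 0, 0), (-dfrac / 2, -dfrac / 2, 0, 0),
                (0, 0, +dts, 0), (0, 0, -dts, 0),
            ):
                nbrs.append(x + np.array(delta))
            for s in (+1, -1):
                y = x.copy()
                y[3] = math.exp(math.log(y[3]) + s * dtl)
                nbrs.append(y)
            ok = []
            for y in nbrs:
                y[0] = np.clip(y[0], 0.0, self.space.fraction_max)
                y[1] = np.clip(y[1], 0.0, self.space.fraction_max)
                y[2] = np.clip(y[2], *self.space.tau_short_bounds)
                y[3] = np.clip(y[3], *self.space.tau_long_bounds)
                if y[0] + y[1] <= self.space.fraction_max + 1e-12:
                    ok.append(y)
            self._batch(np.array(ok), self.ultra_proto, self._ultra, keep_curves=True)
            scores = self._ultra

        rows = [
            {
                "fraction_short": k[0],
                "fraction_long": k[1],
                "tau_short": k[2],
                "tau_long": k[3],
                "sse": v,
            }
            for k, v in scores.items()
        ]
        ranked = pd.DataFrame(rows)
        # total order: SSE, then parsimony (smaller total bound fraction)
        ranked["_bound"] = ranked["fraction_short"] + ranked["fraction_long"]
        ranked = ranked.sort_values(
            ["sse", "_bound"] + PARAM_COLUMNS, kind="mergesort"
        ).drop(columns="_bound").reset_index(drop=True)

        n_avg = min(top_n, len(ranked))
        top = ranked.head(n_avg).copy()
        top["fraction_free"] = 1.0 - top["fraction_short"] - top["fraction_long"]
        cols = ["fraction_free"] + PARAM_COLUMNS
        params = {c: float(top[c].mean()) for c in cols}
        sems = {
            c: float(top[c].std(ddof=1) / math.sqrt(n_avg)) if n_avg > 1 else 0.0
            for c in cols
        }

        fitted = self._average_curve(top)
        return FrapFitResults(
            ranked=ranked,
            top=top,
            params=params,
            sems=sems,
            fitted_curve=fitted,
            target=self.target,
            d_free=self.d_free,
            n_averaged=n_avg,
            flagged_short_search=n_avg < top_n,
        )

    def _average_curve(self, top: pd.DataFrame) -> FrapCurve:
        curves = []
        for _, row in top.iterrows():
            key = self._key(row[PARAM_COLUMNS].to_numpy())
            if key not in self._final_curves:
                self._batch(np.array([key]), self.final_proto, self._final, True)
            curves.append(self._final_curves[key])
        mean_int = np.mean(curves, axis=0)
        return FrapCurve(
            time=self._rec_times,
            intensity=mean_int,
            phase=np.full(self._rec_times.size, "recovery", dtype=object),
            n_particles=self.final_proto.n_particles * self.final_proto.n_cells,
        )


def sensitivity_dfast(
    target: FrapCurve,
    d_values: tuple[float, float, float],
    geom: NucleusGeometry | None = None,
    proto: FrapProtocol | None = None,
    space: SearchSpace | None = None,
    **kwargs,
) -> tuple[list[FrapFitResults], dict]:
    """Re-fit at D_free − SEM, D_free and D_free + SEM.

    Returns the three fit results and the maximum spread of each averaged
    parameter across the three fits — a direct check that the fixed
    diffusion coefficient does not drive the bound-fraction estimates.
    """
    if any(d <= 0 for d in d_values):
        raise ValueError("all D values must be positive")
    results = [
        FrapGridSearch(target, d, geom, proto, space, **kwargs).fit()
        for d in d_values
    ]
    spread = {
        c: float(
            max(r.params[c] for r in results) - min(r.params[c] for r in results)
        )
        for c in ["fraction_free"] + PARAM_COLUMNS
    }
    return results, spread
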
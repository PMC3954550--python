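"""Particle Image Correlation Spectroscopy (PICS).

Estimates the distribution of single-molecule displacements without linking
trajectories: for every pair of frames separated by a given lag, the mean
number of frame-(t+lag) localizations within distance l of a frame-t
localization is a cumulative correlation function C(l²).  Uncorrelated
("background") molecules contribute a term growing with the search area;
after subtracting a fitted background and normalizing by the correlated
plateau, C becomes the cumulative probability P_cum(l²) that a molecule
moved a squared distance at most l² during the lag.

P_cum is fitted with a two-population model

    P_cum(l²) = 1 − [α·exp(−l²/MSD₁) + (1−α)·exp(−l²/MSD₂)]

(α the fast-fraction size, MSD₁ ≥ MSD₂ the per-population mean squared
displacements), and the per-lag MSDs are regressed on the lag time to obtain
diffusion coefficients, D = slope/4, with a free intercept absorbing the
4σ_loc² localization-error offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares


# --------------------------------------------------------------------------
# containers

@dataclass
class PcumCurve:
    """Cumulative displacement distribution for one time lag."""

    lag: float  # s
    l2_grid: np.ndarray  # µm², strictly increasing
    pcum: np.ndarray  # corrected, in [0, 1], non-decreasing
    n_pairs: int  # number of reference localizations
    raw_counts: np.ndarray  # cumulative correlation counts (integers)
    density_correction: float  # fitted background density rho (µm⁻²)
    plateau: float  # fitted correlated plateau used for normalization
    flagged: bool = False

    @property
    def raw_c(self) -> np.ndarray:
        """Uncorrected correlation C(l²) per reference molecule."""
        if self.n_pairs == 0:
            return np.zeros_like(self.l2_grid)
        return self.raw_counts / self.n_pairs


@dataclass
class TwoPopFit:
    """Two-population (or single-population) fit of one P_cum curve."""

    alpha: float  # fast-fraction size, in [0, 1]
    msd_fast: float  # µm²
    msd_slow: float  # µm²
    residual_norm: float
    order: int
    lag: float = math.nan

    def __post_init__(self) -> None:
        if self.msd_fast < self.msd_slow:
            self.msd_fast, self.msd_slow = self.msd_slow, self.msd_fast
            self.alpha = 1.0 - self.alpha


@dataclass
class DiffusionEstimate:
    """Diffusion coefficient from a (weighted) linear MSD-vs-lag fit."""

    d: float  # µm²/s, slope/4 clipped at 0
    intercept: float  # µm², absorbs the localization-error offset
    d_se: float  # µm²/s, from the slope standard error
    lags: np.ndarray
    msd: np.ndarray
    msd_se: np.ndarray | None = None
    flagged: bool = False  # negative fitted slope clipped


# --------------------------------------------------------------------------
# correlation

def default_l2_grid(
    pixel_size: float = 0.220, l_max: float = 5.0, n_points: int = 100
) -> np.ndarray:
    """Log-spaced squared-distance grid from (pixel/10)² to l_max²."""
    return np.geomspace((pixel_size / 10.0) ** 2, l_max**2, n_points)


def pair_squared_displacements(
    table: pd.DataFrame, lag_frames: int
) -> tuple[np.ndarray, int]:
    """All squared distances between frame-t and frame-(t+lag) localizations.

    Pairs are formed only within a series; returns the pooled squared
    distances and the number of reference (frame-t) localizations, counting
    references even when the later frame is empty.
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    xy = table[["x_um", "y_um"]].to_numpy(dtype=float)
    d2_parts: list[np.ndarray] = []
    n_ref = 0
    for (_, _), sub in table.groupby(["cell", "series"], sort=False):
        frames: dict[int, np.ndarray] = {
            int(f): xy[idx.to_numpy()]
            for f, idx in sub.groupby("frame", sort=False).groups.items()
        }
        for t, a in frames.items():
            b = frames.get(t + lag_frames)
            if b is None:
                if any(f > t + lag_frames for f in frames):
                    # later frames exist; the lag frame simply had no peaks
                    n_ref += len(a)
                continue
            n_ref += len(a)
            diff = a[:, None, :] - b[None, :, :]
            d2_parts.append((diff * diff).sum(axis=2).ravel())
    d2 = np.concatenate(d2_parts) if d2_parts else np.empty(0)
    return d2, n_ref


def _background_design(l2: np.ndarray, roi_size: float) -> np.ndarray:
    """Expected disc∩ROI search area for a uniform reference molecule.

    E[A](l) = πl² − (8/3) l³ / L corrects the leading-order edge loss of a
    disc of radius l in a square field of side L.
    """
    l = np.sqrt(l2)
    return math.pi * l2 - (8.0 / 3.0) * l**3 / roi_size


def correlate(
    table: pd.DataFrame,
    lag_frames: int,
    l2_grid: np.ndarray | None = None,
    *,
    lag_time: float | None = None,
    roi_size: float = 11.0,
    background_window: tuple[float, float] = (1.0, 4.0),
    min_pairs: int = 50,
    extra_pairs: list[tuple[np.ndarray, int]] | None = None,
) -> PcumCurve:
    """Build the corrected cumulative displacement distribution for one lag.

    ``extra_pairs`` allows pooling pre-computed (squared distances, n_ref)
    from other acquisitions sharing the same lag time.
    """
    if l2_grid is None:
        l2_grid = default_l2_grid()
    l2_grid = np.asarray(l2_grid, dtype=float)
    if np.any(np.diff(l2_grid) <= 0):
        raise ValueError("l2_grid must be strictly increasing")

    d2, n_ref = pair_squared_displacements(table, lag_frames)
    if extra_pairs:
        d2 = np.concatenate([d2] + [p[0] for p in extra_pairs])
        n_ref += sum(p[1] for p in extra_pairs)
    if lag_time is None:
        lag_time = math.nan

    counts = np.searchsorted(np.sort(d2), l2_grid, side="right").astype(float)
    curve = PcumCurve(
        lag=lag_time,
        l2_grid=l2_grid,
        pcum=np.zeros_like(l2_grid),
        n_pairs=n_ref,
        raw_counts=counts,
        density_correction=0.0,
        plateau=0.0,
        flagged=True,
    )
    if n_ref < min_pairs:
        return curve

    c = counts / n_ref
    lo, hi = background_window
    win = (l2_grid >= lo) & (l2_grid <= hi)
    if win.sum() < 3:
        return curve
    g = _background_design(l2_grid, roi_size)
    design = np.column_stack([np.ones(win.sum()), g[win]])
    coef, *_ = np.linalg.lstsq(design, c[win], rcond=None)
    c0, rho = float(coef[0]), float(coef[1])
    if c0 <= 0:
        return curve

    pcum = np.clip((c - rho * g) / c0, 0.0, 1.0)
    pcum = np.maximum.accumulate(pcum)  # enforce monotone CDF after correction
    curve.pcum = pcum
    curve.density_correction = max(rho, 0.0)
    curve.plateau = c0
    curve.flagged = False
    return curve


def pooled_curves(
    tables_by_lag: dict[float, pd.DataFrame],
    *,
    max_lag: float = 0.0375,
    l2_grid: np.ndarray | None = None,
    roi_size: float = 11.0,
    background_window: tuple[float, float] = (1.0, 4.0),
    min_pairs: int = 50,
    frames_per_series: int = 8,
) -> list[PcumCurve]:
    """P_cum curves for every available lag time, pooled across acquisitions.

    Each acquisition (keyed by its frame lag) contributes frame separations
    1..frames_per_series−1; separations whose lag time coincides (e.g. the
    12.5 ms series' single-frame step and the 6.25 ms series' two-frame
    step) are pooled into one curve.  Only lags up to ``max_lag`` are kept.
    """
    sources: dict[float, list[tuple[pd.DataFrame, int]]] = {}
    for frame_lag, table in tables_by_lag.items():
        for k in range(1, frames_per_series):
            t = round(frame_lag * k, 9)
            if t > max_lag + 1e-12:
                break
            sources.setdefault(t, []).append((table, k))

    empty = next(iter(tables_by_lag.values())).iloc[:0]
    curves = []
    for lag_time in sorted(sources):
        pairs = [
            pair_squared_displacements(tab, k) for tab, k in sources[lag_time]
        ]
        curves.append(
            correlate(
                empty,
                1,
                l2_grid,
                lag_time=lag_time,
                roi_size=roi_size,
                background_window=background_window,
                min_pairs=min_pairs,
                extra_pairs=pairs,
            )
        )
    return curves


# --------------------------------------------------------------------------
# model fitting

def pcum_two_population(
    l2: np.ndarray, alpha: float, msd1: float, msd2: float
) -> np.ndarray:
    """Closed-form two-population cumulative displacement model."""
    return 1.0 - (
        alpha * np.exp(-l2 / msd1) + (1.0 - alpha) * np.exp(-l2 / msd2)
    )


def _pair_survival(r: np.ndarray, roi_size: float) -> np.ndarray:
    """P(partner still inside the square field | step length r).

    Set covariogram of the square: for a uniformly placed reference and an
    isotropic step of length r, 1 − 4r/(πL) + r²/(πL²).
    """
    return np.clip(
        1.0 - 4.0 * r / (math.pi * roi_size) + r**2 / (math.pi * roi_size**2),
        0.0,
        1.0,
    )


def pcum_two_population_edge(
    l2: np.ndarray,
    alpha: float,
    msd1: float,
    msd2: float,
    roi_size: float,
    _n_grid: int = 4000,
) -> np.ndarray:
    """Two-population model conditioned on the pair staying in the field.

    Large steps leave the region of interest more often than small ones, so
    the observed (redetected) displacement distribution is compressed
    relative to the free-space mixture.  The compression factor is the
    exact square-field pair-survival probability, so this model removes the
    finite-field bias from the fitted MSDs.
    """
    r_max = max(math.sqrt(float(np.max(l2))), 4.0 * math.sqrt(msd1 + 1e-12))
    r = np.linspace(0.0, min(r_max, roi_size), _n_grid)
    pdf = alpha * (2 * r / msd1) * np.exp(-(r**2) / msd1) + (1 - alpha) * (
        2 * r / msd2
    ) * np.exp(-(r**2) / msd2)
    weighted = pdf * _pair_survival(r, roi_size)
    cdf = np.concatenate(
        [[0.0], np.cumsum((weighted[1:] + weighted[:-1]) / 2 * np.diff(r))]
    )
    cdf /= cdf[-1]
    return np.interp(np.sqrt(l2), r, cdf)


def fit_populations(
    curve: PcumCurve, order: int = 2, roi_size: float | None = None
) -> TwoPopFit:
    """Least-squares fit of the one/two(/three)-population model to a curve.

    Eight deterministic multistarts span the bounds (α ∈ [0,1], MSDs ≥ 0);
    ties break toward the lowest residual, then the lowest α.  The returned
    fit has ``msd_fast >= msd_slow`` (populations swapped if needed).

    When ``roi_size`` is given, the order-2 model includes the exact
    square-field pair-survival factor (see
    :func:`pcum_two_population_edge`), which corrects the downward MSD bias
    from pairs whose second localization left the field.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    l2, y = curve.l2_grid, curve.pcum
    # scale guess: l² where the curve crosses one half
    idx = int(np.searchsorted(y, 0.5))
    scale = l2[min(idx, len(l2) - 1)]
    scale = max(scale, l2[0])

    tiny = 1e-9
    if order == 1:
        def resid(p):
            return 1.0 - np.exp(-l2 / p[0]) - y

        best = None
        for s in (scale / 3, scale, scale * 3, scale * 10):
            sol = least_squares(resid, [s], bounds=([tiny], [np.inf]))
            if best is None or sol.cost < best.cost:
                best = sol
        norm = float(np.linalg.norm(resid(best.x)))
        return TwoPopFit(1.0, float(best.x[0]), 0.0, norm, 1, curve.lag)

    if order == 3:
        return _fit_three_populations(curve, scale)

    if roi_size is not None:
        def resid(p):
            return pcum_two_population_edge(l2, *p, roi_size) - y
    else:
        def resid(p):
            return pcum_two_population(l2, *p) - y

    starts = [
        (a, m1, m2)
        for a in (0.3, 0.5, 0.7, 0.9)
        for (m1, m2) in ((scale * 2, scale / 20), (scale * 5, scale / 5))
    ]
    best, best_key = None, None
    for p0 in starts:
        sol = least_squares(
            resid, p0, bounds=([0.0, tiny, tiny], [1.0, np.inf, np.inf])
        )
        key = (round(sol.cost, 12), round(float(sol.x[0]), 6))
        if best is None or key < best_key:
            best, best_key = sol, key
    if best is None or not best.success and best.cost > 1e6:
        raise RuntimeError("two-population fit failed to converge")
    a, m1, m2 = (float(v) for v in best.x)
    norm = float(np.linalg.norm(resid(best.x)))
    return TwoPopFit(a, m1, m2, norm, 2, curve.lag)


def _fit_three_populations(curve: PcumCurve, scale: float) -> TwoPopFit:
    """Optional three-population fit (not used by default analyses).

    Returned as a TwoPopFit over the two largest-MSD populations with the
    third folded into ``msd_slow``; provided for model-comparison only since
    three populations are not consistently identifiable across lags.
    """
    l2, y = curve.l2_grid, curve.pcum
    tiny = 1e-9

    def resid(p):
        a1, a2, m1, m2, m3 = p
        a3 = np.clip(1.0 - a1 - a2, 0.0, 1.0)
        return (
            1.0
            - (
                a1 * np.exp(-l2 / m1)
                + a2 * np.exp(-l2 / m2)
                + a3 * np.exp(-l2 / m3)
            )
            - y
        )

    best = None
    for p0 in (
        (0.4, 0.3, scale * 3, scale / 3, scale / 30),
        (0.3, 0.4, scale * 5, scale, scale / 50),
    ):
        sol = least_squares(
            resid,
            p0,
            bounds=([0, 0, tiny, tiny, tiny], [1, 1, np.inf, np.inf, np.inf]),
        )
        if best is None or sol.cost < best.cost:
            best = sol
    a1, a2, m1, m2, m3 = best.x
    norm = float(np.linalg.norm(resid(best.x)))
    return TwoPopFit(float(a1), float(m1), float(m2), norm, 3, curve.lag)


def msd_vs_lag(
    fits: list[TwoPopFit],
    lags: np.ndarray | list[float],
    *,
    fast_se: np.ndarray | None = None,
    slow_se: np.ndarray | None = None,
) -> tuple[DiffusionEstimate, DiffusionEstimate, float, float]:
    """Weighted linear regression of the per-lag MSDs on lag time.

    Returns (fast estimate, slow estimate, mean α over lags, SE of that
    mean).  D = slope/4 with a free intercept; weights are 1/SE² where
    per-lag standard errors are available, otherwise the fit is unweighted.
    Negative slopes are clipped to D = 0 and flagged.
    """
    lags = np.asarray(lags, dtype=float)
    if lags.size < 3:
        raise ValueError("need at least 3 lags for the MSD regression")

    def _fit(msd: np.ndarray, se: np.ndarray | None) -> DiffusionEstimate:
        x = sm.add_constant(lags)
        if se is not None and np.all(np.asarray(se) > 0):
            w = 1.0 / np.asarray(se, dtype=float) ** 2
        else:
            w, se = np.ones_like(lags), None
        res = sm.WLS(msd, x, weights=w).fit()
        slope, intercept = float(res.params[1]), float(res.params[0])
        slope_se = float(res.bse[1])
        flagged = slope < 0
        return DiffusionEstimate(
            d=max(slope, 0.0) / 4.0,
            intercept=intercept,
            d_se=slope_se / 4.0,
            lags=lags,
            msd=np.asarray(msd, dtype=float),
            msd_se=None if se is None else np.asarray(se, dtype=float),
            flagged=flagged,
        )

    msd_f = np.array([f.msd_fast for f in fits])
    msd_s = np.array([f.msd_slow for f in fits])
    alphas = np.array([f.alpha for f in fits])
    fast = _fit(msd_f, fast_se)
    slow = _fit(msd_s, slow_se)
    alpha_mean = float(alphas.mean())
    alpha_se = float(alphas.std(ddof=1) / math.sqrt(len(alphas))) if len(alphas) > 1 else 0.0
    return fast, slow, alpha_mean, alpha_se


def partition_cells(cells: np.ndarray, n_groups: int = 3) -> list[np.ndarray]:
    """Split cell ids into near-equal groups (e.g. 7/7/6 for 20 cells)."""
    cells = np.unique(np.asarray(cells))
    if cells.size < n_groups:
        raise ValueError("need at least as many cells as groups")
    return list(np.array_split(cells, n_groups))


def group_sem(
    tables_by_lag: dict[float, pd.DataFrame],
    analysis,
    n_groups: int = 3,
):
    """Standard errors by re-running a full analysis on cell subgroups.

    ``analysis`` maps a dict lag->table to a flat dict of named scalars;
    the SEM of each scalar is SD(group estimates)/sqrt(n_groups).  Groups in
    which the analysis fails (e.g. no usable curves) are dropped and the
    affected SEMs are reported as NaN if fewer than 2 groups remain.
    Returns (sem dict, per-group list of estimate dicts).
    """
    all_cells = np.unique(
        np.concatenate([t["cell"].unique() for t in tables_by_lag.values()])
    )
    groups = partition_cells(all_cells, n_groups)
    estimates: list[dict] = []
    for g in groups:
        sub = {
            lag: t[t["cell"].isin(g)].reset_index(drop=True)
            for lag, t in tables_by_lag.items()
        }
        try:
            estimates.append(analysis(sub))
        except (ValueError, RuntimeError):
            continue
    keys = set().union(*(e.keys() for e in estimates)) if estimates else set()
    sems = {}
    for k in keys:
        vals = np.array([e[k] for e in estimates if k in e and np.isfinite(e[k])])
        if vals.size >= 2:
            sems[k] = float(vals.std(ddof=1) / math.sqrt(vals.size))
        else:
            sems[k] = math.nan
    return sems, estimates


# --------------------------------------------------------------------------
# model / results objects

@dataclass(frozen=True)
class PicsConfig:
    """Tunable knobs of the PICS pipeline."""

    max_lag: float = 0.0375  # s, longest lag used
    l2_min: float = (0.220 / 10.0) ** 2  # µm²
    l2_max: float = 25.0  # µm²
    n_grid: int = 100
    roi_size: float = 11.0  # µm
    background_window: tuple[float, float] = (1.0, 4.0)  # µm²
    min_pairs: int = 50
    order: int = 2
    frames_per_series: int = 8
    # inverse-variance weighting of the MSD-vs-lag regression is available
    # but off by default: SEs estimated from 3 cell groups carry only 2
    # degrees of freedom, and weighting by such noisy variances is known to
    # bias the slope
    weighted_msd_fit: bool = False

    def grid(self) -> np.ndarray:
        return np.geomspace(self.l2_min, self.l2_max, self.n_grid)


class PicsAnalysis:
    """PICS displacement analysis of one experiment.

    Parameters
    ----------
    tables_by_lag :
        Mapping frame lag (s) -> localization table (columns
        cell/series/frame/x_um/y_um).  A single table may be passed with
        ``frame_lag`` instead.
    config :
        :class:`PicsConfig`; defaults follow the stroboscopic protocol.
    """

    def __init__(
        self,
        tables_by_lag: dict[float, pd.DataFrame] | pd.DataFrame,
        config: PicsConfig | None = None,
        *,
        frame_lag: float | None = None,
    ) -> None:
        if isinstance(tables_by_lag, pd.DataFrame):
            if frame_lag is None:
                raise ValueError("frame_lag is required with a single table")
            tables_by_lag = {frame_lag: tables_by_lag}
        self.tables_by_lag = tables_by_lag
        self.config = config or PicsConfig()

    # -- internal: one complete pass over a set of tables
    def _single_pass(self, tables):
        cfg = self.config
        curves = pooled_curves(
            tables,
            max_lag=cfg.max_lag,
            l2_grid=cfg.grid(),
            roi_size=cfg.roi_size,
            background_window=cfg.background_window,
            min_pairs=cfg.min_pairs,
            frames_per_series=cfg.frames_per_series,
        )
        curves = [c for c in curves if not c.flagged]
        if len(curves) < 3:
            raise ValueError("fewer than 3 usable P_cum curves")
        fits = [
            fit_populations(c, cfg.order, roi_size=cfg.roi_size) for c in curves
        ]
        lags = np.array([c.lag for c in curves])
        return curves, fits, lags

    def _flat_estimates(self, tables) -> dict:
        curves, fits, lags = self._single_pass(tables)
        fast, slow, alpha, _ = msd_vs_lag(fits, lags)
        out = {"alpha": alpha, "d_fast": fast.d, "d_slow": slow.d}
        for f in fits:
            out[f"msd_fast_{f.lag:.6f}"] = f.msd_fast
            out[f"msd_slow_{f.lag:.6f}"] = f.msd_slow
        return out

    def fit(self, n_groups: int = 3) -> "PicsResults":
        """Pooled analysis plus group-resampled standard errors."""
        curves, fits, lags = self._single_pass(self.tables_by_lag)
        sems: dict = {}
        groups: list[dict] = []
        fast_se = slow_se = None
        if n_groups and n_groups >= 2:
            sems, groups = group_sem(
                self.tables_by_lag, self._flat_estimates, n_groups
            )
            fast_se = np.array(
                [sems.get(f"msd_fast_{lag:.6f}", math.nan) for lag in lags]
            )
            slow_se = np.array(
                [sems.get(f"msd_slow_{lag:.6f}", math.nan) for lag in lags]
            )
            if not np.all(np.isfinite(fast_se)) or np.any(fast_se == 0):
                fast_se = None
            if slow_se is not None and (
                not np.all(np.isfinite(slow_se)) or np.any(slow_se == 0)
            ):
                slow_se = None
            if not self.config.weighted_msd_fit:
                fast_se = slow_se = None
        fast, slow, alpha, alpha_se_lags = msd_vs_lag(
            fits, lags, fast_se=fast_se, slow_se=slow_se
        )
        return PicsResults(
            curves=curves,
            population_fits=fits,
            fast=fast,
            slow=slow,
            alpha=alpha,
            alpha_se_over_lags=alpha_se_lags,
            group_sems=sems,
            group_estimates=groups,
            n_groups=n_groups,
        )


@dataclass
class PicsResults:
    """Estimates from a PICS analysis with group-resampled uncertainties."""

    curves: list[PcumCurve]
    population_fits: list[TwoPopFit]
    fast: DiffusionEstimate
    slow: DiffusionEstimate
    alpha: float  # mean fast-fraction size over lags
    alpha_se_over_lags: float
    group_sems: dict
    group_estimates: list[dict]
    n_groups: int

    @property
    def alpha_sem(self) -> float:
        """SEM of the fast-fraction size from the cell-group resampling."""
        return self.group_sems.get("alpha", math.nan)

    @property
    def d_fast_sem(self) -> float:
        return self.group_sems.get("d_fast", math.nan)

    @property
    def d_slow_sem(self) -> float:
        return self.group_sems.get("d_slow", math.nan)

    @property
    def bound_fraction(self) -> float:
        return 1.0 - self.alpha

    def per_lag_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_s": [f.lag for f in self.population_fits],
                "alpha": [f.alpha for f in self.population_fits],
                "msd_fast_um2": [f.msd_fast for f in self.population_fits],
                "msd_slow_um2": [f.msd_slow for f in self.population_fits],
                "residual_norm": [f.residual_norm for f in self.population_fits],
                "n_pairs": [c.n_pairs for c in self.curves],
            }
        )

    def to_dict(self) -> dict:
        return {
            "diffusing_fraction_pct": 100.0 * self.alpha,
            "diffusing_fraction_sem_pct": 100.0 * self.alpha_sem,
            "bound_fraction_pct": 100.0 * self.bound_fraction,
            "d_fast_um2_s": self.fast.d,
            "d_fast_sem_um2_s": self.d_fast_sem,
            "d_slow_um2_s": self.slow.d,
            "d_slow_sem_um2_s": self.d_slow_sem,
            "msd_intercept_fast_um2": self.fast.intercept,
            "msd_intercept_slow_um2": self.slow.intercept,
            "per_lag": self.per_lag_table().to_dict(orient="list"),
        }

    def summary(self) -> str:
        lines = [
            "PICS two-population analysis",
            "----------------------------",
            f"diffusing fraction : {100 * self.alpha:6.1f} "
            f"+/- {100 * self.alpha_sem:.1f} %  (SEM, {self.n_groups} groups)",
            f"bound fraction     : {100 * self.bound_fraction:6.1f} %",
            f"D_fast             : {self.fast.d:6.2f} "
            f"+/- {self.d_fast_sem:.2f} um^2/s",
            f"D_slow             : {self.slow.d:6.3f} "
            f"+/- {self.d_slow_sem:.3f} um^2/s",
            f"MSD intercept fast : {self.fast.intercept:8.4f} um^2",
            f"lags used          : "
            + ", ".join(f"{1e3 * f.lag:.2f} ms" for f in self.population_fits),
        ]
        return "\n".join(lines)

    def plot_pcum(self, ax=None):
        """P_cum curves and their two-population fits per lag."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for c, f in zip(self.curves, self.population_fits):
            (line,) = ax.semilogx(
                c.l2_grid, c.pcum, ".", ms=3, label=f"{1e3 * c.lag:.2f} ms"
            )
            ax.semilogx(
                c.l2_grid,
                pcum_two_population(c.l2_grid, f.alpha, f.msd_fast, f.msd_slow),
                color=line.get_color(),
                lw=1,
            )
        ax.set_xlabel(r"$l^2$ ($\mu m^2$)")
        ax.set_ylabel(r"$P_{cum}$")
        ax.legend(fontsize=7)
        return ax

    def plot_msd(self, ax=None):
        """MSD versus lag with the fitted lines for both populations."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for est, label in ((self.fast, "fast"), (self.slow, "slow")):
            ax.errorbar(
                1e3 * est.lags, est.msd, yerr=est.msd_se, fmt="o", label=label
            )
            xs = np.linspace(0, est.lags.max(), 50)
            ax.plot(1e3 * xs, est.intercept + 4 * est.d * xs, "--")
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel(r"MSD ($\mu m^2$)")
        ax.legend()
        return ax
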
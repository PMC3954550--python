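"""Synthetic CCD frames and 2D Gaussian peak fitting.

Closes the loop to raw-image level: molecules are rendered as
pixel-integrated 2D Gaussians with Poisson shot noise on top of a noisy
background, and localizations are recovered by nonlinear least-squares
fitting of candidate maxima.  The per-axis localization accuracy of a fit
is quoted as FWHM/sqrt(photons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf
from skimage.feature import peak_local_max

FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

PEAKFIT_COLUMNS = [
    "cell",
    "series",
    "frame",
    "x_um",
    "y_um",
    "photons",
    "snr",
    "accuracy_um",
]


@dataclass
class FrameStack:
    """A stack of camera frames (counts) with its calibration."""

    data: np.ndarray  # (n_frames, ny, nx)
    pixel_size: float  # µm
    background_mean: float  # counts
    background_sd: float  # counts

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be (n_frames, ny, nx)")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.clip(self.data, 0, 65535).astype(np.uint16))

    @classmethod
    def read_tiff(cls, path, pixel_size: float, background_mean: float,
                  background_sd: float) -> "FrameStack":
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        return cls(data, pixel_size, background_mean, background_sd)


def _integrated_gaussian(
    xg: np.ndarray, yg: np.ndarray, x0: float, y0: float, sigma: float, photons: float
) -> np.ndarray:
    """Photon expectation per pixel for a 2D Gaussian emitter.

    ``xg``/``yg`` are pixel-left-edge coordinates (units of the grid); the
    pixel spans one unit.
    """
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xg + 1 - x0) / s) - erf((xg - x0) / s))
    fy = 0.5 * (erf((yg + 1 - y0) / s) - erf((yg - y0) / s))
    return photons * fy[:, None] * fx[None, :]


def render_frames(
    positions: pd.DataFrame,
    *,
    n_frames: int | None = None,
    shape: tuple[int, int] = (50, 50),
    pixel_size: float = 0.220,
    psf_sigma: float = 0.17,
    photons_per_molecule: float = 100.0,
    background_mean: float = 10.0,
    background_sd: float = 1.0,
    shot_noise: bool = True,
    seed: int = 0,
) -> FrameStack:
    """Render ground-truth positions into a synthetic frame stack.

    ``positions`` needs columns frame/x_um/y_um (µm, origin at the field
    corner).  Each molecule contributes a pixel-integrated 2D Gaussian of
    ``photons_per_molecule`` expected photons (PSF SD ``psf_sigma`` µm);
    the detected counts are Poisson draws of signal + background plus
    Gaussian read noise of SD ``background_sd``.  With ``shot_noise=False``
    the noiseless expectation is returned.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    if n_frames is None:
        n_frames = int(positions["frame"].max()) + 1 if len(positions) else 1
    ny, nx = shape
    sigma_px = psf_sigma / pixel_size
    halfwin = int(math.ceil(5 * sigma_px)) + 1

    signal = np.zeros((n_frames, ny, nx))
    for frame, sub in positions.groupby("frame"):
        f = int(frame)
        if f >= n_frames:
            continue
        for x_um, y_um in sub[["x_um", "y_um"]].to_numpy():
            xpx, ypx = x_um / pixel_size, y_um / pixel_size
            x_lo = max(int(xpx) - halfwin, 0)
            x_hi = min(int(xpx) + halfwin + 1, nx)
            y_lo = max(int(ypx) - halfwin, 0)
            y_hi = min(int(ypx) + halfwin + 1, ny)
            if x_lo >= x_hi or y_lo >= y_hi:
                continue
            signal[f, y_lo:y_hi, x_lo:x_hi] += _integrated_gaussian(
                np.arange(x_lo, x_hi, dtype=float),
                np.arange(y_lo, y_hi, dtype=float),
                xpx,
                ypx,
                sigma_px,
                photons_per_molecule,
            )

    if shot_noise:
        data = rng.poisson(signal + background_mean).astype(float)
        if background_sd > 0:
            data += rng.normal(0.0, background_sd, data.shape)
        data = np.clip(data, 0.0, None)
        # total background variation: Poisson shot noise plus read noise
        total_sd = math.sqrt(background_mean + background_sd**2)
    else:
        data = signal + background_mean
        total_sd = background_sd
    return FrameStack(data, pixel_size, background_mean, total_sd)


def estimate_background(frame: np.ndarray, margin: int = 2) -> tuple[float, float]:
    """Robust background mean/SD from the frame margins (median, MAD)."""
    border = np.concatenate(
        [
            frame[:margin].ravel(),
            frame[-margin:].ravel(),
            frame[margin:-margin, :margin].ravel(),
            frame[margin:-margin, -margin:].ravel(),
        ]
    )
    med = float(np.median(border))
    mad = float(np.median(np.abs(border - med)))
    return med, max(1.4826 * mad, 1e-6)


def _fit_window(
    window: np.ndarray,
    origin: tuple[int, int],
    guesses: list[tuple[float, float]],
    sigma_guess: float,
    bg_guess: float,
):
    """Least-squares fit of 1 or 2 integrated Gaussians plus a flat offset."""
    ny, nx = window.shape
    y0s, x0s = origin
    xg = np.arange(x0s, x0s + nx, dtype=float)
    yg = np.arange(y0s, y0s + ny, dtype=float)
    k = len(guesses)

    def model(p):
        out = np.full(window.shape, p[-1])
        for i in range(k):
            x0, y0, n, s = p[4 * i : 4 * i + 4]
            out += _integrated_gaussian(xg, yg, x0, y0, s, n)
        return out

    def resid(p):
        return (model(p) - window).ravel()

    p0, lo, hi = [], [], []
    amp0 = max(window.max() - bg_guess, 1.0) * 2 * math.pi * sigma_guess**2
    for gx, gy in guesses:
        p0 += [gx, gy, amp0, sigma_guess]
        lo += [x0s - 1, y0s - 1, 1e-3, 0.3]
        hi += [x0s + nx + 1, y0s + ny + 1, np.inf, max(nx, ny)]
    p0.append(bg_guess)
    lo.append(-np.inf)
    hi.append(np.inf)
    sol = least_squares(resid, p0, bounds=(lo, hi), max_nfev=400)
    return sol


def fit_peaks(
    stack: FrameStack,
    threshold: float = 4.0,
    *,
    psf_sigma_guess: float | None = None,
    cell: int = 0,
    series: int = 0,
) -> pd.DataFrame:
    """Detect and fit single-molecule peaks in every frame.

    Candidate local maxima above ``threshold`` background SDs (after
    background subtraction) are fitted with an offset pixel-integrated 2D
    Gaussian; candidates closer than twice the expected FWHM are fitted
    jointly as two components.  Non-converged or sub-threshold fits are
    dropped.  Returns a table with positions (µm), photon counts, SNR
    (fitted peak height over background SD) and the per-axis accuracy
    FWHM/sqrt(photons).
    """
    px = stack.pixel_size
    sigma_guess = (psf_sigma_guess or 0.17) / px
    pair_dist = 2.0 * FWHM_FACTOR * sigma_guess
    halfwin = max(int(math.ceil(3 * sigma_guess)), 3)

    rows = []
    for f in range(stack.n_frames):
        frame = stack.data[f]
        bg_mean, bg_sd = stack.background_mean, stack.background_sd
        if not np.isfinite(bg_mean) or bg_mean == 0:
            bg_mean, bg_sd = estimate_background(frame)
        coords = peak_local_max(
            frame - bg_mean,
            min_distance=2,
            threshold_abs=threshold * bg_sd,
            exclude_border=False,
        )
        if coords.size == 0:
            continue
        # group candidates that must be fit jointly (≤ 2 components)
        used = np.zeros(len(coords), dtype=bool)
        groups: list[list[int]] = []
        for i in range(len(coords)):
            if used[i]:
                continue
            grp = [i]
            used[i] = True
            for j in range(i + 1, len(coords)):
                if used[j] or len(grp) == 2:
                    continue
                if np.hypot(*(coords[i] - coords[j])) < pair_dist:
                    grp.append(j)
                    used[j] = True
            groups.append(grp)

        ny, nx = frame.shape
        for grp in groups:
            cy = int(round(coords[grp, 0].mean()))
            cx = int(round(coords[grp, 1].mean()))
            y_lo, y_hi = max(cy - halfwin, 0), min(cy + halfwin + 1, ny)
            x_lo, x_hi = max(cx - halfwin, 0), min(cx + halfwin + 1, nx)
            window = frame[y_lo:y_hi, x_lo:x_hi]
            guesses = [(coords[j, 1] + 0.5, coords[j, 0] + 0.5) for j in grp]
            sol = _fit_window(window, (y_lo, x_lo), guesses, sigma_guess, bg_mean)
            if not sol.success:
                continue
            for i in range(len(grp)):
                x0, y0, photons, s = sol.x[4 * i : 4 * i + 4]
                if photons <= 0 or s <= 0:
                    continue
                # implausible widths are noise spikes or unresolved blobs
                if not 0.45 * sigma_guess <= s <= 2.5 * sigma_guess:
                    continue
                peak_height = photons / (2 * math.pi * s**2)
                if peak_height < threshold * bg_sd:
                    continue
                if not (x_lo - 1 <= x0 <= x_hi + 1 and y_lo - 1 <= y0 <= y_hi + 1):
                    continue
                width_um = s * px
                fwhm_um = FWHM_FACTOR * width_um
                rows.append(
                    {
                        "cell": cell,
                        "series": series,
                        "frame": f,
                        "x_um": x0 * px,
                        "y_um": y0 * px,
                        "photons": photons,
                        "snr": peak_height / bg_sd,
                        "accuracy_um": fwhm_um / math.sqrt(photons),
                        "width_um": width_um,
                        "amplitude": peak_height,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=PEAKFIT_COLUMNS + ["width_um", "amplitude"],
    )


def write_peak_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, columns=PEAKFIT_COLUMNS)
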
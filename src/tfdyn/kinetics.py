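"""Three-state binding/diffusion kinetics shared by both simulators.

A nuclear transcription factor is modelled as switching between one freely
diffusing state and two immobile, chromatin-bound states ("short" and "long")
with exponentially distributed residence times.  At equilibrium the state
occupancies equal the fraction sizes of the model, which is what both the
single-molecule and the FRAP observables report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

# state codes used throughout the package
FREE, SHORT, LONG = 0, 1, 2

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class MotionModel:
    """Equilibrium description of the three-state mobility model.

    Parameters
    ----------
    fraction_free, fraction_short, fraction_long :
        Stationary occupancies of the diffusing and the two bound states.
        Must be non-negative and sum to 1 (tolerance 1e-9).
    d_free :
        Diffusion coefficient of the free state, µm²/s.
    d_bound :
        Apparent diffusion coefficient of bound molecules (slow chromatin
        motion), µm²/s.  Must not exceed ``d_free``.
    tau_short, tau_long :
        Mean residence times of the two bound states, s.  ``tau_short`` may
        not exceed ``tau_long`` when both bound fractions are populated.
        ``math.inf`` is allowed (permanently bound, e.g. a fixed-cell
        control).
    """

    fraction_free: float
    fraction_short: float
    fraction_long: float
    d_free: float
    d_bound: float = 0.03
    tau_short: float = 0.7
    tau_long: float = 2.3

    def __post_init__(self) -> None:
        f = (self.fraction_free, self.fraction_short, self.fraction_long)
        if any(x < 0 for x in f):
            raise ValueError("fractions must be non-negative")
        if abs(sum(f) - 1.0) > _FRACTION_TOL:
            raise ValueError(f"fractions must sum to 1, got {sum(f)!r}")
        if self.d_free < 0 or self.d_bound < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.d_bound > self.d_free:
            raise ValueError("d_bound must not exceed d_free")
        if self.tau_short <= 0 or self.tau_long <= 0:
            raise ValueError("residence times must be positive")
        if (
            self.fraction_short > 0
            and self.fraction_long > 0
            and self.tau_short > self.tau_long
        ):
            raise ValueError("tau_short must not exceed tau_long")

    @property
    def fractions(self) -> np.ndarray:
        return np.array(
            [self.fraction_free, self.fraction_short, self.fraction_long]
        )

    @property
    def fraction_bound(self) -> float:
        return self.fraction_short + self.fraction_long

    def diffusion_of_state(self) -> np.ndarray:
        """Per-state diffusion coefficient, indexed by state code."""
        return np.array([self.d_free, self.d_bound, self.d_bound])


@dataclass(frozen=True)
class TransitionRates:
    """First-order rates of the three-state chain, 1/s."""

    k_free_short: float
    k_free_long: float
    k_short_free: float
    k_long_free: float

    def as_matrix(self) -> np.ndarray:
        """Generator matrix Q (rows sum to zero), states (free, short, long)."""
        q = np.array(
            [
                [0.0, self.k_free_short, self.k_free_long],
                [self.k_short_free, 0.0, 0.0],
                [self.k_long_free, 0.0, 0.0],
            ]
        )
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


def rates_from_fractions(model: MotionModel) -> TransitionRates:
    """Transition rates whose stationary distribution equals the model fractions.

    Unbinding rates are the reciprocal residence times; binding rates follow
    from detailed balance of the star-shaped chain:
    ``k_free->s = (fraction_short / fraction_free) / tau_short`` (and the
    analogue for the long state).

    Raises
    ------
    ValueError
        If ``fraction_free`` is zero while a bound state has a finite
        residence time: such a chain cannot hold its occupancy and is not
        simulable.  ``fraction_free == 0`` with infinite residence times is
        accepted (permanently immobile population).
    """
    ff = model.fraction_free
    if ff == 0.0:
        finite = (model.fraction_short > 0 and math.isfinite(model.tau_short)) or (
            model.fraction_long > 0 and math.isfinite(model.tau_long)
        )
        if finite:
            raise ValueError(
                "fraction_free = 0 with a finite residence time has no "
                "stationary chain; use infinite residence times for a "
                "permanently bound population"
            )
        return TransitionRates(0.0, 0.0, 0.0, 0.0)

    def _pair(frac: float, tau: float) -> tuple[float, float]:
        if frac == 0.0 or math.isinf(tau):
            # unreachable or absorbing state: no flux either way
            k_off = 0.0 if math.isinf(tau) else 1.0 / tau
            k_on = 0.0 if math.isinf(tau) else (frac / ff) / tau
            return k_on, k_off
        return (frac / ff) / tau, 1.0 / tau

    k_fs, k_sf = _pair(model.fraction_short, model.tau_short)
    k_fl, k_lf = _pair(model.fraction_long, model.tau_long)
    return TransitionRates(k_fs, k_fl, k_sf, k_lf)


def transition_matrix(rates: TransitionRates, dt: float) -> np.ndarray:
    """Exact state-transition probabilities over an interval dt (matrix exp)."""
    return expm(rates.as_matrix() * dt)


def stationary_distribution(rates: TransitionRates) -> np.ndarray:
    """Stationary distribution of the chain (left null vector of Q).

    For a disconnected chain (zero rates) the distribution is not unique and
    the free state gets all mass; callers with degenerate models should use
    the model fractions directly.
    """
    q = rates.as_matrix()
    # solve pi Q = 0, sum(pi) = 1
    a = np.vstack([q.T, np.ones(3)])
    b = np.zeros(4)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / pi.sum()
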
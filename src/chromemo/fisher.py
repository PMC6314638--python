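"""Fisher-information metric on the color circle and the uniform rescaling.

For the Gaussian response model with mean mu(t) = t + delta(t) and variance
sigma2(t), the Fisher information is

    J(t) = (mu'(t) / sigma(t))**2 + 0.5 * (sigma2'(t) / sigma2(t))**2

with derivatives taken analytically from the fitted trigonometric series.
sqrt(J) dt is a line element: its integral between two hues is a distance
expressing how discriminable they are in memory, and reparametrizing the
circle so that the integrand is constant yields a scale on which every
equal step is equally memorable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromemo.circstats import wrap_angle
from chromemo.errormodel import TrigFit

__all__ = [
    "FisherProfile",
    "fisher_information",
    "fisher_distance",
    "uniform_scale",
    "prominent_extrema",
    "term_decomposition",
]


@dataclass
class FisherProfile:
    """Fisher information sampled on a uniform circular grid.

    ``grid`` covers (−π, π] (ascending, last point π).  ``term1`` and
    ``term2`` are the mean-derivative and variance-derivative summands;
    ``J = term1 + term2`` pointwise.  After :func:`uniform_scale`, ``s``
    holds the cumulative uniform coordinate and ``cnst`` its normalization.
    """

    grid: np.ndarray
    J: np.ndarray
    term1: np.ndarray
    term2: np.ndarray
    s: np.ndarray | None = None
    cnst: float | None = None
    extrema: dict = field(default_factory=dict)

    @property
    def J_mean(self) -> float:
        return float(np.mean(self.J))

    @property
    def J_sd(self) -> float:
        return float(np.std(self.J))

    @property
    def step(self) -> float:
        return 2.0 * np.pi / len(self.grid)

    def circumference(self) -> float:
        """Total Fisher length of the circle, the circular sum of sqrt(J) dt."""
        return float(np.sum(np.sqrt(self.J)) * self.step)

    def to_frame(self) -> pd.DataFrame:
        data = {"t_rad": self.grid, "J": self.J,
                "term1": self.term1, "term2": self.term2}
        if self.s is not None:
            data["s_rad"] = self.s
        return pd.DataFrame(data)


def fisher_information(mu_fit: TrigFit, sigma2_fit: TrigFit,
                       grid_size: int = 4096) -> FisherProfile:
    """Evaluate J(t) on a uniform grid from the two fitted profiles.

    ``mu_fit`` is the mean-error (delta) fit, so mu'(t) = 1 + delta'(t);
    ``sigma2_fit`` must be positive on the whole grid.
    """
    grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False) + 2.0 * np.pi / grid_size
    sigma2 = sigma2_fit(grid)
    if np.any(sigma2 <= 0):
        bad = grid[int(np.argmin(sigma2))]
        raise ValueError(f"variance profile nonpositive at t={bad:.4f}")
    mu_prime = 1.0 + mu_fit.deriv(grid)
    sigma2_prime = sigma2_fit.deriv(grid)
    term1 = mu_prime**2 / sigma2
    term2 = 0.5 * (sigma2_prime / sigma2) ** 2
    return FisherProfile(grid=grid, J=term1 + term2, term1=term1, term2=term2)


def _cumulative_length(profile: FisherProfile) -> np.ndarray:
    """Trapezoid cumulative of sqrt(J) from t=−π to each grid point."""
    sq = np.sqrt(profile.J)
    # prepend the periodic value at −π (== value at π, the last grid point)
    sq_ext = np.concatenate([[sq[-1]], sq])
    h = profile.step
    return np.cumsum(0.5 * (sq_ext[:-1] + sq_ext[1:])) * h


def fisher_distance(profile: FisherProfile, t1: float, t2: float,
                    shorter_arc: bool = True) -> float:
    """Integral of sqrt(J) between two hues (shorter arc by default)."""
    cum = _cumulative_length(profile)
    total = cum[-1]
    t_ext = np.concatenate([[-np.pi], profile.grid])
    cum_ext = np.concatenate([[0.0], cum])

    def arc(t):
        return float(np.interp(wrap_angle(t), t_ext, cum_ext))

    d = abs(arc(t2) - arc(t1))
    return min(d, total - d) if shorter_arc else d


def uniform_scale(profile: FisherProfile) -> FisherProfile:
    """Fill in the mnemonically uniform coordinate s(t).

    s is the cumulative sqrt(J) integral from −π, scaled by
    cnst**(-1/2) with cnst = (circumference / 2π)², so that s maps (−π, π]
    onto (−π, π] and the reparametrized information is the constant cnst.
    """
    cum = _cumulative_length(profile)
    total = cum[-1]
    if total <= 0:
        raise ValueError("degenerate scale: J vanishes identically")
    cnst = (total / (2.0 * np.pi)) ** 2
    s = -np.pi + cum / np.sqrt(cnst)
    profile.s = s
    profile.cnst = float(cnst)
    return profile


def _circular_local_max(values: np.ndarray) -> np.ndarray:
    left = np.roll(values, 1)
    right = np.roll(values, -1)
    return np.flatnonzero((values > left) & (values > right))


def prominent_extrema(profile: FisherProfile) -> dict:
    """Locations of prominent maxima of J and of 1/J.

    A maximum qualifies if it is a circular-grid local maximum and at least
    mean + 2 SD of the respective profile (J for maxima, 1/J for minima).
    """
    J = profile.J
    inv = 1.0 / J
    thr_max = np.mean(J) + 2.0 * np.std(J)
    thr_min = np.mean(inv) + 2.0 * np.std(inv)
    maxima = profile.grid[[i for i in _circular_local_max(J) if J[i] >= thr_max]]
    minima = profile.grid[[i for i in _circular_local_max(inv) if inv[i] >= thr_min]]
    result = {"maxima": maxima, "minima": minima,
              "threshold_max": float(thr_max), "threshold_min": float(thr_min)}
    profile.extrema = result
    return result


def term_decomposition(profile: FisherProfile, mu_fit: TrigFit | None = None,
                       sigma2_fit: TrigFit | None = None) -> dict:
    """Scalar ratios summarizing which parts of J dominate.

    ``first_second``: grid average of term1 over grid average of term2
    (mean-derivative vs variance-derivative contribution).  When the fits
    are supplied, ``one_delta`` additionally compares, inside term1, the
    contribution of the unit slope against that of delta'(t).  Vanishing
    denominators are reported as ``inf``.
    """
    mean2 = float(np.mean(profile.term2))
    out = {}
    out["first_second"] = float(np.mean(profile.term1)) / mean2 if mean2 > 0 else np.inf
    if mu_fit is not None and sigma2_fit is not None:
        sigma2 = sigma2_fit(profile.grid)
        dprime = mu_fit.deriv(profile.grid)
        unit_part = float(np.mean(1.0 / sigma2))
        delta_part = float(np.mean(dprime**2 / sigma2))
        out["one_delta"] = unit_part / delta_part if delta_part > 0 else np.inf
    return out
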
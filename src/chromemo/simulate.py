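"""Synthetic players for the continuous-report color task.

Each simulated player is described by a mean-response function mu(t) and a
variance function sigma2(t); responses to a target t are mu(t) plus Gaussian
noise of SD sigma(t), wrapped onto the circle.  Strategies range from fully
unbiased (mu(t) = t) through mixed to fully categorical (mu(t) equal to the
focal color of the target's category).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromemo.circstats import RESPONSE_COLUMNS, ResponseSet, wrap_angle
from chromemo.errormodel import eval_trig

__all__ = [
    "PlayerProfile",
    "make_profile",
    "make_trig_profile",
    "simulate_responses",
    "make_null_cohort",
    "default_targets",
]

#: study-like defaults: games per player drawn uniformly from this range
DEFAULT_GAMES_RANGE = (10, 26)


def default_targets(n_targets: int = 32) -> np.ndarray:
    """Equally spaced target angles starting at 0, wrapped to (−π, π]."""
    return np.sort(wrap_angle(2.0 * np.pi * np.arange(n_targets) / n_targets))


@dataclass
class PlayerProfile:
    """Ground-truth response model of one simulated player.

    ``delta_coeffs`` define a smooth trigonometric bias delta(t) (order
    inferred from the length, 2m+1); ``sigma2_coeffs`` likewise define
    sigma2(t), which must be positive everywhere.  For the categorical and
    mixed strategies the bias is instead a staircase built from
    ``focal_colors``: mu(t) = (1−λ)·t + λ·focal(category(t)), with category
    boundaries at circular midpoints between adjacent focal colors (an exact
    boundary belongs to the category on its +t side).
    """

    delta_coeffs: np.ndarray = field(default_factory=lambda: np.zeros(1))
    sigma2_coeffs: np.ndarray = field(default_factory=lambda: np.array([0.17**2]))
    strategy: str = "unbiased"
    mixing_weight: float = 0.0
    focal_colors: np.ndarray | None = None
    lapse_rate: float = 0.0
    noise: str = "gaussian"  # or "vonmises"

    def __post_init__(self):
        self.delta_coeffs = np.asarray(self.delta_coeffs, dtype=float)
        self.sigma2_coeffs = np.asarray(self.sigma2_coeffs, dtype=float)
        for name in ("delta_coeffs", "sigma2_coeffs"):
            if len(getattr(self, name)) % 2 == 0:
                raise ValueError(f"{name} must have odd length (b0, a1, b1, ...)")
        if self.strategy not in ("unbiased", "categorical", "mixed"):
            raise ValueError(f"unknown strategy: {self.strategy!r}")
        if self.strategy in ("categorical", "mixed"):
            if self.focal_colors is None or len(self.focal_colors) < 1:
                raise ValueError("categorical/mixed strategies need focal colors")
            self.focal_colors = np.sort(wrap_angle(np.asarray(self.focal_colors,
                                                              dtype=float)))
        if not 0.0 <= self.mixing_weight <= 1.0:
            raise ValueError("mixing weight must lie in [0, 1]")
        grid = np.linspace(-np.pi, np.pi, 2048, endpoint=False)
        if np.any(self.sigma2(grid) <= 0):
            raise ValueError("sigma2(t) must be positive everywhere")

    @property
    def m_delta(self) -> int:
        return (len(self.delta_coeffs) - 1) // 2

    def delta(self, t):
        return eval_trig(self.delta_coeffs, self.m_delta, t)

    def sigma2(self, t):
        m = (len(self.sigma2_coeffs) - 1) // 2
        return eval_trig(self.sigma2_coeffs, m, t)

    def sigma(self, t):
        return np.sqrt(self.sigma2(t))

    def _focal_of(self, t):
        """Focal color of the category containing each angle in ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        foci = self.focal_colors
        k = len(foci)
        if k == 1:
            return np.full_like(t, foci[0])
        # circular boundaries at midpoints between consecutive foci
        nxt = np.roll(foci, -1)
        gaps = np.mod(nxt - foci, 2.0 * np.pi)
        bounds = wrap_angle(foci + gaps / 2.0)  # bounds[i] ends category of foci[i]
        order = np.argsort(bounds)
        bounds_sorted = bounds[order]
        foci_sorted = foci[order]
        # angle belongs to the category whose upper boundary is the first
        # bound strictly above it; an exact boundary goes to the +t side
        idx = np.searchsorted(bounds_sorted, t, side="right") % k
        return foci_sorted[idx]

    def mu(self, t):
        """Mean response as a function of the target angle (unwrapped)."""
        scalar = np.ndim(t) == 0
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if self.strategy == "unbiased":
            base = t_arr + np.atleast_1d(self.delta(t_arr))
        else:
            lam = 1.0 if self.strategy == "categorical" else self.mixing_weight
            # mix along the short arc from t to its focal color
            base = t_arr + lam * wrap_angle(self._focal_of(t_arr) - t_arr)
        return float(base[0]) if scalar else base


def make_profile(strategy: str, sigma0: float = 0.17,
                 delta_coeffs=None, sigma2_coeffs=None,
                 mixing_weight: float = 0.5, focal_colors=None,
                 lapse_rate: float = 0.0, noise: str = "gaussian") -> PlayerProfile:
    """Build a :class:`PlayerProfile` for one of the named strategies.

    ``unbiased`` forces delta(t) ≡ 0; for a smooth nonzero bias construct a
    profile with :func:`make_trig_profile` instead.
    """
    if sigma2_coeffs is None:
        sigma2_coeffs = np.array([sigma0**2])
    if strategy == "unbiased":
        if delta_coeffs is not None and np.any(np.asarray(delta_coeffs) != 0):
            raise ValueError("unbiased strategy has delta(t) = 0")
        delta_coeffs = np.zeros(1)
    elif delta_coeffs is not None:
        raise ValueError("categorical/mixed strategies define mu via focal colors")
    else:
        delta_coeffs = np.zeros(1)
    lam = 1.0 if strategy == "categorical" else (
        mixing_weight if strategy == "mixed" else 0.0)
    return PlayerProfile(delta_coeffs=delta_coeffs, sigma2_coeffs=sigma2_coeffs,
                         strategy=strategy, mixing_weight=lam,
                         focal_colors=focal_colors, lapse_rate=lapse_rate,
                         noise=noise)


def make_trig_profile(delta_coeffs, sigma2_coeffs=None,
                      sigma0: float = 0.17, **kwargs) -> PlayerProfile:
    """Profile with a smooth trigonometric bias delta(t)."""
    if sigma2_coeffs is None:
        sigma2_coeffs = np.array([sigma0**2])
    return PlayerProfile(delta_coeffs=np.asarray(delta_coeffs, dtype=float),
                         sigma2_coeffs=np.asarray(sigma2_coeffs, dtype=float),
                         strategy="unbiased", **kwargs)


def simulate_responses(profile: PlayerProfile, targets, n_games: int,
                       seed: int | None = None, player_id: str = "sim") -> ResponseSet:
    """Simulate ``n_games`` runs; each run presents every target once in
    random order.  Responses are mu(t) plus noise of SD sigma(t), wrapped
    into (−π, π]."""
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise ValueError("empty target list")
    if n_games < 1:
        raise ValueError("n_games must be >= 1")
    rng = np.random.default_rng(seed)
    target_idx = np.arange(len(targets))
    rows = []
    for game in range(n_games):
        order = rng.permutation(len(targets))
        for trial, j in enumerate(order):
            t = targets[j]
            if profile.lapse_rate > 0 and rng.random() < profile.lapse_rate:
                r = rng.uniform(-np.pi, np.pi)
            else:
                mu = profile.mu(t)
                sd = profile.sigma(t)
                if profile.noise == "vonmises":
                    kappa = np.inf if sd == 0 else 1.0 / sd**2
                    r = mu if sd == 0 else rng.vonmises(0.0, kappa) + mu
                else:
                    r = mu + (sd * rng.standard_normal() if sd > 0 else 0.0)
            rows.append((player_id, game, trial, int(target_idx[j]), t,
                         wrap_angle(r)))
    df = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    return ResponseSet(df)


def make_null_cohort(n_players: int, n_games, sigma0: float = 0.17,
                     seed: int | None = None, targets=None) -> list[ResponseSet]:
    """Cohort of unbiased players with constant sigma; used to calibrate the
    attractor screen's false-positive rate.

    ``n_games`` may be an int (same for every player) or an inclusive
    (low, high) range sampled uniformly per player.
    """
    if targets is None:
        targets = default_targets()
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_players):
        if isinstance(n_games, (tuple, list)):
            ng = int(rng.integers(n_games[0], n_games[1] + 1))
        else:
            ng = int(n_games)
        profile = make_profile("unbiased", sigma0=sigma0)
        cohort.append(simulate_responses(profile, targets, ng,
                                         seed=int(rng.integers(2**31)),
                                         player_id=f"null{i:02d}"))
    return cohort


def concat_cohort(cohort: list[ResponseSet]) -> ResponseSet:
    """Stack per-player response sets into one table."""
    return ResponseSet(pd.concat([rs.df for rs in cohort], ignore_index=True))
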
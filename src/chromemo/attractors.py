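"""Attractor / repulsor detection and significance screening.

An attractor is a zero of the fitted mean-error profile crossed with
negative slope (nearby targets are pulled toward it); a repulsor is a zero
crossed with positive slope (a category boundary).  Candidate zeros are
screened against the coefficient covariance of the fit: a candidate is
significant only if the bulk of the coefficient ensemble reproduces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from chromemo.circstats import wrap_angle
from chromemo.errormodel import TrigFit, trig_basis

__all__ = [
    "Candidate",
    "AttractorReport",
    "UniformityResult",
    "find_candidates",
    "significance_screen",
    "cohort_location_uniformity",
]

DEGENERATE_SLOPE_TOL = 1e-6


@dataclass
class Candidate:
    location: float  # in (−π, π]
    slope: float
    kind: str  # "attractor" (slope < 0) or "repulsor" (slope > 0)
    degenerate: bool = False


@dataclass
class AttractorEntry:
    location: float
    kind: str
    slope: float
    fraction: float
    significant: bool


@dataclass
class AttractorReport:
    entries: list
    level: float
    n_samples: int
    window: float
    seed: int | None
    mode: str = "match"

    @property
    def significant(self) -> list:
        return [e for e in self.entries if e.significant]

    def count(self, kind: str, significant_only: bool = True) -> int:
        pool = self.significant if significant_only else self.entries
        return sum(1 for e in pool if e.kind == kind)

    def to_frame(self, player_id=None) -> pd.DataFrame:
        frame = pd.DataFrame(
            [{"location_rad": e.location, "kind": e.kind, "slope": e.slope,
              "significance_fraction": e.fraction, "significant": e.significant}
             for e in self.entries]
        )
        if player_id is not None:
            frame.insert(0, "player_id", player_id)
        return frame


def _bisect_zero(fit: TrigFit, lo: float, hi: float, tol: float = 1e-8) -> float:
    flo = fit(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fmid = fit(mid)
        if hi - lo < tol:
            return mid
        if (flo <= 0) == (fmid <= 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_candidates(fit: TrigFit, grid_size: int = 4096,
                    include_degenerate: bool = False) -> list[Candidate]:
    """Locate all zeros of the fitted profile on (−π, π].

    Zeros are bracketed by sign changes on a uniform grid (periodic closure
    included) and refined by bisection to 1e-8.  Each zero is labeled by the
    sign of the derivative there; near-flat crossings (|slope| below
    :data:`DEGENERATE_SLOPE_TOL`) are excluded unless requested.
    """
    if fit.kind != "delta":
        raise ValueError("candidates are defined on a mean-error (delta) fit")
    grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False)
    vals = fit(grid)
    out = []
    for i in range(grid_size):
        j = (i + 1) % grid_size
        v0, v1 = vals[i], vals[j]
        if v0 == 0.0 and v1 == 0.0:
            continue  # flat stretch, no isolated crossing here
        if (v0 <= 0) != (v1 <= 0):
            lo = grid[i]
            hi = grid[j] if j != 0 else np.pi
            z = wrap_angle(_bisect_zero(fit, lo, hi))
            slope = fit.deriv(z)
            degenerate = abs(slope) < DEGENERATE_SLOPE_TOL
            kind = "attractor" if slope < 0 else "repulsor"
            if degenerate and not include_degenerate:
                continue
            out.append(Candidate(location=z, slope=float(slope), kind=kind,
                                 degenerate=degenerate))
    return out


def significance_screen(fit: TrigFit, level: float = 0.95,
                        n_samples: int = 10_000, window: float = 0.25,
                        seed: int | None = 0, mode: str = "both",
                        grid_size: int = 1024) -> AttractorReport:
    """Screen candidate zeros against the coefficient ensemble.

    The fitted coefficients carry a multivariate Gaussian uncertainty; the
    screen asks whether the whole highest-probability set capturing a
    fraction ``level`` of that distribution (the Mahalanobis ellipsoid)
    still exhibits the candidate.  Two operationalizations are available:

    * ``slope`` — the derivative at the candidate location keeps the
      candidate's sign over the entire ellipsoid.  The derivative is linear
      in the coefficients, so the worst case is closed-form: significant iff
      ``|slope| > r * sd(slope)`` with ``r`` the level-dependent Mahalanobis
      radius.
    * ``match`` — every Monte-Carlo sample retained inside the ellipsoid
      has a zero crossing of the same slope sign within ``±window`` of the
      candidate.

    ``mode="both"`` (default) requires the two simultaneously.  Unanimity
    over the ellipsoid is essential: a fraction-of-samples rule is far too
    permissive, because near-null fits produce sign-matching wiggles in
    most samples, and it floods a bias-free cohort with spurious hits.

    The reported significance fraction is the share of retained samples
    fulfilling the (mode-specific) condition.
    """
    candidates = find_candidates(fit)
    if mode not in ("slope", "match", "both"):
        raise ValueError(f"unknown screening mode: {mode!r}")
    rng = np.random.default_rng(seed)
    entries = []
    if not candidates:
        return AttractorReport(entries=[], level=level, n_samples=n_samples,
                               window=window, seed=seed, mode=mode)

    dim = len(fit.q)
    z = rng.standard_normal((n_samples, dim))
    inside = np.sum(z**2, axis=1) <= stats.chi2.ppf(level, dim)
    C = 0.5 * (fit.C + fit.C.T)
    evals, evecs = np.linalg.eigh(C)
    if np.min(evals) < -1e-10 * max(1.0, np.max(np.abs(evals))):
        raise ValueError("coefficient covariance is not positive semidefinite")
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    Q = fit.q[None, :] + z[inside] @ root.T
    radius = np.sqrt(stats.chi2.ppf(level, dim))

    if mode in ("match", "both"):
        grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False)
        D = Q @ trig_basis(grid, fit.m).T  # (n_kept, grid_size)
        pos = D > 0
        nxt = np.roll(pos, -1, axis=1)
        down = pos & ~nxt   # crossing + -> −: negative slope (attractor)
        up = ~pos & nxt     # crossing − -> +: positive slope (repulsor)

    from chromemo.errormodel import trig_basis_deriv

    for cand in candidates:
        ell = trig_basis_deriv(cand.location, fit.m)[0]
        sd = float(np.sqrt(ell @ C @ ell))
        slope_ok = abs(cand.slope) > radius * sd  # ellipsoid worst case
        if mode == "slope":
            d = Q @ ell
            ok = d < 0 if cand.kind == "attractor" else d > 0
            frac = float(np.mean(ok))
            significant = slope_ok
        else:
            dist = np.abs(wrap_angle(grid - cand.location))
            mask = dist <= window
            cross = down if cand.kind == "attractor" else up
            ok = np.any(cross[:, mask], axis=1)
            frac = float(np.mean(ok))
            match_ok = bool(np.all(ok))
            significant = match_ok if mode == "match" else (match_ok and slope_ok)
        entries.append(AttractorEntry(cand.location, cand.kind, cand.slope,
                                      frac, bool(significant)))
    return AttractorReport(entries=entries, level=level, n_samples=n_samples,
                           window=window, seed=seed, mode=mode)


@dataclass
class UniformityResult:
    """One-sample KS test of angular locations against uniformity."""

    statistic: float | None
    p_value: float | None
    ecdf_x: np.ndarray = field(default_factory=lambda: np.array([]))
    ecdf_y: np.ndarray = field(default_factory=lambda: np.array([]))
    untestable: bool = False
    n: int = 0


def cohort_location_uniformity(locations) -> UniformityResult:
    """KS test of pooled locations (mapped to (0, 1]) against uniform."""
    loc = np.sort(wrap_angle(np.asarray(locations, dtype=float)))
    n = len(loc)
    if n < 5:
        return UniformityResult(statistic=None, p_value=None, untestable=True, n=n)
    u = (loc + np.pi) / (2.0 * np.pi)
    stat, p = stats.kstest(u, "uniform")
    ecdf_y = np.arange(1, n + 1) / n
    return UniformityResult(statistic=float(stat), p_value=float(p),
                            ecdf_x=loc, ecdf_y=ecdf_y, n=n)
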
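"""Trigonometric-series models of the mean-error and variance profiles.

A periodic profile f(t) is expanded as

    f(t) = b0 + sum_{j=1..m} [ a_j sin(j t) + b_j cos(j t) ]

with coefficient vector q = (b0, a1, b1, ..., am, bm).  Because the model is
linear in q, weighted least squares coincides with Gaussian maximum
likelihood, the coefficient covariance is the inverse of the weighted
normal-equations matrix, and the weighted residual sum is a chi-square
variate whose upper tail drives model-order selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from chromemo.circstats import wrap_angle

__all__ = [
    "TrigFit",
    "CohortBiasResult",
    "eval_trig",
    "trig_basis",
    "trig_basis_deriv",
    "fit_coefficients",
    "model_p_value",
    "select_order",
    "fit_variance_profile",
    "cohort_bias_test",
]

logger = logging.getLogger(__name__)


def trig_basis(t, m: int) -> np.ndarray:
    """Design matrix with columns [1, sin t, cos t, ..., sin mt, cos mt]."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    cols = [np.ones_like(t)]
    for j in range(1, m + 1):
        cols.append(np.sin(j * t))
        cols.append(np.cos(j * t))
    return np.column_stack(cols)


def trig_basis_deriv(t, m: int) -> np.ndarray:
    """Term-wise derivative of :func:`trig_basis`."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    cols = [np.zeros_like(t)]
    for j in range(1, m + 1):
        cols.append(j * np.cos(j * t))
        cols.append(-j * np.sin(j * t))
    return np.column_stack(cols)


def eval_trig(q, m: int, t):
    """Evaluate the trigonometric series with coefficients ``q`` at ``t``."""
    q = np.asarray(q, dtype=float)
    if q.shape != (2 * m + 1,):
        raise ValueError(f"expected {2 * m + 1} coefficients for m={m}, got {q.shape}")
    out = trig_basis(t, m) @ q
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


@dataclass
class TrigFit:
    """A fitted trigonometric series with its uncertainty.

    Attributes
    ----------
    m : series order.
    q : coefficients (b0, a1, b1, ..., am, bm).
    C : coefficient covariance, inverse weighted normal-equations matrix.
    chi2 : weighted residual sum of squares at the optimum.
    dof : number of points − (2m+1).
    p_value : upper-tail chi-square probability of ``chi2`` at ``dof``.
    kind : "delta" for the mean-error profile, "sigma2" for the variance.
    """

    m: int
    q: np.ndarray
    C: np.ndarray
    chi2: float
    dof: int
    p_value: float
    kind: str = "delta"

    def __call__(self, t):
        return eval_trig(self.q, self.m, t)

    def deriv(self, t):
        out = trig_basis_deriv(t, self.m) @ self.q
        return float(out[0]) if np.ndim(t) == 0 else out

    @property
    def se(self) -> np.ndarray:
        """Standard errors of the coefficients."""
        return np.sqrt(np.diag(self.C))

    def to_frame(self, player_id=None) -> pd.DataFrame:
        names = ["b0"]
        for j in range(1, self.m + 1):
            names += [f"a{j}", f"b{j}"]
        frame = pd.DataFrame(
            {"index": np.arange(len(self.q)), "name": names,
             "value": self.q, "se": self.se}
        )
        frame.insert(0, "kind", self.kind)
        if player_id is not None:
            frame.insert(0, "player_id", player_id)
        return frame


def model_p_value(chi2: float, dof: int) -> float:
    """Upper-tail probability of a chi-square variate."""
    if chi2 < 0:
        raise ValueError("chi2 must be nonnegative")
    if dof < 1:
        raise ValueError("dof must be >= 1 (series order too large)")
    return float(stats.chi2.sf(chi2, dof))


def fit_coefficients(t, y, w, m: int, kind: str = "delta",
                     wrap_residuals: bool | None = None) -> TrigFit:
    """Weighted least-squares fit of the series at fixed order ``m``.

    Parameters
    ----------
    t, y, w : per-point target angle, observed value and weight.  The weight
        is the expected scatter of ``y`` (the standard error ε/sqrt(n) for
        the mean-error profile), so the objective is
        ``sum(((y - f(t)) / w)**2)``.
    kind : "delta" or "sigma2".
    wrap_residuals : wrap residuals into (−π, π] before squaring; defaults
        to True for kind="delta" (angular data), False otherwise.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    n = len(t)
    p = 2 * m + 1
    if p > n:
        raise ValueError(f"rank-deficient design: {p} coefficients, {n} points")
    if wrap_residuals is None:
        wrap_residuals = kind == "delta"
    X = trig_basis(t, m)
    Xw = X / w[:, None]
    yw = y / w
    q, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < p:
        raise ValueError(f"rank-deficient design: rank {rank} < {p}")
    resid = y - X @ q
    if wrap_residuals:
        resid = wrap_angle(resid)
    chi2 = float(np.sum((resid / w) ** 2))
    C = np.linalg.inv(Xw.T @ Xw)
    C = 0.5 * (C + C.T)
    dof = n - p
    p_value = model_p_value(chi2, dof) if dof >= 1 else np.nan
    return TrigFit(m=m, q=q, C=C, chi2=chi2, dof=dof, p_value=p_value, kind=kind)


def _local_maxima_indices(values: np.ndarray) -> np.ndarray:
    """Indices that are local maxima of a 1-D sequence (ends one-sided)."""
    v = np.asarray(values)
    idx = []
    for i in range(len(v)):
        left_ok = i == 0 or v[i] >= v[i - 1]
        right_ok = i == len(v) - 1 or v[i] >= v[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return np.array(idx, dtype=int)


def select_order(t, y, w, kind: str = "delta", m_min: int = 2,
                 m_max: int | None = None, chi2_cap: float | None = None) -> TrigFit:
    """Scan series orders and pick the fit by the chi-square p-value rule.

    Orders m = m_min .. m_max are fitted; the selected order is the smallest
    local maximum of p_value(m) whose chi2 does not exceed the number of
    points.  If no local maximum qualifies, the global p_value maximum is
    returned and the fallback is logged.
    """
    t = np.asarray(t, dtype=float)
    n = len(t)
    if m_max is None:
        m_max = min(14, (n - 4) // 2)  # keep dof >= 3
    if chi2_cap is None:
        chi2_cap = float(n)
    if m_max < m_min:
        raise ValueError("no feasible order: too few points")
    fits = [fit_coefficients(t, y, w, m, kind=kind) for m in range(m_min, m_max + 1)]
    pvals = np.array([f.p_value for f in fits])
    for i in _local_maxima_indices(pvals):
        if fits[i].chi2 <= chi2_cap:
            return fits[i]
    best = int(np.argmax(pvals))
    logger.info(
        "select_order: no qualifying local maximum of p(m); falling back to "
        "global maximum m=%d (p=%.3g, chi2=%.3g)",
        fits[best].m, pvals[best], fits[best].chi2,
    )
    return fits[best]


def fit_variance_profile(t, eps2, w, m_min: int = 2, m_max: int | None = None,
                         grid_size: int = 1024) -> TrigFit:
    """Order-selected fit of the squared-dispersion profile σ²(t).

    Runs the same machinery as :func:`select_order` on per-target ε² values
    and enforces positivity of the fitted function on a dense grid.  If the
    selected fit dips below zero, lower orders are tried; if none is positive
    the fit is floored (a warning is emitted and ``q`` is shifted so the
    minimum equals min(ε²)/10).
    """
    t = np.asarray(t, dtype=float)
    eps2 = np.asarray(eps2, dtype=float)
    grid = np.linspace(-np.pi, np.pi, grid_size, endpoint=False)
    fit = select_order(t, eps2, w, kind="sigma2", m_min=m_min, m_max=m_max)
    if np.all(fit(grid) > 0):
        return fit
    for m in range(fit.m - 1, m_min - 1, -1):
        cand = fit_coefficients(t, eps2, w, m, kind="sigma2")
        if np.all(cand(grid) > 0):
            logger.info("variance fit: lowered order to m=%d for positivity", m)
            return cand
    floor = float(np.min(eps2)) / 10.0
    shift = floor - float(np.min(fit(grid)))
    warnings.warn(
        "variance profile not positive at any order; flooring at min(eps2)/10",
        stacklevel=2,
    )
    q = fit.q.copy()
    q[0] += shift
    return TrigFit(m=fit.m, q=q, C=fit.C, chi2=np.nan, dof=fit.dof,
                   p_value=np.nan, kind="sigma2")


@dataclass
class CohortBiasResult:
    """Cohort-level tests of systematic response bias.

    ``per_player`` holds the accumulated-squared-error statistic S of each
    player (chi-square with one dof per target) with Bonferroni-corrected
    decisions; ``per_target`` holds cross-player one-sample t-tests of the
    mean error against zero.
    """

    per_player: pd.DataFrame
    per_target: pd.DataFrame
    alpha: float
    excluded_players: list = field(default_factory=list)


def cohort_bias_test(summaries: pd.DataFrame, alpha: float = 0.01) -> CohortBiasResult:
    """Test, per player, whether mean responses deviate from the targets.

    ``summaries`` is the per-cell table from :meth:`ResponseSet.summaries`.
    For each player S = sum_j [ wrap(mean_j − t_j) / (sd_j / sqrt(n_j)) ]²
    is referred to a chi-square with (number of targets) dof; decisions are
    Bonferroni-corrected across players.  Per-target t-tests compare the
    cross-player mean errors against zero (two-sided, uncorrected).
    """
    n_targets_full = summaries["target_rad"].nunique()
    players = sorted(summaries["player_id"].unique().tolist())
    rows, excluded = [], []
    for pid in players:
        sub = summaries[summaries["player_id"] == pid]
        if sub["target_rad"].nunique() < n_targets_full:
            excluded.append(pid)
            warnings.warn(f"player {pid} missing targets; excluded from bias test",
                          stacklevel=2)
            continue
        err = wrap_angle(sub["mean_rad"].to_numpy() - sub["target_rad"].to_numpy())
        se = sub["sd_rad"].to_numpy() / np.sqrt(sub["n"].to_numpy())
        s_stat = float(np.sum((err / se) ** 2))
        p = float(stats.chi2.sf(s_stat, len(err)))
        rows.append({"player_id": pid, "S": s_stat, "dof": len(err), "p_value": p})
    per_player = pd.DataFrame(rows)
    if len(per_player):
        per_player["reject"] = per_player["p_value"] < alpha / len(per_player)

    trows = []
    for t, grp in summaries.groupby("target_rad", sort=True):
        err = wrap_angle(grp["mean_rad"].to_numpy() - t)
        if len(err) >= 2:
            res = stats.ttest_1samp(err, 0.0)
            trows.append({"target_rad": t, "n_players": len(err),
                          "mean_error": float(np.mean(err)),
                          "t_stat": float(res.statistic),
                          "p_value": float(res.pvalue)})
        else:
            trows.append({"target_rad": t, "n_players": len(err),
                          "mean_error": float(np.mean(err)),
                          "t_stat": np.nan, "p_value": np.nan})
    per_target = pd.DataFrame(trows)
    return CohortBiasResult(per_player=per_player, per_target=per_target,
                            alpha=alpha, excluded_players=excluded)
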
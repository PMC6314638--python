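"""Circular summary statistics and preprocessing of response tables.

Angles live on the circle (−π, π].  The circular mean is the argument of the
first trigonometric moment and the circular standard deviation is
``sqrt(-2 ln R)`` with ``R`` the mean resultant length; for the narrow
distributions typical of this task both coincide with their linear
counterparts to high accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseSet",
    "DiscardReport",
    "UndefinedMeanError",
    "wrap_angle",
    "circ_mean",
    "circ_sd",
    "filter_outliers",
    "gaussianity_check",
]

#: resultant lengths below this are treated as degenerate (no defined mean)
RESULTANT_TOL = 1e-9

RESPONSE_COLUMNS = [
    "player_id",
    "game",
    "trial",
    "target_index",
    "target_rad",
    "response_rad",
]


class UndefinedMeanError(ValueError):
    """Raised when the resultant vector is too short to define a mean."""


def wrap_angle(x):
    """Wrap angle(s) into the interval (−π, π]."""
    x = np.asarray(x, dtype=float)
    w = -(np.mod(-x + np.pi, 2.0 * np.pi) - np.pi)
    return w if w.ndim else float(w)


def _resultant(angles):
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one angle")
    s = np.mean(np.sin(a))
    c = np.mean(np.cos(a))
    return s, c, float(np.hypot(s, c))


def circ_mean(angles) -> float:
    """Quadrant-correct circular mean in (−π, π].

    Raises
    ------
    UndefinedMeanError
        If the mean resultant length is below :data:`RESULTANT_TOL`
        (e.g. antipodal or uniform samples).
    """
    s, c, r = _resultant(angles)
    if r <= RESULTANT_TOL:
        raise UndefinedMeanError(
            f"resultant length {r:.3g} too small: circular mean undefined"
        )
    return wrap_angle(np.arctan2(s, c))


def circ_sd(angles) -> float:
    """Circular standard deviation ``sqrt(-2 ln R)`` in radians."""
    _, _, r = _resultant(angles)
    if r <= RESULTANT_TOL:
        raise UndefinedMeanError(
            f"resultant length {r:.3g} too small: dispersion is infinite"
        )
    # r can exceed 1 by rounding for a single angle
    return float(np.sqrt(max(0.0, -2.0 * np.log(min(r, 1.0)))))


@dataclass
class ResponseSet:
    """Trial records of a continuous-report experiment.

    Wraps a dataframe with columns ``player_id, game, trial, target_index,
    target_rad, response_rad``.  Angles are stored in radians in (−π, π].
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in RESPONSE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"response table missing columns: {missing}")
        self.df = self.df[RESPONSE_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def players(self):
        return sorted(self.df["player_id"].unique().tolist())

    @property
    def targets(self):
        return np.sort(self.df["target_rad"].unique())

    def summaries(self) -> pd.DataFrame:
        """Per-(player, target) circular summaries.

        Returns a dataframe with columns ``player_id, target_index,
        target_rad, n, mean_rad, sd_rad``.
        """
        rows = []
        for (pid, tidx, t), grp in self.df.groupby(
            ["player_id", "target_index", "target_rad"], sort=True
        ):
            r = grp["response_rad"].to_numpy()
            rows.append(
                {
                    "player_id": pid,
                    "target_index": tidx,
                    "target_rad": t,
                    "n": len(r),
                    "mean_rad": circ_mean(r),
                    "sd_rad": circ_sd(r),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class DiscardReport:
    """Outcome of the k-SD outlier filter."""

    n_total: int
    n_discarded: int
    skipped_cells: list = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return self.n_discarded / self.n_total if self.n_total else 0.0


def filter_outliers(rs: ResponseSet, k: float = 3.0) -> tuple[ResponseSet, DiscardReport]:
    """Discard responses farther than ``k`` circular SDs from their cell mean.

    The mean and SD of each (player, target) cell are computed on the raw
    (unfiltered) cell; cells with fewer than 3 responses are skipped with a
    warning and nothing is discarded there.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    keep = np.ones(len(rs.df), dtype=bool)
    skipped = []
    for (pid, t), grp in rs.df.groupby(["player_id", "target_rad"], sort=False):
        r = grp["response_rad"].to_numpy()
        if len(r) < 3:
            skipped.append((pid, t))
            continue
        mu = circ_mean(r)
        eps = circ_sd(r)
        dist = np.abs(wrap_angle(r - mu))
        keep[grp.index[dist > k * eps]] = False
    if skipped:
        warnings.warn(
            f"{len(skipped)} cells with n < 3 skipped by outlier filter",
            stacklevel=2,
        )
    filtered = ResponseSet(rs.df[keep].reset_index(drop=True))
    report = DiscardReport(
        n_total=len(rs.df),
        n_discarded=int((~keep).sum()),
        skipped_cells=skipped,
    )
    return filtered, report


def gaussianity_check(
    rs: ResponseSet, alpha: float = 0.05, lilliefors: bool = False
) -> pd.DataFrame:
    """Kolmogorov–Smirnov check of per-cell gaussianity.

    Each (player, target) cell's responses are centered on the cell circular
    mean (wrapped deviations) and compared against a Gaussian with the cell's
    SD.  Decisions are Bonferroni-corrected across testable cells.  Cells
    with fewer than 5 responses are flagged untestable.

    With ``lilliefors=True`` the p-value is instead obtained by Monte Carlo
    under estimated parameters (500 draws), which corrects the optimism of
    plugging fitted parameters into the KS null.
    """
    rows = []
    rng = np.random.default_rng(0)
    for (pid, t), grp in rs.df.groupby(["player_id", "target_rad"], sort=True):
        r = grp["response_rad"].to_numpy()
        n = len(r)
        if n < 5:
            rows.append(
                {"player_id": pid, "target_rad": t, "n": n, "ks_stat": np.nan,
                 "p_value": np.nan, "testable": False}
            )
            continue
        mu = circ_mean(r)
        eps = circ_sd(r)
        d = wrap_angle(r - mu)
        if eps <= 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kstest(d, "norm", args=(0.0, eps))
            if lilliefors:
                null_stats = np.empty(500)
                for i in range(500):
                    z = rng.normal(0.0, eps, size=n)
                    s_hat = z.std()
                    null_stats[i] = stats.kstest(
                        z - z.mean(), "norm", args=(0.0, s_hat)
                    ).statistic
                p = float(np.mean(null_stats >= stat))
        rows.append(
            {"player_id": pid, "target_rad": t, "n": n, "ks_stat": float(stat),
             "p_value": float(p), "testable": True}
        )
    table = pd.DataFrame(rows)
    n_testable = int(table["testable"].sum())
    if n_testable:
        table["reject"] = table["testable"] & (
            table["p_value"] < alpha / n_testable
        )
    else:
        table["reject"] = False
    return table


def summary_to_csv(summaries: pd.DataFrame, path) -> None:
    """Write a per-cell summary table to CSV."""
    summaries.to_csv(path, index=False)
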
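"""Tabular I/O and the end-to-end pipeline runner.

The canonical interchange format is CSV with columns ``player_id, game,
trial, target_index, target_rad, response_rad``; XLSX is supported read-only
for compatibility with raw supplementary response tables.  Column names are
auto-detected from headers (documented in :data:`COLUMN_ALIASES`).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chromemo import attractors as attr_mod
from chromemo import circstats, errormodel, fisher, simulate
from chromemo.circstats import RESPONSE_COLUMNS, ResponseSet, wrap_angle

__all__ = ["RunConfig", "read_responses", "write_responses", "run_pipeline"]

logger = logging.getLogger(__name__)

COLUMN_ALIASES = {
    "player_id": ["player_id", "player", "subject", "subject_id", "id"],
    "game": ["game", "run", "session", "block"],
    "trial": ["trial", "trial_index", "order"],
    "target_index": ["target_index", "target_id", "color_index", "stimulus"],
    "target_rad": ["target_rad", "target", "target_angle", "t", "t_rad"],
    "response_rad": ["response_rad", "response", "response_angle", "r", "r_rad"],
    "response_bar": ["response_bar", "bar_position", "bar", "cursor"],
}

N_BAR_POSITIONS = 743


def _match_columns(columns) -> dict:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for canonical, aliases in COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canonical] = lower[alias]
                break
    return mapping


def _wrap_with_warning(values: np.ndarray, what: str) -> np.ndarray:
    out_of_range = np.abs(values) > np.pi + 1e-9
    if np.any(out_of_range):
        rows = np.flatnonzero(out_of_range)
        warnings.warn(
            f"{len(rows)} {what} values outside (−π, π] wrapped "
            f"(first at row {rows[0]})",
            stacklevel=3,
        )
    return wrap_angle(values)


def read_responses(path, fmt: str | None = None, n_targets: int = 32) -> ResponseSet:
    """Load a trial-by-trial response table from CSV or XLSX.

    Target angles are taken from a ``target_rad``-like column if present,
    otherwise derived from ``target_index`` as equally spaced angles
    (2π·index/n_targets, wrapped).  Responses given as bar positions
    (integers in [0, 743)) are converted to angles on the same convention.
    All angles are wrapped into (−π, π] with a warning.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        raw = pd.read_excel(path)
    elif fmt == "csv":
        raw = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")
    mapping = _match_columns(raw.columns)
    if "player_id" not in mapping:
        raise ValueError(f"cannot identify a player column in {list(raw.columns)}")
    df = pd.DataFrame()
    df["player_id"] = raw[mapping["player_id"]].astype(str)
    df["game"] = raw[mapping["game"]] if "game" in mapping else 0
    df["trial"] = (raw[mapping["trial"]] if "trial" in mapping
                   else np.arange(len(raw)))

    if "target_rad" in mapping:
        df["target_rad"] = _wrap_with_warning(
            raw[mapping["target_rad"]].to_numpy(dtype=float), "target angle")
        if "target_index" in mapping:
            df["target_index"] = raw[mapping["target_index"]].astype(int)
        else:
            angles = simulate.default_targets(n_targets)
            idx = np.argmin(np.abs(wrap_angle(
                df["target_rad"].to_numpy()[:, None] - angles[None, :])), axis=1)
            df["target_index"] = idx
    elif "target_index" in mapping:
        idx = raw[mapping["target_index"]].to_numpy(dtype=int)
        if np.any(idx < 0) or np.any(idx >= n_targets):
            bad = int(np.flatnonzero((idx < 0) | (idx >= n_targets))[0])
            raise ValueError(f"unknown target index at row {bad}")
        df["target_index"] = idx
        df["target_rad"] = wrap_angle(2.0 * np.pi * idx / n_targets)
    else:
        raise ValueError("no target angle or target index column found")

    if "response_rad" in mapping:
        df["response_rad"] = _wrap_with_warning(
            raw[mapping["response_rad"]].to_numpy(dtype=float), "response angle")
    elif "response_bar" in mapping:
        pos = raw[mapping["response_bar"]].to_numpy(dtype=float)
        df["response_rad"] = wrap_angle(2.0 * np.pi * pos / N_BAR_POSITIONS)
        logger.info("responses converted from bar positions (0..%d)",
                    N_BAR_POSITIONS - 1)
    else:
        raise ValueError("no response column found")
    return ResponseSet(df[RESPONSE_COLUMNS])


def write_responses(rs: ResponseSet, path) -> None:
    rs.df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Options for one end-to-end pipeline run."""

    responses_path: str | None = None
    out_dir: str = "chromemo_out"
    # simulation (used when no responses_path is given)
    simulate_strategy: str = "null"  # "null" or "mixed"
    n_players: int = 11
    n_targets: int = 32
    games_range: tuple = simulate.DEFAULT_GAMES_RANGE
    sigma0: float = 0.17
    mixing_weight: float = 0.5
    n_focal: int = 4
    # preprocessing
    outlier_k: float = 3.0
    # fitting
    m_min: int = 2
    m_max: int | None = None
    # screening
    level: float = 0.95
    n_samples: int = 10_000
    window: float = 0.25
    # fisher
    grid_size: int = 4096
    # cohort tests
    alpha_bias: float = 0.01
    alpha_gauss: float = 0.05
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    summaries: pd.DataFrame
    discard_fraction: float
    fits: dict
    reports: dict
    profiles: dict
    cohort_bias: errormodel.CohortBiasResult
    attractor_uniformity: attr_mod.UniformityResult
    repulsor_uniformity: attr_mod.UniformityResult

    def significant_counts(self) -> pd.DataFrame:
        rows = []
        for pid, rep in self.reports.items():
            rows.append({"player_id": pid,
                         "n_attractors": rep.count("attractor"),
                         "n_repulsors": rep.count("repulsor"),
                         "selected_m": self.fits[pid]["delta"].m})
        return pd.DataFrame(rows)


def _simulated_cohort(config: RunConfig) -> ResponseSet:
    rng = np.random.default_rng(config.seed)
    targets = simulate.default_targets(config.n_targets)
    if config.simulate_strategy == "null":
        cohort = simulate.make_null_cohort(
            config.n_players, config.games_range, sigma0=config.sigma0,
            seed=config.seed, targets=targets)
        return simulate.concat_cohort(cohort)
    if config.simulate_strategy == "mixed":
        sets = []
        for i in range(config.n_players):
            foci = np.sort(rng.uniform(-np.pi, np.pi, size=config.n_focal))
            profile = simulate.make_profile(
                "mixed", sigma0=config.sigma0,
                mixing_weight=config.mixing_weight, focal_colors=foci)
            ng = int(rng.integers(config.games_range[0], config.games_range[1] + 1))
            sets.append(simulate.simulate_responses(
                profile, targets, ng, seed=int(rng.integers(2**31)),
                player_id=f"mix{i:02d}"))
        return simulate.concat_cohort(sets)
    raise ValueError(f"unknown simulation strategy {config.simulate_strategy!r}")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Filter → summaries → Δ and σ² fits → attractor screen → Fisher →
    uniform scale → cohort tests; write all reports under the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.responses_path:
            rs = read_responses(config.responses_path, n_targets=config.n_targets)
        else:
            rs = _simulated_cohort(config)

        stage = "filter"
        rs, discard = circstats.filter_outliers(rs, k=config.outlier_k)

        stage = "summaries"
        summaries = rs.summaries()

        fits, reports, profiles = {}, {}, {}
        fit_frames, report_frames, profile_frames, extrema_rows = [], [], [], []
        for pid in sorted(summaries["player_id"].unique()):
            sub = summaries[summaries["player_id"] == pid]
            t = sub["target_rad"].to_numpy()
            n = sub["n"].to_numpy()
            eps = sub["sd_rad"].to_numpy()
            w = eps / np.sqrt(n)
            y = wrap_angle(sub["mean_rad"].to_numpy() - t)

            stage = f"delta fit ({pid})"
            dfit = errormodel.select_order(t, y, w, kind="delta",
                                           m_min=config.m_min, m_max=config.m_max)
            stage = f"variance fit ({pid})"
            sfit = errormodel.fit_variance_profile(t, eps**2, w,
                                                   m_min=config.m_min,
                                                   m_max=config.m_max)
            stage = f"attractor screen ({pid})"
            report = attr_mod.significance_screen(
                dfit, level=config.level, n_samples=config.n_samples,
                window=config.window, seed=config.seed)
            stage = f"fisher profile ({pid})"
            prof = fisher.fisher_information(dfit, sfit, grid_size=config.grid_size)
            fisher.uniform_scale(prof)
            ext = fisher.prominent_extrema(prof)

            fits[pid] = {"delta": dfit, "sigma2": sfit}
            reports[pid] = report
            profiles[pid] = prof
            fit_frames += [dfit.to_frame(pid), sfit.to_frame(pid)]
            frame = report.to_frame(pid)
            if len(frame):
                report_frames.append(frame)
            pf = prof.to_frame()
            pf.insert(0, "player_id", pid)
            profile_frames.append(pf)
            for kind in ("maxima", "minima"):
                for loc in ext[kind]:
                    extrema_rows.append({"player_id": pid, "location_rad": loc,
                                         "kind": kind[:-1]})
            logger.info("player %s: m=%d, %d candidates, %d significant",
                        pid, dfit.m, len(report.entries), len(report.significant))

        stage = "cohort tests"
        bias = errormodel.cohort_bias_test(summaries, alpha=config.alpha_bias)
        sig_att = [e.location for rep in reports.values()
                   for e in rep.significant if e.kind == "attractor"]
        sig_rep = [e.location for rep in reports.values()
                   for e in rep.significant if e.kind == "repulsor"]
        att_unif = attr_mod.cohort_location_uniformity(sig_att)
        rep_unif = attr_mod.cohort_location_uniformity(sig_rep)

        stage = "write"
        header = {"config_hash": config.hash(), "seed": config.seed}
        summaries.to_csv(out / "summaries.csv", index=False)
        pd.concat(fit_frames, ignore_index=True).to_csv(out / "fits.csv", index=False)
        if report_frames:
            pd.concat(report_frames, ignore_index=True).to_csv(
                out / "attractors.csv", index=False)
        else:
            pd.DataFrame(columns=["player_id", "location_rad", "kind", "slope",
                                  "significance_fraction", "significant"]
                         ).to_csv(out / "attractors.csv", index=False)
        pd.concat(profile_frames, ignore_index=True).to_csv(
            out / "fisher_profiles.csv", index=False)
        pd.DataFrame(extrema_rows,
                     columns=["player_id", "location_rad", "kind"]
                     ).to_csv(out / "extrema.csv", index=False)
        log = dict(header)
        log.update({
            "n_responses": int(discard.n_total),
            "n_discarded": int(discard.n_discarded),
            "discard_fraction": discard.fraction,
            "players": {pid: {"selected_m": fits[pid]["delta"].m,
                              "n_candidates": len(reports[pid].entries),
                              "n_significant": len(reports[pid].significant)}
                        for pid in fits},
            "bias_rejections": (int(bias.per_player["reject"].sum())
                                if len(bias.per_player) else 0),
            "attractor_uniformity_p": att_unif.p_value,
            "repulsor_uniformity_p": rep_unif.p_value,
            "config": asdict(config),
        })
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return PipelineResult(config=config, summaries=summaries,
                          discard_fraction=discard.fraction, fits=fits,
                          reports=reports, profiles=profiles, cohort_bias=bias,
                          attractor_uniformity=att_unif,
                          repulsor_uniformity=rep_unif)
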
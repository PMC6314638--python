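"""Physically defined circular color locus from screen-primary spectra.

The screen is calibrated with a per-wavelength second-order polynomial in
the (R, G, B) drive coordinates.  The stimulus locus is the closed curve of
maximally saturated colors (one coordinate zero) with constant integrated
spectral energy, resampled so that consecutive colors differ by a constant
amount of displaced spectral energy, i.e. constant ∫|δE(λ)|dλ.  Angles t
parametrize the locus with t = 0 anchored at the deepest blue and increasing
t running through cyan and green before yellow and red.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from chromemo.circstats import wrap_angle

__all__ = [
    "Spectrum",
    "ScreenModel",
    "ColorLocus",
    "CalibrationError",
    "LocusError",
    "SyntheticScreen",
    "synthetic_measurements",
    "fit_screen_model",
    "total_intensity",
    "build_locus",
    "select_targets",
    "spectrum_to_xyY",
]

#: default visible-range wavelength grid (nm); the integration bounds are a
#: convention, not a measured quantity
DEFAULT_WAVELENGTHS = np.arange(380.0, 781.0, 1.0)


class CalibrationError(ValueError):
    """Raised when the calibration design is unusable (rank-deficient)."""


class LocusError(ValueError):
    """Raised when the iso-intensity locus cannot be constructed."""


@dataclass
class Spectrum:
    """Spectral power density on a common wavelength grid."""

    wavelengths: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.wavelengths.shape != self.power.shape:
            raise ValueError("wavelength and power grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("spectral power must be nonnegative")
        self.power = np.clip(self.power, 0.0, None)

    def intensity(self) -> float:
        """Integrated power over the grid (trapezoid rule)."""
        return float(np.trapezoid(self.power, self.wavelengths))


def _features(rgb: np.ndarray) -> np.ndarray:
    """Quadratic feature map of normalized drive coordinates.

    Columns: 1, r, g, b, r², g², b², rg, rb, gb with r = R/255 etc.
    """
    u = np.atleast_2d(np.asarray(rgb, dtype=float)) / 255.0
    r, g, b = u[:, 0], u[:, 1], u[:, 2]
    return np.column_stack([np.ones_like(r), r, g, b,
                            r * r, g * g, b * b, r * g, r * b, g * b])


_LINEAR_COLS = slice(0, 4)  # intercept + three linear terms


@dataclass
class ScreenModel:
    """Per-wavelength quadratic polynomial predicting emitted power."""

    wavelengths: np.ndarray
    coef: np.ndarray  # (10, n_wavelengths)
    residuals_quadratic: np.ndarray = field(default=None)
    residuals_linear: np.ndarray = field(default=None)

    def predict_power(self, rgb) -> np.ndarray:
        """Predicted spectral power, clipped at zero.

        ``rgb`` may be one triple or an (n, 3) array; returns (n_wl,) or
        (n, n_wl) accordingly.
        """
        rgb_arr = np.asarray(rgb, dtype=float)
        power = _features(rgb_arr) @ self.coef
        power = np.clip(power, 0.0, None)
        return power[0] if rgb_arr.ndim == 1 else power

    def predict(self, rgb) -> Spectrum:
        return Spectrum(self.wavelengths, self.predict_power(rgb))


def fit_screen_model(measurements) -> ScreenModel:
    """Least-squares quadratic calibration from (rgb, Spectrum) pairs.

    Also fits the nested linear model so the two residual profiles can be
    compared; by construction the quadratic residual sum never exceeds the
    linear one.
    """
    if len(measurements) < 10:
        raise CalibrationError("need at least 10 calibration measurements")
    rgbs = np.array([np.asarray(rgb, dtype=float) for rgb, _ in measurements])
    wl = measurements[0][1].wavelengths
    for _, spec in measurements:
        if not np.array_equal(spec.wavelengths, wl):
            raise ValueError("all calibration spectra must share one grid")
    Y = np.array([spec.power for _, spec in measurements])
    X = _features(rgbs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CalibrationError(
            "rank-deficient calibration design: rgb triples too few or collinear"
        )
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid_quad = np.sum((Y - X @ coef) ** 2, axis=0)
    Xl = X[:, _LINEAR_COLS]
    coef_l, _, _, _ = np.linalg.lstsq(Xl, Y, rcond=None)
    resid_lin = np.sum((Y - Xl @ coef_l) ** 2, axis=0)
    return ScreenModel(wavelengths=wl, coef=coef,
                       residuals_quadratic=resid_quad, residuals_linear=resid_lin)


def total_intensity(model: ScreenModel, rgb) -> float:
    """Integrated predicted power of one rgb triple over the visible grid."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,) or np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError(f"rgb must be a triple in [0, 255]^3, got {rgb}")
    return Spectrum(model.wavelengths, model.predict_power(rgb)).intensity()


def _intensity_many(model: ScreenModel, rgbs: np.ndarray) -> np.ndarray:
    power = model.predict_power(rgbs)
    return np.trapezoid(power, model.wavelengths, axis=1)


def _trace_plane(model: ScreenModel, target: float, zero_axis: int,
                 n_theta: int) -> np.ndarray:
    """Iso-intensity arc on one coordinate plane of the rgb cube.

    On the plane where ``zero_axis`` vanishes, directions in the remaining
    two coordinates are swept from one axis to the other; the radius along
    each direction is bisected so the predicted intensity equals ``target``.
    Returns an (n_theta, 3) array from the first free axis to the second.
    """
    free = [a for a in range(3) if a != zero_axis]
    thetas = np.linspace(0.0, np.pi / 2.0, n_theta)
    dirs = np.zeros((n_theta, 3))
    dirs[:, free[0]] = np.cos(thetas)
    dirs[:, free[1]] = np.sin(thetas)
    with np.errstate(divide="ignore"):
        rho_max = np.min(np.where(dirs > 1e-12, 255.0 / np.where(dirs > 1e-12, dirs, 1.0),
                                  np.inf), axis=1)
    hi_int = _intensity_many(model, dirs * rho_max[:, None])
    axis_names = "RGB"
    if np.any(hi_int < target):
        raise LocusError(
            f"target intensity {target:.4g} not achievable on plane "
            f"{axis_names[zero_axis]}=0"
        )
    lo = np.zeros(n_theta)
    hi = rho_max.copy()
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        vals = _intensity_many(model, dirs * mid[:, None])
        too_low = vals < target
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    rho = 0.5 * (lo + hi)
    return dirs * rho[:, None]


def _spectral_steps(model: ScreenModel, rgbs: np.ndarray) -> np.ndarray:
    """∫|δE(λ)|dλ between consecutive rows, including last→first."""
    power = model.predict_power(rgbs)
    diff = np.abs(power - np.roll(power, -1, axis=0))
    return np.trapezoid(diff, model.wavelengths, axis=1)


@dataclass
class ColorLocus:
    """Closed iso-intensity, maximally saturated, equal-spectral-step locus."""

    rgb: np.ndarray          # (n, 3), each row has at least one zero entry
    t: np.ndarray            # (n,), strictly increasing in (−π, π]
    spectra: np.ndarray      # (n, n_wavelengths) predicted power
    wavelengths: np.ndarray
    target_intensity: float

    @property
    def n_colors(self) -> int:
        return len(self.t)

    def intensities(self) -> np.ndarray:
        return np.trapezoid(self.spectra, self.wavelengths, axis=1)

    def steps(self) -> np.ndarray:
        diff = np.abs(self.spectra - np.roll(self.spectra, -1, axis=0))
        return np.trapezoid(diff, self.wavelengths, axis=1)

    def to_frame(self) -> pd.DataFrame:
        xyY = np.array([spectrum_to_xyY(Spectrum(self.wavelengths, p))
                        for p in self.spectra])
        return pd.DataFrame({
            "index": np.arange(self.n_colors),
            "t_rad": self.t,
            "R": self.rgb[:, 0], "G": self.rgb[:, 1], "B": self.rgb[:, 2],
            "x": xyY[:, 0], "y": xyY[:, 1], "Y": xyY[:, 2],
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_locus(model: ScreenModel, target_intensity: float,
                n_colors: int = 743, n_fine: int = 2048,
                saturation_tol: float = 1e-6) -> ColorLocus:
    """Construct the closed stimulus locus at a given total intensity.

    The three coordinate-plane arcs (B=0: red→green, R=0: green→blue,
    G=0: blue→red) are traced by vectorized bisection, concatenated into a
    closed fine path, and resampled to ``n_colors`` points of equal spectral
    step ∫|δE|dλ.  Angles are assigned uniformly with t = 0 at the entry of
    maximal B and minimal R+G, oriented so that green-side hues carry small
    positive t.
    """
    if n_colors < 3:
        raise ValueError("n_colors must be >= 3")
    # arcs meet at the single-channel corner points; order them into a
    # closed loop red -> green -> blue -> red
    arc_rg = _trace_plane(model, target_intensity, zero_axis=2, n_theta=n_fine)
    arc_gb = _trace_plane(model, target_intensity, zero_axis=0, n_theta=n_fine)
    # for G=0 the free axes are (R, B), so the sweep runs R->B; reverse it
    arc_br = _trace_plane(model, target_intensity, zero_axis=1, n_theta=n_fine)[::-1]
    arcs = [arc_rg, arc_gb, arc_br]

    # spectral arclength within each arc (chords between fine points)
    cums, lengths = [], []
    for arc in arcs:
        power = model.predict_power(arc)
        d = np.trapezoid(np.abs(np.diff(power, axis=0)), model.wavelengths, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(d)])
        cums.append(cum)
        lengths.append(cum[-1])
    total = float(np.sum(lengths))
    if total <= 0:
        raise LocusError("degenerate locus: spectra do not change along the path")

    # allocate sample counts per arc proportionally (largest remainder), so
    # the corner points are themselves samples and no equal-energy step
    # straddles a kink between coordinate planes
    ideal = np.array(lengths) / total * n_colors
    counts = np.maximum(1, np.floor(ideal).astype(int))
    while counts.sum() < n_colors:
        counts[np.argmax(ideal - counts)] += 1
    while counts.sum() > n_colors:
        counts[np.argmin(ideal - counts)] -= 1

    pieces = []
    for arc, cum, length, cnt in zip(arcs, cums, lengths, counts):
        positions = np.arange(cnt) * length / cnt  # corner included, end excluded
        pieces.append(np.column_stack([np.interp(positions, cum, arc[:, k])
                                       for k in range(3)]))
    rgb = np.vstack(pieces)
    # each sample lies on one coordinate plane; clean rounding residue
    rgb[np.abs(rgb) <= 255 * saturation_tol] = 0.0
    spectra = model.predict_power(rgb)

    score = rgb[:, 2] - rgb[:, 0] - rgb[:, 1]  # deep blue: max B, min R+G
    anchor = int(np.argmax(score))
    order = (np.arange(n_colors) + anchor) % n_colors
    rgb, spectra = rgb[order], spectra[order]
    # orientation: a quarter turn after blue must be greener than red
    quarter = n_colors // 4
    if rgb[quarter, 1] < rgb[-quarter, 1]:
        rgb = np.vstack([rgb[:1], rgb[1:][::-1]])
        spectra = np.vstack([spectra[:1], spectra[1:][::-1]])
    t = wrap_angle(2.0 * np.pi * np.arange(n_colors) / n_colors)
    sort = np.argsort(t)
    return ColorLocus(rgb=rgb[sort], t=t[sort], spectra=spectra[sort],
                      wavelengths=model.wavelengths,
                      target_intensity=float(target_intensity))


def select_targets(locus: ColorLocus, n_targets: int = 32) -> np.ndarray:
    """Equally spaced target angles (spacing 2π/n_targets) anchored at t=0."""
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    return np.sort(wrap_angle(2.0 * np.pi * np.arange(n_targets) / n_targets))


# --- synthetic screen ------------------------------------------------------

class SyntheticScreen:
    """A software stand-in for a measured display.

    Three Gaussian-shaped primaries (red/green/blue peaks near 610, 545 and
    465 nm) with a mild per-channel quadratic nonlinearity in the drive
    value.  Green is the most luminous channel and blue the least, as in
    common LED panels.
    """

    PEAKS = (610.0, 545.0, 465.0)
    WIDTHS = (32.0, 40.0, 28.0)
    AMPLITUDES = (1.0, 1.3, 0.7)
    QUAD = (0.25, 0.20, 0.30)

    def __init__(self, wavelengths=None, quadratic: bool = True,
                 scale: float = 1.0):
        self.wavelengths = (DEFAULT_WAVELENGTHS if wavelengths is None
                            else np.asarray(wavelengths, dtype=float))
        self.quadratic = quadratic
        self.scale = scale
        self._profiles = np.array([
            amp * np.exp(-0.5 * ((self.wavelengths - peak) / width) ** 2)
            for peak, width, amp in zip(self.PEAKS, self.WIDTHS, self.AMPLITUDES)
        ])

    def channel_gain(self, u: np.ndarray, channel: int) -> np.ndarray:
        if self.quadratic:
            return u + self.QUAD[channel] * u**2
        return u

    def emit(self, rgb) -> Spectrum:
        u = np.asarray(rgb, dtype=float) / 255.0
        power = np.zeros_like(self.wavelengths)
        for ch in range(3):
            power = power + self.channel_gain(u[ch], ch) * self._profiles[ch]
        return Spectrum(self.wavelengths, self.scale * power)


def synthetic_measurements(screen: SyntheticScreen | None = None,
                           levels=(0, 64, 128, 192, 255),
                           n_random: int = 40, seed: int = 0,
                           noise_sd: float = 0.0):
    """Calibration set: per-channel ramps, grays, and random cube points."""
    if screen is None:
        screen = SyntheticScreen()
    rng = np.random.default_rng(seed)
    rgbs = []
    for level in levels:
        for ch in range(3):
            rgb = [0, 0, 0]
            rgb[ch] = level
            rgbs.append(tuple(rgb))
        rgbs.append((level, level, level))
    rgbs.extend(tuple(v) for v in rng.integers(0, 256, size=(n_random, 3)))
    out = []
    for rgb in dict.fromkeys(rgbs):  # unique, order-preserving
        spec = screen.emit(rgb)
        power = spec.power
        if noise_sd > 0:
            power = np.clip(power + rng.normal(0, noise_sd, power.shape), 0, None)
        out.append((np.asarray(rgb, dtype=float),
                    Spectrum(screen.wavelengths, power)))
    return out


# --- colorimetry -----------------------------------------------------------

def _gauss_piece(x, alpha, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return alpha * np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_xbar(wl):
    """Analytic multi-lobe approximation of the 2° observer x-bar function."""
    wl = np.asarray(wl, dtype=float)
    return (_gauss_piece(wl, 1.056, 599.8, 37.9, 31.0)
            + _gauss_piece(wl, 0.362, 442.0, 16.0, 26.7)
            + _gauss_piece(wl, -0.065, 501.1, 20.4, 26.2))


def cie_ybar(wl):
    wl = np.asarray(wl, dtype=float)
    return (_gauss_piece(wl, 0.821, 568.8, 46.9, 40.5)
            + _gauss_piece(wl, 0.286, 530.9, 16.3, 31.1))


def cie_zbar(wl):
    wl = np.asarray(wl, dtype=float)
    return (_gauss_piece(wl, 1.217, 437.0, 11.8, 36.0)
            + _gauss_piece(wl, 0.681, 459.0, 26.0, 13.8))


def spectrum_to_xyY(spectrum: Spectrum) -> tuple[float, float, float]:
    """CIE 1931 chromaticity (x, y) and luminance-like Y of a spectrum."""
    wl, p = spectrum.wavelengths, spectrum.power
    X = np.trapezoid(p * cie_xbar(wl), wl)
    Y = np.trapezoid(p * cie_ybar(wl), wl)
    Z = np.trapezoid(p * cie_zbar(wl), wl)
    s = X + Y + Z
    if s <= 0:
        return (0.0, 0.0, 0.0)
    return (float(X / s), float(Y / s), float(Y))


def load_target_xyY() -> pd.DataFrame:
    """Packaged reference table of the 32 target colors' CIE xyY values."""
    path = Path(__file__).parent / "data" / "targets_xyY.csv"
    return pd.read_csv(path)


def read_spectra_manifest(manifest_path) -> list:
    """Read calibration spectra from a manifest CSV (file, R, G, B).

    Each referenced file is a CSV with columns wavelength_nm, power; paths
    are resolved relative to the manifest.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    out = []
    for _, row in manifest.iterrows():
        spec_df = pd.read_csv(manifest_path.parent / row["file"])
        out.append((
            np.array([row["R"], row["G"], row["B"]], dtype=float),
            Spectrum(spec_df["wavelength_nm"].to_numpy(),
                     spec_df["power"].to_numpy()),
        ))
    return out
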
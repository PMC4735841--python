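"""Gamma-spectroscopy characterization chain.

Spectrum histogramming, photopeak Gaussian fits, linear ADC->keV calibration,
SiPM gain-vs-temperature correction and per-channel response equalization.
The nominal ADC scale used when synthesizing spectra is 5 keV per ADC count;
it is arbitrary and only serves to exercise the chain end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Spectrum",
    "PhotopeakFit",
    "CalibrationCurve",
    "TemperatureModel",
    "FitError",
    "histogram_energies",
    "fit_photopeak",
    "build_calibration",
    "gain_factor",
    "fit_temperature_slope",
    "equalize_channels",
    "NOMINAL_KEV_PER_ADC",
]

log = logging.getLogger(__name__)

FWHM_OVER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Nominal ADC gain used by the synthetic digitizer (keV per ADC count).
NOMINAL_KEV_PER_ADC = 5.0


class FitError(RuntimeError):
    """A spectral fit failed to converge or the input was degenerate."""


@dataclass
class Spectrum:
    """Fixed-width histogram of pulse heights (ADC counts or keV)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    unit_label: str = "keV"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.bin_centers, self.counts]),
                   header=f"bin_center_{self.unit_label}\tcounts",
                   comments="# ", delimiter="\t", fmt="%.10g")

    @classmethod
    def load(cls, path, unit_label: str = "keV") -> "Spectrum":
        data = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        centers, counts = data[:, 0], data[:, 1]
        width = centers[1] - centers[0] if len(centers) > 1 else 1.0
        edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
        return cls(edges, counts, unit_label)


def histogram_energies(values, bin_width: float, range_: tuple,
                       unit_label: str = "keV") -> Spectrum:
    """Histogram pulse heights with fixed-width bins over ``range_``.

    Values outside the range are dropped (and logged); an empty input gives
    a valid all-zero spectrum."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo, hi = map(float, range_)
    values = np.asarray(values, dtype=float)
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    inside = (values >= lo) & (values <= edges[-1])
    dropped = int(values.size - inside.sum())
    if dropped:
        log.info("histogram_energies: dropped %d of %d values outside "
                 "[%g, %g]", dropped, values.size, lo, edges[-1])
    counts, _ = np.histogram(values[inside], bins=edges)
    return Spectrum(edges, counts, unit_label)


@dataclass
class PhotopeakFit:
    centroid: float
    sigma: float
    amplitude: float
    background: float
    fit_window: tuple
    centroid_err: float = np.nan

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not self.fit_window[0] <= self.centroid <= self.fit_window[1]:
            raise ValueError("centroid outside fit window")

    @property
    def fwhm(self) -> float:
        return FWHM_OVER_SIGMA * self.sigma

    @property
    def fwhm_percent(self) -> float:
        return 100.0 * self.fwhm / self.centroid


def _gauss_const(x, amp, mu, sigma, bkg):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2) + bkg


def fit_photopeak(spectrum: Spectrum, window: tuple) -> PhotopeakFit:
    """Least-squares Gaussian + constant background fit inside ``window``.

    The window must contain at least five populated bins.  Raises
    :class:`FitError` on degenerate input or non-convergence."""
    lo, hi = window
    centers = spectrum.bin_centers
    sel = (centers >= lo) & (centers <= hi)
    x = centers[sel]
    y = spectrum.counts[sel].astype(float)
    if np.count_nonzero(y) < 5:
        raise FitError(f"window [{lo}, {hi}] has fewer than 5 populated bins")
    bkg0 = float(np.min(y))
    amp0 = float(np.max(y) - bkg0)
    if amp0 <= 0:
        raise FitError("no peak above background in window")
    mu0 = float(x[np.argmax(y)])
    above = y - bkg0 > amp0 / 2
    sigma0 = max((x[above].max() - x[above].min()) / FWHM_OVER_SIGMA,
                 (x[1] - x[0]))
    try:
        popt, pcov = curve_fit(
            _gauss_const, x, y, p0=[amp0, mu0, sigma0, bkg0],
            bounds=([0.0, lo, 1e-9, 0.0],
                    [np.inf, hi, (hi - lo), np.inf]), maxfev=20000)
    except (RuntimeError, ValueError) as err:
        raise FitError(f"photopeak fit failed in [{lo}, {hi}]: {err}") from err
    amp, mu, sigma, bkg = popt
    mu_err = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.nan
    return PhotopeakFit(centroid=float(mu), sigma=float(sigma),
                        amplitude=float(amp), background=float(bkg),
                        fit_window=(float(lo), float(hi)), centroid_err=mu_err)


@dataclass
class CalibrationCurve:
    """Linear energy calibration keV = slope * ADC + intercept."""

    slope: float
    intercept: float
    fit_points: list = field(default_factory=list)
    r_squared: float = 1.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")

    def adc_to_kev(self, adc):
        return self.slope * np.asarray(adc, dtype=float) + self.intercept

    def kev_to_adc(self, kev):
        return (np.asarray(kev, dtype=float) - self.intercept) / self.slope

    def residuals(self):
        pts = np.asarray(self.fit_points, dtype=float)
        return pts[:, 1] - self.adc_to_kev(pts[:, 0])


def build_calibration(fit_points) -> CalibrationCurve:
    """Ordinary least squares line through (ADC centroid, known keV) points."""
    pts = np.asarray(fit_points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two (ADC, keV) calibration points")
    adc, kev = pts[:, 0], pts[:, 1]
    if np.ptp(adc) == 0:
        raise ValueError("degenerate calibration: all ADC values equal")
    slope, intercept = np.polyfit(adc, kev, 1)
    pred = slope * adc + intercept
    ss_res = float(np.sum((kev - pred) ** 2))
    ss_tot = float(np.sum((kev - kev.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(float(slope), float(intercept),
                            [tuple(p) for p in pts], r2)


@dataclass
class TemperatureModel:
    """Linear SiPM gain drift: gain(T) = 1 + slope * (T - T_ref).

    The measured drift is about -5% of gain per degree Celsius around the
    25.5 C operating point; the linear form is taken valid on a 10-40 C
    window."""

    reference_temperature_c: float = 25.5
    slope_fraction_per_degc: float = -0.05
    validity_window_c: tuple = (10.0, 40.0)

    def gain_factor(self, temperature_c: float) -> float:
        lo, hi = self.validity_window_c
        t = np.asarray(temperature_c, dtype=float)
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError(f"temperature outside validity window [{lo}, {hi}] C")
        g = 1.0 + self.slope_fraction_per_degc * (t - self.reference_temperature_c)
        if np.any(g <= 0):
            raise ValueError("temperature model yields non-positive gain")
        return float(g) if g.ndim == 0 else g

    def correct(self, measured, temperature_c: float):
        """Undo the temperature drift: divide by the gain factor."""
        return np.asarray(measured, dtype=float) / self.gain_factor(temperature_c)


def gain_factor(model: TemperatureModel, temperature_c) -> float:
    return model.gain_factor(temperature_c)


def fit_temperature_slope(gains, reference_temperature_c: float | None = None):
    """Least-squares slope of gain versus temperature, normalized at reference.

    ``gains`` is a sequence of (temperature_C, gain).  The returned value is
    the fractional gain change per degree Celsius relative to the gain at the
    reference temperature (default: the mean of the scanned temperatures)."""
    pts = np.asarray(gains, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least three temperature points")
    t, g = pts[:, 0], pts[:, 1]
    if np.ptp(t) == 0:
        raise ValueError("degenerate temperature scan")
    slope, intercept = np.polyfit(t, g, 1)
    if reference_temperature_c is None:
        reference_temperature_c = float(np.mean(t))
    g_ref = slope * reference_temperature_c + intercept
    if g_ref <= 0:
        raise ValueError("non-positive fitted gain at reference temperature")
    return float(slope / g_ref)


def equalize_channels(mean_signals) -> np.ndarray:
    """Multiplicative per-channel correction factors for an 8x8 readout grid.

    f_ch = grand_mean / mean_ch, so that corrected channel means are all
    equal to the grand mean; channels with non-positive means are reported
    as dead."""
    m = np.asarray(mean_signals, dtype=float)
    if m.shape != (8, 8):
        raise ValueError("expected an 8x8 grid of channel means")
    dead = np.argwhere(m <= 0)
    if len(dead):
        chans = ", ".join(f"({int(r)}, {int(c)})" for r, c in dead)
        raise ValueError(f"dead channels (row, col): {chans}")
    return m.mean() / m


def uniformity(mean_signals) -> float:
    """Channel-response spread, stdev/mean."""
    m = np.asarray(mean_signals, dtype=float)
    return float(np.std(m) / np.mean(m))
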
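"""Spectral wavelength calibration.

A pushbroom spectrograph is calibrated against a pencil lamp (e.g. Hg-Ar):
individual atomic emission lines are fitted with a Lorentzian profile to locate
their centres and estimate the instrument's spectral resolution (the fitted
full width at half maximum), and a low-order polynomial maps detector pixel
positions to wavelengths given several known lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import curve_fit

from .cube import SpectralAxis


class CalibrationError(RuntimeError):
    """Raised when a line fit fails to converge or is degenerate."""


@dataclass(frozen=True)
class CalibrationLine:
    """One fitted emission line: centre, FWHM and fit uncertainty (all nm)."""

    center_nm: float
    fwhm_nm: float
    center_se_nm: float
    amplitude: float
    offset: float

    def __post_init__(self) -> None:
        if not self.fwhm_nm > 0:
            raise ValueError("FWHM must be positive")
        if self.center_se_nm < 0:
            raise ValueError("centre standard error must be non-negative")


def _lorentzian(lam: np.ndarray, offset: float, amp: float, center: float,
                gamma: float) -> np.ndarray:
    return offset + amp * gamma**2 / ((lam - center) ** 2 + gamma**2)


def fit_lorentzian_line(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    window_nm: float = 10.0,
    center_guess_nm: float | None = None,
) -> CalibrationLine:
    """Fit ``offset + A·γ²/((λ−c)² + γ²)`` to a single emission line.

    The fit window is ``center_guess ± window_nm/2``; the default guess is the
    global intensity maximum.  FWHM = 2γ; the centre standard error comes from
    the fit covariance.
    """
    y = np.asarray(spectrum, dtype=float)
    lam = axis.wavelengths_nm
    if y.shape != lam.shape:
        raise ValueError("spectrum length must match axis length")
    if center_guess_nm is None:
        center_guess_nm = float(lam[np.argmax(y)])
    sel = np.abs(lam - center_guess_nm) <= window_nm / 2
    if sel.sum() < 5:
        raise ValueError("fit window must contain at least 5 samples")
    lam_w, y_w = lam[sel], y[sel]

    offset0 = float(np.min(y_w))
    amp0 = float(np.max(y_w) - offset0)
    c0 = float(lam_w[np.argmax(y_w)])
    # initial gamma: half-width at half maximum of the discrete profile
    above = lam_w[y_w - offset0 >= amp0 / 2]
    gamma0 = max((above.max() - above.min()) / 2, np.diff(lam_w).min()) if above.size else 1.0
    p0 = (offset0, amp0, c0, gamma0)
    try:
        popt, pcov = curve_fit(_lorentzian, lam_w, y_w, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise CalibrationError(f"Lorentzian fit did not converge (p0={p0})") from exc
    if not np.all(np.isfinite(popt)) or not np.isfinite(pcov[2, 2]) or pcov[2, 2] < 0:
        raise CalibrationError(f"degenerate fit covariance (p0={p0})")
    offset, amp, center, gamma = popt
    return CalibrationLine(
        center_nm=float(center),
        fwhm_nm=float(2 * abs(gamma)),
        center_se_nm=float(np.sqrt(pcov[2, 2])),
        amplitude=float(amp),
        offset=float(offset),
    )


@dataclass(frozen=True)
class PixelWavelengthMap:
    """Polynomial pixel→nm mapping with per-line residuals."""

    poly: Polynomial
    residuals_nm: np.ndarray

    def __call__(self, pixel_positions) -> np.ndarray:
        return self.poly(np.asarray(pixel_positions, dtype=float))

    def axis(self, pixel_positions) -> SpectralAxis:
        return SpectralAxis(self(pixel_positions))


def calibrate_axis(
    pixel_positions,
    known_lines_nm,
    degree: int = 1,
) -> PixelWavelengthMap:
    """Least-squares polynomial pixel→wavelength calibration.

    Requires strictly more reference lines than the polynomial degree.
    """
    px = np.asarray(pixel_positions, dtype=float)
    nm = np.asarray(known_lines_nm, dtype=float)
    if px.shape != nm.shape or px.ndim != 1:
        raise ValueError("pixel positions and line wavelengths must be 1-D and equal length")
    if px.size <= degree:
        raise ValueError(
            f"{px.size} reference lines cannot determine a degree-{degree} map"
        )
    poly = Polynomial.fit(px, nm, deg=degree).convert()
    return PixelWavelengthMap(poly=poly, residuals_nm=nm - poly(px))
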
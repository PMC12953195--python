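"""Fluorescence spectra arithmetic and the ligand-depletion binding fit.

A titration holds the receptor (importin species) fixed at total
concentration PT and varies the total peptide concentration LT.  Because
PT is comparable to Kd, the bound fraction is obtained from the exact
mass-balance quadratic rather than the hyperbolic approximation:

    F(LT) = F0 + (dFmax / (2 PT)) *
            [(PT + LT + Kd) - sqrt((PT + LT + Kd)**2 - 4 PT LT)]

The signal change dFmax is unconstrained in sign (binding quenched the
fluorescence in the systems this package models).  Observed intensities can
first be corrected for the inner-filter effect with the standard
half-absorbance factor 10**((A_ex + A_em)/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Spectrum",
    "TitrationSeries",
    "BindingFit",
    "FitFailure",
    "inner_filter_correct",
    "addition_spectrum",
    "compare_spectra",
    "binding_curve",
    "fit_titration",
]


class FitFailure(RuntimeError):
    """Titration could not be fit to the depletion isotherm."""


@dataclass(frozen=True)
class Spectrum:
    wavelength: np.ndarray       # nm, strictly increasing
    intensity: np.ndarray        # arbitrary units
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if wl.shape != it.shape or wl.ndim != 1:
            raise ValueError("wavelength/intensity must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise ValueError("intensities must be finite")

    @property
    def lambda_max(self) -> float:
        return float(self.wavelength[int(np.argmax(self.intensity))])


@dataclass(frozen=True)
class TitrationSeries:
    ligand_total_um: np.ndarray   # varied peptide concentration, uM
    signal: np.ndarray            # blank-subtracted fluorescence
    protein_total_um: float       # fixed importin concentration, uM
    excitation_nm: float | None = None

    def __post_init__(self) -> None:
        lt = np.asarray(self.ligand_total_um, dtype=float)
        f = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "ligand_total_um", lt)
        object.__setattr__(self, "signal", f)
        if lt.shape != f.shape or lt.ndim != 1:
            raise ValueError("concentration/signal must be matching 1-D arrays")
        if np.any(lt < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(lt) <= 0):
            raise ValueError("ligand concentrations must strictly increase")
        if self.protein_total_um <= 0:
            raise ValueError("protein concentration must be > 0")


@dataclass(frozen=True)
class BindingFit:
    kd_um: float
    sigma_kd_um: float
    f0: float
    dfmax: float
    residual_norm: float
    identifiable: bool
    note: str = ""


def inner_filter_correct(f_obs, a_excitation, a_emission):
    """Half-absorbance inner-filter correction: F * 10**((Aex+Aem)/2)."""
    a_ex = np.asarray(a_excitation, dtype=float)
    a_em = np.asarray(a_emission, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be >= 0")
    return np.asarray(f_obs, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)


def _common_grid(s1: Spectrum, s2: Spectrum) -> np.ndarray:
    lo = max(s1.wavelength[0], s2.wavelength[0])
    hi = min(s1.wavelength[-1], s2.wavelength[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint wavelength ranges")
    finer = s1 if s1.wavelength.size >= s2.wavelength.size else s2
    grid = finer.wavelength
    return grid[(grid >= lo) & (grid <= hi)]


def addition_spectrum(s1: Spectrum, s2: Spectrum) -> Spectrum:
    """Pointwise sum on a common grid (linear resampling if needed)."""
    grid = _common_grid(s1, s2)
    i1 = np.interp(grid, s1.wavelength, s1.intensity)
    i2 = np.interp(grid, s2.wavelength, s2.intensity)
    return Spectrum(grid, i1 + i2, excitation_nm=s1.excitation_nm)


def compare_spectra(complex_spectrum: Spectrum,
                    addition: Spectrum) -> dict:
    """Intensity difference at the addition spectrum's maximum, and the
    lambda-max shift (complex minus addition), in nm."""
    grid = _common_grid(complex_spectrum, addition)
    ic = np.interp(grid, complex_spectrum.wavelength,
                   complex_spectrum.intensity)
    ia = np.interp(grid, addition.wavelength, addition.intensity)
    k = int(np.argmax(ia))
    return {
        "intensity_difference_at_addition_max": float(ic[k] - ia[k]),
        "lambda_max_shift_nm": float(grid[int(np.argmax(ic))] - grid[k]),
    }


def binding_curve(lt_um, pt_um: float, kd_um: float,
                  f0: float, dfmax: float) -> np.ndarray:
    """Forward ligand-depletion isotherm F(LT)."""
    if pt_um <= 0:
        raise ValueError("PT must be > 0")
    if kd_um <= 0:
        raise ValueError("Kd must be > 0")
    lt = np.asarray(lt_um, dtype=float)
    s = pt_um + lt + kd_um
    disc = np.clip(s * s - 4.0 * pt_um * lt, 0.0, None)
    return f0 + (dfmax / (2.0 * pt_um)) * (s - np.sqrt(disc))


def fit_titration(series: TitrationSeries,
                  weights: np.ndarray | None = None,
                  kd_identifiability_window: tuple[float, float] = (0.1, 10.0),
                  ) -> BindingFit:
    """Nonlinear least-squares (Kd, F0, dFmax) fit of a titration.

    The identifiability flag is cleared when the fitted Kd falls outside
    [PT * lo, max(LT) * hi] for the configured window factors, or when its
    covariance-based uncertainty exceeds the estimate itself.
    """
    lt = series.ligand_total_um
    f = series.signal
    if lt.size < 5:
        raise ValueError("need at least 5 titration points")
    positive = lt[lt > 0]
    if positive.size and positive.max() / positive.min() < 3.0:
        raise ValueError("titration must span at least a 3-fold range")
    pt = series.protein_total_um

    span = float(f[-1] - f[0])
    if np.allclose(f, f[0], atol=1e-12 + 1e-9 * abs(f[0])):
        raise FitFailure("flat titration: no signal change to fit")

    def model(lt_arr, log_kd, f0, dfmax):
        return binding_curve(lt_arr, pt, np.exp(log_kd), f0, dfmax)

    sigma = None if weights is None else 1.0 / np.asarray(weights, float)
    p0 = (np.log(max(np.median(lt[lt > 0]), 1e-3)), float(f[0]), span)
    try:
        popt, pcov = curve_fit(model, lt, f, p0=p0, sigma=sigma,
                               absolute_sigma=False, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailure(f"titration fit did not converge: {exc}") from exc
    log_kd, f0, dfmax = popt
    kd = float(np.exp(log_kd))
    sigma_kd = kd * float(np.sqrt(max(pcov[0, 0], 0.0)))
    resid = f - model(lt, *popt)
    lo_fac, hi_fac = kd_identifiability_window
    lo = pt * lo_fac
    hi = float(lt.max()) * hi_fac
    # boundary counts as unidentifiable (tolerance absorbs optimizer noise)
    inside = lo * (1.0 + 1e-6) < kd < hi * (1.0 - 1e-6)
    identifiable = bool(inside) and np.isfinite(sigma_kd) and sigma_kd < kd
    note = "" if identifiable else (
        f"Kd = {kd:.3g} uM outside identifiable window [{lo:.3g}, {hi:.3g}] "
        "uM or ill-determined; no trustable Kd")
    return BindingFit(kd_um=kd, sigma_kd_um=sigma_kd, f0=float(f0),
                      dfmax=float(dfmax),
                      residual_norm=float(np.linalg.norm(resid)),
                      identifiable=identifiable, note=note)
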
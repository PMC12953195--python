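"""Translational diffusion and hydrodynamic radii from PFG-NMR decays.

The pulsed-field-gradient spin-echo signal of a monodisperse species decays
as the Stejskal-Tanner mono-exponential in the squared gradient strength,

    I(g) = I0 * exp(-D * (gamma * g * delta)**2 * (Delta - delta/3)),

with D the translational self-diffusion coefficient, gamma the 1H
gyromagnetic ratio, delta the gradient pulse length and Delta the diffusion
delay.  Radii come from two independent routes: (i) the ratio to an
internal dioxane reference of known Rh = 2.12 A (Stokes-Einstein terms for
temperature and viscosity cancel in the ratio), and (ii) the empirical
random-coil scaling law Rh = a * MW**b (Rh in nm, MW in Da).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DosyDecay",
    "HydroResult",
    "ScalingLaw",
    "GYROMAGNETIC_1H",
    "DIOXANE_RH_A",
    "fit_decay",
    "rh_from_reference",
    "rh_random_coil",
    "assess_monomeric_disordered",
]

# 1H gyromagnetic ratio in rad s^-1 G^-1 (2.6752e8 rad s^-1 T^-1 / 1e4 G/T)
GYROMAGNETIC_1H = 26752.0
DIOXANE_RH_A = 2.12  # hydrodynamic radius of dioxane, Angstrom


@dataclass(frozen=True)
class DosyDecay:
    """One gradient-strength vs intensity decay trace.

    gradient G cm^-1, delta/Delta in s; D then comes out in cm^2 s^-1.
    """

    gradient: np.ndarray
    intensity: np.ndarray
    gamma: float = GYROMAGNETIC_1H
    delta: float = 0.002        # gradient pulse length (s)
    big_delta: float = 0.100    # diffusion delay (s)
    label: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "gradient", g)
        object.__setattr__(self, "intensity", i)
        if g.shape != i.shape or g.ndim != 1 or g.size < 3:
            raise ValueError("gradient/intensity must be equal-length 1-D "
                             "arrays with at least 3 points")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def b_values(self) -> np.ndarray:
        """Stejskal-Tanner exponent prefactor b = (gamma g delta)^2 (Delta - delta/3)."""
        return ((self.gamma * self.gradient * self.delta) ** 2
                * (self.big_delta - self.delta / 3.0))


@dataclass(frozen=True)
class ScalingLaw:
    """Empirical random-coil scaling Rh = a * MW**b (Rh nm, MW Da)."""

    a: float = 0.027
    sigma_a: float = 0.01
    b: float = 0.50
    sigma_b: float = 0.01

    def __post_init__(self) -> None:
        if self.a <= 0 or not (0.0 < self.b < 1.0):
            raise ValueError("require a > 0 and 0 < b < 1")


@dataclass(frozen=True)
class HydroResult:
    D: float                    # cm^2 s^-1
    sigma_D: float
    rh_reference: float | None  # Angstrom, dioxane-referenced
    sigma_rh_reference: float | None
    rh_scaling: float | None    # Angstrom, scaling-law
    sigma_rh_scaling: float | None
    methods: tuple[str, ...] = field(default=("stejskal-tanner",))


class FitFailure(RuntimeError):
    """Decay could not be fit (flat or rising trace, singular fit)."""


def fit_decay(decay: DosyDecay) -> tuple[float, float]:
    """Least-squares (D, sigma_D) from a Stejskal-Tanner decay."""
    b = decay.b_values
    i = decay.intensity
    if i[0] <= 0:
        raise FitFailure("non-positive initial intensity")
    # reject non-decaying traces before fitting
    slope = np.polyfit(b, np.log(np.clip(i, 1e-300, None)), 1)[0]
    if slope >= 0:
        raise FitFailure("trace does not decay with gradient strength "
                         f"(log-linear slope {slope:.3g} >= 0)")
    d0 = -slope

    def model(bv, i0, d):
        return i0 * np.exp(-np.clip(d * bv, -700.0, 700.0))

    try:
        popt, pcov = curve_fit(model, b, i, p0=(i[0], d0), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy failure path
        raise FitFailure(str(exc)) from exc
    i0, d = popt
    if d <= 0 or not np.isfinite(pcov).all():
        raise FitFailure(f"degenerate fit (D = {d:.3g})")
    return float(d), float(np.sqrt(pcov[1, 1]))


def rh_from_reference(d_solute: float, d_reference: float,
                      rh_reference: float = DIOXANE_RH_A,
                      sigma_d_solute: float = 0.0,
                      sigma_d_reference: float = 0.0) -> tuple[float, float]:
    """Rh (A) from the internal-reference ratio, with quadrature error."""
    if d_solute <= 0 or d_reference <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    rh = rh_reference * d_reference / d_solute
    rel = np.hypot(sigma_d_solute / d_solute, sigma_d_reference / d_reference)
    return float(rh), float(rh * rel)


def rh_random_coil(mw: float,
                   law: ScalingLaw | None = None) -> tuple[float, float]:
    """Random-coil Rh (A) from molecular weight via the scaling law.

    First-order propagation through sigma_a and sigma_b.
    """
    if mw <= 0:
        raise ValueError("MW must be > 0")
    law = law or ScalingLaw()
    rh_nm = law.a * mw ** law.b
    # d/da = MW^b ; d/db = a MW^b ln MW
    var = ((mw ** law.b) * law.sigma_a) ** 2 \
        + (rh_nm * np.log(mw) * law.sigma_b) ** 2
    return float(10.0 * rh_nm), float(10.0 * np.sqrt(var))


def assess_monomeric_disordered(measured: tuple[float, float],
                                predicted: tuple[float, float]) -> dict:
    """Overlap verdict between measured and random-coil-predicted Rh."""
    rh_m, s_m = measured
    rh_p, s_p = predicted
    if s_m < 0 or s_p < 0:
        raise ValueError("uncertainties must be >= 0")
    margin = (s_m + s_p) - abs(rh_m - rh_p)
    return {
        "verdict": "consistent" if margin >= 0 else "inconsistent",
        "overlap_margin": float(margin),
    }
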
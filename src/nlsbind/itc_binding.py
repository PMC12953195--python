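"""Single-site ITC forward model and fit.

An overflow-cell titration dilutes both species at each injection: after
injection j the totals in the cell are

    LT_j = [L]_syr * (1 - prod_{k<=j} (1 - v_k/V0))
    PT_j = [P]_cell * prod_{k<=j} (1 - v_k/V0).

An apparent stoichiometry n rescales the binding-competent protein to
n*PT.  The complex concentration follows from the single-site quadratic

    [PL] = [(1 + Ka nPT + Ka LT) - sqrt((1 + Ka nPT + Ka LT)^2
            - 4 Ka^2 nPT LT)] / (2 Ka)

and the ligand-normalized heat of injection j is

    Q_j = V0 dH ([PL]_j - [PL]_{j-1} (1 - v_j/V0)) / (v_j [L]_syr) + Qd,

with Qd a constant background ("dilution") heat.  Internally Eq-level
arithmetic is done in molar units (Ka in M^-1); the public surface speaks
micromolar.  The fit estimates (Ka, dH, n, Qd) by nonlinear least squares
and derives Kd = 1/Ka plus the thermodynamic profile
dG = -R T ln Ka, -TdS = dG - dH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ItcProtocol",
    "ItcIsotherm",
    "ItcFit",
    "ThermoProfile",
    "FitFailure",
    "R_KCAL",
    "cell_concentrations",
    "complex_concentration",
    "injection_heats",
    "fit_isotherm",
    "kd_from_ka",
    "thermodynamic_profile",
]

R_KCAL = 1.987e-3  # gas constant, kcal mol^-1 K^-1


class FitFailure(RuntimeError):
    """Isotherm could not be fit to the single-site model."""


@dataclass(frozen=True)
class ItcProtocol:
    """Injection geometry and concentrations of one titration."""

    cell_volume_ul: float = 200.3            # Auto-iTC200 nominal cell
    injection_volumes_ul: tuple[float, ...] = (2.0,) * 19
    syringe_ligand_um: float = 100.0
    cell_protein_um: float = 10.0
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.injection_volumes_ul)
        object.__setattr__(self, "injection_volumes_ul", v)
        if self.cell_volume_ul <= 0 or any(x <= 0 for x in v):
            raise ValueError("all volumes must be > 0")
        if sum(v) >= self.cell_volume_ul:
            raise ValueError("total injected volume must stay below V0")
        if self.syringe_ligand_um <= 0 or self.cell_protein_um <= 0:
            raise ValueError("concentrations must be > 0")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def dilution_factors(self) -> np.ndarray:
        """Cumulative prod_{k<=j} (1 - v_k/V0), j = 1..N."""
        v = np.asarray(self.injection_volumes_ul)
        return np.cumprod(1.0 - v / self.cell_volume_ul)


@dataclass(frozen=True)
class ItcIsotherm:
    molar_ratio: np.ndarray     # LT_j / PT_j per injection
    heats_kcal_mol: np.ndarray  # ligand-normalized heat per injection

    def __post_init__(self) -> None:
        mr = np.asarray(self.molar_ratio, dtype=float)
        q = np.asarray(self.heats_kcal_mol, dtype=float)
        object.__setattr__(self, "molar_ratio", mr)
        object.__setattr__(self, "heats_kcal_mol", q)
        if mr.shape != q.shape or mr.ndim != 1:
            raise ValueError("molar_ratio/heats must be matching 1-D arrays")
        if np.any(np.diff(mr) <= 0):
            raise ValueError("molar ratio must strictly increase")


@dataclass(frozen=True)
class ItcFit:
    ka_m: float                 # M^-1
    sigma_ka_m: float
    dh_kcal_mol: float
    sigma_dh: float
    n: float
    sigma_n: float
    qd_kcal_mol: float
    sigma_qd: float
    residual_norm: float

    @property
    def kd_um(self) -> float:
        return kd_from_ka(self.ka_m)

    @property
    def sigma_kd_um(self) -> float:
        return self.kd_um * self.sigma_ka_m / self.ka_m


@dataclass(frozen=True)
class ThermoProfile:
    dg_kcal_mol: float
    dh_kcal_mol: float
    minus_tds_kcal_mol: float
    temperature_k: float
    entropically_driven: bool = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "entropically_driven",
            self.minus_tds_kcal_mol < 0 and self.dh_kcal_mol > 0)


def cell_concentrations(protocol: ItcProtocol,
                        j: int) -> tuple[float, float]:
    """(LT_j, PT_j) in uM after injection j (1-based)."""
    if not (1 <= j <= protocol.n_injections):
        raise ValueError(
            f"injection index {j} out of range 1..{protocol.n_injections}")
    frac = protocol.dilution_factors()[j - 1]
    lt = protocol.syringe_ligand_um * (1.0 - frac)
    pt = protocol.cell_protein_um * frac
    return float(lt), float(pt)


def complex_concentration(pt_um: float, lt_um: float, ka_m: float,
                          n: float = 1.0) -> float:
    """[PL] in uM from the single-site quadratic with competent protein n*PT."""
    if ka_m <= 0:
        raise ValueError("Ka must be > 0")
    if pt_um < 0 or lt_um < 0:
        raise ValueError("concentrations must be >= 0")
    pt = n * pt_um * 1e-6       # M
    lt = lt_um * 1e-6
    s = 1.0 + ka_m * pt + ka_m * lt
    disc = max(s * s - 4.0 * ka_m * ka_m * pt * lt, 0.0)
    pl = (s - np.sqrt(disc)) / (2.0 * ka_m)
    return float(pl * 1e6)


def injection_heats(protocol: ItcProtocol, ka_m: float, dh_kcal_mol: float,
                    n: float = 1.0, qd_kcal_mol: float = 0.0) -> np.ndarray:
    """Ligand-normalized heats Q_j (kcal per mol injectant), j = 1..N."""
    v = np.asarray(protocol.injection_volumes_ul)
    v0 = protocol.cell_volume_ul
    heats = np.empty(protocol.n_injections)
    pl_prev = 0.0
    for j in range(1, protocol.n_injections + 1):
        lt, pt = cell_concentrations(protocol, j)
        pl = complex_concentration(pt, lt, ka_m, n)
        vj = v[j - 1]
        # concentration units cancel against [L]_syr; volume units against V0
        heats[j - 1] = (v0 * dh_kcal_mol
                        * (pl - pl_prev * (1.0 - vj / v0))
                        / (vj * protocol.syringe_ligand_um)) + qd_kcal_mol
        pl_prev = pl
    return heats


def molar_ratios(protocol: ItcProtocol) -> np.ndarray:
    """LT_j / PT_j for j = 1..N."""
    out = np.empty(protocol.n_injections)
    for j in range(1, protocol.n_injections + 1):
        lt, pt = cell_concentrations(protocol, j)
        out[j - 1] = lt / pt
    return out


def fit_isotherm(isotherm: ItcIsotherm, protocol: ItcProtocol,
                 p0: tuple[float, float, float, float] | None = None,
                 ) -> ItcFit:
    """Least-squares (Ka, dH, n, Qd) from a normalized-heat isotherm.

    Ka is fit on a log scale.  The default start point places Kd near the
    cell protein concentration (c-value ~ 1-10), dH at the first-injection
    heat, n = 1 and Qd at the mean tail heat.
    """
    q = isotherm.heats_kcal_mol
    if q.size < 8:
        raise ValueError("need at least 8 injections to fit")
    if q.size != protocol.n_injections:
        raise ValueError("isotherm length does not match protocol")
    if np.allclose(q, q[0], atol=1e-12 + 1e-9 * abs(q[0])):
        raise FitFailure("isotherm carries no signal (constant heats)")

    def model(_x, log_ka, dh, n, qd):
        return injection_heats(protocol, np.exp(log_ka), dh, n, qd)

    if p0 is None:
        qd0 = float(np.mean(q[-3:]))
        dh0 = float(q[0] - qd0)
        if dh0 == 0.0:
            dh0 = float(np.ptp(q)) or 1.0
        ka0 = 1.0 / (protocol.cell_protein_um * 1e-6)  # c ~ 1
        p0 = (np.log(ka0), dh0, 1.0, qd0)
    else:
        ka, dh, n, qd = p0
        p0 = (np.log(ka), dh, n, qd)
    x = np.arange(q.size)
    lo_lka, hi_lka = np.log(1e-2), np.log(1e15)
    try:
        popt, pcov = curve_fit(
            model, x, q, p0=p0, maxfev=40000,
            bounds=([lo_lka, -1e4, 1e-3, -1e3],
                    [hi_lka, 1e4, 1e2, 1e3]))
    except (RuntimeError, ValueError) as exc:
        raise FitFailure(f"isotherm fit did not converge: {exc}") from exc
    log_ka, dh, n, qd = popt
    ka = float(np.exp(log_ka))
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if not np.isfinite(popt).all():
        raise FitFailure("isotherm fit returned non-finite parameters")
    # c-value degeneracy: the weak-binding ridge (n -> 0 with dH blowing
    # up, dH*n*Ka nearly invariant) or Ka escaping to a bound means the
    # data do not determine Kd
    if n < 0.1 or log_ka < lo_lka + 1e-3 or log_ka > hi_lka - 1e-3:
        raise FitFailure(
            "c-value degenerate regime: fitted n = "
            f"{n:.3g}, Ka = {ka:.3g} 1/M (weak-binding ridge or parameter "
            "bound); Kd is not identifiable from this isotherm")
    resid = q - model(x, *popt)
    return ItcFit(ka_m=ka, sigma_ka_m=float(ka * perr[0]),
                  dh_kcal_mol=float(dh), sigma_dh=float(perr[1]),
                  n=float(n), sigma_n=float(perr[2]),
                  qd_kcal_mol=float(qd), sigma_qd=float(perr[3]),
                  residual_norm=float(np.linalg.norm(resid)))


def kd_from_ka(ka_m: float) -> float:
    """Kd in uM from Ka in M^-1."""
    if ka_m <= 0:
        raise ValueError("Ka must be > 0")
    return 1e6 / ka_m


def thermodynamic_profile(ka_m: float, dh_kcal_mol: float,
                          temperature_k: float = 298.15) -> ThermoProfile:
    """dG, dH, -TdS (kcal/mol) at temperature T."""
    if ka_m <= 0 or temperature_k <= 0:
        raise ValueError("require Ka > 0 and T > 0")
    dg = -R_KCAL * temperature_k * np.log(ka_m)
    return ThermoProfile(dg_kcal_mol=float(dg), dh_kcal_mol=dh_kcal_mol,
                         minus_tds_kcal_mol=float(dg - dh_kcal_mol),
                         temperature_k=temperature_k)
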
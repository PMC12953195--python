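"""Biolayer-interferometry kinetics: drift-corrected exponential fits.

The association segment of a reference-subtracted sensorgram is fit with

    R(t) = Req - Req exp(-kobs (t - t0)) - R'eq (t - t0),

which is structurally zero at t0; the dissociation segment with

    R(t) = R1 exp(-koff (t - t0)) - R''eq (t - t0),

which equals R1 at t0.  The linear terms absorb the slow instrumental
drift seen at long times.  Observed rates at several analyte
concentrations follow the pseudo-first-order relation
kobs = kon * c + koff; the regression slope and intercept give kon
(uM^-1 s^-1) and koff (s^-1), and Kd = koff/kon with first-order
error propagation.  A two-state (single on/off path) binding mechanism is
assumed throughout and recorded on every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "SensorgramSchedule",
    "Sensorgram",
    "AssociationFit",
    "DissociationFit",
    "KineticsResult",
    "FitFailure",
    "association_model",
    "dissociation_model",
    "fit_association",
    "fit_dissociation",
    "pseudo_first_order",
    "kd_from_rates",
]


class FitFailure(RuntimeError):
    """Sensorgram segment could not be fit."""


@dataclass(frozen=True)
class SensorgramSchedule:
    """Contiguous (name, start s, duration s) segments of one run."""

    segments: tuple[tuple[str, float, float], ...] = (
        ("baseline1", 0.0, 30.0),
        ("load", 30.0, 120.0),
        ("baseline2", 150.0, 30.0),
        ("association", 180.0, 120.0),
        ("dissociation", 300.0, 120.0),
    )

    def __post_init__(self) -> None:
        t = 0.0
        for name, start, dur in self.segments:
            if not np.isclose(start, t):
                raise ValueError(
                    f"segment {name!r} starts at {start}, expected {t} "
                    "(segments must be contiguous and non-overlapping)")
            if dur <= 0:
                raise ValueError(f"segment {name!r} has duration {dur} <= 0")
            t = start + dur

    def start(self, name: str) -> float:
        for seg, start, _ in self.segments:
            if seg == name:
                return start
        raise KeyError(name)

    def window(self, name: str) -> tuple[float, float]:
        for seg, start, dur in self.segments:
            if seg == name:
                return start, start + dur
        raise KeyError(name)

    @property
    def total_duration(self) -> float:
        _, start, dur = self.segments[-1]
        return start + dur


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray            # s, strictly increasing
    response: np.ndarray        # instrument units
    concentration_um: float     # analyte concentration during association
    schedule: SensorgramSchedule = SensorgramSchedule()

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("time/response must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        a0, _ = self.schedule.window("association")
        _, d1 = self.schedule.window("dissociation")
        if t[0] > a0 or t[-1] < d1 - 1e-9:
            raise ValueError("trace must span association and dissociation")

    def segment(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.schedule.window(name)
        mask = (self.time >= lo) & (self.time <= hi)
        return self.time[mask], self.response[mask]


@dataclass(frozen=True)
class AssociationFit:
    req: float
    kobs: float                 # s^-1
    drift: float                # response units s^-1 (R'eq)
    sigma_req: float
    sigma_kobs: float
    sigma_drift: float


@dataclass(frozen=True)
class DissociationFit:
    r1: float
    koff: float                 # s^-1
    drift: float                # R''eq
    sigma_r1: float
    sigma_koff: float
    sigma_drift: float


@dataclass(frozen=True)
class KineticsResult:
    kon: float                  # uM^-1 s^-1
    sigma_kon: float
    koff: float                 # s^-1
    sigma_koff: float
    kd_um: float
    sigma_kd_um: float
    two_state_assumed: bool = True


def association_model(t, req: float, kobs: float, drift: float,
                      t0: float = 180.0) -> np.ndarray:
    """Drift-corrected mono-exponential rise; exactly zero at t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t0):
        raise ValueError("association model defined for t >= t0")
    dt = t - t0
    return req - req * np.exp(-kobs * dt) - drift * dt


def dissociation_model(t, r1: float, koff: float, drift: float,
                       t0: float = 300.0) -> np.ndarray:
    """Drift-corrected mono-exponential decay; equals R1 at t0."""
    t = np.asarray(t, dtype=float)
    if np.any(t < t0):
        raise ValueError("dissociation model defined for t >= t0")
    dt = t - t0
    return r1 * np.exp(-koff * dt) - drift * dt


def _segment_fit(t, r, model, p0, t0):
    if t.size < 20:
        raise FitFailure(f"segment has {t.size} samples; need >= 20")
    try:
        popt, pcov = curve_fit(lambda tt, *p: model(tt, *p, t0=t0),
                               t, r, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailure(f"segment fit did not converge: {exc}") from exc
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    if not (np.isfinite(popt).all() and np.isfinite(perr).all()):
        raise FitFailure("segment fit produced non-finite estimates")
    return popt, perr


def fit_association(trace: Sensorgram) -> AssociationFit:
    """Fit the association segment for (Req, kobs, R'eq)."""
    t, r = trace.segment("association")
    t0 = trace.schedule.start("association")
    span = float(r[-1] - r[0]) if r.size else 0.0
    if r.size and np.ptp(r) > 0 and abs(span) < 0.05 * np.ptp(r):
        raise FitFailure("association segment shows no net rise "
                         "(likely pure noise)")
    p0 = (span if span != 0 else 1.0, 0.05, 0.0)
    popt, perr = _segment_fit(t, r, association_model, p0, t0)
    req, kobs, drift = popt
    if kobs <= 0:
        raise FitFailure(f"non-positive kobs ({kobs:.3g} 1/s)")
    rel_err = perr[1] / abs(kobs)
    if rel_err > 1.0:
        raise FitFailure(f"kobs undetermined (relative error {rel_err:.2f})")
    return AssociationFit(req=float(req), kobs=float(kobs),
                          drift=float(drift), sigma_req=float(perr[0]),
                          sigma_kobs=float(perr[1]),
                          sigma_drift=float(perr[2]))


def fit_dissociation(trace: Sensorgram) -> DissociationFit:
    """Fit the dissociation segment for (R1, koff, R''eq)."""
    t, r = trace.segment("dissociation")
    t0 = trace.schedule.start("dissociation")
    p0 = (float(r[0]) if r.size else 1.0, 0.05, 0.0)
    popt, perr = _segment_fit(t, r, dissociation_model, p0, t0)
    r1, koff, drift = popt
    if koff < 0:
        raise FitFailure(f"negative koff ({koff:.3g} 1/s)")
    return DissociationFit(r1=float(r1), koff=float(koff),
                           drift=float(drift), sigma_r1=float(perr[0]),
                           sigma_koff=float(perr[1]),
                           sigma_drift=float(perr[2]))


def pseudo_first_order(kobs: np.ndarray, concentrations_um: np.ndarray,
                       ) -> tuple[float, float, float, float]:
    """OLS of kobs on concentration: (kon, koff, sigma_kon, sigma_koff).

    Slope = kon in uM^-1 s^-1, intercept = koff in s^-1.  A negative
    intercept is reported as-is with a warning note left to the caller;
    flooring (if any) happens only in derived Kd values.
    """
    kobs = np.asarray(kobs, dtype=float)
    c = np.asarray(concentrations_um, dtype=float)
    if kobs.shape != c.shape or kobs.ndim != 1:
        raise ValueError("kobs/concentrations must be matching 1-D arrays")
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    res = stats.linregress(c, kobs)
    return (float(res.slope), float(res.intercept),
            float(res.stderr), float(res.intercept_stderr))


def kd_from_rates(kon: float, koff: float, sigma_kon: float = 0.0,
                  sigma_koff: float = 0.0) -> KineticsResult:
    """Kd = koff/kon (uM) with first-order quadrature error propagation."""
    if kon <= 0:
        raise ValueError("kon must be > 0")
    koff_eff = max(koff, 0.0)   # floor applies only to the derived Kd
    kd = koff_eff / kon
    if koff_eff > 0:
        rel = np.hypot(sigma_kon / kon, sigma_koff / koff_eff)
        sigma_kd = kd * rel
    else:
        sigma_kd = sigma_koff / kon
    return KineticsResult(kon=kon, sigma_kon=sigma_kon, koff=koff,
                          sigma_koff=sigma_koff, kd_um=float(kd),
                          sigma_kd_um=float(sigma_kd))
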
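"""Seeded generators for every instrument-level input the pipeline reads.

Each generator evaluates the exact forward model of its consumer module on
the stated experimental design and adds Gaussian noise (plus, for BLI,
linear drift terms).  With sigma = 0 the output equals the noiseless
forward model pointwise; identical (parameters, seed) give identical
output.  Defaults reproduce the study designs: fluorescence titrations at
PT = 3 uM with 0-30 uM ligand; ITC as 19 x 2 uL injections of 100 uM
ligand into 10 uM protein; BLI association at 1-10 uM analyte on the
30/120/30/120/120 s schedule; DOSY with a paired 1% dioxane internal
reference trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bli_kinetics import Sensorgram, SensorgramSchedule, \
    association_model, dissociation_model
from .fluor_binding import TitrationSeries, binding_curve
from .hydrodynamics import DosyDecay
from .itc_binding import ItcIsotherm, ItcProtocol, injection_heats, \
    molar_ratios
from .nmr_disorder import RandomCoilModel, ShiftEntry, ShiftTable, \
    load_random_coil_model

__all__ = [
    "NoiseSpec",
    "simulate_titration",
    "simulate_itc",
    "simulate_thermogram",
    "integrate_thermogram",
    "simulate_bli",
    "simulate_dosy",
    "simulate_shift_table",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian noise: absolute sigma in signal units, or relative."""

    sigma: float = 0.0
    relative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def apply(self, clean: np.ndarray,
              rng: np.random.Generator | None = None) -> np.ndarray:
        if self.sigma == 0.0:
            return np.asarray(clean, dtype=float).copy()
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        clean = np.asarray(clean, dtype=float)
        scale = self.sigma * (np.abs(clean) if self.relative else 1.0)
        return clean + rng.normal(0.0, 1.0, clean.shape) * scale

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


DEFAULT_LT_GRID_UM = np.linspace(0.0, 30.0, 16)


def simulate_titration(kd_um: float, f0: float, dfmax: float,
                       pt_um: float = 3.0,
                       lt_grid_um: np.ndarray | None = None,
                       noise: NoiseSpec = NoiseSpec(),
                       excitation_nm: float | None = 280.0,
                       ) -> TitrationSeries:
    """Fluorescence titration from the ligand-depletion isotherm."""
    lt = (DEFAULT_LT_GRID_UM if lt_grid_um is None
          else np.asarray(lt_grid_um, dtype=float))
    f = binding_curve(lt, pt_um, kd_um, f0, dfmax)
    return TitrationSeries(ligand_total_um=lt, signal=noise.apply(f),
                           protein_total_um=pt_um,
                           excitation_nm=excitation_nm)


def simulate_itc(protocol: ItcProtocol | None = None,
                 ka_m: float = 1e5, dh_kcal_mol: float = 27.7,
                 n: float = 0.85, qd_kcal_mol: float = 0.0,
                 noise: NoiseSpec = NoiseSpec()) -> ItcIsotherm:
    """Normalized-heat isotherm from the single-site injection model."""
    protocol = protocol or ItcProtocol()
    q = injection_heats(protocol, ka_m, dh_kcal_mol, n, qd_kcal_mol)
    return ItcIsotherm(molar_ratio=molar_ratios(protocol),
                       heats_kcal_mol=noise.apply(q))


def simulate_thermogram(protocol: ItcProtocol, heats_kcal_mol: np.ndarray,
                        spacing_s: float = 150.0, tau_s: float = 4.0,
                        dt_s: float = 0.05,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic power trace: one exponential-decay peak per injection.

    Peak k integrates (trapezoid) to the heat content of injection k in
    ucal, i.e. Q_k * v_k * [L]_syr expressed per mole of injectant.  Power
    is in ucal/s on a uniform time grid.  Simulator convention only.
    """
    v = np.asarray(protocol.injection_volumes_ul)
    q = np.asarray(heats_kcal_mol, dtype=float)
    t_end = spacing_s * (q.size + 1)
    t = np.arange(0.0, t_end, dt_s)
    power = np.zeros_like(t)
    for k, qk in enumerate(q):
        # kcal/mol * uL * uM = kcal * 1e-12 mol/mol... work in ucal:
        # moles injected = v_k[uL]*1e-6 L * Lsyr[uM]*1e-6 M = v*Lsyr*1e-12 mol
        # heat = qk[kcal/mol] * moles * 1e9 ucal/kcal
        heat_ucal = qk * v[k] * protocol.syringe_ligand_um * 1e-3
        t0 = spacing_s * (k + 1)
        mask = t >= t0
        power[mask] += (heat_ucal / tau_s) * np.exp(-(t[mask] - t0) / tau_s)
    return t, power


def integrate_thermogram(t: np.ndarray, power: np.ndarray,
                         protocol: ItcProtocol,
                         spacing_s: float = 150.0) -> np.ndarray:
    """Trapezoidal per-injection integration back to kcal/mol heats."""
    v = np.asarray(protocol.injection_volumes_ul)
    heats = np.empty(protocol.n_injections)
    for k in range(protocol.n_injections):
        t0 = spacing_s * (k + 1)
        t1 = t0 + spacing_s
        mask = (t >= t0) & (t < t1)
        area_ucal = np.trapezoid(power[mask], t[mask])
        heats[k] = area_ucal / (v[k] * protocol.syringe_ligand_um * 1e-3)
    return heats


def simulate_bli(kon_um_s: float, koff_s: float, rmax: float = 1.0,
                 concentrations_um: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0),
                 schedule: SensorgramSchedule | None = None,
                 association_drift: float = 0.0,
                 dissociation_drift: float = 0.0,
                 noise: NoiseSpec = NoiseSpec(),
                 dt_s: float = 0.5) -> list[Sensorgram]:
    """Two-state Langmuir sensorgrams at several analyte concentrations.

    kobs = kon*c + koff and Req(c) = Rmax c / (c + Kd) with
    Kd = koff/kon.  The analyte-channel response is zero through
    baseline/load segments (reference-subtracted convention), follows the
    drift-corrected association model, and continues into dissociation
    from R1 = R(association end), keeping R continuous at every boundary.
    """
    if any(c <= 0 for c in concentrations_um):
        raise ValueError("concentrations must be > 0")
    schedule = schedule or SensorgramSchedule()
    kd = koff_s / kon_um_s
    rng = noise.rng()
    a0, a1 = schedule.window("association")
    d0, d1 = schedule.window("dissociation")
    traces = []
    for c in concentrations_um:
        t = np.arange(0.0, schedule.total_duration + dt_s / 2, dt_s)
        r = np.zeros_like(t)
        kobs = kon_um_s * c + koff_s
        req = rmax * c / (c + kd)
        am = (t >= a0) & (t < d0)
        r[am] = association_model(t[am], req, kobs, association_drift, t0=a0)
        r1 = float(association_model(np.array([d0]), req, kobs,
                                     association_drift, t0=a0)[0])
        dm = t >= d0
        r[dm] = dissociation_model(t[dm], r1, koff_s, dissociation_drift,
                                   t0=d0)
        traces.append(Sensorgram(time=t, response=noise.apply(r, rng),
                                 concentration_um=c, schedule=schedule))
    return traces


DEFAULT_GRADIENTS = np.linspace(2.0, 60.0, 16)  # G cm^-1


def simulate_dosy(d_solute_cm2_s: float,
                  d_reference_cm2_s: float = 6.14e-6,
                  gradients: np.ndarray | None = None,
                  i0: float = 1.0, delta_s: float = 0.002,
                  big_delta_s: float = 0.100,
                  noise: NoiseSpec = NoiseSpec(),
                  ) -> tuple[DosyDecay, DosyDecay]:
    """(solute, dioxane-reference) Stejskal-Tanner decay pair."""
    if d_solute_cm2_s <= 0 or d_reference_cm2_s <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    g = (DEFAULT_GRADIENTS if gradients is None
         else np.asarray(gradients, dtype=float))
    rng = noise.rng()
    out = []
    for d, label in ((d_solute_cm2_s, "solute"),
                     (d_reference_cm2_s, "dioxane")):
        probe = DosyDecay(gradient=g, intensity=np.full_like(g, i0),
                          delta=delta_s, big_delta=big_delta_s, label=label)
        clean = i0 * np.exp(-d * probe.b_values)
        out.append(DosyDecay(gradient=g,
                             intensity=np.clip(noise.apply(clean, rng),
                                               0.0, None),
                             delta=delta_s, big_delta=big_delta_s,
                             label=label))
    return out[0], out[1]


def simulate_shift_table(sequence: str, start_residue: int = 1,
                         mode: str = "coil",
                         helical_span: tuple[int, int] | None = None,
                         bias_ppm: float = 0.3,
                         noise: NoiseSpec = NoiseSpec(),
                         model: RandomCoilModel | None = None) -> ShiftTable:
    """Halpha shift table: coil mode, or a helically biased segment.

    Helical bias shifts Halpha upfield (delta_obs = delta_rc - bias) on
    positions within ``helical_span`` (intact-protein numbering,
    inclusive).
    """
    if mode not in ("coil", "helical-segment"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "helical-segment" and helical_span is None:
        raise ValueError("helical-segment mode needs helical_span")
    model = model or load_random_coil_model()
    rng = noise.rng()
    entries = []
    for i, aa in enumerate(sequence):
        pos = start_residue + i
        nxt = sequence[i + 1] if i + 1 < len(sequence) else None
        ref = model.reference(aa, "HA", nxt)
        if ref is None:
            continue
        delta = ref
        if (mode == "helical-segment"
                and helical_span[0] <= pos <= helical_span[1]):
            delta -= bias_ppm
        if noise.sigma > 0:
            delta += rng.normal(0.0, noise.sigma)
        entries.append(ShiftEntry(position=pos, residue=aa, atom="HA",
                                  delta_obs=float(delta)))
    return ShiftTable(entries=tuple(entries))
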
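"""Pipeline orchestration and publication-style report tables.

``run_pipeline`` chains the stages — peptide properties, hydrodynamics,
disorder classification, and the three binding fits on synthetic data —
for every preset system, collecting one row per (peptide, importin) pair.
A failed fit never fabricates a number: the cell renders as "-" and the
failure is logged.  Numeric cells are rounded to 2 significant figures in
rendered tables (full precision is kept in the JSON output).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from pathlib import Path

import pandas as pd

from . import bli_kinetics, fluor_binding, hydrodynamics, itc_binding
from . import nmr_disorder, peptides, presets, synthetic_data
from .synthetic_data import NoiseSpec

__all__ = ["round_sig", "run_pipeline", "render_table"]

log = logging.getLogger("nlsbind")

FAILURE_MARK = "-"


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    q = 10.0 ** (exp - sig + 1)
    return math.copysign(math.floor(abs(x) / q + 0.5) * q, x)


def _fmt(x, sig: int = 2) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return FAILURE_MARK
    r = round_sig(float(x), sig)
    return f"{r:g}"


def _peptide_stage() -> dict:
    rows = {}
    law = hydrodynamics.ScalingLaw()
    for name, rec in presets.peptide_records().items():
        props = peptides.properties_json(rec)
        rh, s_rh = hydrodynamics.rh_random_coil(props["average_mass_da"], law)
        props["rh_scaling_A"] = rh
        props["sigma_rh_scaling_A"] = s_rh
        rows[name] = props
    return rows


def _hydro_stage(seed: int) -> dict:
    rows = {}
    for k, name in enumerate(sorted(presets.PEPTIDE_STRINGS)):
        noise = NoiseSpec(sigma=0.005, relative=False, seed=seed + k)
        d_true = 9.2e-7
        solute, dioxane = synthetic_data.simulate_dosy(d_true, noise=noise)
        try:
            d, s_d = hydrodynamics.fit_decay(solute)
            d_ref, s_dref = hydrodynamics.fit_decay(dioxane)
            rh, s_rh = hydrodynamics.rh_from_reference(d, d_ref,
                                                       sigma_d_solute=s_d,
                                                       sigma_d_reference=s_dref)
            rows[name] = {"D_cm2_s": d, "sigma_D": s_d,
                          "rh_reference_A": rh, "sigma_rh_reference_A": s_rh}
        except hydrodynamics.FitFailure as exc:
            log.warning("DOSY fit failed for %s: %s", name, exc)
            rows[name] = {"error": str(exc)}
    return rows


def _disorder_stage(seed: int) -> dict:
    rows = {}
    records = presets.peptide_records()
    for k, (name, rec) in enumerate(sorted(records.items())):
        table = synthetic_data.simulate_shift_table(
            rec.sequence, start_residue=rec.start_residue,
            noise=NoiseSpec(sigma=0.02, seed=seed + 100 + k))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            deltas, excluded = nmr_disorder.conformational_shifts(
                table, rec.sequence, rec.start_residue)
        rows[name] = nmr_disorder.classify_disorder(deltas)
        rows[name]["excluded"] = excluded
    return rows


def _itc_stage(seed: int, sigma: float = 0.3) -> dict:
    rows = {}
    protocol = itc_binding.ItcProtocol()
    for k, p in enumerate(presets.ITC_PRESETS):
        key = f"{p.peptide}/{p.importin}"
        iso = synthetic_data.simulate_itc(
            protocol, p.ka_m, p.dh_kcal_mol, p.n, qd_kcal_mol=0.5,
            noise=NoiseSpec(sigma=sigma, seed=seed + 200 + k))
        try:
            fit = itc_binding.fit_isotherm(iso, protocol)
            profile = itc_binding.thermodynamic_profile(
                fit.ka_m, fit.dh_kcal_mol, protocol.temperature_k)
            rows[key] = {
                "Ka_M": fit.ka_m, "Kd_uM": fit.kd_um,
                "dH_kcal_mol": fit.dh_kcal_mol, "n": fit.n,
                "dG_kcal_mol": profile.dg_kcal_mol,
                "minus_TdS_kcal_mol": profile.minus_tds_kcal_mol,
                "entropically_driven": profile.entropically_driven,
            }
        except itc_binding.FitFailure as exc:
            log.warning("ITC fit failed for %s: %s", key, exc)
            rows[key] = {"error": str(exc)}
    return rows


def _fluor_stage(seed: int, sigma: float = 0.01) -> dict:
    # Table-2-like design: fit synthetic titrations at the ITC Kd values
    rows = {}
    for k, p in enumerate(presets.ITC_PRESETS):
        key = f"{p.peptide}/{p.importin}"
        kd = itc_binding.kd_from_ka(p.ka_m)
        series = synthetic_data.simulate_titration(
            kd, f0=1.0, dfmax=-0.5,
            noise=NoiseSpec(sigma=sigma, seed=seed + 300 + k))
        try:
            fit = fluor_binding.fit_titration(series)
            if not fit.identifiable:
                log.warning("fluorescence Kd unidentifiable for %s: %s",
                            key, fit.note)
                rows[key] = {"error": fit.note or "unidentifiable"}
            else:
                rows[key] = {"Kd_uM": fit.kd_um,
                             "sigma_Kd_uM": fit.sigma_kd_um}
        except fluor_binding.FitFailure as exc:
            log.warning("fluorescence fit failed for %s: %s", key, exc)
            rows[key] = {"error": str(exc)}
    return rows


def _bli_stage(seed: int, sigma: float = 0.01) -> dict:
    rows = {}
    for k, p in enumerate(presets.BLI_PRESETS):
        key = f"{p.peptide}/{p.importin}"
        traces = synthetic_data.simulate_bli(
            p.kon_um_s, p.koff_s, rmax=1.0,
            association_drift=2e-4, dissociation_drift=1e-4,
            noise=NoiseSpec(sigma=sigma, seed=seed + 400 + k))
        try:
            kobs = [bli_kinetics.fit_association(tr).kobs for tr in traces]
            conc = [tr.concentration_um for tr in traces]
            kon, koff, s_kon, s_koff = bli_kinetics.pseudo_first_order(
                kobs, conc)
            res = bli_kinetics.kd_from_rates(kon, koff, s_kon, s_koff)
            rows[key] = {"kon_uM_s": res.kon, "koff_s": res.koff,
                         "Kd_uM": res.kd_um, "sigma_Kd_uM": res.sigma_kd_um}
        except (bli_kinetics.FitFailure, ValueError) as exc:
            log.warning("BLI fit failed for %s: %s", key, exc)
            rows[key] = {"error": str(exc)}
    return rows


STAGES = ("peptides", "hydrodynamics", "disorder", "itc", "fluorescence",
          "bli")


def run_pipeline(seed: int = 0, out_dir: str | Path | None = None,
                 stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages on the preset systems; return the bundle.

    When ``out_dir`` is given, writes ``results.json`` plus one rendered
    TSV table per stage there.
    """
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    bundle: dict = {"seed": seed}
    runners = {
        "peptides": lambda: _peptide_stage(),
        "hydrodynamics": lambda: _hydro_stage(seed),
        "disorder": lambda: _disorder_stage(seed),
        "itc": lambda: _itc_stage(seed),
        "fluorescence": lambda: _fluor_stage(seed),
        "bli": lambda: _bli_stage(seed),
    }
    for stage in STAGES:
        if stage in stages:
            log.info("running stage %s (seed %d)", stage, seed)
            bundle[stage] = runners[stage]()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(
            json.dumps(bundle, indent=2, default=str) + "\n")
        for stage in stages:
            text, _ = render_table(bundle[stage])
            (out / f"{stage}.tsv").write_text(text)
    return bundle


def render_table(results: dict, sig: int = 2) -> tuple[str, str]:
    """Render a stage's row dict as (TSV text, JSON text).

    Deterministic column order (sorted keys); failed cells render as "-".
    """
    if not results:
        return "", json.dumps({}, indent=2)
    columns: list[str] = []
    for row in results.values():
        for key in row:
            if key not in columns and key != "error":
                columns.append(key)
    columns = sorted(columns)
    records = []
    for name in results:
        row = results[name]
        rec = {"system": name}
        failed = "error" in row
        for col in columns:
            val = None if failed else row.get(col)
            if isinstance(val, (int, float)) and not isinstance(val, bool):
                rec[col] = _fmt(val, sig)
            elif val is None:
                rec[col] = FAILURE_MARK
            else:
                rec[col] = str(val)
        records.append(rec)
    frame = pd.DataFrame.from_records(records, columns=["system"] + columns)
    return (frame.to_csv(sep="\t", index=False),
            json.dumps(results, indent=2, default=str))
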
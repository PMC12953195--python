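#!/usr/bin/env python
"""Single-site ITC fits and thermodynamic profiles for all preset pairs.

Simulates the 19 x 2 uL titration (10 uM protein cell, 100 uM peptide
syringe) at each (peptide, importin) preset with 0.3 kcal/mol heat noise,
refits (Ka, dH, n, Qd), and derives Kd = 1/Ka, dG and -TdS.  All systems
come out entropically driven (dH > 0, -TdS < 0).  Writes
results/itc.tsv.
"""

import argparse
from pathlib import Path

from nlsbind.itc_binding import FitFailure, ItcProtocol, fit_isotherm, \
    thermodynamic_profile
from nlsbind.presets import ITC_PRESETS
from nlsbind.report import render_table, round_sig
from nlsbind.synthetic_data import NoiseSpec, simulate_itc

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    protocol = ItcProtocol()
    rows = {}
    for k, p in enumerate(ITC_PRESETS):
        name = f"{p.peptide}/{p.importin}"
        iso = simulate_itc(protocol, p.ka_m, p.dh_kcal_mol, p.n,
                           qd_kcal_mol=0.5,
                           noise=NoiseSpec(sigma=0.3, seed=args.seed + k))
        try:
            fit = fit_isotherm(iso, protocol)
        except FitFailure as exc:
            rows[name] = {"error": str(exc)}
            print(f"{name}: no trustable fit ({exc})")
            continue
        prof = thermodynamic_profile(fit.ka_m, fit.dh_kcal_mol)
        rows[name] = {"Ka_M": fit.ka_m, "Kd_uM": fit.kd_um,
                      "dH_kcal_mol": fit.dh_kcal_mol, "n": fit.n,
                      "dG_kcal_mol": prof.dg_kcal_mol,
                      "mTdS_kcal_mol": prof.minus_tds_kcal_mol,
                      "entropic": prof.entropically_driven}
        print(f"{name}: Ka {round_sig(fit.ka_m, 2):.2g} 1/M, Kd "
              f"{round_sig(fit.kd_um, 2):g} uM, dH {fit.dh_kcal_mol:.1f}, "
              f"n {fit.n:.2f}; dG {prof.dg_kcal_mol:.1f}, -TdS "
              f"{prof.minus_tds_kcal_mol:.1f} kcal/mol"
              f"{' (entropically driven)' if prof.entropically_driven else ''}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "itc.tsv").write_text(render_table(rows)[0])
    print("\nNote: the ~10 uM cells (full-length importin) sit at "
          "c = Ka[P]n ~ 1 where a free 4-parameter fit determines Kd only "
          "to within ~a factor of 2; the ~1 uM cells (c ~ 6) are well "
          "conditioned.")
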
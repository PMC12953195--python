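#!/usr/bin/env python
"""Disorder classification from Halpha shifts and NOE connectivity.

Generates coil-mode synthetic shift tables for each peptide (sigma = 0.02
ppm, well inside the 0.1 ppm band), classifies them, and summarizes a
sequential-only NOE set; also shows that a helically biased segment is
flagged structured.  Writes results/disorder.tsv.
"""

import argparse
from pathlib import Path

from nlsbind.nmr_disorder import (NoeContact, classify_disorder,
                                  conformational_shifts,
                                  noe_connectivity_summary)
from nlsbind.presets import peptide_records
from nlsbind.report import render_table
from nlsbind.synthetic_data import NoiseSpec, simulate_shift_table

if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    rows = {}
    for k, (name, rec) in enumerate(sorted(peptide_records().items())):
        table = simulate_shift_table(
            rec.sequence, start_residue=rec.start_residue,
            noise=NoiseSpec(sigma=0.02, seed=args.seed + k))
        deltas, _ = conformational_shifts(table, rec.sequence,
                                          rec.start_residue)
        verdict = classify_disorder(deltas)
        noes = noe_connectivity_summary(
            [NoeContact(i, i + 1, "aN")
             for i in range(rec.start_residue, rec.end_residue)])
        rows[name] = {"shift_verdict": verdict["verdict"],
                      "n_assigned": verdict["n_assigned"],
                      "noe_verdict": noes["verdict"]}
        print(f"{name}: {verdict['n_assigned']} assigned Halpha, all "
              f"|ddelta| <= 0.1 ppm -> {verdict['verdict']}; sequential-"
              f"only NOEs -> {noes['verdict']}")

    # counterexample: a helical stretch is caught
    rec = peptide_records()["PADI1-NLS1"]
    helical = simulate_shift_table(rec.sequence, rec.start_residue,
                                   mode="helical-segment",
                                   helical_span=(530, 538), bias_ppm=0.3)
    d, _ = conformational_shifts(helical, rec.sequence, rec.start_residue)
    out = classify_disorder(d)
    print(f"helically biased control: {out['verdict']}, offending "
          f"residues {out['offending_residues']}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "disorder.tsv").write_text(render_table(rows)[0])
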
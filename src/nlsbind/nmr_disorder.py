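"""Disorder classification from Halpha conformational shifts and NOEs.

The sequence-corrected conformational shift of residue i is

    ddelta_i = delta_obs(i) - delta_rc(i, neighbors),

where delta_rc is the random-coil reference corrected for neighboring
residue effects.  A peptide is classified random-coil when every assigned
|ddelta| lies within the accepted band (<= 0.1 ppm for Halpha, inclusive).
NOE connectivity gives an orthogonal check: a disordered chain shows only
sequential (i, i+1) contacts, no medium- (i, i+2..4) or long-range ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

__all__ = [
    "ShiftEntry",
    "ShiftTable",
    "RandomCoilModel",
    "NoeContact",
    "load_random_coil_model",
    "conformational_shifts",
    "classify_disorder",
    "noe_connectivity_summary",
    "read_shift_table",
    "DISORDER_THRESHOLD_PPM",
]

DISORDER_THRESHOLD_PPM = 0.1
NOE_CLASSES = frozenset({"aN", "bN", "NN", "ad", "ab"})
NOE_INTENSITIES = frozenset({"strong", "medium", "weak"})


@dataclass(frozen=True)
class ShiftEntry:
    position: int          # intact-protein numbering
    residue: str           # one-letter code
    atom: str              # e.g. "HA"
    delta_obs: float       # ppm

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_obs <= 12.0):
            raise ValueError(
                f"shift {self.delta_obs} ppm at position {self.position} "
                "outside the 0-12 ppm proton window")


@dataclass(frozen=True)
class ShiftTable:
    entries: tuple[ShiftEntry, ...]
    temperature_k: float | None = None
    ph: float | None = None


@dataclass(frozen=True)
class RandomCoilModel:
    """Base random-coil shifts plus bounded neighbor corrections."""

    base: dict[tuple[str, str], float]          # (residue, atom) -> ppm
    pre_pro: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(abs(c) >= 1.0 for c in self.pre_pro.values()):
            raise ValueError("neighbor corrections must satisfy |corr| < 1 ppm")

    def reference(self, residue: str, atom: str,
                  next_residue: str | None = None) -> float | None:
        key = (residue, atom)
        if key not in self.base:
            return None
        delta = self.base[key]
        if next_residue == "P":
            delta += self.pre_pro.get(key, 0.0)
        return delta


@dataclass(frozen=True)
class NoeContact:
    i: int
    j: int
    contact_class: str              # aN, bN, NN, ad, ab
    intensity: str = "medium"       # strong / medium / weak
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.i > self.j:
            raise ValueError("require i <= j")
        if self.contact_class not in NOE_CLASSES:
            raise ValueError(f"unknown NOE class {self.contact_class!r}")
        if self.intensity not in NOE_INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")


def load_random_coil_model() -> RandomCoilModel:
    """Load the packaged Halpha random-coil reference table."""
    with resources.files("nlsbind.data").joinpath(
            "random_coil_halpha.csv").open() as fh:
        table = pd.read_csv(fh, comment="#")
    base = {(r.residue, r.atom): float(r.delta_rc)
            for r in table.itertuples()}
    pre_pro = {(r.residue, r.atom): float(r.pre_pro_corr)
               for r in table.itertuples()}
    return RandomCoilModel(base=base, pre_pro=pre_pro)


def conformational_shifts(shifts: ShiftTable, sequence: str,
                          start_residue: int = 1,
                          model: RandomCoilModel | None = None,
                          ) -> tuple[dict[int, float], list[int]]:
    """Per-residue ddelta (ppm) keyed by position; excluded positions listed.

    ``sequence`` spans positions start_residue .. start_residue+len-1 in
    intact-protein numbering; every entry must match it.
    """
    model = model or load_random_coil_model()
    deltas: dict[int, float] = {}
    excluded: list[int] = []
    end = start_residue + len(sequence) - 1
    for entry in shifts.entries:
        if not (start_residue <= entry.position <= end):
            raise ValueError(
                f"position {entry.position} outside the peptide span "
                f"{start_residue}-{end}")
        idx = entry.position - start_residue
        if sequence[idx] != entry.residue:
            raise ValueError(
                f"residue mismatch at position {entry.position}: table says "
                f"{entry.residue!r}, sequence has {sequence[idx]!r}")
        next_res = sequence[idx + 1] if idx + 1 < len(sequence) else None
        ref = model.reference(entry.residue, entry.atom, next_res)
        if ref is None:
            excluded.append(entry.position)
            continue
        deltas[entry.position] = entry.delta_obs - ref
    if excluded:
        warnings.warn(
            f"{len(excluded)} entr(ies) lacked a random-coil reference and "
            f"were excluded: positions {excluded}", stacklevel=2)
    return deltas, excluded


def classify_disorder(deltas: dict[int, float],
                      threshold: float = DISORDER_THRESHOLD_PPM) -> dict:
    """Random-coil verdict: all |ddelta| <= threshold (inclusive)."""
    if not deltas:
        raise ValueError("no assigned residues: disorder is indeterminate")
    offending = sorted(p for p, d in deltas.items() if abs(d) > threshold)
    return {
        "verdict": "random-coil" if not offending else "structured",
        "offending_residues": offending,
        "threshold_ppm": threshold,
        "n_assigned": len(deltas),
    }


def noe_connectivity_summary(contacts: list[NoeContact]) -> dict:
    """Count sequential/medium/long NOEs and give a coil verdict."""
    counts = {"sequential": 0, "medium": 0, "long": 0, "intraresidue": 0}
    for c in contacts:
        sep = c.j - c.i
        if sep == 0:
            counts["intraresidue"] += 1
        elif sep == 1:
            counts["sequential"] += 1
        elif sep <= 4:
            counts["medium"] += 1
        else:
            counts["long"] += 1
    if not contacts:
        verdict = "indeterminate"
    elif counts["medium"] == 0 and counts["long"] == 0 \
            and counts["sequential"] >= 1:
        verdict = "coil-consistent"
    else:
        verdict = "not-coil-consistent"
    return {"counts": counts, "verdict": verdict}


def read_shift_table(path, temperature_k: float | None = None,
                     ph: float | None = None) -> ShiftTable:
    """Read a delimited (position, residue, atom, shift) text table."""
    table = pd.read_csv(path, sep=None, engine="python", comment="#")
    table.columns = [c.strip().lower() for c in table.columns]
    entries = tuple(
        ShiftEntry(position=int(r.position), residue=str(r.residue).upper(),
                   atom=str(r.atom).upper(), delta_obs=float(r.shift))
        for r in table.itertuples())
    return ShiftTable(entries=entries, temperature_k=temperature_k, ph=ph)
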
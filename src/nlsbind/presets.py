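"""Published system presets: the four NLS peptides and their fitted
binding parameters, used as realistic defaults for the synthetic
generators and for derived-value arithmetic (Kd = 1/Ka, Kd = koff/kon).

All peptides are N-acetylated and C-amidated; numbering matches the
intact PADI isoform.  PADI1-NLS1 carries Cys546Ser and PADI3-NLS2
Cys564Ser (as synthesized); PADI2-NLS2 carries an extra C-terminal Tyr
added for quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

from .peptides import PeptideRecord, parse_annotated_sequence

__all__ = [
    "PEPTIDE_STRINGS",
    "peptide_records",
    "ItcPreset",
    "BliPreset",
    "ITC_PRESETS",
    "BLI_PRESETS",
    "PUBLISHED_MW_DA",
]

PEPTIDE_STRINGS: dict[str, str] = {
    "PADI1-NLS1": "K^520^HQAKRSINEMLADRHLQRDNLHAQKSIDW^549^",
    "PADI2-NLS2": "K^499^LFREKQKDGHGEAIMFKGLGGMSSKRIT^527^Y",
    "PADI3-NLS1": "H^361^KTLPVVFDSPRNGELQDFPYKRIL^385^",
    "PADI3-NLS2": "R^552^EVLKRELGLAESDIIDIPQLFKTERKKAT^581^",
}

# MWs as printed alongside the sequences (Da).  The PADI1-NLS1 value
# matches the wild-type Cys546 sequence rather than the synthesized
# Cys546Ser variant (16.07 Da lower); reported as printed.
PUBLISHED_MW_DA: dict[str, float] = {
    "PADI1-NLS1": 3697.16,
    "PADI2-NLS2": 3455.00,
    "PADI3-NLS1": 3011.42,
    "PADI3-NLS2": 3539.08,
}


def peptide_records() -> dict[str, PeptideRecord]:
    """Parse the annotated preset sequences into capped records."""
    out = {}
    for name, text in PEPTIDE_STRINGS.items():
        rec = parse_annotated_sequence(f"{text} ({name})")
        out[name] = rec
    return out


@dataclass(frozen=True)
class ItcPreset:
    """Single-site ITC parameters for one (peptide, importin) pair."""

    peptide: str
    importin: str               # "Impa3" or "dImpa3"
    ka_m: float                 # M^-1
    dh_kcal_mol: float
    n: float
    kd_consistent: bool = True  # printed Kd agrees with 1/Ka at 2 s.f.


ITC_PRESETS: tuple[ItcPreset, ...] = (
    ItcPreset("PADI1-NLS1", "Impa3", 1.0e5, 27.7, 0.85,
              kd_consistent=False),   # prints 9.8 uM vs 1/Ka = 10 uM
    ItcPreset("PADI2-NLS2", "Impa3", 7.6e4, 34.4, 0.96),
    ItcPreset("PADI3-NLS1", "Impa3", 1.6e5, 9.6, 0.84),
    ItcPreset("PADI3-NLS2", "Impa3", 1.2e5, 2.8, 0.85,
              kd_consistent=False),   # prints 8.1 uM vs 1/Ka = 8.3 uM
    ItcPreset("PADI1-NLS1", "dImpa3", 7.0e5, 15.9, 0.87),
    ItcPreset("PADI2-NLS2", "dImpa3", 8.7e4, 19.2, 0.81,
              kd_consistent=False),   # prints 1.2 uM vs 1/Ka = 11.5 uM
    ItcPreset("PADI3-NLS1", "dImpa3", 8.0e5, 16.7, 0.82),
    ItcPreset("PADI3-NLS2", "dImpa3", 6.0e5, 11.3, 0.95),
)


@dataclass(frozen=True)
class BliPreset:
    """Two-state kinetic rates for one (peptide, importin) pair."""

    peptide: str
    importin: str
    kon_um_s: float             # uM^-1 s^-1
    koff_s: float               # s^-1
    kd_consistent: bool = True  # printed Kd agrees with koff/kon at 2 s.f.


BLI_PRESETS: tuple[BliPreset, ...] = (
    BliPreset("PADI1-NLS1", "Impa3", 0.039, 0.09),
    BliPreset("PADI2-NLS2", "Impa3", 0.038, 0.09),
    BliPreset("PADI3-NLS2", "Impa3", 0.008, 0.014, kd_consistent=False),
    BliPreset("PADI1-NLS1", "dImpa3", 0.03, 0.06),
    BliPreset("PADI2-NLS2", "dImpa3", 0.05, 0.06),
    BliPreset("PADI3-NLS2", "dImpa3", 0.006, 0.16, kd_consistent=False),
)
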
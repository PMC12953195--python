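"""Peptide records and physicochemical quantities.

Handles annotated peptide sequences of the kind used for synthetic NLS
(nuclear localization signal) peptides: a numbered span matching the intact
parent protein, optional terminal caps (N-acetyl, C-amide), and optional
extra residues outside the numbered span (e.g. a tyrosine appended for
spectrophotometric quantification).  Provides average molecular mass,
molar extinction coefficients, aromatic inventories, and Beer-Lambert
concentration from absorbance.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "PeptideRecord",
    "MassModel",
    "ExtinctionModel",
    "ParseError",
    "parse_annotated_sequence",
    "read_fasta",
    "average_mass",
    "extinction_coefficient",
    "concentration_from_absorbance",
    "aromatic_inventory",
]

CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")

# Average (isotope-abundance weighted) residue masses in Da, standard
# 3-decimal table for amino-acid residues in a polypeptide chain.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.052, "A": 71.079, "S": 87.078, "P": 97.117, "V": 99.133,
    "T": 101.105, "C": 103.139, "L": 113.159, "I": 113.159, "N": 114.104,
    "D": 115.089, "Q": 128.131, "K": 128.174, "E": 129.116, "M": 131.193,
    "H": 137.141, "F": 147.177, "R": 156.188, "Y": 163.176, "W": 186.213,
}

WATER_MASS = 18.015
ACETYL_DELTA = 42.04   # N-terminal H -> CH3CO
AMIDE_DELTA = -0.98    # C-terminal OH -> NH2

# Per-residue molar absorptivities (M^-1 cm^-1).  280 nm values are the
# standard Trp/Tyr coefficients used for protein quantification; cystine is
# omitted because the peptides are Cys-free by design (Cys->Ser mutants).
# The 258 nm per-Phe value is a configurable default: Phe-based
# quantification is used only when a sequence carries no Trp/Tyr.
DEFAULT_EXTINCTION: dict[tuple[str, float], float] = {
    ("W", 280.0): 5500.0,
    ("Y", 280.0): 1490.0,
    ("F", 258.0): 200.0,
}


class ParseError(ValueError):
    """Malformed annotated-sequence text."""


@dataclass(frozen=True)
class MassModel:
    residue_masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES))
    water_mass: float = WATER_MASS
    acetyl_delta: float = ACETYL_DELTA
    amide_delta: float = AMIDE_DELTA


@dataclass(frozen=True)
class ExtinctionModel:
    """Additive per-residue molar absorptivity, keyed by (residue, nm)."""
    coefficients: dict[tuple[str, float], float] = field(
        default_factory=lambda: dict(DEFAULT_EXTINCTION))

    def per_residue(self, residue: str, wavelength: float) -> float:
        return self.coefficients.get((residue, float(wavelength)), 0.0)


@dataclass(frozen=True)
class PeptideRecord:
    """A capped synthetic peptide with intact-protein residue numbering."""

    name: str
    sequence: str
    start_residue: int
    end_residue: int
    n_cap: str = "acetyl"           # {"free", "acetyl"}
    c_cap: str = "amide"            # {"free", "amide"}
    extra_residues: tuple[tuple[str, str], ...] = ()
    predictor_score: float | None = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - CANONICAL
        if bad:
            raise ValueError(
                f"non-canonical residue(s) {sorted(bad)} in {self.name!r}")
        span = self.end_residue - self.start_residue + 1
        n_numbered = len(self.sequence) - len(self.extra_residues)
        if span != n_numbered:
            raise ValueError(
                f"{self.name!r}: numbered span {self.start_residue}-"
                f"{self.end_residue} covers {span} residues but sequence "
                f"carries {n_numbered} numbered residues")
        if self.n_cap not in ("free", "acetyl"):
            raise ValueError(f"unknown n_cap {self.n_cap!r}")
        if self.c_cap not in ("free", "amide"):
            raise ValueError(f"unknown c_cap {self.c_cap!r}")

    @property
    def numbered_sequence(self) -> str:
        """Residues belonging to the numbered intact-protein span."""
        n_extra = len(self.extra_residues)
        return self.sequence[: len(self.sequence) - n_extra]

    def position_of(self, index: int) -> int:
        """Intact-protein position of 0-based sequence index."""
        return self.start_residue + index


_ANNOT = re.compile(
    r"^\s*([A-Za-z])\s*(?:\^(\d+)\^|(\d+))\s*"   # leading residue + index
    r"([A-Za-z]*)\s*"                            # body of numbered span
    r"(?:\^(\d+)\^|(\d+))?\s*"                   # trailing index
    r"([A-Za-z]*)\s*"                            # extra residues after span
    r"(?:\(([^)]*)\))?\s*$"                      # optional (name)
)


def parse_annotated_sequence(text: str, *, n_cap: str = "acetyl",
                             c_cap: str = "amide") -> PeptideRecord:
    """Parse a Table-style annotated sequence.

    Accepts both caret-superscript (``K^520^HQ...W^549^``) and plain-digit
    (``K520HQ...W549``) numbering; residues after the trailing index are
    extra (un-numbered) residues; a trailing parenthetical names the
    peptide.
    """
    cleaned = re.sub(r"[‐‑‒–—]", "-", text)
    m = _ANNOT.match(cleaned)
    if m is None:
        raise ParseError(f"cannot parse annotated sequence: {text!r}")
    first, s1, s2, body, e1, e2, extra, name = m.groups()
    start = int(s1 if s1 is not None else s2)
    if e1 is None and e2 is None:
        if body or extra:
            raise ParseError(f"missing trailing residue index in {text!r}")
        end = start
        seq = first.upper()
        extras: tuple[tuple[str, str], ...] = ()
    else:
        end = int(e1 if e1 is not None else e2)
        seq = (first + body + extra).upper()
        extras = tuple(
            (f"post-{end}+{i + 1}", aa) for i, aa in enumerate(extra.upper()))
    record = PeptideRecord(
        name=(name or f"peptide_{start}_{end}").strip(),
        sequence=seq, start_residue=start, end_residue=end,
        n_cap=n_cap, c_cap=c_cap, extra_residues=extras)
    return record


def read_fasta(path, *, n_cap: str = "free", c_cap: str = "free",
               start_residue: int = 1) -> list[PeptideRecord]:
    """Read plain FASTA sequences; caps and numbering supplied by caller."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(PeptideRecord(
            name=rec.id, sequence=seq, start_residue=start_residue,
            end_residue=start_residue + len(seq) - 1,
            n_cap=n_cap, c_cap=c_cap))
    return records


def average_mass(record: PeptideRecord,
                 model: MassModel | None = None) -> float:
    """Average molecular mass (Da) including water and terminal caps."""
    model = model or MassModel()
    total = model.water_mass
    for i, aa in enumerate(record.sequence):
        try:
            total += model.residue_masses[aa]
        except KeyError:
            raise KeyError(
                f"no mass for residue {aa!r} at sequence index {i} "
                f"(intact-protein position {record.position_of(i)})") from None
    if record.n_cap == "acetyl":
        total += model.acetyl_delta
    if record.c_cap == "amide":
        total += model.amide_delta
    return total


def extinction_coefficient(record: PeptideRecord, wavelength: float,
                           model: ExtinctionModel | None = None) -> float:
    """Molar extinction coefficient (M^-1 cm^-1), linear over residues."""
    model = model or ExtinctionModel()
    eps = sum(model.per_residue(aa, wavelength) for aa in record.sequence)
    if eps == 0.0:
        warnings.warn(
            f"{record.name}: extinction coefficient at {wavelength:g} nm is "
            "zero (no absorbing residues); quantify via Phe absorbance at "
            "258 nm instead", stacklevel=2)
    return eps


def concentration_from_absorbance(absorbance: float, epsilon: float,
                                  path_cm: float = 1.0) -> float:
    """Beer-Lambert concentration (M) from absorbance."""
    if epsilon <= 0:
        raise ValueError(
            "epsilon must be > 0; for Trp/Tyr-free peptides use the "
            "Phe-based coefficient at 258 nm")
    if path_cm <= 0:
        raise ValueError("path length must be > 0")
    return absorbance / (epsilon * path_cm)


def aromatic_inventory(record: PeptideRecord) -> dict[str, list[int]]:
    """Positions (intact-protein numbering) of W/Y/F/H residues.

    Extra residues outside the numbered span are reported with synthetic
    positions continuing past ``end_residue``.
    """
    inventory: dict[str, list[int]] = {"W": [], "Y": [], "F": [], "H": []}
    for i, aa in enumerate(record.sequence):
        if aa in inventory:
            inventory[aa].append(record.position_of(i))
    return inventory


def properties_json(record: PeptideRecord,
                    mass_model: MassModel | None = None,
                    ext_model: ExtinctionModel | None = None) -> dict:
    """All computed peptide properties as a JSON-ready dict."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eps280 = extinction_coefficient(record, 280.0, ext_model)
        eps258 = extinction_coefficient(record, 258.0, ext_model)
    return {
        "name": record.name,
        "sequence": record.sequence,
        "span": [record.start_residue, record.end_residue],
        "n_cap": record.n_cap,
        "c_cap": record.c_cap,
        "extra_residues": [list(x) for x in record.extra_residues],
        "average_mass_da": round(average_mass(record, mass_model), 2),
        "epsilon_280": eps280,
        "epsilon_258": eps258,
        "aromatics": aromatic_inventory(record),
        "predictor_score": record.predictor_score,
    }
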
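"""Oligonucleotide sequence notation, compositions, and masses.

Sequences are written in the compact notation used for synthetic oligos:
``d[...]`` for DNA, ``r[...]`` for RNA, with optional parenthesized repeat
groups, e.g. ``d[(TTAGGG)4TTA]`` for the 27-mer human telomeric sequence.
Masses follow the free-acid, neutral convention for vendor desalted
oligos: 5'-OH and 3'-OH termini unless a 5'-phosphate is requested.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .composition import ElementalComposition, average_mass, monoisotopic_mass

__all__ = [
    "OligoSequence",
    "MoleculeSpec",
    "parse_oligo_notation",
    "oligo_composition",
    "oligo_average_mass",
    "builtin_molecules",
    "TMPYP4_CATION",
    "TOSYLATE_ANION",
    "AMMONIUM",
]

_DNA_BASES = frozenset("ACGT")
_RNA_BASES = frozenset("ACGU")

# Nucleotide residue compositions: nucleoside-5'-monophosphate minus water
# (the internal repeating unit of the phosphodiester chain).
_RESIDUES = {
    "DNA": {
        "A": ElementalComposition("C10H12N5O5P"),
        "C": ElementalComposition("C9H12N3O6P"),
        "G": ElementalComposition("C10H12N5O6P"),
        "T": ElementalComposition("C10H13N2O7P"),
    },
    "RNA": {
        "A": ElementalComposition("C10H12N5O6P"),
        "C": ElementalComposition("C9H12N3O7P"),
        "G": ElementalComposition("C10H12N5O7P"),
        "U": ElementalComposition("C9H11N2O8P"),
    },
}

WATER = ElementalComposition("H2O")
HPO3 = ElementalComposition("HPO3")


@dataclass(frozen=True)
class OligoSequence:
    """A single nucleic-acid strand.

    Parameters
    ----------
    alphabet : "DNA" or "RNA"
    residues : base letters 5'->3' (``ACGT`` for DNA, ``ACGU`` for RNA)
    five_prime_phosphate : whether the 5' terminus carries a phosphate
        (vendor desalted oligos are 5'-OH; default False).
    """

    alphabet: str
    residues: str
    five_prime_phosphate: bool = False

    def __post_init__(self) -> None:
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"alphabet must be DNA or RNA, got {self.alphabet!r}")
        if not self.residues:
            raise ValueError("empty sequence")
        legal = _DNA_BASES if self.alphabet == "DNA" else _RNA_BASES
        bad = set(self.residues) - legal
        if bad:
            raise ValueError(
                f"illegal base(s) {sorted(bad)} for {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        prefix = "d" if self.alphabet == "DNA" else "r"
        return f"{prefix}[{self.residues}]"

    def base_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for b in self.residues:
            counts[b] = counts.get(b, 0) + 1
        return counts


@dataclass(frozen=True)
class MoleculeSpec:
    """A small molecule or ion taking part in complex formation.

    ``intrinsic_charge`` is the charge the species carries in solution:
    +4 for the TMPyP4 tetracation, -1 for the tosylate counter-ion, +1 for
    the ammonium adduct.
    """

    name: str
    composition: ElementalComposition = field(hash=False)
    intrinsic_charge: int = 0

    def average_mass(self) -> float:
        return average_mass(self.composition)

    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition)

    def mass(self, mass_mode: str = "average") -> float:
        if mass_mode == "average":
            return self.average_mass()
        if mass_mode == "monoisotopic":
            return self.monoisotopic_mass()
        raise ValueError(f"unknown mass mode: {mass_mode!r}")


# meso-tetrakis(N-methyl-4-pyridyl)porphyrin tetracation and friends.
TMPYP4_CATION = MoleculeSpec("TMPyP4", ElementalComposition("C44H38N8"), +4)
TOSYLATE_ANION = MoleculeSpec("tosylate", ElementalComposition("C7H7O3S"), -1)
AMMONIUM = MoleculeSpec("ammonium", ElementalComposition("NH4"), +1)
CHLORIDE_ANION = MoleculeSpec("chloride", ElementalComposition("Cl"), -1)


def builtin_molecules() -> dict[str, MoleculeSpec]:
    """The molecules of the TMPyP4/G-quadruplex system, keyed by name."""
    return {
        m.name: m
        for m in (TMPYP4_CATION, TOSYLATE_ANION, AMMONIUM, CHLORIDE_ANION)
    }


# Grammar: optional d/r prefix, bracketed body; body is bases and repeat
# groups "(BASES)n" where n may be written plain ("4") or with the
# underscore dialect ("_4_") that markdown renderings produce.
_REPEAT = re.compile(r"\(([A-Za-z]+)\)_?(-?\d+)_?")


def parse_oligo_notation(text: str) -> OligoSequence:
    """Parse sequence notation like ``d[(TTAGGG)4TTA]`` into a strand.

    Accepts ``d[...]`` (DNA), ``r[...]`` (RNA), or a bare base string
    (alphabet inferred: U implies RNA, otherwise DNA).  Repeat groups are
    expanded left to right.

    Raises
    ------
    ValueError
        on unbalanced brackets, non-positive repeat counts, or bases
        illegal for the alphabet.
    """
    text = text.strip()
    if not text:
        raise ValueError("empty sequence notation")

    m = re.fullmatch(r"([dr])\[(.*)\]", text, flags=re.DOTALL)
    if m:
        alphabet = "DNA" if m.group(1) == "d" else "RNA"
        body = m.group(2)
    else:
        if "[" in text or "]" in text:
            raise ValueError(f"unbalanced or misplaced brackets in {text!r}")
        alphabet = "RNA" if "U" in text.upper() else "DNA"
        body = text

    def expand_repeat(match: re.Match) -> str:
        unit, count = match.group(1), int(match.group(2))
        if count <= 0:
            raise ValueError(f"repeat count must be positive, got {count}")
        return unit * count

    expanded = _REPEAT.sub(expand_repeat, body)
    if "(" in expanded or ")" in expanded:
        raise ValueError(f"unbalanced or malformed repeat group in {text!r}")
    expanded = expanded.replace(" ", "").upper()
    return OligoSequence(alphabet=alphabet, residues=expanded)


def oligo_composition(seq: OligoSequence) -> ElementalComposition:
    """Elemental composition of the neutral free-acid strand.

    Sum of residue compositions plus one water (chain termination); minus
    HPO3 when the 5' terminus is a hydroxyl rather than a phosphate.
    """
    residues = _RESIDUES[seq.alphabet]
    comp = ElementalComposition()
    for base in seq.residues:
        comp = comp + residues[base]
    comp = comp + WATER
    if not seq.five_prime_phosphate:
        comp = comp - HPO3
    return comp


def oligo_average_mass(seq: OligoSequence) -> float:
    """Average mass in Da of the neutral strand."""
    return average_mass(oligo_composition(seq))
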
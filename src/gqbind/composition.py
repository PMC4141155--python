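"""Elemental compositions and mass arithmetic.

All masses in gqbind are computed from a single frozen atomic mass table
(``data/atomic_weights.tsv``) so that results are reproducible to the last
digit across platforms.  Two mass modes are supported: ``average`` (IUPAC
standard atomic weights, appropriate for unresolved isotope envelopes of
~8.5 kDa oligonucleotides) and ``monoisotopic`` (principal isotope).
"""

from __future__ import annotations

import re
from collections import Counter
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ElementalComposition",
    "average_mass",
    "monoisotopic_mass",
    "ATOMIC_WEIGHTS",
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
]

# Mass of the proton: removed from / added to ions during (de)protonation.
PROTON_MASS = 1.007276

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_mass_table() -> tuple[dict[str, float], dict[str, float]]:
    avg: dict[str, float] = {}
    mono: dict[str, float] = {}
    text = (
        resources.files("gqbind").joinpath("data/atomic_weights.tsv").read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        el, a, m = line.split("\t")
        avg[el] = float(a)
        mono[el] = float(m)
    return avg, mono


ATOMIC_WEIGHTS, MONOISOTOPIC_MASSES = _load_mass_table()


class ElementalComposition(Counter):
    """Multiset of element counts, e.g. ``C10H14N2O5`` for thymidine.

    Supports ``+`` and ``-``; subtraction raises if any count would go
    negative (a composition cannot contain a negative number of atoms).
    Unlike :class:`collections.Counter`, zero counts are pruned so equal
    compositions compare equal regardless of construction history.
    """

    def __init__(self, data: Mapping[str, int] | Iterable | str | None = None):
        if isinstance(data, str):
            super().__init__()
            self._parse_formula(data)
        elif data is None:
            super().__init__()
        else:
            super().__init__(data)
        self._validate()

    def _parse_formula(self, formula: str) -> None:
        consumed = 0
        for el, n in _FORMULA_TOKEN.findall(formula):
            if not el:
                continue
            self[el] += int(n) if n else 1
            consumed += len(el) + len(n)
        if consumed != len(formula):
            raise ValueError(f"cannot parse chemical formula: {formula!r}")

    def _validate(self) -> None:
        for el, n in list(self.items()):
            if not isinstance(n, int):
                raise TypeError(f"count for {el} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el}: {n}")
            if n == 0:
                del self[el]

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] += n
        out._validate()
        return out

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = ElementalComposition(self)
        for el, n in other.items():
            out[el] -= n
            if out[el] < 0:
                raise ValueError(
                    f"subtraction yields negative count for {el}: "
                    f"{self.get(el, 0)} - {n}"
                )
        out._validate()
        return out

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError("composition can only be scaled by a non-negative int")
        return ElementalComposition({el: n * k for el, n in self.items()})

    __rmul__ = __mul__

    def hill_formula(self) -> str:
        """Formula in Hill order (C, H, then alphabetical)."""
        els = sorted(self, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{el}{self[el] if self[el] != 1 else ''}" for el in els)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.hill_formula()


def _mass(comp: Mapping[str, int], table: Mapping[str, float]) -> float:
    total = 0.0
    for el, n in comp.items():
        try:
            total += n * table[el]
        except KeyError:
            raise KeyError(f"unknown element symbol: {el!r}") from None
    return total


def average_mass(comp: Mapping[str, int]) -> float:
    """Average molecular mass in Da from standard atomic weights."""
    return _mass(comp, ATOMIC_WEIGHTS)


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da from principal-isotope masses."""
    return _mass(comp, MONOISOTOPIC_MASSES)
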
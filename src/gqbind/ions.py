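"""Candidate complex-ion species and their theoretical m/z.

A gas-phase ion is described by its stoichiometry: how many quadruplex
strands, ligand cations, counter-ion anions, and ammonium adducts it
carries, plus its (negative) charge state.  m/z follows from explicit
charge bookkeeping: the ligand is an intrinsic tetracation and the
charged adducts are compensated by deprotonation of the phosphate
backbone, so the number of protons removed is

    n_H = 4*n_ligand + n_ammonium - n_counterion - z

and m/z = (total neutral+adduct mass - n_H * m_proton) / |z|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .composition import PROTON_MASS
from .oligo import MoleculeSpec, builtin_molecules

__all__ = [
    "IonSpecies",
    "TheoreticalIon",
    "EnumerationConfig",
    "ion_mz",
    "enumerate_species",
    "theoretical_ions",
]


@dataclass(frozen=True, order=True)
class IonSpecies:
    """Stoichiometry record (quadruplex : ligand : counter-ion : ammonium, z)."""

    n_ligand: int
    n_counterion: int
    n_ammonium: int
    charge: int
    n_quadruplex: int = 1

    def __post_init__(self) -> None:
        if self.n_quadruplex < 1:
            raise ValueError("species must contain at least one quadruplex")
        if min(self.n_ligand, self.n_counterion, self.n_ammonium) < 0:
            raise ValueError("adduct counts must be non-negative")
        if self.charge > -1:
            raise ValueError("negative-mode species require charge <= -1")

    @property
    def total_adducts(self) -> int:
        return self.n_counterion + self.n_ammonium

    @property
    def ligand_charge_contribution(self) -> int:
        return 4 * self.n_ligand

    def label(self) -> str:
        """Field-style label, e.g. ``[1:1]^5- +1Ts +2NH4`` or ``[Q]^5-``."""
        z = abs(self.charge)
        if self.n_ligand == 0:
            core = f"[Q]^{z}-" if self.n_quadruplex == 1 else f"[{self.n_quadruplex}Q]^{z}-"
        else:
            core = f"[{self.n_quadruplex}:{self.n_ligand}]^{z}-"
        parts = [core]
        if self.n_counterion:
            parts.append(f"+{self.n_counterion}Ts")
        if self.n_ammonium:
            parts.append(f"+{self.n_ammonium}NH4")
        return " ".join(parts)

    @property
    def stoichiometry_class(self) -> tuple[int, int]:
        """(n_ligand, n_counterion) — the solution-phase species this ion reports."""
        return (self.n_ligand, self.n_counterion)


@dataclass(frozen=True)
class TheoreticalIon:
    species: IonSpecies
    mz: float
    mass_mode: str = "average"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")


def ion_mz(
    species: IonSpecies,
    quadruplex_mass: float,
    molecules: Mapping[str, MoleculeSpec] | None = None,
    mass_mode: str = "average",
    ligand: str = "TMPyP4",
    counterion: str = "tosylate",
) -> float:
    """Theoretical m/z of a complex ion in negative mode.

    Raises
    ------
    ValueError
        if the requested charge is unreachable (would require adding
        protons to the intrinsic charge rather than removing them).
    """
    mols = molecules if molecules is not None else builtin_molecules()
    lig = mols[ligand]
    ci = mols[counterion]
    nh4 = mols["ammonium"]

    intrinsic = (
        lig.intrinsic_charge * species.n_ligand
        + nh4.intrinsic_charge * species.n_ammonium
        + ci.intrinsic_charge * species.n_counterion
    )
    n_h = intrinsic - species.charge
    if n_h < 0:
        raise ValueError(
            f"species {species.label()} cannot reach charge {species.charge}: "
            f"would require adding {-n_h} protons"
        )
    mass = (
        species.n_quadruplex * quadruplex_mass
        + species.n_ligand * lig.mass(mass_mode)
        + species.n_counterion * ci.mass(mass_mode)
        + species.n_ammonium * nh4.mass(mass_mode)
        - n_h * PROTON_MASS
    )
    return mass / abs(species.charge)


@dataclass(frozen=True)
class EnumerationConfig:
    """Ranges of adduct counts / charge states to enumerate.

    Defaults mirror the species observed for TMPyP4 tetratosylate with
    the telomeric quadruplex: ligand 0-2, counter-ion 0-3, ammonium 0-2,
    charge states -4..-6.
    """

    ligand_range: Sequence[int] = (0, 1, 2)
    counterion_range: Sequence[int] = (0, 1, 2, 3)
    ammonium_range: Sequence[int] = (0, 1, 2)
    charges: Sequence[int] = (-4, -5, -6)

    def __post_init__(self) -> None:
        for name in ("ligand_range", "counterion_range", "ammonium_range", "charges"):
            if not tuple(getattr(self, name)):
                raise ValueError(f"{name} is empty")


def enumerate_species(config: EnumerationConfig | None = None) -> list[IonSpecies]:
    """All ion species in the configured ranges, deterministically ordered.

    Order: ascending (n_ligand, n_counterion, n_ammonium, |z|).
    """
    cfg = config or EnumerationConfig()
    seen = set()
    out = []
    for nl, nc, na, z in itertools.product(
        cfg.ligand_range, cfg.counterion_range, cfg.ammonium_range, cfg.charges
    ):
        key = (nl, nc, na, z)
        if key in seen:
            continue
        seen.add(key)
        out.append(IonSpecies(n_ligand=nl, n_counterion=nc, n_ammonium=na, charge=z))
    out.sort(key=lambda s: (s.n_ligand, s.n_counterion, s.n_ammonium, -s.charge))
    return out


def theoretical_ions(
    species: Iterable[IonSpecies],
    quadruplex_mass: float,
    molecules: Mapping[str, MoleculeSpec] | None = None,
    mass_mode: str = "average",
    **kwargs,
) -> list[TheoreticalIon]:
    """Compute m/z for each species, skipping charge-unreachable ones."""
    out = []
    for sp in species:
        try:
            mz = ion_mz(sp, quadruplex_mass, molecules, mass_mode, **kwargs)
        except ValueError:
            continue
        out.append(TheoreticalIon(species=sp, mz=mz, mass_mode=mass_mode))
    return out
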
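"""Matching observed peaks to theoretical ions and aggregating areas.

Matching is greedy in increasing |observed - theoretical| with each peak
and each theoretical ion used at most once; ties prefer the species with
fewer adducts (the more parsimonious explanation).  Assigned areas are
then pooled per (n_ligand, n_counterion) stoichiometry class — charge
states and ammonium counts are gas-phase artifacts of one solution
species, so they collapse within a class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ions import IonSpecies, TheoreticalIon
from .spectra import Peak, Spectrum

__all__ = ["Assignment", "SpeciesAbundanceTable", "match_peaks", "aggregate_abundances"]

DEFAULT_TOLERANCE = 1.0  # Da/charge; inter-species spacings at z=-5 are >= ~3.4


@dataclass(frozen=True)
class Assignment:
    peak: Peak
    species: IonSpecies
    theoretical_mz: float

    @property
    def delta_mz(self) -> float:
        """Observed minus theoretical, Da per unit charge."""
        return self.peak.mz - self.theoretical_mz


@dataclass(frozen=True)
class SpeciesAbundanceTable:
    """Summed areas per (n_ligand, n_counterion) class plus unassigned area."""

    areas: dict[tuple[int, int], float] = field(default_factory=dict)
    unassigned_area: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()) or self.unassigned_area < 0:
            raise ValueError("areas must be non-negative")

    @property
    def total_area(self) -> float:
        return float(sum(self.areas.values()) + self.unassigned_area)

    def collapse_counterion(self) -> dict[int, float]:
        """Areas per ligand count, summed over counter-ion adducts."""
        out: dict[int, float] = {}
        for (nl, _nc), area in self.areas.items():
            out[nl] = out.get(nl, 0.0) + area
        return out


def match_peaks(
    spectrum: Spectrum,
    ions: list[TheoreticalIon],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[Assignment]:
    """Greedily assign peaks to theoretical ions within a m/z tolerance.

    Candidate (peak, ion) pairs within tolerance are processed in order
    of increasing |delta|, breaking ties by smaller total adduct count
    then lexicographic species order; each peak and each ion is used at
    most once.  Unmatched peaks simply stay unassigned.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    seen = {}
    for ion in ions:
        key = ion.species
        if key in seen and abs(seen[key].mz - ion.mz) > 1e-9:
            raise ValueError(f"duplicate theoretical ion with conflicting m/z: {key}")
        seen[key] = ion
    ions = list(seen.values())

    candidates = []
    for pi, peak in enumerate(spectrum.peaks):
        for ion in ions:
            d = abs(peak.mz - ion.mz)
            if d <= tolerance:
                # quantize |delta| so that numerically coincident distances
                # resolve by the parsimony rule, not floating-point noise
                candidates.append((round(d, 6), ion.species.total_adducts, ion.species, pi, ion))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used_peaks: set[int] = set()
    used_ions: set[IonSpecies] = set()
    assignments = []
    for _d, _na, _sp, pi, ion in candidates:
        if pi in used_peaks or ion.species in used_ions:
            continue
        used_peaks.add(pi)
        used_ions.add(ion.species)
        assignments.append(
            Assignment(peak=spectrum.peaks[pi], species=ion.species, theoretical_mz=ion.mz)
        )
    assignments.sort(key=lambda a: a.peak.mz)
    return assignments


def aggregate_abundances(
    assignments: list[Assignment], unassigned_area: float = 0.0
) -> SpeciesAbundanceTable:
    """Pool assigned areas into (n_ligand, n_counterion) classes.

    Area is conserved: the table total equals assigned + unassigned input
    area exactly.
    """
    areas: dict[tuple[int, int], float] = {}
    for a in assignments:
        key = a.species.stoichiometry_class
        areas[key] = areas.get(key, 0.0) + a.peak.area
    return SpeciesAbundanceTable(areas=areas, unassigned_area=unassigned_area)


def assignment_report_rows(assignments: list[Assignment]) -> list[dict]:
    """Rows for the assignment report TSV."""
    return [
        {
            "observed_mz": a.peak.mz,
            "area": a.peak.area,
            "species": a.species.label(),
            "theoretical_mz": a.theoretical_mz,
            "delta_mz": a.delta_mz,
        }
        for a in assignments
    ]
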
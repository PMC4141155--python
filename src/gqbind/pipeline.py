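"""End-to-end helpers tying annotation and binding inference together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .assign import (
    Assignment,
    SpeciesAbundanceTable,
    aggregate_abundances,
    match_peaks,
    DEFAULT_TOLERANCE,
)
from .binding import (
    BindingConstants,
    EquilibriumState,
    SummaryStat,
    concentrations_from_areas,
    estimate_constants,
    fraction_bound,
    replicate_summary,
)
from .ions import EnumerationConfig, enumerate_species, theoretical_ions
from .oligo import MoleculeSpec, OligoSequence, builtin_molecules, oligo_average_mass
from .spectra import ReplicateSet, Spectrum

__all__ = ["annotate_spectrum", "infer_binding", "pooled_binding", "BindingReport"]


def annotate_spectrum(
    spectrum: Spectrum,
    oligo: OligoSequence,
    tolerance: float = DEFAULT_TOLERANCE,
    enumeration: EnumerationConfig | None = None,
    molecules: Mapping[str, MoleculeSpec] | None = None,
    ligand: str = "TMPyP4",
    counterion: str = "tosylate",
) -> tuple[list[Assignment], SpeciesAbundanceTable]:
    """Enumerate candidate ions, match peaks, and pool areas by class."""
    ions = theoretical_ions(
        enumerate_species(enumeration),
        oligo_average_mass(oligo),
        molecules,
        ligand=ligand,
        counterion=counterion,
    )
    assignments = match_peaks(spectrum, ions, tolerance=tolerance)
    assigned_area = sum(a.peak.area for a in assignments)
    unassigned = spectrum.total_area - assigned_area
    table = aggregate_abundances(assignments, unassigned_area=max(unassigned, 0.0))
    return assignments, table


@dataclass(frozen=True)
class BindingReport:
    """Per-replicate and pooled binding results for one target."""

    fraction_bound: SummaryStat
    k1: SummaryStat
    k2: SummaryStat
    states: tuple[EquilibriumState, ...]
    counterion_only_is_bound: bool

    @property
    def pooled_constants(self) -> BindingConstants:
        return BindingConstants(K1=self.k1.mean, K2=max(self.k2.mean, 0.0))


def infer_binding(
    spectrum: Spectrum,
    oligo: OligoSequence,
    c_q: float | None = None,
    c_l: float | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    counterion_only_is_bound: bool = False,
    **kwargs,
) -> tuple[float, EquilibriumState, BindingConstants]:
    """Fraction bound, species concentrations, and constants for one spectrum.

    Concentrations default to the spectrum metadata and must be positive.
    """
    cq = c_q if c_q is not None else spectrum.metadata.c_q
    cl = c_l if c_l is not None else spectrum.metadata.c_l
    if not cq or not cl or cq <= 0 or cl <= 0:
        raise ValueError("strand and ligand concentrations are required")
    _, table = annotate_spectrum(spectrum, oligo, tolerance=tolerance, **kwargs)
    frac = fraction_bound(table, counterion_only_is_bound=counterion_only_is_bound)
    state = concentrations_from_areas(table, cq, cl)
    constants = estimate_constants(state)
    return frac, state, constants


def pooled_binding(
    replicates: ReplicateSet,
    oligo: OligoSequence,
    tolerance: float = DEFAULT_TOLERANCE,
    counterion_only_is_bound: bool = False,
    **kwargs,
) -> BindingReport:
    """Run binding inference per replicate and pool mean ± SD."""
    fracs, k1s, k2s, states = [], [], [], []
    for spectrum in replicates.spectra:
        frac, state, constants = infer_binding(
            spectrum,
            oligo,
            tolerance=tolerance,
            counterion_only_is_bound=counterion_only_is_bound,
            **kwargs,
        )
        fracs.append(frac)
        k1s.append(constants.K1)
        k2s.append(constants.K2)
        states.append(state)
    return BindingReport(
        fraction_bound=replicate_summary(fracs),
        k1=replicate_summary(k1s),
        k2=replicate_summary(k2s),
        states=tuple(states),
        counterion_only_is_bound=counterion_only_is_bound,
    )
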
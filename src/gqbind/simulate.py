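"""Seeded generators for synthetic spectra and melting curves.

The spectrum generator realizes exactly the assumption the analysis
rests on: peak areas proportional to solution abundances of the free
quadruplex and its 1:1 / 1:2 ligand complexes.  Given true binding
constants it forward-solves the equilibrium, splits each solution
species' area deterministically across charge states, ammonium counts
and counter-ion adducts according to configured probability vectors,
then corrupts the ideal peak list with Gaussian m/z jitter, log-normal
multiplicative area noise, and uniform decoy peaks.  Every random draw
flows from one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .binding import BindingConstants, EquilibriumState, solve_equilibrium
from .ions import IonSpecies, TheoreticalIon, ion_mz
from .melting import MeltingCurve
from .oligo import MoleculeSpec, OligoSequence, builtin_molecules, oligo_average_mass

__all__ = [
    "SpectrumSimConfig",
    "GroundTruth",
    "simulate_binding_spectrum",
    "simulate_melting_curve",
    "TELOMERIC_DNA_CONSTANTS",
    "TELOMERIC_RNA_CONSTANTS",
]

# Replicate-mean constants for TMPyP4 tetrachloride with the telomeric
# DNA and RNA quadruplexes, used as default simulation ground truth.
TELOMERIC_DNA_CONSTANTS = BindingConstants(K1=1.87e6, K2=2.83e5)
TELOMERIC_RNA_CONSTANTS = BindingConstants(K1=5.62e7, K2=2.62e6)

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)


def _validate_probs(name: str, probs: Mapping[int, float]) -> None:
    if not probs:
        raise ValueError(f"{name} is empty")
    vals = list(probs.values())
    if any(p < 0 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
        raise ValueError(f"{name} must be a probability vector summing to 1")


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Conditions of a simulated equimolar quadruplex/ligand infusion.

    Defaults model the 10 µM equimolar DNA/TMPyP4-tetrachloride mixture:
    no counter-ion adducts, the 2-ammonium ion dominant, charge states
    -4/-5/-6 with -5 predominant.  ``counterion_probs`` with weight on
    1-3 adducts switches to tetratosylate-like spectra.
    """

    truth: BindingConstants = TELOMERIC_DNA_CONSTANTS
    c_q: float = 10e-6
    c_l: float = 10e-6
    ammonium_probs: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.1, 1: 0.3, 2: 0.6}
    )
    charge_probs: Mapping[int, float] = field(
        default_factory=lambda: {-4: 0.2, -5: 0.6, -6: 0.2}
    )
    counterion_probs: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    response_factors: Mapping[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: 1.0, 2: 1.0}
    )
    mz_jitter_sd: float = 0.02
    area_noise_sd: float = 0.05
    n_decoys: int = 5
    decoy_scale: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        _validate_probs("ammonium_probs", self.ammonium_probs)
        _validate_probs("charge_probs", self.charge_probs)
        _validate_probs("counterion_probs", self.counterion_probs)
        if self.mz_jitter_sd < 0 or self.area_noise_sd < 0 or self.decoy_scale < 0:
            raise ValueError("noise scales must be non-negative")
        if self.n_decoys < 0:
            raise ValueError("decoy count must be non-negative")
        if not (self.c_q > 0 and self.c_l > 0):
            raise ValueError("concentrations must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually emitted, for recovery tests."""

    state: EquilibriumState
    ions: tuple[TheoreticalIon, ...]
    ideal_areas: tuple[float, ...]  # pre-noise area of each ion
    n_decoys: int


def simulate_binding_spectrum(
    config: SpectrumSimConfig,
    oligo: OligoSequence,
    molecules: Mapping[str, MoleculeSpec] | None = None,
    ligand: str = "TMPyP4",
    counterion: str = "tosylate",
):
    """Generate one synthetic spectrum plus its ground truth.

    Returns (Spectrum, GroundTruth); deterministic for a fixed seed.
    """
    from .spectra import Peak, Spectrum, SpectrumMetadata

    rng = np.random.default_rng(config.seed)
    mols = molecules if molecules is not None else builtin_molecules()
    m_q = oligo_average_mass(oligo)
    state = solve_equilibrium(config.c_q, config.c_l, config.truth)

    class_conc = {0: state.free_q, 1: state.c11, 2: state.c12}
    ions: list[TheoreticalIon] = []
    ideal_areas: list[float] = []
    for nl, conc in class_conc.items():
        base_area = (conc / config.c_q) * config.response_factors.get(nl, 1.0)
        if base_area <= 0:
            continue
        for nc, p_nc in config.counterion_probs.items():
            for na, p_na in config.ammonium_probs.items():
                for z, p_z in config.charge_probs.items():
                    w = p_nc * p_na * p_z
                    if w <= 0:
                        continue
                    sp = IonSpecies(
                        n_ligand=nl, n_counterion=nc, n_ammonium=na, charge=z
                    )
                    mz = ion_mz(sp, m_q, mols, "average", ligand, counterion)
                    ions.append(TheoreticalIon(species=sp, mz=mz))
                    ideal_areas.append(base_area * w)

    observed = []
    for ion, area in zip(ions, ideal_areas):
        mz = ion.mz + rng.normal(0.0, config.mz_jitter_sd) if config.mz_jitter_sd else ion.mz
        noisy = area * rng.lognormal(0.0, config.area_noise_sd) if config.area_noise_sd else area
        observed.append((float(mz), float(noisy)))

    if config.n_decoys:
        lo = min(mz for mz, _ in observed) - 50.0
        hi = max(mz for mz, _ in observed) + 50.0
        max_area = max(a for _, a in observed)
        for _ in range(config.n_decoys):
            observed.append(
                (
                    float(rng.uniform(lo, hi)),
                    float(max_area * config.decoy_scale * rng.uniform(0.2, 1.0)),
                )
            )

    merged: dict[float, float] = {}
    for mz, a in observed:
        merged[mz] = merged.get(mz, 0.0) + a
    peaks = tuple(Peak(mz, a) for mz, a in sorted(merged.items()))
    spectrum = Spectrum(
        peaks=peaks,
        metadata=SpectrumMetadata(
            c_q=config.c_q, c_l=config.c_l, ligand=ligand, counterion=counterion
        ),
    )
    truth = GroundTruth(
        state=state,
        ions=tuple(ions),
        ideal_areas=tuple(ideal_areas),
        n_decoys=config.n_decoys,
    )
    return spectrum, truth


def simulate_melting_curve(
    tm_c: float,
    vant_hoff_enthalpy: float = 50.0,
    folded_baseline: tuple[float, float] = (1.0, -0.0005),
    unfolded_baseline: tuple[float, float] = (0.75, -0.0002),
    noise_sd: float = 0.0,
    grid: np.ndarray | None = None,
    seed: int = 0,
    wavelength: str = "295 nm",
) -> MeltingCurve:
    """Two-state melting curve with van't Hoff thermodynamics.

    theta_folded(T) = 1 / (1 + exp[(dH/R) (1/Tm - 1/T)]) in kelvin, so
    theta(Tm) = 1/2 exactly; absorbance interpolates between the linear
    folded and unfolded baselines (intercept, slope per °C) plus optional
    Gaussian noise.  Default baselines are hypochromic (folded above
    unfolded), as at 295 nm.

    ``vant_hoff_enthalpy`` is in kcal/mol and must be positive.
    """
    if vant_hoff_enthalpy <= 0:
        raise ValueError("van't Hoff enthalpy must be positive")
    t = np.arange(20.0, 95.0 + 1e-9, 0.5) if grid is None else np.asarray(grid, float)
    if not (t[0] <= tm_c <= t[-1]):
        raise ValueError(f"Tm {tm_c} °C outside the temperature grid")
    rng = np.random.default_rng(seed)
    t_k = t + 273.15
    tm_k = tm_c + 273.15
    exponent = (vant_hoff_enthalpy / GAS_CONSTANT_KCAL) * (1 / tm_k - 1 / t_k)
    theta = 1.0 / (1.0 + np.exp(np.clip(exponent, -700, 700)))
    a_f = folded_baseline[0] + folded_baseline[1] * t
    a_u = unfolded_baseline[0] + unfolded_baseline[1] * t
    a = theta * a_f + (1 - theta) * a_u
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, size=t.shape)
    return MeltingCurve(temperature=t, absorbance=a, wavelength=wavelength)
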
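"""Sequential two-site binding equilibrium and constant estimation.

The quadruplex Q binds the ligand L in two steps,

    Q + L <-> QL        K1 = [QL] / ([Q][L])
    QL + L <-> QL2      K2 = [QL2] / ([QL][L])

Native-MS peak areas are assumed proportional to solution abundances of
Q, QL, and QL2, so known total concentrations turn relative areas into
absolute concentrations; the free ligand follows by difference from the
ligand mass balance, and K1/K2 are then evaluated directly.  The forward
problem (concentrations from constants) reduces to a single bracketed
root-find on free ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .assign import SpeciesAbundanceTable

__all__ = [
    "EquilibriumState",
    "BindingConstants",
    "SummaryStat",
    "SaturationError",
    "fraction_bound",
    "concentrations_from_areas",
    "estimate_constants",
    "solve_equilibrium",
    "replicate_summary",
    "affinity_ratio",
    "format_constant",
]

_BALANCE_RTOL = 1e-12


class SaturationError(ValueError):
    """Raised when the ligand mass balance cannot be closed.

    Observed complex abundances would require more ligand than was
    supplied (free ligand <= 0), which breaks the by-difference closure.
    """


@dataclass(frozen=True)
class BindingConstants:
    """Sequential association constants, 1/M. K2 == 0 flags 'not estimable'."""

    K1: float
    K2: float

    def __post_init__(self) -> None:
        if not (self.K1 >= 0 and self.K2 >= 0):
            raise ValueError("association constants must be non-negative")

    @property
    def k2_estimable(self) -> bool:
        return self.K2 > 0


@dataclass(frozen=True)
class EquilibriumState:
    """Species concentrations (mol/L) satisfying both mass balances."""

    free_q: float
    c11: float
    c12: float
    free_l: float

    def __post_init__(self) -> None:
        if min(self.free_q, self.c11, self.c12, self.free_l) < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def total_q(self) -> float:
        return self.free_q + self.c11 + self.c12

    @property
    def total_l(self) -> float:
        return self.free_l + self.c11 + 2 * self.c12

    @property
    def fraction_bound(self) -> float:
        """(QL + QL2) / total quadruplex."""
        return (self.c11 + self.c12) / self.total_q


def fraction_bound(
    table: SpeciesAbundanceTable, counterion_only_is_bound: bool = False
) -> float:
    """Fraction of quadruplex carrying ligand, from pooled peak areas.

    The ratio of ligand-containing class areas to all quadruplex class
    areas.  Counter-ion-only adducts of the free quadruplex count as
    bound only under the ``counterion_only_is_bound`` policy (they carry
    no ligand but do carry a component of the ligand salt).
    """
    total = sum(table.areas.values())
    if total <= 0:
        raise ValueError("no quadruplex-containing area in table")
    bound = 0.0
    for (nl, nc), area in table.areas.items():
        if nl >= 1 or (counterion_only_is_bound and nc >= 1):
            bound += area
    return bound / total


def concentrations_from_areas(
    table: SpeciesAbundanceTable, c_q: float, c_l: float
) -> EquilibriumState:
    """Turn relative class areas into absolute species concentrations.

    Areas are pooled over the counter-ion dimension; each class i takes
    concentration C_Q * A_i / sum(A), and free ligand closes the ligand
    balance by difference.

    Raises
    ------
    SaturationError
        if the implied free ligand is <= 0.
    """
    if not (c_q > 0 and c_l > 0):
        raise ValueError("total concentrations must be positive")
    by_ligand = table.collapse_counterion()
    if not by_ligand or sum(by_ligand.values()) <= 0:
        raise ValueError("abundance table holds no positive quadruplex area")
    extra = [nl for nl in by_ligand if nl not in (0, 1, 2)]
    if extra:
        raise ValueError(
            f"classes with ligand count {sorted(extra)} exceed the 1:2 model"
        )
    total = sum(by_ligand.values())
    conc = {nl: c_q * a / total for nl, a in by_ligand.items()}
    free_q = conc.get(0, 0.0)
    c11 = conc.get(1, 0.0)
    c12 = conc.get(2, 0.0)
    free_l = c_l - c11 - 2 * c12
    if free_l <= 0:
        raise SaturationError(
            "ligand mass balance violated: complexes imply "
            f"{c11 + 2 * c12:.4g} M bound ligand >= total {c_l:.4g} M"
        )
    return EquilibriumState(free_q=free_q, c11=c11, c12=c12, free_l=free_l)


def estimate_constants(state: EquilibriumState) -> BindingConstants:
    """Evaluate K1 and K2 from species concentrations.

    K2 is reported as 0 ("not estimable") when no 1:2 complex was
    observed rather than raising.
    """
    if state.free_q <= 0 or state.free_l <= 0:
        raise ValueError("free quadruplex and free ligand must be positive")
    if state.c11 <= 0:
        raise ValueError("1:1 complex concentration must be positive for K1")
    k1 = state.c11 / (state.free_q * state.free_l)
    k2 = state.c12 / (state.c11 * state.free_l)
    return BindingConstants(K1=k1, K2=k2)


def solve_equilibrium(
    c_q: float, c_l: float, constants: BindingConstants
) -> EquilibriumState:
    """Forward-solve species concentrations at given totals and constants.

    Free ligand l is the unique root in (0, C_L] of the ligand balance

        g(l) = l + (K1*l + 2*K1*K2*l^2) * C_Q / (1 + K1*l + K1*K2*l^2) - C_L,

    which is continuous and strictly increasing with g(0) = -C_L < 0 and
    g(C_L) >= 0; the remaining species follow in closed form.  Both mass
    balances hold to 1e-12 relative.
    """
    if not (math.isfinite(c_q) and math.isfinite(c_l)) or c_q <= 0 or c_l <= 0:
        raise ValueError("total concentrations must be finite and positive")
    k1, k2 = constants.K1, constants.K2
    if k1 == 0:
        return EquilibriumState(free_q=c_q, c11=0.0, c12=0.0, free_l=c_l)

    def g(l: float) -> float:
        denom = 1 + k1 * l + k1 * k2 * l * l
        return l + (k1 * l + 2 * k1 * k2 * l * l) * c_q / denom - c_l

    free_l = brentq(g, 0.0, c_l, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    free_q = c_q / (1 + k1 * free_l + k1 * k2 * free_l * free_l)
    c11 = k1 * free_q * free_l
    c12 = k1 * k2 * free_q * free_l * free_l
    state = EquilibriumState(free_q=free_q, c11=c11, c12=c12, free_l=free_l)
    if abs(state.total_q - c_q) > _BALANCE_RTOL * c_q or abs(
        state.total_l - c_l
    ) > max(_BALANCE_RTOL * c_l, 1e-25):
        raise ArithmeticError("mass balances not closed to tolerance")
    return state


@dataclass(frozen=True)
class SummaryStat:
    """Replicate mean with sample SD (n-1 denominator); SD missing at n=1."""

    mean: float
    sd: float | None
    n: int

    def format(self) -> str:
        if self.sd is None:
            return f"{self.mean:.3g} (n={self.n})"
        return f"{self.mean:.3g} ± {self.sd:.2g} (n={self.n})"


def replicate_summary(values: list[float] | np.ndarray) -> SummaryStat:
    """Mean and sample standard deviation across replicates."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate values")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return SummaryStat(mean=mean, sd=sd, n=int(arr.size))


def affinity_ratio(
    k_a: BindingConstants, k_b: BindingConstants
) -> tuple[float, float]:
    """Elementwise (K1a/K1b, K2a/K2b) for comparing two targets."""
    if k_b.K1 <= 0 or k_b.K2 <= 0:
        raise ZeroDivisionError("denominator constants must be positive")
    return (k_a.K1 / k_b.K1, k_a.K2 / k_b.K2)


def format_constant(value: float) -> str:
    """Render a constant in the report style 'X.XX x 10^n M-1'."""
    if value <= 0:
        return "not estimable"
    exponent = math.floor(math.log10(value))
    mantissa = value / 10**exponent
    return f"{mantissa:.2f} × 10^{exponent} M⁻¹"
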
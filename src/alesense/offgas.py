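"""Gas-conversion rates from inflow and off-gas composition.

A stirred-tank bioreactor aerated at a known flow converts O2 to CO2; the
nitrogen (plus argon) fraction is inert and balances the unmeasured outflow.
With inflow mole fractions y_O2,in / y_CO2,in and dried off-gas fractions
y_O2,out / y_CO2,out, the volumetric oxygen uptake rate and carbon dioxide
emission rate are

    OUR = F/(Vm·Vr) · [ y_O2,in  − I·y_O2,out ]
    CER = F/(Vm·Vr) · [ −y_CO2,in + I·y_CO2,out ]
    I   = (1 − y_O2,in − y_CO2,in) / (1 − y_O2,out − y_CO2,out)

in mol L⁻¹ h⁻¹, both positive in normal aerobic growth.  ``invert_rates``
solves the same relations for the off-gas fractions given OUR and CER; the
simulator uses it to emit synthetic sensor signals, and the pair of functions
is an exact algebraic round trip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stoichiometry import RateModel

__all__ = [
    "GasSpec",
    "GasReading",
    "compute_our",
    "compute_cer",
    "invert_rates",
    "conversion_rates",
]

#: Molar volume of an ideal gas at 25 °C and 1 atm, L per mol.
MOLAR_VOLUME_25C = 24.465


@dataclass(frozen=True)
class GasSpec:
    """Aeration and vessel parameters for the gas balance.

    f_air_in : inflow gas flow, L h⁻¹
    v_molar  : molar volume, L mol⁻¹ (24.465 at 25 °C, 1 atm)
    v_reactor: liquid working volume, L
    y_o2_in, y_co2_in : inflow mole fractions (atmospheric defaults)
    """

    f_air_in: float = 69.0
    v_molar: float = MOLAR_VOLUME_25C
    v_reactor: float = 0.575
    y_o2_in: float = 0.2091
    y_co2_in: float = 0.0004

    def __post_init__(self) -> None:
        for name in ("f_air_in", "v_molar", "v_reactor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 <= self.y_o2_in < 1 and 0 <= self.y_co2_in < 1):
            raise ValueError("inflow fractions must lie in [0, 1)")
        if self.y_o2_in + self.y_co2_in >= 1:
            raise ValueError("inflow fractions must sum to < 1")

    @property
    def k_gas(self) -> float:
        """F/(Vm·Vr): mol of gas per litre of broth per hour per unit fraction."""
        return self.f_air_in / (self.v_molar * self.v_reactor)

    @property
    def inert_in(self) -> float:
        return 1.0 - self.y_o2_in - self.y_co2_in


@dataclass(frozen=True)
class GasReading:
    """One off-gas sample: time in hours and dried-gas mole fractions."""

    t: float
    y_o2_out: float
    y_co2_out: float

    def __post_init__(self) -> None:
        if not (0 <= self.y_o2_out < 1 and 0 <= self.y_co2_out < 1):
            raise ValueError("off-gas fractions must lie in [0, 1)")
        if self.y_o2_out + self.y_co2_out >= 1:
            raise ValueError("off-gas fractions must sum to < 1")


def _inert_ratio(spec: GasSpec, y_o2_out, y_co2_out):
    inert_out = 1.0 - np.asarray(y_o2_out, dtype=float) - np.asarray(y_co2_out, dtype=float)
    if np.any(inert_out <= 0):
        raise ValueError("outflow inert fraction must be > 0")
    return spec.inert_in / inert_out


def compute_our(reading, spec: GasSpec, y_co2_out=None):
    """Volumetric oxygen uptake rate, mol L⁻¹ h⁻¹ (uptake positive).

    ``reading`` may be a :class:`GasReading` or an array of O2 out-fractions
    (then ``y_co2_out`` must hold the matching CO2 fractions).
    """
    if isinstance(reading, GasReading):
        y_o2, y_co2 = reading.y_o2_out, reading.y_co2_out
    else:
        y_o2, y_co2 = reading, y_co2_out
    ratio = _inert_ratio(spec, y_o2, y_co2)
    return spec.k_gas * (spec.y_o2_in - ratio * np.asarray(y_o2, dtype=float))


def compute_cer(reading, spec: GasSpec, y_co2_out=None):
    """Volumetric carbon dioxide emission rate, mol L⁻¹ h⁻¹ (emission positive).

    Negative values flag CO2 readings below the inert-corrected inflow level,
    e.g. stripping artifacts right after a medium exchange.
    """
    if isinstance(reading, GasReading):
        y_o2, y_co2 = reading.y_o2_out, reading.y_co2_out
    else:
        y_o2, y_co2 = reading, y_co2_out
    ratio = _inert_ratio(spec, y_o2, y_co2)
    return spec.k_gas * (ratio * np.asarray(y_co2, dtype=float) - spec.y_co2_in)


def invert_rates(our, cer, spec: GasSpec):
    """Off-gas fractions (y_o2_out, y_co2_out) that realise given OUR and CER.

    Exact inverse of :func:`compute_our` / :func:`compute_cer`: with
    u = y_O2,in − OUR/k and v = y_CO2,in + CER/k the outflow fractions are
    u/(I_in+u+v) and v/(I_in+u+v).  Raises if the requested rates are not
    physically realisable (u or v negative).
    """
    u = spec.y_o2_in - np.asarray(our, dtype=float) / spec.k_gas
    v = spec.y_co2_in + np.asarray(cer, dtype=float) / spec.k_gas
    if np.any(u < 0):
        raise ValueError("OUR exceeds the oxygen supplied by the inflow")
    if np.any(v < 0):
        raise ValueError("CER more negative than the inflow CO2 supply")
    denom = spec.inert_in + u + v
    return u / denom, v / denom


def conversion_rates(our, cer, model: RateModel):
    """Map (OUR, CER) to (rx, rs) in C-mol L⁻¹ h⁻¹.

    rx is the biomass formation rate (positive during growth) and rs the
    substrate consumption rate as a positive magnitude; for solver-derived
    models rs − rx = CER holds identically (carbon balance).
    """
    return model.rates(our, cer)
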
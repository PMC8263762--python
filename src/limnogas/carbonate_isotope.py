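"""Carbonate-system speciation and the d13C-CO2 mass balance.

At the pH of a soda lake (>= 9.5) almost all dissolved inorganic carbon is
HCO3- and CO3=, so the isotopic composition of the small CO2(aq) pool must
be recovered from the measured d13C of total dissolved inorganic carbon
(TDIC) by an equilibrium mass balance:

    d13C-CO2 = d13C-TDIC - (HCO3/TDIC) * eps_HCO3-CO2
                          - (CO3/TDIC) * (eps_CO3-HCO3 + eps_HCO3-CO2)

with temperature-dependent equilibrium enrichment factors (per mil)

    eps_HCO3-CO2 = 9866/T - 24.12        (T in K)
    eps_CO3-HCO3 = 1.85 - 666/T

Speciation helpers convert between pH, TDIC, alkalinity and the three
carbonate species using freshwater apparent constants (Harned-type fits);
no ionic-strength correction is applied by default (see the methods note
for the hypersaline-bottom-water caveat).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import MOLAR_MASS_CO3, MOLAR_MASS_HCO3, T0_K

__all__ = [
    "EquilibriumConstants",
    "CarbonateSpeciation",
    "Delta13CResult",
    "InfeasibleStateError",
    "freshwater_constants",
    "enrichment_factors",
    "delta13c_co2_from_tdic",
    "speciation_fractions",
    "speciate_carbonate",
    "ph_from_carbonate_ratio",
    "mg_to_mmol",
]


class InfeasibleStateError(ValueError):
    """The requested carbonate state is not physically realizable."""


@dataclass(frozen=True)
class EquilibriumConstants:
    """Apparent carbonic-acid and water equilibrium constants at one temperature."""

    K1: float  # mol L-1, CO2(aq) + H2O <-> H+ + HCO3-
    K2: float  # mol L-1, HCO3- <-> H+ + CO3=
    Kw: float  # mol2 L-2, water autoionization
    temperature_c: float
    source: str = ""

    def __post_init__(self) -> None:
        if min(self.K1, self.K2, self.Kw) <= 0:
            raise ValueError("equilibrium constants must be positive")
        if self.K1 <= self.K2:
            raise ValueError("expected K1 > K2 for carbonic acid")

    @property
    def pK1(self) -> float:
        return -math.log10(self.K1)

    @property
    def pK2(self) -> float:
        return -math.log10(self.K2)


def freshwater_constants(temperature_c: float) -> EquilibriumConstants:
    """Freshwater (zero ionic strength) carbonic-acid constants.

    K1 from the Harned & Davis (1943) fit, K2 from Harned & Scholes (1941),
    Kw from Harned & Owen; all as log10 fits in absolute temperature, valid
    for roughly 0-50 degC.
    """
    t = temperature_c + T0_K
    log_k1 = -3404.71 / t + 14.8435 - 0.032786 * t
    log_k2 = -2902.39 / t + 6.4980 - 0.02379 * t
    log_kw = -4470.99 / t + 6.0875 - 0.01706 * t
    return EquilibriumConstants(
        K1=10.0 ** log_k1,
        K2=10.0 ** log_k2,
        Kw=10.0 ** log_kw,
        temperature_c=temperature_c,
        source="Harned & Davis 1943 / Harned & Scholes 1941 / Harned & Owen",
    )


def enrichment_factors(temperature_k: float) -> tuple[float, float]:
    """Equilibrium 13C enrichment factors (per mil) at ``temperature_k``.

    Returns ``(eps_HCO3-CO2, eps_CO3-HCO3)``.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0 K")
    eps_hco3_co2 = 9866.0 / temperature_k - 24.12
    eps_co3_hco3 = 1.85 - 666.0 / temperature_k
    return eps_hco3_co2, eps_co3_hco3


@dataclass
class Delta13CResult:
    """d13C-CO2 with the evaluated species fractions and enrichment factors."""

    delta13c_co2: float  # per mil vs V-PDB
    delta13c_tdic: float
    tdic_mmol_l: float
    f_hco3: float
    f_co3: float
    eps_hco3_co2: float
    eps_co3_hco3: float
    temperature_k: float


def delta13c_co2_from_tdic(
    hco3_mmol_l: float,
    co3_mmol_l: float,
    co2_mmol_l: float,
    delta13c_tdic: float,
    temperature_k: float,
) -> Delta13CResult:
    """Isotope mass balance for d13C of dissolved CO2, from d13C-TDIC.

    Assumes chemical and isotopic equilibrium among CO2(aq), HCO3- and CO3=.
    Concentrations in mmol L-1; the result carries the species fractions and
    enrichment factors for provenance.
    """
    if min(hco3_mmol_l, co3_mmol_l, co2_mmol_l) < 0:
        raise ValueError("species concentrations must be >= 0")
    tdic = hco3_mmol_l + co3_mmol_l + co2_mmol_l
    if tdic <= 0:
        raise InfeasibleStateError("TDIC must be > 0 for the isotope mass balance")
    eps1, eps2 = enrichment_factors(temperature_k)
    f_hco3 = hco3_mmol_l / tdic
    f_co3 = co3_mmol_l / tdic
    value = delta13c_tdic - f_hco3 * eps1 - f_co3 * (eps2 + eps1)
    return Delta13CResult(
        delta13c_co2=value,
        delta13c_tdic=delta13c_tdic,
        tdic_mmol_l=tdic,
        f_hco3=f_hco3,
        f_co3=f_co3,
        eps_hco3_co2=eps1,
        eps_co3_hco3=eps2,
        temperature_k=temperature_k,
    )


@dataclass
class CarbonateSpeciation:
    """CO2(aq), HCO3- and CO3= concentrations (mmol L-1) at one pH."""

    co2_mmol_l: float
    hco3_mmol_l: float
    co3_mmol_l: float
    ph: float
    constants: EquilibriumConstants

    @property
    def tdic_mmol_l(self) -> float:
        return self.co2_mmol_l + self.hco3_mmol_l + self.co3_mmol_l


def speciation_fractions(
    ph: float, constants: EquilibriumConstants
) -> tuple[float, float, float]:
    """Fractions (f_CO2, f_HCO3, f_CO3) of TDIC at ``ph``; they sum to 1.

    Hydrogen-ion activity is taken as a_H = 10**(-pH).
    """
    if not 0.0 < ph < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    a_h = 10.0 ** (-ph)
    k1, k2 = constants.K1, constants.K2
    denom = a_h * a_h + k1 * a_h + k1 * k2
    return a_h * a_h / denom, k1 * a_h / denom, k1 * k2 / denom


def speciate_carbonate(
    ph: float,
    *,
    tdic_mmol_l: float | None = None,
    hco3_mmol_l: float | None = None,
    co3_mmol_l: float | None = None,
    alkalinity_meq_l: float | None = None,
    temperature_c: float = 21.0,
    constants: EquilibriumConstants | None = None,
) -> CarbonateSpeciation:
    """Closed-form carbonate speciation from pH and one known quantity.

    Exactly one of the following must be supplied:

    * ``tdic_mmol_l`` — total dissolved inorganic carbon;
    * both ``hco3_mmol_l`` and ``co3_mmol_l`` — the titrated pair, from
      which CO2(aq) is inferred as HCO3 * a_H / K1;
    * ``alkalinity_meq_l`` — carbonate alkalinity
      (HCO3 + 2 CO3 + OH - H, in meq L-1).
    """
    consts = constants or freshwater_constants(temperature_c)
    a_h = 10.0 ** (-ph)
    f_co2, f_hco3, f_co3 = speciation_fractions(ph, consts)

    known = [tdic_mmol_l is not None,
             hco3_mmol_l is not None and co3_mmol_l is not None,
             alkalinity_meq_l is not None]
    if sum(known) != 1:
        raise ValueError(
            "supply exactly one of tdic_mmol_l, the (hco3, co3) pair, "
            "or alkalinity_meq_l"
        )

    if tdic_mmol_l is not None:
        if tdic_mmol_l <= 0:
            raise InfeasibleStateError("TDIC must be > 0")
        return CarbonateSpeciation(
            f_co2 * tdic_mmol_l, f_hco3 * tdic_mmol_l, f_co3 * tdic_mmol_l,
            ph, consts,
        )

    if alkalinity_meq_l is not None:
        alk_eq_l = alkalinity_meq_l * 1e-3
        # Alk = TDIC*(f_hco3 + 2 f_co3) + Kw/aH - aH
        carb = alk_eq_l - consts.Kw / a_h + a_h
        if carb <= 0:
            raise InfeasibleStateError(
                "alkalinity and pH imply non-positive carbonate content"
            )
        tdic_mol = carb / (f_hco3 + 2.0 * f_co3)
        tdic = tdic_mol * 1e3
        return CarbonateSpeciation(
            f_co2 * tdic, f_hco3 * tdic, f_co3 * tdic, ph, consts
        )

    assert hco3_mmol_l is not None and co3_mmol_l is not None
    if hco3_mmol_l <= 0 or co3_mmol_l < 0:
        raise InfeasibleStateError("HCO3 must be > 0 and CO3 >= 0")
    co2 = hco3_mmol_l * a_h / consts.K1
    return CarbonateSpeciation(co2, hco3_mmol_l, co3_mmol_l, ph, consts)


def ph_from_carbonate_ratio(
    hco3_mmol_l: float, co3_mmol_l: float, constants: EquilibriumConstants
) -> float:
    """pH implied by a measured HCO3-/CO3= ratio: pH = pK2 + log10(CO3/HCO3)."""
    if hco3_mmol_l <= 0 or co3_mmol_l <= 0:
        raise ValueError("both species must be > 0 to invert the ratio")
    return constants.pK2 + math.log10(co3_mmol_l / hco3_mmol_l)


def mg_to_mmol(mg_l: float, molar_mass_g_mol: float) -> float:
    """Convert mg L-1 to mmol L-1 (molar mass in g mol-1)."""
    return mg_l / molar_mass_g_mol


#: Convenience molar masses re-exported for callers doing mg -> mmol.
HCO3_G_MOL = MOLAR_MASS_HCO3
CO3_G_MOL = MOLAR_MASS_CO3
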
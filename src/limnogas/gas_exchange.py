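"""Thin-boundary-layer (TBL) water-air diffusive gas fluxes.

Flux of gas i across the water-air interface:

    Phi_i = beta * k_i * (C_i,w - C_i,eq)

where C_i,w is the surface-water concentration, C_i,eq the concentration at
equilibrium with the atmosphere, k_i the gas transfer velocity, and beta the
chemical-enhancement factor (CO2 only; unity for all other gases).  The
transfer velocity is scaled from an empirical wind-speed relation for
k600 (the velocity normalized to Schmidt number 600):

    k_i = k600 * (Sc_i / 600) ** x,   x = -0.67 (U10 < 3 m/s) or -0.5

Schmidt numbers come from fourth-order polynomial fits in temperature;
equilibrium concentrations from freshwater/seawater solubility fits (Weiss
for CO2, Wiesenburg-Guinasso Bunsen coefficients for CH4) at the station
pressure; beta from the Hoover-Berkshire stagnant-film reaction-diffusion
model, which matters at soda-lake pH where CO2 is consumed by hydration and
hydroxylation within the diffusive boundary layer.

Fluxes are reported in mg C m-2 d-1, positive from water to air.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .carbonate_isotope import EquilibriumConstants, freshwater_constants
from .constants import (
    BAROMETRIC_SCALE_HEIGHT_M,
    CM_PER_H_TO_M_PER_D,
    DEFAULT_CH4_MOLE_FRACTION,
    DEFAULT_CO2_MOLE_FRACTION,
    MOLAR_MASS_C,
    MOLAR_MASS_O2,
    MOLAR_VOLUME_STP,
    T0_K,
)

__all__ = [
    "SCHMIDT_COEFFICIENTS",
    "K600_MODELS",
    "EnhancementResult",
    "FluxResult",
    "schmidt_number",
    "k600_model",
    "schmidt_exponent",
    "transfer_velocity",
    "station_pressure",
    "co2_molar_solubility",
    "ch4_molar_solubility",
    "equilibrium_concentration",
    "co2_diffusivity",
    "hydration_rate",
    "hydroxylation_rate",
    "enhancement_factor",
    "diffusive_flux",
    "oxygen_saturation",
    "flux_table",
]

#: Fourth-order Schmidt-number polynomials in temperature (degC), freshwater.
SCHMIDT_COEFFICIENTS: dict[str, tuple[float, ...]] = {
    "CO2": (2116.8, -136.25, 4.7353, -0.09231, 0.0007555),
    "CH4": (2101.2, -131.54, 4.4931, -0.08676, 0.00070663),
}

#: Empirical wind-speed relations for k600 (cm h-1), U10 in m s-1.
K600_MODELS = {
    "crusius_wanninkhof": lambda u10: 0.72 * u10,
    "cole_caraco": lambda u10: 0.215 * u10 ** 1.7 + 2.07,
    "nightingale": lambda u10: 0.23 * u10 ** 2 + 0.1 * u10,
}


def schmidt_number(gas: str, temperature_c: float, out_of_range: str = "raise") -> float:
    """Schmidt number of CO2 or CH4 in freshwater at ``temperature_c``.

    The polynomial fits are valid for 0-40 degC; outside that range the
    behaviour is controlled by ``out_of_range`` ("raise" or "warn").
    """
    if gas not in SCHMIDT_COEFFICIENTS:
        raise KeyError(
            f"no Schmidt polynomial for {gas!r}; have {sorted(SCHMIDT_COEFFICIENTS)}"
        )
    if not 0.0 <= temperature_c <= 40.0:
        msg = f"temperature {temperature_c} degC outside the 0-40 degC fit range"
        if out_of_range == "raise":
            raise ValueError(msg)
        import warnings

        warnings.warn(msg, stacklevel=2)
    coeffs = SCHMIDT_COEFFICIENTS[gas]
    return float(np.polynomial.polynomial.polyval(temperature_c, coeffs))


def k600_model(model: str, u10_m_s: float) -> float:
    """k600 (cm h-1) from one of the registered wind-speed relations."""
    if model not in K600_MODELS:
        raise KeyError(f"unknown k600 model {model!r}; valid: {sorted(K600_MODELS)}")
    if u10_m_s < 0:
        raise ValueError("wind speed must be >= 0")
    return float(K600_MODELS[model](u10_m_s))


def schmidt_exponent(u10_m_s: float) -> float:
    """Schmidt exponent x: -0.67 for smooth surfaces (U10 < 3 m/s), else -0.5.

    At exactly 3 m/s the rough-surface value -0.5 is used (continuity with
    the high-wind regime).
    """
    return -0.67 if u10_m_s < 3.0 else -0.5


def transfer_velocity(k600_cm_h: float, sc: float, u10_m_s: float) -> float:
    """Gas transfer velocity k_i = k600 * (Sc/600)**x, in cm h-1."""
    if k600_cm_h <= 0 or sc <= 0:
        raise ValueError("k600 and Sc must be > 0")
    return k600_cm_h * (sc / 600.0) ** schmidt_exponent(u10_m_s)


def station_pressure(
    elevation_m: float, scale_height_m: float = BAROMETRIC_SCALE_HEIGHT_M
) -> float:
    """Station pressure (atm) from the isothermal barometric formula."""
    return math.exp(-elevation_m / scale_height_m)


def co2_molar_solubility(temperature_c: float, salinity: float = 0.0) -> float:
    """CO2 molar solubility K0 (mol L-1 atm-1), Weiss (1974) fit."""
    t = temperature_c + T0_K
    ln_k0 = (
        -58.0931
        + 90.5069 * (100.0 / t)
        + 22.2940 * math.log(t / 100.0)
        + salinity
        * (0.027766 - 0.025888 * (t / 100.0) + 0.0050578 * (t / 100.0) ** 2)
    )
    return math.exp(ln_k0)


def ch4_molar_solubility(temperature_c: float, salinity: float = 0.0) -> float:
    """CH4 molar solubility (mol L-1 atm-1) from the Wiesenburg-Guinasso
    (1979) Bunsen-coefficient fit, divided by the STP molar volume."""
    t = temperature_c + T0_K
    ln_bunsen = (
        -68.8862
        + 101.4956 * (100.0 / t)
        + 28.7314 * math.log(t / 100.0)
        + salinity
        * (-0.076146 + 0.043970 * (t / 100.0) - 0.0068672 * (t / 100.0) ** 2)
    )
    return math.exp(ln_bunsen) / MOLAR_VOLUME_STP


_SOLUBILITY = {"CO2": co2_molar_solubility, "CH4": ch4_molar_solubility}


def equilibrium_concentration(
    gas: str,
    temperature_c: float,
    mole_fraction: float,
    pressure_atm: float = 1.0,
    salinity: float = 0.0,
) -> float:
    """Dissolved concentration (µmol L-1) at equilibrium with the atmosphere.

    C_eq = solubility(T, S) * mole_fraction * station pressure.
    """
    if gas not in _SOLUBILITY:
        raise KeyError(f"no solubility fit for {gas!r}; have {sorted(_SOLUBILITY)}")
    if not 0.0 <= mole_fraction < 1.0:
        raise ValueError("atmospheric mole fraction must lie in [0, 1)")
    sol = _SOLUBILITY[gas](temperature_c, salinity)
    return sol * mole_fraction * pressure_atm * 1e6


def co2_diffusivity(temperature_c: float) -> float:
    """Molecular diffusivity of CO2 in water (cm2 s-1), Zeebe's power-law fit."""
    return 14.6836e-5 * ((T0_K + temperature_c) / 217.2056 - 1.0) ** 1.997


def hydration_rate(temperature_c: float) -> float:
    """CO2 + H2O hydration rate constant r1 (s-1), Johnson (1982) fit."""
    t = temperature_c + T0_K
    return math.exp(1246.98 - 6.19e4 / t - 183.0 * math.log(t))


def hydroxylation_rate(temperature_c: float) -> float:
    """CO2 + OH- rate constant r2 (L mol-1 s-1), Pinsent et al. (1956) fit."""
    t = temperature_c + T0_K
    return 10.0 ** (13.635 - 2895.0 / t)


@dataclass
class EnhancementResult:
    """Chemical-enhancement factor for CO2 invasion with all intermediates."""

    beta: float
    tau: float
    r: float  # s-1, combined hydration + hydroxylation rate
    r1: float  # s-1
    r2: float  # L mol-1 s-1
    diffusivity_cm2_s: float
    k_co2_cm_s: float


def enhancement_factor(
    temperature_c: float,
    ph: float,
    k_co2_cm_h: float,
    constants: EquilibriumConstants | None = None,
    r1: float | None = None,
    r2: float | None = None,
) -> EnhancementResult:
    """Hoover-Berkshire chemical-enhancement factor beta for CO2 invasion.

    In the stagnant boundary layer CO2 reacts while it diffuses, with
    combined pseudo-first-order rate r = r1 + r2*Kw/a_H.  With
    tau = 1 + a_H**2 / (K1*K2 + K1*a_H) and Q = sqrt(r*tau/D) * D / k:

        beta = tau / ((tau - 1) + tanh(Q)/Q)

    beta -> 1 as k -> infinity (thin layers outrun the chemistry) and is
    always >= 1.
    """
    if not 0.0 < ph < 14.0:
        raise ValueError("pH must lie in (0, 14)")
    if k_co2_cm_h <= 0:
        raise ValueError("k_CO2 must be > 0 (beta is unbounded as k -> 0)")
    consts = constants or freshwater_constants(temperature_c)
    r1_val = hydration_rate(temperature_c) if r1 is None else r1
    r2_val = hydroxylation_rate(temperature_c) if r2 is None else r2
    a_h = 10.0 ** (-ph)
    r = r1_val + r2_val * consts.Kw / a_h
    tau = 1.0 + a_h * a_h / (consts.K1 * consts.K2 + consts.K1 * a_h)
    diffusivity = co2_diffusivity(temperature_c)
    k_cm_s = k_co2_cm_h / 3600.0
    q = math.sqrt(r * tau / diffusivity) * diffusivity / k_cm_s
    tanh_term = 1.0 if q < 1e-8 else math.tanh(q) / q
    beta = tau / ((tau - 1.0) + tanh_term)
    return EnhancementResult(
        beta=beta, tau=tau, r=r, r1=r1_val, r2=r2_val,
        diffusivity_cm2_s=diffusivity, k_co2_cm_s=k_cm_s,
    )


@dataclass
class FluxResult:
    """Per-gas water-air diffusive flux with full provenance."""

    gas: str
    flux_mg_c_m2_d: float  # positive = water -> air
    k600_cm_h: float | None
    sc: float | None
    k_cm_h: float
    beta: float
    c_w_umol_l: float
    c_eq_umol_l: float
    model: str | None = None


def diffusive_flux(
    gas: str,
    c_w_umol_l: float,
    c_eq_umol_l: float,
    k_cm_h: float,
    beta: float = 1.0,
    k600_cm_h: float | None = None,
    sc: float | None = None,
    model: str | None = None,
) -> FluxResult:
    """TBL diffusive flux Phi = beta * k * (C_w - C_eq), in mg C m-2 d-1.

    Unit chain: k in cm h-1 -> m d-1 (x 0.24); µmol L-1 is mmol m-3; carbon
    mass 12.011 mg mmol-1.  Chemical enhancement applies to CO2 only; a
    beta != 1 for any other gas is rejected.
    """
    if k_cm_h <= 0:
        raise ValueError("transfer velocity must be > 0")
    if beta < 1.0:
        raise ValueError("beta must be >= 1")
    if gas != "CO2" and beta != 1.0:
        raise ValueError("chemical enhancement (beta != 1) applies to CO2 only")
    k_m_d = k_cm_h * CM_PER_H_TO_M_PER_D
    flux = beta * k_m_d * (c_w_umol_l - c_eq_umol_l) * MOLAR_MASS_C
    return FluxResult(
        gas=gas, flux_mg_c_m2_d=flux, k600_cm_h=k600_cm_h, sc=sc,
        k_cm_h=k_cm_h, beta=beta, c_w_umol_l=c_w_umol_l,
        c_eq_umol_l=c_eq_umol_l, model=model,
    )


# Garcia & Gordon (1992) refit of Benson & Krause, surface O2 solubility.
_O2_A = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
_O2_B = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
_O2_C0 = -2.75915e-7


def oxygen_saturation(
    temperature_c: float, salinity: float = 0.0, pressure_atm: float = 1.0
) -> float:
    """Dissolved O2 at air saturation (mg L-1), Garcia-Gordon formulation.

    Valid for -5 to 40 degC and salinity 0-42 (practical scale); scaled
    linearly by station pressure and converted from µmol kg-1 assuming
    density 1 kg L-1 (adequate for reporting against sonde readings).
    """
    ts = math.log((298.15 - temperature_c) / (T0_K + temperature_c))
    ln_c = sum(a * ts ** i for i, a in enumerate(_O2_A))
    ln_c += salinity * sum(b * ts ** i for i, b in enumerate(_O2_B))
    ln_c += _O2_C0 * salinity * salinity
    umol_kg = math.exp(ln_c)
    return umol_kg * MOLAR_MASS_O2 * 1e-3 * pressure_atm


def flux_table(
    c_w_umol_l: Mapping[str, float],
    temperature_c: float = 21.0,
    u10_m_s: float = 2.0,
    models: Iterable[str] | None = None,
    elevation_m: float | None = None,
    pressure_atm: float | None = None,
    atmosphere: Mapping[str, float] | None = None,
    salinity: float = 0.0,
    ph: float | None = None,
    enhancement: str = "unit",
) -> pd.DataFrame:
    """Tabulate TBL fluxes for several gases across the k600 model registry.

    Parameters
    ----------
    c_w_umol_l:
        Surface-water concentrations keyed by gas ("CO2", "CH4").
    enhancement:
        "unit" keeps beta = 1 for every gas; "hoover_berkshire" computes
        beta for CO2 from ``ph`` (required in that mode).
    atmosphere:
        Dry-air mole fractions keyed by gas; defaults 410 ppm CO2 and
        1.87 ppm CH4.
    elevation_m / pressure_atm:
        Either a site elevation (barometric pressure is derived) or an
        explicit station pressure; default 1 atm.
    """
    if enhancement not in ("unit", "hoover_berkshire"):
        raise ValueError("enhancement must be 'unit' or 'hoover_berkshire'")
    if enhancement == "hoover_berkshire" and ph is None:
        raise ValueError("hoover_berkshire enhancement requires a pH")
    if pressure_atm is None:
        pressure_atm = station_pressure(elevation_m) if elevation_m is not None else 1.0
    atm = {
        "CO2": DEFAULT_CO2_MOLE_FRACTION,
        "CH4": DEFAULT_CH4_MOLE_FRACTION,
        **(atmosphere or {}),
    }
    model_ids = list(models) if models is not None else sorted(K600_MODELS)

    rows = []
    for model in model_ids:
        k600 = k600_model(model, u10_m_s)
        for gas, c_w in c_w_umol_l.items():
            sc = schmidt_number(gas, temperature_c)
            k = transfer_velocity(k600, sc, u10_m_s)
            c_eq = equilibrium_concentration(
                gas, temperature_c, atm[gas], pressure_atm, salinity
            )
            beta = 1.0
            if gas == "CO2" and enhancement == "hoover_berkshire":
                beta = enhancement_factor(temperature_c, ph, k).beta
            res = diffusive_flux(
                gas, c_w, c_eq, k, beta=beta, k600_cm_h=k600, sc=sc, model=model
            )
            rows.append(
                {
                    "gas": gas,
                    "model": model,
                    "k600_cm_h": k600,
                    "Sc": sc,
                    "k_cm_h": k,
                    "beta": beta,
                    "Ceq_umol_L": c_eq,
                    "flux_mgC_m2_d": res.flux_mg_c_m2_d,
                }
            )
    return pd.DataFrame(rows)
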
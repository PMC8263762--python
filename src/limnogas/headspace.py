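"""Flask headspace-equilibration: dissolved and total gas amounts.

Dissolved gases are sampled into a partially filled, pre-evacuated flask;
at analysis time the headspace is assumed to be in Henry's-law equilibrium
with the water.  From the measured headspace mole fraction the moles in the
headspace (ideal gas), the aqueous concentration (Henry's law), the moles
remaining dissolved, and the total moles are recovered; a partial pressure
is reported from the total moles via the ideal-gas law over the nominal
flask volume.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .constants import R_GAS_L_ATM, T0_K

__all__ = [
    "HenryConstant",
    "FlaskPartition",
    "DEFAULT_HENRY_CONSTANTS",
    "partition_flask",
    "read_flask_table",
    "read_henry_table",
    "partition_table",
]


@dataclass(frozen=True)
class HenryConstant:
    """Molar solubility K_H (mol L-1 atm-1) of one gas at a stated temperature."""

    gas: str
    value: float  # mol L-1 atm-1
    temperature_c: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("Henry constant must be > 0")


# Replaceable defaults near 25 degC (freshwater), Sander (2015) compilation.
DEFAULT_HENRY_CONSTANTS: dict[str, HenryConstant] = {
    "CO2": HenryConstant("CO2", 3.39e-2, 25.0, "Sander (2015) compilation"),
    "CH4": HenryConstant("CH4", 1.42e-3, 25.0, "Sander (2015) compilation"),
    "N2": HenryConstant("N2", 6.42e-4, 25.0, "Sander (2015) compilation"),
    "O2": HenryConstant("O2", 1.27e-3, 25.0, "Sander (2015) compilation"),
    "Ar": HenryConstant("Ar", 1.40e-3, 25.0, "Sander (2015) compilation"),
    "He": HenryConstant("He", 3.78e-4, 25.0, "Sander (2015) compilation"),
    "H2": HenryConstant("H2", 7.79e-4, 25.0, "Sander (2015) compilation"),
}


@dataclass
class FlaskPartition:
    """One flask sample's gas partitioning with full provenance."""

    gas: str
    headspace_moles: float  # n_g, mol
    dissolved_moles: float  # n_l, mol
    total_moles: float  # n_t = n_l + n_g, mol
    aqueous_concentration_umol_l: float
    partial_pressure_atm: float  # from n_t, ideal gas over the flask volume
    flask_volume_l: float
    water_volume_l: float
    temperature_c: float
    warnings: list = field(default_factory=list)


def partition_flask(
    gas: str,
    headspace_mole_fraction: float,
    flask_volume_l: float,
    water_volume_l: float,
    temperature_c: float,
    henry: HenryConstant,
    headspace_pressure_atm: float = 1.0,
    temperature_tolerance_c: float = 5.0,
) -> FlaskPartition:
    """Partition one gas between flask headspace and water.

    The headspace volume is ``flask_volume_l - water_volume_l``.  The
    headspace moles follow the ideal-gas law at the analysis temperature;
    the aqueous concentration is ``K_H x (mole fraction x pressure)``;
    dissolved moles are concentration times water volume; total moles are
    the exact sum.  The reported partial pressure re-expands the total moles
    over the nominal (full) flask volume — the "total gas-accessible volume"
    convention, so that it is comparable across fill fractions.

    If the Henry constant's stated temperature differs from the sample
    temperature by more than ``temperature_tolerance_c`` a warning is
    recorded in the result provenance (not raised).
    """
    if not 0.0 <= headspace_mole_fraction <= 1.0:
        raise ValueError("headspace mole fraction must lie in [0, 1]")
    if not 0.0 < water_volume_l < flask_volume_l:
        raise ValueError("need 0 < water volume < flask volume")
    if headspace_pressure_atm <= 0:
        raise ValueError("headspace pressure must be > 0")

    warnings: list[str] = []
    if abs(henry.temperature_c - temperature_c) > temperature_tolerance_c:
        warnings.append(
            f"Henry constant stated at {henry.temperature_c} degC used at "
            f"{temperature_c} degC (tolerance {temperature_tolerance_c} degC)"
        )

    headspace_volume_l = flask_volume_l - water_volume_l
    t_k = temperature_c + T0_K
    p_i = headspace_mole_fraction * headspace_pressure_atm  # atm
    n_g = p_i * headspace_volume_l / (R_GAS_L_ATM * t_k)
    c_aq_mol_l = henry.value * p_i
    n_l = c_aq_mol_l * water_volume_l
    n_t = n_l + n_g
    partial_pressure = n_t * R_GAS_L_ATM * t_k / flask_volume_l
    return FlaskPartition(
        gas=gas,
        headspace_moles=n_g,
        dissolved_moles=n_l,
        total_moles=n_t,
        aqueous_concentration_umol_l=c_aq_mol_l * 1e6,
        partial_pressure_atm=partial_pressure,
        flask_volume_l=flask_volume_l,
        water_volume_l=water_volume_l,
        temperature_c=temperature_c,
        warnings=warnings,
    )


def read_flask_table(path) -> pd.DataFrame:
    """Read the flask CSV dialect.

    Columns: ``sample_id, gas, mole_fraction, headspace_pressure_atm,
    flask_vol_L, water_vol_L, temp_C``.
    """
    required = {
        "sample_id", "gas", "mole_fraction", "headspace_pressure_atm",
        "flask_vol_L", "water_vol_L", "temp_C",
    }
    table = pd.read_csv(path)
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"flask table missing columns: {sorted(missing)}")
    return table


def read_henry_table(path) -> dict[str, HenryConstant]:
    """Read a replacement Henry-constant table (``gas, value, temp_C, source``)."""
    table = pd.read_csv(path)
    return {
        str(row.gas): HenryConstant(
            str(row.gas), float(row.value), float(row.temp_C),
            str(getattr(row, "source", "")),
        )
        for row in table.itertuples()
    }


def partition_table(
    flasks: pd.DataFrame,
    henry_constants: dict[str, HenryConstant] | None = None,
) -> pd.DataFrame:
    """Apply :func:`partition_flask` to every row of a flask table."""
    constants = henry_constants or DEFAULT_HENRY_CONSTANTS
    rows = []
    for row in flasks.itertuples():
        gas = str(row.gas)
        if gas not in constants:
            raise KeyError(f"no Henry constant for gas {gas!r}")
        part = partition_flask(
            gas=gas,
            headspace_mole_fraction=float(row.mole_fraction),
            flask_volume_l=float(row.flask_vol_L),
            water_volume_l=float(row.water_vol_L),
            temperature_c=float(row.temp_C),
            henry=constants[gas],
            headspace_pressure_atm=float(row.headspace_pressure_atm),
        )
        rows.append(
            {
                "sample_id": row.sample_id,
                "gas": gas,
                "headspace_moles": part.headspace_moles,
                "dissolved_moles": part.dissolved_moles,
                "total_moles": part.total_moles,
                "aqueous_umol_L": part.aqueous_concentration_umol_l,
                "partial_pressure_atm": part.partial_pressure_atm,
                "warnings": "; ".join(part.warnings),
            }
        )
    return pd.DataFrame(rows)
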
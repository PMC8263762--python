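"""Synthetic stratified-lake data with known ground truth.

Generates the three kinds of input the pipeline consumes — depth profiles,
molecular-formula abundance tables, and flask headspace measurements — for a
two-layer meromictic soda-lake scenario: an oxycline near 1.5 m, a
chemocline near 3.5 m, CH4 rising from ~153 (surface) to 615 µmol L-1
(bottom), CO2 from 1 to ~120 µmol L-1, and a DOM table in which a planted
fraction of aliphatic-like formulas covaries with CH4 while a planted
fraction of aromatic-like formulas anti-covaries.

Every generator is a pure function of (scenario, seed): a single integer
seed drives one named pseudorandom stream per generator, so adding a
generator never perturbs existing fixtures.  Each generator returns both
the noisy data and the noise-free truth needed to compute downstream
expected values in closed form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dom_screen import FormulaRecord, classify_formula
from .headspace import DEFAULT_HENRY_CONSTANTS, HenryConstant
from .profile_core import DepthProfile

__all__ = [
    "LakeScenario",
    "ProfileTruth",
    "generate_profile",
    "generate_formula_table",
    "generate_flask_sample",
]

# Sub-stream ids: one per generator.
_STREAM_PROFILE = 1
_STREAM_FORMULAS = 2
_STREAM_FLASK = 3


@dataclass(frozen=True)
class LakeScenario:
    """Parameters of the synthetic two-layer meromictic lake.

    Surface/bottom endpoint values follow the measured ranges of the
    emulated soda lake; transitions are logistic across the oxycline
    (temperature, dissolved O2) or the chemocline (everything else).
    """

    seed: int = 0
    depths: tuple = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 4.5)
    oxycline_m: float = 1.5
    chemocline_m: float = 3.5
    steepness_per_m: float = 8.0

    temp_surface_c: float = 22.4
    temp_bottom_c: float = 20.5
    ph_surface: float = 9.61
    ph_bottom: float = 9.47
    cond_surface_us_cm: float = 4500.0
    cond_bottom_us_cm: float = 30000.0
    do_surface_mg_l: float = 3.6
    do_bottom_mg_l: float = 0.1
    ch4_surface_umol_l: float = 153.0
    ch4_bottom_umol_l: float = 615.0
    co2_surface_umol_l: float = 1.0
    co2_bottom_umol_l: float = 120.0
    doc_surface_mg_l: float = 97.3
    doc_bottom_mg_l: float = 593.0
    hco3_surface_mg_l: float = 2500.0
    hco3_bottom_mg_l: float = 9523.0
    co3_surface_mg_l: float = 600.0
    co3_bottom_mg_l: float = 2196.0
    d13c_ch4_surface: float = -16.0
    d13c_ch4_bottom: float = -78.0
    d13c_tdic_surface: float = 2.91
    d13c_tdic_bottom: float = 10.7

    #: Relative Gaussian noise sd on conductivity, O2, gases, DOC and
    #: carbonate species (temperature, pH and isotope ratios stay clean).
    noise_rel: float = 0.02

    # DOM table parameters.
    n_aliphatic: int = 200
    n_aromatic: int = 100
    n_other: int = 100
    planted_aliphatic_pos_frac: float = 0.275
    planted_aromatic_neg_frac: float = 0.34
    dom_amplitude: float = 1.0
    dom_noise_rel: float = 0.05

    def __post_init__(self) -> None:
        zmin, zmax = min(self.depths), max(self.depths)
        if not (zmin <= self.oxycline_m <= self.chemocline_m <= zmax):
            raise ValueError("layer boundaries must satisfy "
                             "min depth <= oxycline <= chemocline <= max depth")
        for name in ("planted_aliphatic_pos_frac", "planted_aromatic_neg_frac"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ProfileTruth:
    """Noise-free profile and bookkeeping for a generated realization."""

    scenario: LakeScenario
    clean: pd.DataFrame  # same shape/columns as the noisy profile
    truncation_count: int  # noise draws clipped at zero


def _logistic(z: np.ndarray, center: float, steepness: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-steepness * (z - center)))


def generate_profile(scenario: LakeScenario) -> tuple[DepthProfile, ProfileTruth]:
    """Generate a noisy depth profile plus its noise-free truth."""
    s = scenario
    z = np.asarray(s.depths, dtype=float)
    f_oxy = _logistic(z, s.oxycline_m, s.steepness_per_m)
    f_chem = _logistic(z, s.chemocline_m, s.steepness_per_m)

    def across(f, surface, bottom):
        return surface + (bottom - surface) * f

    clean = pd.DataFrame(
        {
            "temp_C": across(f_oxy, s.temp_surface_c, s.temp_bottom_c),
            "pH": across(f_chem, s.ph_surface, s.ph_bottom),
            "cond_uS_cm": across(f_chem, s.cond_surface_us_cm, s.cond_bottom_us_cm),
            "DO_mg_L": across(f_oxy, s.do_surface_mg_l, s.do_bottom_mg_l),
            "CH4_umol_L": across(f_chem, s.ch4_surface_umol_l, s.ch4_bottom_umol_l),
            "CO2_umol_L": across(f_chem, s.co2_surface_umol_l, s.co2_bottom_umol_l),
            "DOC_mg_L": across(f_chem, s.doc_surface_mg_l, s.doc_bottom_mg_l),
            "HCO3_mg_L": across(f_chem, s.hco3_surface_mg_l, s.hco3_bottom_mg_l),
            "CO3_mg_L": across(f_chem, s.co3_surface_mg_l, s.co3_bottom_mg_l),
            "d13C_CH4": across(f_chem, s.d13c_ch4_surface, s.d13c_ch4_bottom),
            "d13C_TDIC": across(f_chem, s.d13c_tdic_surface, s.d13c_tdic_bottom),
        },
        index=pd.Index(z, name="depth_m"),
    )

    rng = np.random.default_rng([s.seed, _STREAM_PROFILE])
    noisy = clean.copy()
    truncations = 0
    noisy_cols = ("cond_uS_cm", "DO_mg_L", "CH4_umol_L", "CO2_umol_L",
                  "DOC_mg_L", "HCO3_mg_L", "CO3_mg_L")
    if s.noise_rel > 0:
        for col in noisy_cols:
            vals = clean[col].to_numpy() * (1.0 + rng.normal(0.0, s.noise_rel, len(z)))
            truncations += int((vals < 0).sum())
            noisy[col] = np.clip(vals, 0.0, None)

    profile = DepthProfile(station_id=f"synthetic-{s.seed}", data=noisy)
    return profile, ProfileTruth(scenario=s, clean=clean, truncation_count=truncations)


# ---------------------------------------------------------------------------
# Formula table

_CLASS_SAMPLERS = {
    # (H/C range, O/C range) used as proposal distributions; rejection
    # sampling against classify_formula guarantees the intended label.
    "aliphatic-like": ((1.5, 2.1), (0.02, 0.25)),
    "aromatic-like": ((0.4, 0.9), (0.05, 0.4)),
    "other": ((1.0, 1.45), (0.35, 0.8)),
}


def _sample_formula(rng: np.random.Generator, target_class: str,
                    formula_id: str) -> FormulaRecord:
    hc_range, oc_range = _CLASS_SAMPLERS[target_class]
    for _ in range(200):
        c = int(rng.integers(10, 41))
        h = max(2, int(round(c * rng.uniform(*hc_range))))
        o = int(round(c * rng.uniform(*oc_range)))
        n = int(rng.integers(0, 2)) if target_class == "other" else 0
        rec = FormulaRecord(formula_id, c, h, n, o, 0)
        if classify_formula(rec) == target_class:
            return rec
    raise RuntimeError(f"could not sample a {target_class} formula")  # pragma: no cover


def generate_formula_table(
    scenario: LakeScenario, profile: DepthProfile
) -> tuple[list[FormulaRecord], pd.DataFrame]:
    """Generate a formula table with planted CH4 covariation.

    Within each class, the planted fraction of formulas receives an
    abundance that is a rank-uniform monotone transform of the profile's
    CH4 concentrations (negated ordering for the anti-correlated aromatic
    fraction) with multiplicative Gaussian noise; the remainder receive
    independent lognormal noise.  Returns the records and a truth table
    (``formula_id, class, planted`` in {pos, neg, none}).
    """
    s = scenario
    ch4 = profile.column("CH4_umol_L", dropna=False).to_numpy(dtype=float)
    if len(ch4) < 4 or np.isnan(ch4).any():
        raise ValueError("profile needs CH4 at >= 4 depths for the formula table")
    n_depths = len(ch4)
    ranks = stats.rankdata(ch4)  # monotone in CH4

    rng = np.random.default_rng([s.seed, _STREAM_FORMULAS])
    records: list[FormulaRecord] = []
    truth_rows = []
    counter = 0
    plan = (
        ("aliphatic-like", s.n_aliphatic, "pos", s.planted_aliphatic_pos_frac),
        ("aromatic-like", s.n_aromatic, "neg", s.planted_aromatic_neg_frac),
        ("other", s.n_other, None, 0.0),
    )
    for cls, n_cls, direction, frac in plan:
        n_planted = int(round(frac * n_cls))
        for i in range(n_cls):
            counter += 1
            rec = _sample_formula(rng, cls, f"F{counter:05d}")
            planted = direction if i < n_planted else "none"
            base = rng.uniform(0.5, 2.0)
            if planted in ("pos", "neg"):
                order = ranks if planted == "pos" else (n_depths + 1 - ranks)
                clean_ab = base * (1.0 + s.dom_amplitude * (order - 1) / (n_depths - 1))
                ab = clean_ab * (1.0 + rng.normal(0.0, s.dom_noise_rel, n_depths))
                ab = np.clip(ab, 1e-9, None)
            else:
                ab = base * rng.lognormal(0.0, 0.5, n_depths)
            rec.abundances = ab
            records.append(rec)
            truth_rows.append(
                {"formula_id": rec.formula_id, "class": cls,
                 "planted": planted or "none"}
            )
    return records, pd.DataFrame(truth_rows)


def generate_flask_sample(
    gas: str,
    aqueous_concentration_umol_l: float,
    flask_volume_l: float = 0.25,
    water_volume_l: float = 0.15,
    temperature_c: float = 21.0,
    henry: HenryConstant | None = None,
    headspace_pressure_atm: float = 1.0,
    sample_id: str = "synthetic",
) -> dict:
    """Inverse of flask partitioning: the headspace mole fraction that maps
    back exactly to the requested aqueous concentration.

    Returns a row dict in the flask-CSV dialect.
    """
    if aqueous_concentration_umol_l < 0:
        raise ValueError("aqueous concentration must be >= 0")
    if not 0.0 < water_volume_l < flask_volume_l:
        raise ValueError("need 0 < water volume < flask volume")
    h = henry or DEFAULT_HENRY_CONSTANTS[gas]
    c_mol_l = aqueous_concentration_umol_l * 1e-6
    mole_fraction = c_mol_l / (h.value * headspace_pressure_atm)
    if mole_fraction > 1.0:
        raise ValueError("concentration exceeds what a pure-gas headspace can carry")
    return {
        "sample_id": sample_id,
        "gas": gas,
        "mole_fraction": mole_fraction,
        "headspace_pressure_atm": headspace_pressure_atm,
        "flask_vol_L": flask_volume_l,
        "water_vol_L": water_volume_l,
        "temp_C": temperature_c,
    }
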
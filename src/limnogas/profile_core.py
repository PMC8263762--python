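"""Depth-profile data model, CSV I/O, and stratification diagnostics.

A :class:`DepthProfile` holds one station's vertical profile of
physico-chemical measurements (temperature, pH, conductivity, dissolved O2,
dissolved gas concentrations, carbon isotope ratios, carbonate species, DOC)
on a strictly increasing, positive-downward depth grid.  Diagnostics locate
the chemocline (sharpest conductivity change) and the oxycline (where O2
drops below an anoxia threshold), extrapolate a gas depletion depth from the
near-surface concentration decrease, and convert chlorophyll-a extract
absorbance to a water-sample concentration.

Missing cells are preserved as NaN; diagnostics skip depths with missing
required fields and report which depths were used, rather than interpolating.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PROFILE_COLUMNS",
    "DepthProfile",
    "LayerPartition",
    "DepletionResult",
    "ProfileValidationError",
    "InsufficientDataError",
    "NoTransitionError",
    "load_profile",
    "write_profile",
    "locate_layers",
    "depletion_depth",
    "chlorophyll_from_absorbance",
]

#: Canonical optional columns of the profile CSV dialect (plus required depth_m).
PROFILE_COLUMNS = (
    "temp_C",
    "pH",
    "cond_uS_cm",
    "DO_mg_L",
    "CH4_umol_L",
    "CO2_umol_L",
    "N2_umol_L",
    "Ar_umol_L",
    "He_umol_L",
    "H2_umol_L",
    "d13C_CH4",
    "d13C_CO2",
    "d13C_TDIC",
    "HCO3_mg_L",
    "CO3_mg_L",
    "DOC_mg_L",
)

# Columns that must be non-negative where present (delta13C values may be negative).
_NONNEGATIVE_COLUMNS = (
    "cond_uS_cm",
    "DO_mg_L",
    "CH4_umol_L",
    "CO2_umol_L",
    "N2_umol_L",
    "Ar_umol_L",
    "He_umol_L",
    "H2_umol_L",
    "HCO3_mg_L",
    "CO3_mg_L",
    "DOC_mg_L",
)


class ProfileValidationError(ValueError):
    """A profile violates a structural invariant (depth order, ranges)."""


class InsufficientDataError(ValueError):
    """Too few usable depths for the requested diagnostic."""


class NoTransitionError(ValueError):
    """The profile never crosses the requested threshold."""


@dataclass
class DepthProfile:
    """One station's depth-indexed table of measurements.

    ``data`` is indexed by depth in metres (positive downward, strictly
    increasing) and carries any subset of :data:`PROFILE_COLUMNS`; missing
    measurements are NaN.
    """

    station_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ProfileValidationError("profile must contain at least one depth record")
        depths = np.asarray(self.data.index, dtype=float)
        if np.any(~np.isfinite(depths)) or np.any(depths < 0):
            raise ProfileValidationError("depths must be finite and >= 0")
        bad = np.nonzero(np.diff(depths) <= 0)[0]
        if bad.size:
            rows = ", ".join(str(i + 2) for i in bad)  # +2: header row + 1-based
            raise ProfileValidationError(
                f"depths must be strictly increasing; violation at row(s) {rows}"
            )
        for col in _NONNEGATIVE_COLUMNS:
            if col in self.data.columns:
                vals = self.data[col]
                if (vals.dropna() < 0).any():
                    offending = list(self.data.index[vals < 0])
                    raise ProfileValidationError(
                        f"{col} must be >= 0; negative at depth(s) {offending}"
                    )
        if "pH" in self.data.columns:
            ph = self.data["pH"].dropna()
            if ((ph <= 0) | (ph >= 14)).any():
                raise ProfileValidationError("pH values must lie in (0, 14)")
        self.data.index.name = "depth_m"

    @property
    def depths(self) -> np.ndarray:
        """Depth grid in m, positive downward."""
        return np.asarray(self.data.index, dtype=float)

    def column(self, name: str, dropna: bool = True) -> pd.Series:
        """Return one measured variable, by canonical column name."""
        if name not in self.data.columns:
            return pd.Series(dtype=float, name=name)
        s = self.data[name]
        return s.dropna() if dropna else s


@dataclass
class LayerPartition:
    """Two-boundary layering: oxic surface (OSW), anoxic surface (ASW), bottom (BW)."""

    chemocline_depth: float
    oxycline_depth: float
    labels: pd.Series  # one of {"OSW", "ASW", "BW"} per profile depth
    oxycline_clamped: bool = False

    def __post_init__(self) -> None:
        if self.oxycline_depth > self.chemocline_depth:
            raise ProfileValidationError(
                "oxycline must be at or above the chemocline "
                f"({self.oxycline_depth} > {self.chemocline_depth})"
            )


@dataclass
class DepletionResult:
    """Linear extrapolation of a near-surface concentration decrease to zero."""

    gas: str
    depth: float  # m where the fitted line crosses zero concentration (NaN if none)
    slope: float  # µmol L-1 m-1, concentration vs depth (positive downward)
    intercept: float  # µmol L-1 at depth 0
    depths_used: tuple
    no_depletion: bool  # True when concentration does not decrease toward the surface
    above_surface: bool  # True when the crossing lies above the water surface (< 0 m)


def load_profile(
    path,
    format_spec: Mapping[str, str] | None = None,
    station_id: str | None = None,
) -> DepthProfile:
    """Read a profile CSV into a validated :class:`DepthProfile`.

    Parameters
    ----------
    path:
        CSV with a header row, comma separator, decimal point, UTF-8.  A
        ``depth_m`` column is required (possibly via ``format_spec``).
    format_spec:
        Optional mapping from file column names to canonical names
        (``depth_m`` plus :data:`PROFILE_COLUMNS`).  Unmapped columns are
        ignored; by default canonical names are taken as-is.
    station_id:
        Stored on the profile; defaults to the file stem.
    """
    raw = pd.read_csv(path)
    if format_spec:
        raw = raw.rename(columns=dict(format_spec))
    if "depth_m" not in raw.columns:
        raise ProfileValidationError("profile CSV must provide a depth_m column")
    keep = ["depth_m"] + [c for c in PROFILE_COLUMNS if c in raw.columns]
    table = raw[keep].apply(pd.to_numeric).astype(float)
    table = table.set_index("depth_m")
    sid = station_id if station_id is not None else str(getattr(path, "stem", path))
    return DepthProfile(station_id=sid, data=table)


def write_profile(profile: DepthProfile, path, float_format: str = "%.10g") -> None:
    """Write a profile back to the CSV dialect accepted by :func:`load_profile`."""
    profile.data.to_csv(path, float_format=float_format)


def locate_layers(
    profile: DepthProfile, anoxia_threshold_mg_l: float = 0.5
) -> LayerPartition:
    """Locate the chemocline and oxycline and label each depth OSW/ASW/BW.

    The chemocline is the midpoint of the depth interval with the largest
    absolute finite-difference conductivity gradient (ties broken toward the
    shallowest interval).  The oxycline is the shallowest interval midpoint
    where dissolved O2 crosses from at-or-above to below
    ``anoxia_threshold_mg_l`` (default 0.5 mg L-1); a profile that is anoxic
    already at its shallowest measured depth puts the oxycline at that depth.
    """
    cond = profile.column("cond_uS_cm")
    do = profile.column("DO_mg_L")
    if len(cond) < 3 or len(do) < 3:
        raise InsufficientDataError(
            "locate_layers needs conductivity and dissolved O2 at >= 3 depths "
            f"(have {len(cond)} and {len(do)})"
        )

    z = cond.index.to_numpy(dtype=float)
    grad = np.abs(np.diff(cond.to_numpy(dtype=float)) / np.diff(z))
    i = int(np.argmax(grad))  # argmax returns the first (shallowest) maximum
    chemocline = 0.5 * (z[i] + z[i + 1])

    zo = do.index.to_numpy(dtype=float)
    o2 = do.to_numpy(dtype=float)
    oxycline = None
    if o2[0] < anoxia_threshold_mg_l:
        oxycline = float(zo[0])
    else:
        for j in range(len(o2) - 1):
            if o2[j] >= anoxia_threshold_mg_l and o2[j + 1] < anoxia_threshold_mg_l:
                oxycline = 0.5 * (zo[j] + zo[j + 1])
                break
    if oxycline is None:
        raise NoTransitionError(
            f"dissolved O2 never crosses below {anoxia_threshold_mg_l} mg L-1"
        )

    clamped = oxycline > chemocline
    if clamped:
        oxycline = chemocline

    def label(depth: float) -> str:
        if depth <= oxycline:
            return "OSW"
        if depth <= chemocline:
            return "ASW"
        return "BW"

    labels = pd.Series(
        [label(d) for d in profile.depths], index=profile.data.index, name="layer"
    )
    return LayerPartition(
        chemocline_depth=float(chemocline),
        oxycline_depth=float(oxycline),
        labels=labels,
        oxycline_clamped=clamped,
    )


def depletion_depth(
    profile: DepthProfile,
    gas: str = "CH4",
    fit_window: Sequence[float] = (2.0, 4.5),
) -> DepletionResult:
    """Extrapolate where a gas would reach zero concentration.

    Fits an ordinary least-squares line of concentration against depth over
    ``fit_window`` (inclusive) and returns the depth at which the line
    crosses zero.  With depth positive downward, upward depletion means the
    fitted slope dC/dz is positive; a non-positive slope is flagged as
    no-depletion and no crossing is returned.  A crossing above the surface
    (negative depth) is returned as-is with ``above_surface`` set.
    """
    col = f"{gas}_umol_L"
    conc = profile.column(col)
    lo, hi = min(fit_window), max(fit_window)
    sel = conc[(conc.index >= lo) & (conc.index <= hi)]
    if len(sel) < 2:
        raise InsufficientDataError(
            f"depletion_depth needs >= 2 {gas} concentrations in [{lo}, {hi}] m"
        )
    z = sel.index.to_numpy(dtype=float)
    c = sel.to_numpy(dtype=float)
    slope, intercept = np.polyfit(z, c, 1)
    if slope <= 0:
        return DepletionResult(gas, math.nan, float(slope), float(intercept),
                               tuple(z), True, False)
    crossing = -intercept / slope
    return DepletionResult(
        gas, float(crossing), float(slope), float(intercept),
        tuple(z), False, crossing < 0,
    )


def chlorophyll_from_absorbance(
    peak_absorbance: float,
    path_length_cm: float,
    extract_volume_ml: float,
    filtered_volume_l: float,
    coefficient_l_g_cm: float = 84.1,
) -> float:
    """Convert a chlorophyll-a extract absorbance peak to µg L-1 of lake water.

    Beer-Lambert: extract concentration = A / (a* x l) with the specific
    absorption coefficient ``a*`` read as 84.1 L g-1 cm-1 (the standard
    magnitude for Chl-a in 90% acetone), then scaled by the extract-to-sample
    volume ratio.
    """
    if peak_absorbance < 0:
        raise ValueError("absorbance must be >= 0")
    for name, v in (
        ("path_length_cm", path_length_cm),
        ("extract_volume_ml", extract_volume_ml),
        ("filtered_volume_l", filtered_volume_l),
        ("coefficient_l_g_cm", coefficient_l_g_cm),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    extract_g_l = peak_absorbance / (coefficient_l_g_cm * path_length_cm)
    extract_ug_l = extract_g_l * 1e6
    return extract_ug_l * (extract_volume_ml / 1000.0) / filtered_volume_l
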
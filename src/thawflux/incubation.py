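"""Headspace gas kinetics for closed-jar soil incubations.

Converts headspace mole fractions (ppm) measured by GC-FID/TCD into gas
masses via the ideal-gas law, forms interval fluxes between sampling days,
and computes the Q10 temperature-sensitivity coefficient

    Q10 = (R2 / R1) ** (10 / (T2 − T1))

for every ordered temperature pair on every sampling interval.  Fluxes are
reported per kilogram of soil on a wet-mass basis by default (a dry-mass
correction factor is exposed), matching how jar aliquots are weighed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol-1 K-1
MOLAR_MASS = {"CH4": 16.04, "CO2": 44.01}  # g mol-1
STANDARD_PRESSURE = 101325.0  # Pa

_REQUIRED_COLUMNS = ("jar", "replicate", "temp_C", "day", "gas", "ppm", "ppm_sd")


class UndefinedQ10Error(ValueError):
    """Raised when a Q10 ratio is requested for a non-positive flux."""


@dataclass(frozen=True)
class JarGeometry:
    """Closed incubation jar: a 60 mL vial with slurried soil under N2.

    ``headspace_temperature`` (K) overrides the default assumption that the
    headspace sits at the incubation temperature of each measurement.
    """

    jar_volume_ml: float = 60.0
    water_volume_ml: float = 5.0
    soil_mass_wet_g: float = 5.0
    soil_particle_density_g_ml: float = 2.0
    pressure_pa: float = STANDARD_PRESSURE
    headspace_temperature_k: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "jar_volume_ml",
            "water_volume_ml",
            "soil_mass_wet_g",
            "soil_particle_density_g_ml",
            "pressure_pa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.jar_volume_ml <= 0 or self.soil_particle_density_g_ml <= 0:
            raise ValueError("jar volume and particle density must be positive")
        if self.headspace_volume_ml <= 0:
            raise ValueError(
                "water + soil fill the jar: headspace volume is non-positive"
            )

    @property
    def headspace_volume_ml(self) -> float:
        return (
            self.jar_volume_ml
            - self.water_volume_ml
            - self.soil_mass_wet_g / self.soil_particle_density_g_ml
        )


def headspace_volume(geometry: JarGeometry) -> float:
    """Headspace volume (mL) left above water and soil in the jar."""
    return geometry.headspace_volume_ml


def moles_from_ppm(
    mole_fraction_ppm: float,
    headspace_volume_ml: float,
    pressure_pa: float = STANDARD_PRESSURE,
    temperature_k: float = 277.15,
) -> float:
    """Moles of a trace gas in the headspace from its mole fraction (ppm)."""
    if mole_fraction_ppm < 0:
        raise ValueError("mole fraction must be non-negative")
    if headspace_volume_ml <= 0 or pressure_pa <= 0 or temperature_k <= 0:
        raise ValueError("volume, pressure and temperature must be positive")
    volume_m3 = headspace_volume_ml * 1e-6
    return mole_fraction_ppm * 1e-6 * pressure_pa * volume_m3 / (R_GAS * temperature_k)


@dataclass
class FluxDataset:
    """Long-format headspace time series with jar geometry attached.

    ``data`` columns: jar, replicate, temp_C, day, gas, ppm, ppm_sd.
    Each (jar, day, gas) combination must be unique; days lie in [0, 60]
    for the standard design but any non-negative days are accepted.
    """

    data: pd.DataFrame
    geometry: JarGeometry = field(default_factory=JarGeometry)

    def __post_init__(self) -> None:
        missing = set(_REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"flux table missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("flux table is empty")
        if (self.data["ppm"] < 0).any():
            raise ValueError("mole fractions must be non-negative")
        if (self.data["day"] < 0).any():
            raise ValueError("days must be non-negative")
        dup = self.data.duplicated(subset=["jar", "day", "gas"])
        if dup.any():
            raise ValueError("duplicate (jar, day, gas) measurements present")

    @property
    def temperatures(self) -> list[float]:
        return sorted(self.data["temp_C"].unique())

    @property
    def days(self) -> list[float]:
        return sorted(self.data["day"].unique())

    def to_csv(self, path, **kwargs) -> None:
        self.data.to_csv(path, index=False, **kwargs)

    @classmethod
    def from_csv(cls, path, geometry: JarGeometry | None = None) -> "FluxDataset":
        frame = pd.read_csv(path, sep=None, engine="python")
        return cls(frame, geometry or JarGeometry())


@dataclass(frozen=True)
class Q10Result:
    """A single pairwise Q10 entry for one sampling interval."""

    day: float
    t1: float
    t2: float
    r1: float  # g day-1 kg-soil-1
    r2: float
    q10: float

    def __post_init__(self) -> None:
        if self.t2 <= self.t1:
            raise ValueError("Q10 pairs require t2 > t1")
        if self.q10 <= 0:
            raise ValueError("Q10 must be positive")


def mass_series(dataset: FluxDataset, gas: str = "CH4") -> pd.DataFrame:
    """Per-jar gas mass (g) over time from headspace mole fractions.

    Returns columns jar, replicate, temp_C, day, mass_g, mass_sd_g.
    Measurement uncertainty propagates linearly (the ppm→mass map is
    linear in the mole fraction at fixed geometry).
    """
    if gas not in MOLAR_MASS:
        raise ValueError(f"unknown gas {gas!r}; expected one of {list(MOLAR_MASS)}")
    geom = dataset.geometry
    sub = dataset.data[dataset.data["gas"] == gas].copy()
    if len(sub) == 0:
        raise ValueError(f"no {gas} measurements in dataset")
    temp_k = (
        np.full(len(sub), geom.headspace_temperature_k)
        if geom.headspace_temperature_k is not None
        else sub["temp_C"].to_numpy() + 273.15
    )
    # linear factor g/ppm for each record
    factor = (
        1e-6
        * geom.pressure_pa
        * geom.headspace_volume_ml
        * 1e-6
        / (R_GAS * temp_k)
        * MOLAR_MASS[gas]
    )
    sub["mass_g"] = sub["ppm"].to_numpy() * factor
    sub["mass_sd_g"] = sub["ppm_sd"].to_numpy() * factor
    return sub[["jar", "replicate", "temp_C", "day", "mass_g", "mass_sd_g"]].sort_values(
        ["jar", "day"], ignore_index=True
    )


def interval_flux(
    masses: pd.DataFrame,
    soil_mass_kg: float,
    dry_mass_fraction: float = 1.0,
) -> pd.DataFrame:
    """Forward-difference fluxes (g day-1 kg-soil-1) between sampling days.

    ``soil_mass_kg`` is the as-weighed (wet) aliquot mass; set
    ``dry_mass_fraction`` < 1 to normalise to dry-equivalent soil mass.
    Each interval is labelled by its end day.
    """
    if soil_mass_kg <= 0:
        raise ValueError("soil mass must be positive")
    if not 0 < dry_mass_fraction <= 1:
        raise ValueError("dry_mass_fraction must be in (0, 1]")
    norm = soil_mass_kg * dry_mass_fraction
    rows = []
    for jar, group in masses.groupby("jar", sort=False):
        g = group.sort_values("day")
        days = g["day"].to_numpy(dtype=float)
        if len(days) < 2:
            raise ValueError(f"jar {jar!r} has fewer than 2 time points")
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"jar {jar!r} has non-increasing days")
        dm = np.diff(g["mass_g"].to_numpy())
        dt = np.diff(days)
        for end_day, t1, flux in zip(days[1:], days[:-1], dm / dt / norm):
            rows.append(
                {
                    "jar": jar,
                    "replicate": g["replicate"].iloc[0],
                    "temp_C": g["temp_C"].iloc[0],
                    "day_start": t1,
                    "day": end_day,
                    "flux_g_day_kg": flux,
                }
            )
    return pd.DataFrame(rows)


def q10(r1: float, r2: float, t1: float, t2: float) -> float:
    """Temperature-sensitivity coefficient from two fluxes.

    Scale-invariant in the fluxes and symmetric under swapping the two
    (flux, temperature) pairs.
    """
    if t1 == t2:
        raise ValueError("t1 and t2 must differ")
    if r1 <= 0 or r2 <= 0:
        raise UndefinedQ10Error(
            f"Q10 undefined for non-positive fluxes (r1={r1}, r2={r2})"
        )
    return (r2 / r1) ** (10.0 / (t2 - t1))


@dataclass
class Q10Summary:
    """All pairwise Q10 entries plus per-day and grand means."""

    results: list[Q10Result]
    per_day_mean: dict[float, float]
    grand_mean: float | None
    excluded_pairs: list[dict]
    warnings: list[str]


def q10_matrix(
    dataset: FluxDataset,
    gas: str = "CH4",
    min_temp_c: float = -10.0,
    dry_mass_fraction: float = 1.0,
) -> Q10Summary:
    """Pairwise Q10 values for every sampling interval and temperature pair.

    Jars at or below ``min_temp_c`` are excluded up front (production is
    effectively zero in deeply frozen treatments, making the ratio
    ill-defined); pairs involving a non-positive replicate-mean flux are
    excluded and reported rather than silently dropped.  The grand mean is
    the arithmetic mean over all valid (interval, pair) entries.
    """
    masses = mass_series(dataset, gas)
    fluxes = interval_flux(
        masses, dataset.geometry.soil_mass_wet_g / 1000.0, dry_mass_fraction
    )
    fluxes = fluxes[fluxes["temp_C"] > min_temp_c]
    results: list[Q10Result] = []
    excluded: list[dict] = []
    notes: list[str] = []
    if len(fluxes) == 0:
        return Q10Summary([], {}, None, [], ["no jars above the temperature cutoff"])

    mean_flux = (
        fluxes.groupby(["day", "temp_C"])["flux_g_day_kg"].mean().reset_index()
    )
    for day, group in mean_flux.groupby("day"):
        temps = sorted(group["temp_C"])
        by_temp = dict(zip(group["temp_C"], group["flux_g_day_kg"]))
        if len(temps) < 2:
            notes.append(f"day {day}: only one temperature above cutoff")
            continue
        for t1, t2 in itertools.combinations(temps, 2):
            r1, r2 = by_temp[t1], by_temp[t2]
            if r1 <= 0 or r2 <= 0:
                excluded.append(
                    {"day": day, "t1": t1, "t2": t2, "r1": r1, "r2": r2,
                     "reason": "non-positive flux"}
                )
                continue
            results.append(Q10Result(day, t1, t2, r1, r2, q10(r1, r2, t1, t2)))

    per_day = {}
    for day in sorted({r.day for r in results}):
        vals = [r.q10 for r in results if r.day == day]
        per_day[day] = float(np.mean(vals))
    grand = float(np.mean([r.q10 for r in results])) if results else None
    if grand is None:
        notes.append("no valid temperature pair with positive fluxes")
        warnings.warn("q10_matrix produced no valid pairs", stacklevel=2)
    return Q10Summary(results, per_day, grand, excluded, notes)


def detect_plateau(
    masses: pd.DataFrame | pd.Series,
    slope_threshold_g_day: float,
) -> float | None:
    """Earliest day after which the mass slope stays below a threshold.

    Accepts either a two-column frame (day, mass_g) for a single jar or a
    Series indexed by day.  Returns the start day of the first interval
    whose forward-difference |slope| falls below ``slope_threshold_g_day``
    and remains below it for every later interval, or None.
    """
    if isinstance(masses, pd.Series):
        days = np.asarray(masses.index, dtype=float)
        vals = masses.to_numpy(dtype=float)
    else:
        g = masses.sort_values("day")
        days = g["day"].to_numpy(dtype=float)
        vals = g["mass_g"].to_numpy(dtype=float)
    if len(days) < 3:
        raise ValueError("need at least 3 time points to call a plateau")
    slopes = np.abs(np.diff(vals) / np.diff(days))
    below = slopes < slope_threshold_g_day
    for i in range(len(below)):
        if below[i:].all():
            return float(days[i])
    return None


def replicate_mean_mass(masses: pd.DataFrame) -> pd.DataFrame:
    """Mean mass per (temp_C, day) across replicate jars."""
    return (
        masses.groupby(["temp_C", "day"])["mass_g"].mean().reset_index()
    )


def summarize(summary: Q10Summary) -> dict:
    """JSON-serialisable view of a Q10 analysis."""
    return {
        "grand_mean_q10": summary.grand_mean,
        "per_day_mean_q10": {str(k): v for k, v in summary.per_day_mean.items()},
        "n_pairs": len(summary.results),
        "n_excluded": len(summary.excluded_pairs),
        "excluded_pairs": summary.excluded_pairs,
        "warnings": summary.warnings,
        "pairs": [
            {
                "day": r.day, "t1": r.t1, "t2": r.t2,
                "r1": r.r1, "r2": r.r2, "q10": r.q10,
            }
            for r in summary.results
        ],
    }
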
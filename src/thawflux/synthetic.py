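"""Synthetic incubation, isotope and VOC data with known ground truth.

The generators emulate the statistical structure of the study designs the
downstream analyses assume — triplicate closed-jar incubations at
−30/−4/4/10 °C sampled on days 0–60, δ13C-CH4 linear in temperature, and
GCxGC feature tables with planted condition-specific compounds, blank
contamination and replicate noise — so parameter recovery can be tested
without any instrument data.

Noise model: peak areas and gas fluxes are positive and heteroscedastic,
so they carry multiplicative lognormal noise with a stated coefficient of
variation; δ values carry additive Gaussian noise.  One integer seed
drives a named-stream generator per output, so adding a new generator
never perturbs existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from thawflux.incubation import (
    MOLAR_MASS,
    R_GAS,
    FluxDataset,
    JarGeometry,
)
from thawflux.isotopes import IsotopeRecord
from thawflux.voc import PresenceMatrix, VOCFeatureTable


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent named substream of the master seed."""
    ss = np.random.SeedSequence([seed, abs(hash(name)) % (2**32)])
    return np.random.default_rng(ss)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


@dataclass(frozen=True)
class FluxGenSpec:
    """Ground-truth description of a jar-incubation experiment.

    Defaults are the study conditions: triplicate jars at −30/−4/4/10 °C
    sampled on days 0/7/15/22/60, reference CH4 flux 1e-5 g day-1 kg-1 at
    4 °C with Q10 = 7.9, and 10 % multiplicative noise.  Below
    ``min_activity_temp`` production is multiplied by ``cutoff_factor``
    (default 0), reflecting undetectable CH4 in deeply frozen treatments.
    """

    q10_true: float = 7.9
    ref_flux: float = 1.0e-5  # g CH4 day-1 kg-soil-1 at ref_temp
    ref_temp: float = 4.0  # °C
    temps: tuple[float, ...] = (-30.0, -4.0, 4.0, 10.0)
    sample_days: tuple[float, ...] = (0.0, 7.0, 15.0, 22.0, 60.0)
    noise_cv: float = 0.1
    n_replicates: int = 3
    seed: int = 0
    min_activity_temp: float = -10.0
    cutoff_factor: float = 0.0
    q10_co2: float = 2.0
    ref_flux_co2: float = 5.0e-5
    geometry: JarGeometry = field(default_factory=JarGeometry)

    def __post_init__(self) -> None:
        if self.q10_true <= 0 or self.q10_co2 <= 0:
            raise ValueError("q10 values must be positive")
        if self.ref_flux < 0 or self.ref_flux_co2 < 0:
            raise ValueError("reference fluxes must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if len(self.temps) == 0:
            raise ValueError("temps must be non-empty")
        if len(self.sample_days) == 0:
            raise ValueError("sample_days must be non-empty")
        if np.any(np.diff(self.sample_days) <= 0):
            raise ValueError("sample_days must be strictly increasing")

    def expected_flux(self, temp_c: float, gas: str = "CH4") -> float:
        """Noise-free flux at a temperature (g day-1 kg-soil-1)."""
        if gas == "CH4":
            base, q = self.ref_flux, self.q10_true
        else:
            base, q = self.ref_flux_co2, self.q10_co2
        flux = base * q ** ((temp_c - self.ref_temp) / 10.0)
        if temp_c <= self.min_activity_temp:
            flux *= self.cutoff_factor
        return flux


def gen_flux_dataset(spec: FluxGenSpec) -> FluxDataset:
    """Simulate headspace CH4/CO2 ppm time series for the jar design.

    Cumulative gas mass grows linearly in time at the temperature-dependent
    expected flux, so the inter-temperature mass (and flux) ratio is
    q10_true**((T2−T1)/10); each measurement carries multiplicative
    lognormal noise of the stated CV.
    """
    rng = _stream(spec.seed, "flux")
    geom = spec.geometry
    soil_kg = geom.soil_mass_wet_g / 1000.0
    rows = []
    for gas in ("CH4", "CO2"):
        for temp in spec.temps:
            flux = spec.expected_flux(temp, gas)
            for rep in range(1, spec.n_replicates + 1):
                jar = f"{gas}_T{temp:g}_r{rep}"
                noise = _lognormal_factor(rng, spec.noise_cv, len(spec.sample_days))
                for day, eps in zip(spec.sample_days, noise):
                    mass_g = flux * soil_kg * day * eps
                    temp_k = (
                        geom.headspace_temperature_k
                        if geom.headspace_temperature_k is not None
                        else temp + 273.15
                    )
                    total_mol = (
                        geom.pressure_pa
                        * geom.headspace_volume_ml
                        * 1e-6
                        / (R_GAS * temp_k)
                    )
                    ppm = mass_g / MOLAR_MASS[gas] / total_mol * 1e6
                    rows.append(
                        {
                            "jar": jar,
                            "replicate": rep,
                            "temp_C": temp,
                            "day": day,
                            "gas": gas,
                            "ppm": ppm,
                            "ppm_sd": ppm * spec.noise_cv,
                        }
                    )
    return FluxDataset(pd.DataFrame(rows), geom)


def gen_isotope_records(
    slope: float = 1.8316,
    intercept: float = -57.449,
    temps: Sequence[float] = (-4.0, 4.0, 10.0),
    delta_substrate: float = -25.60,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[IsotopeRecord]:
    """δ13C records with CH4 linear in temperature and constant substrate.

    Defaults reproduce the observed end-of-incubation line: δ13C-CH4
    enriches by ~1.83 ‰ per °C around −57.4 ‰ while soil organic matter
    sits at −25.60 ‰.  Gaussian noise of ``noise_sd`` ‰ is added to the
    CH4 values only.
    """
    if len(temps) == 0:
        raise ValueError("temps must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _stream(seed, "isotopes")
    eps = rng.normal(0.0, noise_sd, len(temps)) if noise_sd > 0 else np.zeros(len(temps))
    records = [IsotopeRecord("substrate", float(t), delta_substrate) for t in temps]
    records += [
        IsotopeRecord("CH4", float(t), slope * t + intercept + e, noise_sd)
        for t, e in zip(temps, eps)
    ]
    return records


@dataclass(frozen=True)
class VOCGenSpec:
    """Ground-truth description of a planted VOC feature-table experiment.

    ``planted_signatures`` maps condition label → feature indices whose
    live samples carry real signal in that condition; everything else is
    blank-level contamination only.  The triplicate thin-film design is
    emulated with instrument and media blanks plus autoclaved controls.
    """

    n_features: int = 50
    conditions: tuple[str, ...] = ("200 cm (5 C)", "200 cm (12 C)")
    planted_signatures: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    blank_level: float = 100.0
    replicate_cv: float = 0.2
    n_replicates: int = 3
    seed: int = 0
    signal_level: float = 1.0e5

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition labels")
        if self.blank_level < 0 or self.signal_level <= 0:
            raise ValueError("levels must be non-negative (signal positive)")
        for cond, idxs in self.planted_signatures.items():
            if cond not in self.conditions:
                raise ValueError(f"planted condition {cond!r} not in conditions")
            for i in idxs:
                if not 0 <= i < self.n_features:
                    raise ValueError(f"planted feature index {i} out of range")


def gen_voc_table(spec: VOCGenSpec) -> tuple[VOCFeatureTable, PresenceMatrix]:
    """Feature table with planted condition-specific compounds + ground truth.

    Live samples in a planted (feature, condition) cell draw areas around
    ``signal_level`` on top of blank contamination; autoclaved controls and
    blanks carry contamination only.  Running the standard averaging →
    blank subtraction → control subtraction → presence pipeline on the
    output recovers the returned presence matrix exactly in the noiseless,
    blank-free limit.
    """
    rng = _stream(spec.seed, "voc")
    n, conds = spec.n_features, spec.conditions
    feature_ids = [f"F{i:04d}" for i in range(n)]

    planted = np.zeros((n, len(conds)), dtype=bool)
    for j, cond in enumerate(conds):
        for i in spec.planted_signatures.get(cond, ()):
            planted[i, j] = True

    columns: dict[str, np.ndarray] = {}
    samples: list[dict] = []

    def blank_draw(size):
        return spec.blank_level * _lognormal_factor(rng, spec.replicate_cv, size)

    for b in range(1, spec.n_replicates + 1):
        for role in ("instrument_blank", "media_blank"):
            sid = f"{role}_{b}"
            columns[sid] = blank_draw(n)
            samples.append({"sample": sid, "condition": "blank", "role": role})

    for j, cond in enumerate(conds):
        for rep in range(1, spec.n_replicates + 1):
            sid = f"live_{cond}_{rep}"
            signal = np.where(
                planted[:, j],
                spec.signal_level * _lognormal_factor(rng, spec.replicate_cv, n),
                0.0,
            )
            columns[sid] = signal + blank_draw(n)
            samples.append({"sample": sid, "condition": cond, "role": "live"})
            cid = f"autoclaved_{cond}_{rep}"
            columns[cid] = blank_draw(n)
            samples.append({"sample": cid, "condition": cond, "role": "autoclaved"})

    areas = pd.DataFrame(columns, index=pd.Index(feature_ids, name="feature_id"))
    features = pd.DataFrame(
        {
            "mean_rt1": 60.0 + 7.0 * np.arange(n),
            "mean_rt2": 0.5 + 0.013 * np.arange(n),
            "compound": [f"compound_{i:04d}" for i in range(n)],
            "kegg_id": [None] * n,
            "superclass": [None] * n,
        },
        index=areas.index,
    )
    sample_meta = pd.DataFrame(samples).set_index("sample")
    table = VOCFeatureTable(areas, features, sample_meta)
    truth = PresenceMatrix(
        pd.DataFrame(planted, index=areas.index, columns=list(conds))
    )
    return table, truth
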
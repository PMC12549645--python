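"""Stable carbon isotope bookkeeping for incubation headspace gases.

All δ13C values are per-mil deviations from the Vienna Pee Dee Belemnite
(VPDB) standard.  The apparent total fractionation factor between substrate
organic matter and product CH4 follows the convention

    alpha_tot = R_substrate / R_product = (δ_sub + 1000) / (δ_prod + 1000)

which is > 1 for 13C-depleted CH4.  A closed-system Rayleigh estimator is
provided to interpret residual-CH4 enrichment by methanotrophy; it uses the
linearised convention ε_ox = 1000·(1/α_ox − 1), negative when the residual
pool enriches during oxidation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: 13C/12C ratio of the VPDB standard.
VPDB_RATIO = 0.0112372

_DELTA_FLOOR = -1000.0  # ‰ — below this the isotope ratio would be negative


@dataclass(frozen=True)
class IsotopeRecord:
    """A δ13C measurement of one carbon pool at one incubation temperature."""

    pool: str  # "substrate" | "CH4" | "CO2"
    temperature: float  # °C
    delta13c: float  # ‰ vs VPDB
    sd: float = 0.0  # ‰

    def __post_init__(self) -> None:
        if self.delta13c <= _DELTA_FLOOR:
            raise ValueError(
                f"delta13C must exceed {_DELTA_FLOOR}‰ (got {self.delta13c})"
            )
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class RegressionFit:
    """Ordinary least-squares fit of δ13C against temperature."""

    slope: float  # ‰ per °C
    intercept: float  # ‰
    r_squared: float
    n: int
    degenerate: bool = False  # True when SS_tot == 0 and R² is set to 0

    def predict(self, temperature: float) -> float:
        return self.slope * temperature + self.intercept


def delta_to_ratio(delta13c: float, standard_ratio: float = VPDB_RATIO) -> float:
    """Convert a δ13C value (‰) to an absolute 13C/12C isotope ratio."""
    if delta13c <= _DELTA_FLOOR:
        raise ValueError(f"delta13C must exceed {_DELTA_FLOOR}‰ (got {delta13c})")
    if standard_ratio <= 0:
        raise ValueError("standard_ratio must be positive")
    return (delta13c / 1000.0 + 1.0) * standard_ratio


def alpha_total(delta_substrate: float, delta_product: float) -> float:
    """Apparent total fractionation factor substrate → product.

    The standard ratio cancels, so the result depends only on the two δ
    values.  Greater than 1 whenever the product is 13C-depleted relative
    to the substrate (the usual case for biogenic CH4).
    """
    if delta_substrate <= _DELTA_FLOOR:
        raise ValueError("substrate δ13C must exceed −1000‰")
    denom = delta_product + 1000.0
    if denom <= 0:
        raise ValueError("product δ13C must exceed −1000‰")
    return (delta_substrate + 1000.0) / denom


def delta_temperature_regression(records: Iterable[IsotopeRecord]) -> RegressionFit:
    """OLS of δ13C on incubation temperature for records of a single pool.

    With SS_tot = 0 (identical δ at every temperature) R² is defined as 0
    and the fit is flagged degenerate instead of propagating 0/0.
    """
    recs = list(records)
    pools = {r.pool for r in recs}
    if len(pools) > 1:
        raise ValueError(f"records span several pools: {sorted(pools)}")
    temps = np.array([r.temperature for r in recs], dtype=float)
    deltas = np.array([r.delta13c for r in recs], dtype=float)
    if np.unique(temps).size < 2:
        raise ValueError("need ≥2 distinct temperatures for a regression")

    res = stats.linregress(temps, deltas)
    resid = deltas - (res.slope * temps + res.intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((deltas - deltas.mean()) ** 2))
    if ss_tot == 0.0:
        return RegressionFit(0.0, float(deltas[0]), 0.0, len(recs), degenerate=True)
    r2 = 1.0 - ss_res / ss_tot
    return RegressionFit(float(res.slope), float(res.intercept), r2, len(recs))


def mixture_delta(
    pools: Sequence[tuple[float, float]], exact: bool = False
) -> float:
    """δ13C of a mixture of carbon pools given (moles, δ13C) pairs.

    The default is the linear-δ approximation (mole-weighted mean of δ),
    which is standard practice at natural abundance.  ``exact=True`` mixes
    true isotope ratios instead: 13C and 12C moles are summed separately
    and converted back to δ.
    """
    moles = np.array([m for m, _ in pools], dtype=float)
    deltas = np.array([d for _, d in pools], dtype=float)
    if np.any(moles < 0):
        raise ValueError("pool moles must be non-negative")
    total = moles.sum()
    if total <= 0:
        raise ValueError("total moles must be positive")
    if not exact:
        return float(np.dot(moles, deltas) / total)
    ratios = (deltas / 1000.0 + 1.0) * VPDB_RATIO
    heavy = moles * ratios / (1.0 + ratios)
    light = moles / (1.0 + ratios)
    mix_ratio = heavy.sum() / light.sum()
    return float((mix_ratio / VPDB_RATIO - 1.0) * 1000.0)


def delta_after_oxidation(
    delta_initial: float, fraction_remaining: float, epsilon_ox: float
) -> float:
    """Forward closed-system Rayleigh model (linearised).

    δ of the residual CH4 pool after the fraction ``fraction_remaining``
    of the initial pool is left, with enrichment factor ``epsilon_ox`` (‰,
    negative for residual-pool enrichment):  δ = δ0 + ε·ln f.
    """
    if not 0.0 < fraction_remaining <= 1.0:
        raise ValueError("fraction_remaining must be in (0, 1]")
    return delta_initial + epsilon_ox * math.log(fraction_remaining)


def rayleigh_fraction_remaining(
    delta_initial: float, delta_observed: float, epsilon_ox: float
) -> float:
    """Invert the closed-system Rayleigh model for the fraction remaining.

    f = exp((δ_obs − δ_init)/ε_ox).  With the residual-enrichment sign
    convention ε_ox < 0, an observed δ below the initial δ is inconsistent
    with oxidation and rejected.
    """
    if epsilon_ox == 0:
        raise ValueError("epsilon_ox must be nonzero")
    shift = delta_observed - delta_initial
    if epsilon_ox < 0 and shift < 0:
        raise ValueError(
            "delta_observed < delta_initial is inconsistent with "
            "residual-pool enrichment (epsilon_ox < 0): oxidation can only "
            "enrich the remaining CH4"
        )
    if epsilon_ox > 0 and shift > 0:
        raise ValueError(
            "delta_observed > delta_initial is inconsistent with "
            "epsilon_ox > 0 under the residual-pool convention"
        )
    f = math.exp(shift / epsilon_ox)
    if f > 1.0:  # numerical guard; shift/epsilon <= 0 by the checks above
        f = 1.0
    return f


def read_isotope_table(path) -> list[IsotopeRecord]:
    """Read a delimited table with columns pool, temp_C, delta13C[, sd]."""
    frame = pd.read_csv(path, sep=None, engine="python")
    required = {"pool", "temp_C", "delta13C"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"isotope table missing columns: {sorted(missing)}")
    sd = frame["sd"] if "sd" in frame.columns else pd.Series(0.0, index=frame.index)
    return [
        IsotopeRecord(str(row.pool), float(row.temp_C), float(row.delta13C), float(s))
        for row, s in zip(frame.itertuples(), sd)
    ]


def fractionation_report(
    delta_substrate: float,
    ch4_records: Iterable[IsotopeRecord],
    epsilon_grid: Sequence[float] | None = None,
) -> dict:
    """Collate α_tot per temperature, the δ–T fit and an optional Rayleigh scan.

    Returns a JSON-serialisable dict.  α values are reported both at full
    precision and rounded to 3 decimal places for comparison with printed
    literature values.
    """
    recs = sorted(ch4_records, key=lambda r: r.temperature)
    alphas = [
        {
            "temperature_C": r.temperature,
            "delta13C_CH4_permil": r.delta13c,
            "alpha_total": alpha_total(delta_substrate, r.delta13c),
            "alpha_total_3dp": round(alpha_total(delta_substrate, r.delta13c), 3),
        }
        for r in recs
    ]
    fit = delta_temperature_regression(recs)
    out = {
        "delta13C_substrate_permil": delta_substrate,
        "alphas": alphas,
        "regression": {
            "slope_permil_per_C": fit.slope,
            "intercept_permil": fit.intercept,
            "r_squared": fit.r_squared,
            "n": fit.n,
        },
    }
    if epsilon_grid is not None and len(recs) >= 2:
        coldest, warmest = recs[0], recs[-1]
        out["rayleigh_scan"] = [
            {
                "epsilon_ox_permil": eps,
                "fraction_remaining": rayleigh_fraction_remaining(
                    coldest.delta13c, warmest.delta13c, eps
                ),
            }
            for eps in epsilon_grid
        ]
    return out
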
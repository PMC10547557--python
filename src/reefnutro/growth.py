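"""Per-individual somatic growth and biomass production.

Growth follows the von Bertalanffy model dL/dt = K (L_inf - L) with the
species' standardized growth coefficient K_max (yr^-1) and asymptotic
length taken equal to the species maximum length L_max. The exact one-day
length increment is

    dL = (L_inf - L) * (1 - exp(-K_max / 365))

which converts to a daily mass increment through the length-weight
relationship, dW = a (L + dL)^b - a L^b. Natural and fishing mortality are
excluded by construction: the quantity is the maximum potential daily
production of each observed fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survey import length_to_mass, to_per_hectare
from .traits import TROPHIC_GROUPS

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class IndividualProduction:
    mass: float                  # g
    daily_length_growth: float   # cm / d
    daily_mass_production: float  # g / d


def daily_length_increment(length_cm, l_max_cm, k_max):
    """One-day von Bertalanffy length increment (cm), clamped at the asymptote.

    Fish recorded at or above L_max (possible with binned lengths) grow
    zero rather than receive a negative increment.
    """
    length = np.asarray(length_cm, dtype=float)
    linf = np.asarray(l_max_cm, dtype=float)
    k = np.asarray(k_max, dtype=float)
    gap = np.maximum(linf - length, 0.0)
    dl = gap * (-np.expm1(-k / DAYS_PER_YEAR))
    if np.isscalar(length_cm) and np.isscalar(l_max_cm):
        return float(dl)
    return dl


def daily_growth(length_cm, l_max_cm, k_max, lw_a, lw_b) -> IndividualProduction:
    """Mass, daily length growth and daily mass production of one fish."""
    if not (length_cm > 0 and l_max_cm > 0 and k_max > 0):
        raise ValueError("length, l_max and k_max must be > 0")
    dl = daily_length_increment(length_cm, l_max_cm, k_max)
    mass = length_to_mass(length_cm, lw_a, lw_b)
    dw = length_to_mass(length_cm + dl, lw_a, lw_b) - mass
    return IndividualProduction(mass=mass, daily_length_growth=dl, daily_mass_production=dw)


def add_production(cleaned: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Attach per-row growth columns to a cleaned observation table.

    Adds ``dl_cm_d`` (per individual) and ``prod_g_d`` (per individual);
    row totals are ``count * prod_g_d``.
    """
    tinfo = traits.set_index("species_id")[["l_max_cm", "k_max", "lw_a", "lw_b"]]
    df = cleaned.join(tinfo, on="species_id")
    dl = daily_length_increment(
        df["resolved_length_cm"].to_numpy(), df["l_max_cm"].to_numpy(), df["k_max"].to_numpy()
    )
    a = df["lw_a"].to_numpy()
    b = df["lw_b"].to_numpy()
    w0 = length_to_mass(df["resolved_length_cm"].to_numpy(), a, b)
    w1 = length_to_mass(df["resolved_length_cm"].to_numpy() + dl, a, b)
    df = df.assign(dl_cm_d=dl, prod_g_d=w1 - w0)
    if "mass_g" not in df.columns:
        df["mass_g"] = w0
    return df.drop(columns=["l_max_cm", "k_max", "lw_a", "lw_b"])


def transect_production(cleaned: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Per-transect, per-trophic-group biomass production (g d^-1 ha^-1).

    Missing (transect, group) combinations are filled with zero so every
    transect reports all trophic groups. Also carries standing biomass
    (kg ha^-1) since it shares the aggregation.
    """
    df = add_production(cleaned, traits)
    df["prod_total_g_d"] = df["count"] * df["prod_g_d"]
    df["mass_total_g"] = df["count"] * df["mass_g"]
    grouped = (
        df.groupby(["site_id", "transect_id", "trophic_group"], observed=True)
        .agg(
            prod_g=("prod_total_g_d", "sum"),
            mass_g=("mass_total_g", "sum"),
            area_m2=("area_m2", "first"),
        )
        .reset_index()
    )
    areas = cleaned[["site_id", "transect_id", "area_m2"]].drop_duplicates()
    full = (
        areas.merge(pd.DataFrame({"trophic_group": list(TROPHIC_GROUPS)}), how="cross")
        .merge(grouped.drop(columns="area_m2"), on=["site_id", "transect_id", "trophic_group"], how="left")
        .fillna({"prod_g": 0.0, "mass_g": 0.0})
    )
    full["production_g_d_ha"] = to_per_hectare(full["prod_g"].to_numpy(), full["area_m2"].to_numpy())
    full["standing_biomass_kg_ha"] = (
        to_per_hectare(full["mass_g"].to_numpy(), full["area_m2"].to_numpy()) / 1000.0
    )
    return full.drop(columns=["prod_g", "mass_g"]).sort_values(
        ["site_id", "transect_id", "trophic_group"]
    ).reset_index(drop=True)
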
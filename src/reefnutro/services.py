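"""Fishery services per site and trophic group.

Three services are computed from the cleaned survey: standing biomass
(kg ha^-1), biomass production/turnover (production g d^-1 ha^-1 divided by
standing biomass, expressed as a percentage on a daily or annual basis),
and nutrient production — the daily rate at which each of six dietary
nutrients is accrued in edible fish tissue per hectare. Nutrient
production multiplies each fish's daily somatic production by the edible
fraction of finfish (default 87%) and its species' tissue concentration
per 100 g.

Transect-level estimates are averaged (unweighted) to site level, and
site-level values are converted to relative contributions (%) of each
trophic group to each service. Sessile invertivores are excluded from
contributions: they are not fishery targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .growth import add_production
from .survey import to_per_hectare
from .traits import NUTRIENTS, TROPHIC_GROUPS, NutrientProfile

EDIBLE_FRACTION_DEFAULT = 0.87
DAYS_PER_YEAR = 365.0

#: trophic groups counted in fishery-service contributions
CONTRIBUTION_GROUPS: tuple[str, ...] = tuple(
    g for g in TROPHIC_GROUPS if g != "sessile_invertivore"
)

#: service column -> human-readable unit
NUTRIENT_RATE_COLUMNS: dict[str, str] = {
    f"{name}_{unit}_d_ha": f"{unit} d^-1 ha^-1" for name, (col, unit) in NUTRIENTS.items()
}
SERVICE_COLUMNS = ["standing_biomass_kg_ha", "production_g_d_ha", "turnover_pct",
                   *NUTRIENT_RATE_COLUMNS]


class UndefinedCompositionError(ValueError):
    """Raised when relative contributions are requested on an all-zero total."""


def nutrient_production(
    production_g_d_ha: float,
    profile: NutrientProfile,
    edible_fraction: float = EDIBLE_FRACTION_DEFAULT,
) -> dict[str, float]:
    """Per-nutrient production rates from a biomass production rate.

    ``rate_n = production * edible_fraction * concentration_n / 100 g``;
    units follow each concentration's unit per day per hectare (calcium,
    iron, zinc: mg; selenium, vitamin A: ug; omega-3: g).
    """
    if not (0 < edible_fraction <= 1):
        raise ValueError("edible_fraction must lie in (0, 1]")
    return {
        f"{name}_{unit}_d_ha": production_g_d_ha * edible_fraction * getattr(profile, name) / 100.0
        for name, (col, unit) in NUTRIENTS.items()
    }


def turnover(production_g_d_ha, standing_biomass_kg_ha, basis: str = "annual"):
    """Biomass turnover (%): production divided by standing biomass.

    Daily basis: ``100 * (production/1000) / biomass``; annual basis
    multiplies by 365. Zero biomass with zero production is defined as 0;
    zero biomass with production is an impossible state.
    """
    if basis not in ("daily", "annual"):
        raise ValueError(f"unknown turnover basis {basis!r}")
    prod = np.asarray(production_g_d_ha, dtype=float)
    biom = np.asarray(standing_biomass_kg_ha, dtype=float)
    if np.any((biom <= 0) & (prod > 0)):
        raise ValueError("positive production with zero standing biomass")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(biom > 0, 100.0 * (prod / 1000.0) / np.where(biom > 0, biom, 1.0), 0.0)
    if basis == "annual":
        t = t * DAYS_PER_YEAR
    if np.isscalar(production_g_d_ha) and np.isscalar(standing_biomass_kg_ha):
        return float(t)
    return t


def transect_services(
    cleaned: pd.DataFrame,
    traits: pd.DataFrame,
    edible_fraction: float = EDIBLE_FRACTION_DEFAULT,
    basis: str = "annual",
) -> pd.DataFrame:
    """All services per transect and trophic group (long-by-group, wide-by-service)."""
    if not (0 < edible_fraction <= 1):
        raise ValueError("edible_fraction must lie in (0, 1]")
    df = add_production(cleaned, traits)
    conc = traits.set_index("species_id")[[col for col, _ in NUTRIENTS.values()]]
    df = df.join(conc, on="species_id")
    df["prod_total_g_d"] = df["count"] * df["prod_g_d"]
    df["mass_total_g"] = df["count"] * df["mass_g"]
    for name, (col, unit) in NUTRIENTS.items():
        df[f"{name}_{unit}_d_ha"] = df["prod_total_g_d"] * edible_fraction * df[col] / 100.0
    rate_cols = list(NUTRIENT_RATE_COLUMNS)
    agg = {c: (c, "sum") for c in rate_cols}
    agg["prod_g"] = ("prod_total_g_d", "sum")
    agg["mass_g"] = ("mass_total_g", "sum")
    grouped = (
        df.groupby(["site_id", "transect_id", "trophic_group"], observed=True)
        .agg(**agg)
        .reset_index()
    )
    areas = cleaned[["site_id", "transect_id", "area_m2"]].drop_duplicates()
    full = (
        areas.merge(pd.DataFrame({"trophic_group": list(TROPHIC_GROUPS)}), how="cross")
        .merge(grouped, on=["site_id", "transect_id", "trophic_group"], how="left")
        .fillna({c: 0.0 for c in [*rate_cols, "prod_g", "mass_g"]})
    )
    scale = 10_000.0 / full["area_m2"].to_numpy()
    for c in rate_cols:
        full[c] = full[c].to_numpy() * scale
    full["production_g_d_ha"] = full["prod_g"].to_numpy() * scale
    full["standing_biomass_kg_ha"] = full["mass_g"].to_numpy() * scale / 1000.0
    full["turnover_pct"] = turnover(
        full["production_g_d_ha"].to_numpy(), full["standing_biomass_kg_ha"].to_numpy(), basis
    )
    keep = ["site_id", "transect_id", "trophic_group", *SERVICE_COLUMNS]
    return full[keep].sort_values(["site_id", "transect_id", "trophic_group"]).reset_index(drop=True)


def site_services(transect_table: pd.DataFrame, basis: str | None = None) -> pd.DataFrame:
    """Unweighted mean of each service across a site's transects, per group.

    ``basis`` is informational here (turnover was computed per transect);
    it is stamped into the result attrs when given.
    """
    out = (
        transect_table.groupby(["site_id", "trophic_group"], observed=True)[list(SERVICE_COLUMNS)]
        .mean()
        .reset_index()
    )
    if basis is not None:
        out.attrs["turnover_basis"] = basis
    return out


def relative_contributions(
    site_table: pd.DataFrame,
    service: str,
    groups: tuple[str, ...] = CONTRIBUTION_GROUPS,
) -> pd.DataFrame:
    """Percent contribution of each trophic group to one service, per site.

    Shares sum to 100 within 1e-9 at each site. Sites where the service
    totals zero across the included groups raise
    :class:`UndefinedCompositionError`.
    """
    if service not in SERVICE_COLUMNS:
        raise ValueError(f"unknown service {service!r}; one of {SERVICE_COLUMNS}")
    sub = site_table[site_table["trophic_group"].isin(groups)].copy()
    totals = sub.groupby("site_id", observed=True)[service].transform("sum")
    zero_sites = sorted(sub.loc[totals <= 0, "site_id"].unique())
    if zero_sites:
        raise UndefinedCompositionError(
            f"service {service!r} totals zero at sites {zero_sites}; composition undefined"
        )
    sub["contribution_pct"] = 100.0 * sub[service] / totals
    return sub[["site_id", "trophic_group", "contribution_pct"]].reset_index(drop=True)


def site_covariates(cleaned: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Wide site-level covariate table for the composition model.

    Fishable biomass is total standing biomass after the ingest exclusions
    (all trophic groups, sessile invertivores included), averaged over
    transects; joined with depth, benthic cover, country and management.
    """
    per_tr = (
        cleaned.assign(mass_total_g=cleaned["count"] * cleaned["mass_g"])
        .groupby(["site_id", "transect_id"], observed=True)
        .agg(mass_g=("mass_total_g", "sum"), area_m2=("area_m2", "first"))
        .reset_index()
    )
    per_tr["biomass_kg_ha"] = to_per_hectare(per_tr["mass_g"].to_numpy(), per_tr["area_m2"].to_numpy()) / 1000.0
    fishable = per_tr.groupby("site_id", observed=True)["biomass_kg_ha"].mean().rename("fishable_biomass_kg_ha")
    return sites.join(fishable, on="site_id")


def services_long(site_table: pd.DataFrame) -> pd.DataFrame:
    """Tidy one-row-per (site, trophic group, metric) export."""
    return site_table.melt(
        id_vars=["site_id", "trophic_group"],
        value_vars=list(SERVICE_COLUMNS),
        var_name="metric",
        value_name="value",
    )
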
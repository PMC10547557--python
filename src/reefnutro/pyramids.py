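"""Trophic-pyramid construction and classification.

Fishery-service values for the three groups targeted by fishers —
herbivores (scraping detritivores and browsers combined), mobile
invertivores and piscivores — are closed to a 3-part simplex per site and
service. A reef is *bottom-heavy* when herbivores dominate and *top-heavy*
when piscivores do; two operational rules are provided:

- ``herbivore_majority``: bottom-heavy iff the herbivore share exceeds 0.5
  (ties and anything at or below 0.5 are top-heavy);
- ``herbivore_vs_piscivore``: bottom-heavy iff the herbivore share exceeds
  the piscivore share, with exact ties flagged as ``"tie"``.

The rules agree whenever either the herbivore or the piscivore share holds
an outright majority; they can only diverge when no such majority exists
(e.g. an invertivore-dominated reef where herbivores still exceed
piscivores).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .services import SERVICE_COLUMNS, UndefinedCompositionError

HERBIVORE_PARTS = ("herbivore_scraper_detritivore", "herbivore_browser")
COMPOSITION_GROUPS = ("herbivore", "mobile_invertivore", "piscivore")
PYRAMID_RULES = ("herbivore_majority", "herbivore_vs_piscivore")

ZERO_ADJUST_DEFAULT = 1e-4


def merge_herbivores(service_table: pd.DataFrame, turnover_basis: str = "annual") -> pd.DataFrame:
    """Combine the two herbivore groups into a single ``herbivore`` group.

    Biomass, production and nutrient rates are additive and are summed;
    turnover is a ratio, so it is recomputed from the merged production
    and standing biomass (on ``turnover_basis``) when those columns are
    present. Grouping keys other than ``trophic_group`` are preserved.
    """
    from .services import turnover as _turnover

    present = set(service_table["trophic_group"])
    missing = [g for g in HERBIVORE_PARTS if g not in present]
    if missing:
        raise ValueError(f"herbivore groups absent from table: {missing}")
    df = service_table.copy()
    df["trophic_group"] = df["trophic_group"].replace(dict.fromkeys(HERBIVORE_PARTS, "herbivore"))
    keys = [c for c in df.columns if c in ("site_id", "transect_id", "service", "trophic_group")]
    value_cols = [c for c in df.columns if c in SERVICE_COLUMNS or c == "contribution_pct"]
    out = df.groupby(keys, observed=True, as_index=False)[value_cols].sum()
    if {"turnover_pct", "production_g_d_ha", "standing_biomass_kg_ha"} <= set(out.columns):
        merged = out["trophic_group"] == "herbivore"
        out.loc[merged, "turnover_pct"] = _turnover(
            out.loc[merged, "production_g_d_ha"].to_numpy(),
            out.loc[merged, "standing_biomass_kg_ha"].to_numpy(),
            basis=turnover_basis,
        )
    return out


def to_simplex(values, zero_adjust: float = ZERO_ADJUST_DEFAULT) -> np.ndarray:
    """Close a non-negative 3-vector to a strictly positive simplex.

    Values are divided by their total; exact zeros are then replaced by
    ``zero_adjust`` and the vector renormalized, since a Dirichlet
    response has no support on the simplex boundary. Each part moves by at
    most ``2 * zero_adjust`` during the adjustment.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size != 3:
        raise ValueError("expected a 3-vector")
    if np.any(v < 0):
        raise ValueError("composition parts must be >= 0")
    total = v.sum()
    if total <= 0:
        raise UndefinedCompositionError("all-zero composition has no simplex representation")
    p = v / total
    if zero_adjust > 0 and np.any(p == 0):
        p = np.where(p == 0, zero_adjust, p)
        p = p / p.sum()
    return p


def classify_pyramid(proportions, rule: str = "herbivore_vs_piscivore") -> str:
    """Classify a (herbivore, mobile invertivore, piscivore) simplex.

    Returns ``"bottom_heavy"``, ``"top_heavy"``, or — only under the
    ``herbivore_vs_piscivore`` rule at an exact tie — ``"tie"``.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size != 3:
        raise ValueError("expected a 3-part simplex")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be a simplex (non-negative, summing to 1)")
    herb, _, pisc = p
    if rule == "herbivore_majority":
        return "bottom_heavy" if herb > 0.5 else "top_heavy"
    if rule == "herbivore_vs_piscivore":
        if herb == pisc:
            return "tie"
        return "bottom_heavy" if herb > pisc else "top_heavy"
    raise ValueError(f"unknown pyramid rule {rule!r}; one of {PYRAMID_RULES}")


def build_composition_records(
    site_table: pd.DataFrame,
    covariates: pd.DataFrame,
    services: tuple[str, ...] = tuple(SERVICE_COLUMNS),
    zero_adjust: float = ZERO_ADJUST_DEFAULT,
) -> pd.DataFrame:
    """Model-ready table: one row per site and service.

    Columns: the 3 composition parts ``p_herbivore, p_mobile_invertivore,
    p_piscivore`` (strictly positive, summing to 1), the service label,
    and the site covariates (fishable biomass, five benthic covers, depth,
    country, management).
    """
    merged = merge_herbivores(site_table)
    merged = merged[merged["trophic_group"].isin(COMPOSITION_GROUPS)]
    rows = []
    for service in services:
        wide = merged.pivot(index="site_id", columns="trophic_group", values=service)
        for g in COMPOSITION_GROUPS:
            if g not in wide.columns:
                wide[g] = 0.0
        for site_id, row in wide.iterrows():
            p = to_simplex(row[list(COMPOSITION_GROUPS)].to_numpy(), zero_adjust)
            rows.append({
                "site_id": site_id, "service": service,
                "p_herbivore": p[0], "p_mobile_invertivore": p[1], "p_piscivore": p[2],
            })
    records = pd.DataFrame(rows)
    cov_cols = ["site_id", "country", "management", "depth_m", "coral_pct", "turf_pct",
                "macroalgae_pct", "rubble_pct", "bare_pct", "fishable_biomass_kg_ha"]
    return records.merge(covariates[cov_cols], on="site_id", how="left")


def classify_sites(
    records: pd.DataFrame, rule: str = "herbivore_vs_piscivore"
) -> pd.Series:
    """Vector of pyramid classes for a composition-record table."""
    parts = records[["p_herbivore", "p_mobile_invertivore", "p_piscivore"]].to_numpy()
    return pd.Series(
        [classify_pyramid(p, rule) for p in parts], index=records.index, name="pyramid"
    )
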
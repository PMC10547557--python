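"""Underwater visual census (UVC) ingest, validation and filtering.

Surveys arrive as long tables: one row per (site, transect, species,
length) with a count. Lengths are either point estimates to the nearest cm
or recorded in 5 cm bins (lower edge stored) up to a 40 cm cut-off, above
which lengths are point values. Ingest resolves binned lengths, applies
the fishery-relevance exclusion filters (fish < 5 cm, untargeted
damselfishes, highly mobile elasmobranchs), converts lengths to masses via
the allometric length-weight relationship, and attaches transect areas for
per-hectare scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MANAGEMENT_REGIMES = ("open_access", "restricted", "no_take")
BENTHIC_COLUMNS = ("coral_pct", "turf_pct", "macroalgae_pct", "rubble_pct", "bare_pct")

SURVEY_COLUMNS = ["site_id", "transect_id", "species_id", "length_cm", "length_is_binned", "count"]
SITE_COLUMNS = ["site_id", "country", "management", "depth_m", *BENTHIC_COLUMNS]
TRANSECT_COLUMNS = ["transect_id", "site_id", "width_m", "length_m"]

M2_PER_HA = 10_000.0


class SurveyIngestError(ValueError):
    """Raised on malformed or inconsistent survey inputs."""


@dataclass(frozen=True)
class ExclusionLog:
    """Counts of survey rows removed by each exclusion rule.

    A row matching several rules is counted once, under the first rule in
    the order: small fish, damselfish, elasmobranch.
    """

    small: int = 0
    damselfish: int = 0
    elasmobranch: int = 0

    @property
    def total(self) -> int:
        return self.small + self.damselfish + self.elasmobranch


def load_survey(path_or_df) -> pd.DataFrame:
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyIngestError(f"survey table missing columns: {missing}")
    df["length_cm"] = pd.to_numeric(df["length_cm"])
    df["count"] = pd.to_numeric(df["count"])
    df["length_is_binned"] = df["length_is_binned"].astype(bool)
    if (df["length_cm"] <= 0).any():
        raise SurveyIngestError("lengths must be strictly positive")
    if ((df["count"] < 1) | (df["count"] != df["count"].round())).any():
        raise SurveyIngestError("counts must be integers >= 1")
    df["count"] = df["count"].astype(int)
    return df.reset_index(drop=True)


def load_sites(path_or_df) -> pd.DataFrame:
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyIngestError(f"site table missing columns: {missing}")
    bad = sorted(set(df["management"]) - set(MANAGEMENT_REGIMES))
    if bad:
        raise SurveyIngestError(f"unknown management regimes {bad}; expected {MANAGEMENT_REGIMES}")
    df["depth_m"] = pd.to_numeric(df["depth_m"])
    if (df["depth_m"] <= 0).any():
        raise SurveyIngestError("depth_m must be > 0")
    covers = df[list(BENTHIC_COLUMNS)].apply(pd.to_numeric)
    if ((covers < 0) | (covers > 100)).any().any():
        raise SurveyIngestError("benthic covers must lie in [0, 100]")
    if (covers.sum(axis=1) > 100 + 1e-9).any():
        raise SurveyIngestError("benthic covers at a site must sum to <= 100")
    if df["site_id"].duplicated().any():
        raise SurveyIngestError("duplicate site ids")
    return df.reset_index(drop=True)


def load_transects(path_or_df) -> pd.DataFrame:
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in TRANSECT_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyIngestError(f"transect table missing columns: {missing}")
    df["area_m2"] = pd.to_numeric(df["width_m"]) * pd.to_numeric(df["length_m"])
    if (df["area_m2"] <= 0).any():
        raise SurveyIngestError("transect areas must be > 0")
    if df["transect_id"].duplicated().any():
        raise SurveyIngestError("duplicate transect ids")
    return df.reset_index(drop=True)


def resolve_length(
    length_cm,
    is_binned,
    bin_width: float = 5.0,
    bin_cut: float = 40.0,
    convention: str = "midpoint",
):
    """Resolve recorded lengths to point estimates (cm).

    Point lengths pass through. Binned lengths (lower bin edge recorded)
    map to the bin midpoint by default; above ``bin_cut`` fish are sized to
    the nearest cm even in binned surveys, so such records pass through.
    ``convention`` may be ``"midpoint"``, ``"lower"`` or ``"geometric"``
    (geometric mean of the bin edges).
    """
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    length = np.asarray(length_cm, dtype=float)
    binned = np.asarray(is_binned, dtype=bool) & (length <= bin_cut)
    if convention == "midpoint":
        resolved = np.where(binned, length + bin_width / 2.0, length)
    elif convention == "lower":
        resolved = length.copy()
    elif convention == "geometric":
        resolved = np.where(binned, np.sqrt(length * (length + bin_width)), length)
    else:
        raise ValueError(f"unknown bin convention {convention!r}")
    if np.isscalar(length_cm):
        return float(resolved)
    return resolved


def apply_exclusion_filters(
    survey: pd.DataFrame,
    traits: pd.DataFrame,
    min_length_cm: float = 5.0,
    bin_width: float = 5.0,
    bin_convention: str = "midpoint",
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Remove fishery-irrelevant observations.

    Drops rows whose resolved length is below ``min_length_cm``, rows of
    damselfish species not targeted by fisheries, and rows of highly
    mobile elasmobranchs. Returns the surviving rows (with a
    ``resolved_length_cm`` column added) and an :class:`ExclusionLog`.
    Every species in the survey must appear in the trait table.
    """
    unknown = sorted(set(survey["species_id"]) - set(traits["species_id"]))
    if unknown:
        raise SurveyIngestError(f"species missing from trait table: {unknown}")
    flags = traits.set_index("species_id")[["is_damselfish", "is_elasmobranch"]]
    merged = survey.join(flags, on="species_id")
    resolved = resolve_length(
        merged["length_cm"].to_numpy(), merged["length_is_binned"].to_numpy(),
        bin_width=bin_width, convention=bin_convention,
    )
    merged = merged.assign(resolved_length_cm=resolved)
    small = merged["resolved_length_cm"] < min_length_cm
    dams = ~small & merged["is_damselfish"]
    elas = ~small & ~dams & merged["is_elasmobranch"]
    log = ExclusionLog(
        small=int(small.sum()), damselfish=int(dams.sum()), elasmobranch=int(elas.sum())
    )
    kept = merged.loc[~(small | dams | elas)].drop(columns=["is_damselfish", "is_elasmobranch"])
    return kept.reset_index(drop=True), log


def length_to_mass(length_cm, lw_a, lw_b):
    """Allometric length (cm) to wet mass (g): ``w = a * L**b``."""
    mass = np.asarray(lw_a, dtype=float) * np.asarray(length_cm, dtype=float) ** np.asarray(lw_b, dtype=float)
    if not np.all(np.isfinite(mass)):
        raise ValueError("non-finite mass from length-weight coefficients")
    if np.isscalar(length_cm) and np.isscalar(lw_a):
        return float(mass)
    return mass


def to_per_hectare(value, area_m2):
    """Scale a per-transect quantity to per hectare."""
    area = np.asarray(area_m2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("transect area must be > 0 m^2")
    out = np.asarray(value, dtype=float) * (M2_PER_HA / area)
    if np.isscalar(value) and np.isscalar(area_m2):
        return float(out)
    return out


def ingest(
    survey,
    sites,
    traits: pd.DataFrame,
    transects,
    min_length_cm: float = 5.0,
    bin_width: float = 5.0,
    bin_convention: str = "midpoint",
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Full ingest: validate, filter, resolve lengths, attach mass and area.

    Returns a cleaned observation table with columns
    ``site_id, transect_id, species_id, resolved_length_cm, count,
    mass_g, area_m2, trophic_group`` plus the exclusion log. ``mass_g`` is
    the per-individual mass.
    """
    survey = load_survey(survey)
    sites = load_sites(sites)
    transects = load_transects(transects)
    unknown_sites = sorted(set(survey["site_id"]) - set(sites["site_id"]))
    if unknown_sites:
        raise SurveyIngestError(f"survey references unknown sites: {unknown_sites}")
    unknown_tr = sorted(set(survey["transect_id"]) - set(transects["transect_id"]))
    if unknown_tr:
        raise SurveyIngestError(f"survey references unknown transects: {unknown_tr}")
    kept, log = apply_exclusion_filters(
        survey, traits, min_length_cm=min_length_cm,
        bin_width=bin_width, bin_convention=bin_convention,
    )
    tinfo = traits.set_index("species_id")[["trophic_group", "lw_a", "lw_b"]]
    kept = kept.join(tinfo, on="species_id")
    kept["mass_g"] = length_to_mass(
        kept["resolved_length_cm"].to_numpy(), kept["lw_a"].to_numpy(), kept["lw_b"].to_numpy()
    )
    kept = kept.join(transects.set_index("transect_id")["area_m2"], on="transect_id")
    return kept.drop(columns=["lw_a", "lw_b"]), log
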
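"""Species-level biology and nutrition.

Each reef-fish species carries a maximum length ``l_max`` (cm), a
standardized von Bertalanffy growth coefficient ``k_max`` (yr^-1, the
growth coefficient the species exhibits when parameterized at its maximum
size), length-weight coefficients (``w = lw_a * L**lw_b`` in grams for L in
cm), a trophic group, and the concentration of six dietary nutrients in raw
muscle tissue per 100 g portion.

Nutrient density is the summed percent contribution of one fillet portion
to the recommended daily intakes (RNI) of the six nutrients, each nutrient
capped (default 100%) so that highly concentrated nutrients such as
selenium cannot dominate the score.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

TROPHIC_GROUPS: tuple[str, ...] = (
    "herbivore_scraper_detritivore",
    "herbivore_browser",
    "planktivore",
    "omnivore",
    "sessile_invertivore",
    "mobile_invertivore",
    "piscivore",
)

#: nutrient name -> (trait-table column, concentration unit per 100 g)
NUTRIENTS: dict[str, tuple[str, str]] = {
    "calcium": ("ca_mg", "mg"),
    "iron": ("fe_mg", "mg"),
    "zinc": ("zn_mg", "mg"),
    "selenium": ("se_ug", "ug"),
    "vitamin_a": ("vita_ug", "ug"),
    "omega3": ("om3_g", "g"),
}

TRAIT_COLUMNS = [
    "species_id", "trophic_group", "l_max_cm", "k_max", "lw_a", "lw_b",
    "ca_mg", "fe_mg", "zn_mg", "se_ug", "vita_ug", "om3_g",
    "is_damselfish", "is_elasmobranch",
]

#: common free-text labels mapped onto the closed trophic-group enum;
#: users may extend via the ``alias_map`` argument of :func:`load_traits`.
DEFAULT_TROPHIC_ALIASES: dict[str, str] = {
    "herbivore (scraper)": "herbivore_scraper_detritivore",
    "herbivore (detritivore)": "herbivore_scraper_detritivore",
    "scraping detritivore": "herbivore_scraper_detritivore",
    "herbivore (browser)": "herbivore_browser",
    "browsing macroalgal feeder": "herbivore_browser",
    "invertivore (mobile)": "mobile_invertivore",
    "invertivore (sessile)": "sessile_invertivore",
}


class TraitTableError(ValueError):
    """Raised when a species trait table violates its invariants."""


class RNIConfigError(KeyError):
    """Raised when the RNI table is missing a required nutrient."""


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance variable."""


@dataclass(frozen=True)
class NutrientProfile:
    """Concentrations in raw muscle tissue per 100 g portion."""

    calcium: float   # mg
    iron: float      # mg
    zinc: float      # mg
    selenium: float  # ug
    vitamin_a: float  # ug
    omega3: float    # g

    def __post_init__(self) -> None:
        for name in NUTRIENTS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise TraitTableError(f"nutrient {name!r} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in NUTRIENTS}


@dataclass(frozen=True)
class RNITable:
    """Recommended daily nutrient intakes for a reference population.

    Units per day match :class:`NutrientProfile` units per 100 g.
    """

    intakes: Mapping[str, float]
    reference_population: str = "adult women 18-65"
    source: str = "package default (WHO/FAO-based)"

    def __post_init__(self) -> None:
        for name, v in self.intakes.items():
            if not (np.isfinite(v) and v > 0):
                raise RNIConfigError(f"RNI for {name!r} must be a positive number, got {v}")

    def intake(self, nutrient: str) -> float:
        try:
            return float(self.intakes[nutrient])
        except KeyError:
            raise RNIConfigError(
                f"RNI table ({self.reference_population}) has no entry for nutrient {nutrient!r}"
            ) from None


def default_rni() -> RNITable:
    """RNI table shipped with the package (adult women 18-65)."""
    ref = importlib.resources.files("reefnutro").joinpath("data/rni_default.yaml")
    raw = yaml.safe_load(ref.read_text())
    return RNITable(
        intakes={k: float(v) for k, v in raw["intakes"].items()},
        reference_population=str(raw.get("reference_population", "adult women 18-65")),
    )


def load_rni(path) -> RNITable:
    """Load an RNI table from YAML (``intakes:`` mapping) or two-column CSV."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        intakes = {k: float(v) for k, v in raw["intakes"].items()}
        pop = str(raw.get("reference_population", "unspecified"))
    else:
        df = pd.read_csv(path)
        nutrient_col, value_col = df.columns[:2]
        intakes = dict(zip(df[nutrient_col].astype(str), df[value_col].astype(float)))
        pop = "unspecified"
    return RNITable(intakes=intakes, reference_population=pop, source=path)


@dataclass(frozen=True)
class SpeciesTraits:
    species_id: str
    trophic_group: str
    l_max: float
    k_max: float
    lw_a: float
    lw_b: float
    nutrients: NutrientProfile
    is_damselfish: bool = False
    is_elasmobranch: bool = False
    lw_b_bounds: tuple[float, float] = field(default=(2.0, 4.0), repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.trophic_group not in TROPHIC_GROUPS:
            raise TraitTableError(
                f"{self.species_id}: unknown trophic group {self.trophic_group!r}"
            )
        if not self.l_max > 0:
            raise TraitTableError(f"{self.species_id}: l_max must be > 0")
        if not self.k_max > 0:
            raise TraitTableError(f"{self.species_id}: k_max must be > 0")
        if not self.lw_a > 0:
            raise TraitTableError(f"{self.species_id}: lw_a must be > 0")
        lo, hi = self.lw_b_bounds
        if not (lo <= self.lw_b <= hi):
            raise TraitTableError(
                f"{self.species_id}: lw_b={self.lw_b} outside sanity bounds [{lo}, {hi}]"
            )


def load_traits(
    path_or_df,
    alias_map: Mapping[str, str] | None = None,
    lw_b_bounds: tuple[float, float] = (2.0, 4.0),
) -> pd.DataFrame:
    """Read and validate a species trait table.

    Accepts a CSV path or a pre-built DataFrame with the canonical columns.
    Unknown trophic-group labels are first passed through the default alias
    map plus ``alias_map``; anything still unrecognized is rejected.
    """
    df = path_or_df.copy() if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"trait table missing columns: {missing}")
    aliases = dict(DEFAULT_TROPHIC_ALIASES)
    if alias_map:
        aliases.update(alias_map)
    df["trophic_group"] = df["trophic_group"].map(lambda g: aliases.get(g, g))
    bad = sorted(set(df["trophic_group"]) - set(TROPHIC_GROUPS))
    if bad:
        raise TraitTableError(f"unknown trophic groups {bad}; extend the alias map or fix the table")
    if df["species_id"].duplicated().any():
        dups = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
        raise TraitTableError(f"duplicate species ids: {dups}")
    numeric = ["l_max_cm", "k_max", "lw_a", "lw_b"] + [col for col, _ in NUTRIENTS.values()]
    for col in numeric:
        df[col] = pd.to_numeric(df[col])
        if not np.isfinite(df[col]).all():
            raise TraitTableError(f"non-finite values in {col}")
    for col in ("l_max_cm", "k_max", "lw_a"):
        if (df[col] <= 0).any():
            raise TraitTableError(f"{col} must be strictly positive")
    lo, hi = lw_b_bounds
    if ((df["lw_b"] < lo) | (df["lw_b"] > hi)).any():
        raise TraitTableError(f"lw_b outside sanity bounds [{lo}, {hi}]")
    for col, _ in NUTRIENTS.values():
        if (df[col] < 0).any():
            raise TraitTableError(f"negative concentrations in {col}")
    df["is_damselfish"] = df["is_damselfish"].astype(bool)
    df["is_elasmobranch"] = df["is_elasmobranch"].astype(bool)
    return df.reset_index(drop=True)


def profile_from_row(row: Mapping) -> NutrientProfile:
    return NutrientProfile(**{name: float(row[col]) for name, (col, _) in NUTRIENTS.items()})


def nutrient_density(
    profile: NutrientProfile,
    rni: RNITable | None = None,
    portion: float = 100.0,
    cap: float = 100.0,
) -> float:
    """Percent contribution of one ``portion``-gram fillet to daily intakes.

    Each nutrient contributes ``100 * concentration * (portion/100) / rni``
    percent, capped at ``cap`` before summation. With the default 100% cap
    the result lies in [0, 600]. Pass ``cap=np.inf`` for the uncapped
    linear sum.
    """
    if rni is None:
        rni = default_rni()
    if not portion > 0:
        raise ValueError("portion must be > 0 g")
    if not cap > 0:
        raise ValueError("cap must be > 0 %")
    total = 0.0
    for name in NUTRIENTS:
        contrib = 100.0 * getattr(profile, name) * (portion / 100.0) / rni.intake(name)
        total += min(cap, contrib)
    return total


def nutrient_density_table(
    traits: pd.DataFrame,
    rni: RNITable | None = None,
    portion: float = 100.0,
    cap: float = 100.0,
) -> pd.Series:
    """Vectorized :func:`nutrient_density` over a trait table."""
    if rni is None:
        rni = default_rni()
    if not portion > 0:
        raise ValueError("portion must be > 0 g")
    total = np.zeros(len(traits))
    for name, (col, _) in NUTRIENTS.items():
        contrib = 100.0 * traits[col].to_numpy(float) * (portion / 100.0) / rni.intake(name)
        total += np.minimum(cap, contrib)
    return pd.Series(total, index=traits.index, name="nutrient_density_pct")


def growth_nutrient_association(
    traits: pd.DataFrame,
    rni: RNITable | None = None,
    method: str = "pearson",
    log_k: bool = True,
) -> pd.DataFrame:
    """Correlate nutrient density and each concentration with the growth coefficient.

    Returns one row per variable (``nutrient_density`` plus the six
    concentrations) with the correlation coefficient ``r`` against
    log10(k_max) (matching the log axis such associations are examined on)
    and the sample size. ``method`` may be ``"pearson"`` or ``"spearman"``.
    """
    from scipy import stats

    if len(traits) < 3:
        raise ValueError("need at least 3 species with complete traits")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    k = traits["k_max"].to_numpy(float)
    x = np.log10(k) if log_k else k
    if np.ptp(x) == 0:
        raise UndefinedCorrelationError("k_max has zero variance; correlation undefined")
    variables = {"nutrient_density": nutrient_density_table(traits, rni).to_numpy()}
    for name, (col, _) in NUTRIENTS.items():
        variables[name] = traits[col].to_numpy(float)
    rows = []
    for name, y in variables.items():
        if np.ptp(y) == 0:
            raise UndefinedCorrelationError(f"{name} has zero variance; correlation undefined")
        if method == "pearson":
            r, p = stats.pearsonr(x, y)
        else:
            r, p = stats.spearmanr(x, y)
        rows.append({"variable": name, "r": float(r), "p_value": float(p), "n": len(x)})
    return pd.DataFrame(rows)


def traits_from_rows(rows: Iterable[SpeciesTraits]) -> pd.DataFrame:
    """Build a canonical trait DataFrame from :class:`SpeciesTraits` objects."""
    records = []
    for t in rows:
        rec = {
            "species_id": t.species_id,
            "trophic_group": t.trophic_group,
            "l_max_cm": t.l_max,
            "k_max": t.k_max,
            "lw_a": t.lw_a,
            "lw_b": t.lw_b,
            "is_damselfish": t.is_damselfish,
            "is_elasmobranch": t.is_elasmobranch,
        }
        for name, (col, _) in NUTRIENTS.items():
            rec[col] = getattr(t.nutrients, name)
        records.append(rec)
    return load_traits(pd.DataFrame.from_records(records)[TRAIT_COLUMNS])
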
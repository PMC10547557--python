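"""Synthetic multi-country reef-fish studies with known ground truth.

The generator emulates the structure of a multi-country underwater visual
census program: a species pool whose growth coefficient declines
allometrically with maximum length and whose mineral concentrations are
size-linked; sites nested in countries with management regimes and mixed
benthic regimes (coral / turf / macroalgae / rubble / bare); 1-8 belt
transects per site drawn from the standard dimension set (5x50, 10x50,
2x30 m); and fish observations whose counts are filled to a target
fishable biomass drawn from a wide gradient (default 10-6000 kg ha^-1),
with the trophic composition of that biomass drawn from the same
hierarchical Dirichlet model the fitter assumes. Damselfish, elasmobranch
and sub-5 cm rows can be planted at a configurable rate to exercise the
exclusion filters.

Everything is driven by one integer seed; identical configurations yield
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import CATEGORIES, COVARIATES_DEFAULT, softmax_mean
from .survey import BENTHIC_COLUMNS, MANAGEMENT_REGIMES
from .traits import TRAIT_COLUMNS, TROPHIC_GROUPS, load_traits

#: modelled composition categories map onto these survey trophic groups
OTHER_GROUPS = ("planktivore", "omnivore", "sessile_invertivore")

#: (width m, length m, probability) — the standard belt-transect dimensions
TRANSECT_DIMS = ((5.0, 50.0, 0.79), (10.0, 50.0, 0.14), (2.0, 30.0, 0.07))

#: replicates per site depend on transect size: programs using small belts
#: survey 5-8 per site, those using large belts only 1-3 (median 3 overall)
TRANSECT_COUNTS_BY_AREA = {
    60.0: ((5, 6, 7, 8), (0.35, 0.3, 0.2, 0.15)),
    250.0: ((2, 3, 4, 5), (0.2, 0.45, 0.25, 0.1)),
    500.0: ((1, 2, 3), (0.35, 0.4, 0.25)),
}

_GROUP_SHARE = {
    "herbivore_scraper_detritivore": 0.12, "herbivore_browser": 0.08,
    "planktivore": 0.13, "omnivore": 0.12, "sessile_invertivore": 0.08,
    "mobile_invertivore": 0.25, "piscivore": 0.17,
}
_DAMSEL_FRACTION = 0.04
_ELASMO_FRACTION = 0.01
_LMAX_MEDIAN = {
    "herbivore_scraper_detritivore": 32.0, "herbivore_browser": 42.0,
    "planktivore": 14.0, "omnivore": 20.0, "sessile_invertivore": 16.0,
    "mobile_invertivore": 26.0, "piscivore": 55.0,
}

#: diet effect on the standardized growth coefficient at a given L_max
_DIET_K_FACTOR = {
    "herbivore_scraper_detritivore": 1.6, "herbivore_browser": 1.3,
    "planktivore": 1.5, "omnivore": 1.2, "sessile_invertivore": 1.0,
    "mobile_invertivore": 1.0, "piscivore": 0.65,
}

_BENTHIC_REGIMES = {
    "coral": (12.0, 3.0, 2.0, 2.0, 1.0),
    "turf": (3.0, 12.0, 2.0, 2.0, 1.0),
    "macroalgae": (2.0, 2.0, 12.0, 2.0, 1.0),
    "rubble": (2.0, 3.0, 2.0, 12.0, 1.0),
    "bare": (2.0, 2.0, 1.0, 3.0, 10.0),
}


@dataclass(frozen=True)
class DirichletTruth:
    """Ground-truth parameters of the composition model, standardized scale.

    Arrays are ordered (herbivore, piscivore) for the two non-reference
    categories and follow :data:`reefnutro.model.COVARIATES_DEFAULT` for
    the covariate axis.
    """

    intercept: tuple[float, float] = (1.2, -0.6)
    beta: tuple[tuple[float, float], ...] = (
        (-0.3, 0.5),   # fishable biomass
        (0.3, 0.0),    # hard coral
        (0.1, -0.1),   # turf
        (0.3, 0.0),    # macroalgae
        (-0.2, -0.1),  # rubble
        (0.0, -0.2),   # bare substrate
        (-0.2, 0.3),   # depth
    )
    sd_slope: float = 0.2
    sd_mgmt: float = 0.3
    phi: float = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_countries: int = 4
    sites_per_country: int = 80
    species_pool_size: int = 541
    biomass_range_kg_ha: tuple[float, float] = (10.0, 6000.0)
    truth: DirichletTruth = field(default_factory=DirichletTruth)
    #: expected planted filter-fodder rows per genuine observation row
    contamination_rate: float = 0.05
    #: share of fishable biomass held by planktivores/omnivores/sessile invertivores
    other_group_share: float = 0.15
    #: scraper fraction of the herbivore share (rest is browser)
    scraper_fraction: float = 0.7
    #: management mix per country (open_access, restricted, no_take)
    management_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    #: fraction of countries recording 5-cm length bins below 40 cm
    binned_country_fraction: float = 0.5
    #: couple mineral concentrations (and selenium, inversely) to body size
    nutrient_size_links: bool = True
    #: draw compositions from a logistic-normal instead (misspecification mode)
    misspecified: bool = False

    def __post_init__(self) -> None:
        if self.n_countries < 1 or self.sites_per_country < 1:
            raise ValueError("counts must be >= 1")
        if self.species_pool_size < len(TROPHIC_GROUPS):
            raise ValueError("species pool must cover every trophic group")
        if self.biomass_range_kg_ha[0] <= 0:
            raise ValueError("biomass gradient minimum must be > 0")


def recovery_truth() -> DirichletTruth:
    """Ground truth for parameter-recovery studies.

    Uses a high-precision regime (phi = 80) so that at n = 300 sites an
    absolute recovery band of +/-0.15 on standardized coefficients sits at
    three-plus posterior standard deviations for every fixed effect: the
    check is then sensitive to estimator bias rather than to the
    irreducible Monte Carlo noise of a single simulated data set.
    """
    return DirichletTruth(phi=80.0)


def herbivore_dominated_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A study regime with strong herbivore dominance of fishery services."""
    truth = DirichletTruth(
        intercept=(2.2, -1.2),
        beta=tuple((0.5 * h, 0.5 * p) for h, p in DirichletTruth().beta),
        sd_slope=0.15, sd_mgmt=0.2, phi=40.0,
    )
    return SimulationConfig(seed=seed, truth=truth, **overrides)


def _lognormal(rng, median, sigma, size):
    return median * np.exp(sigma * rng.standard_normal(size))


def simulate_species_pool(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a species trait table.

    Maximum length is log-normal within each trophic group; the growth
    coefficient follows ``K_max = c * L_max^gamma * exp(noise)`` with
    ``gamma < 0``, clipped to the observed global range [0.011, 16.43].
    With ``nutrient_size_links`` on, calcium, iron and zinc decline with
    maximum length, selenium increases, and vitamin A and omega-3 are
    size-independent (piscivores carry more vitamin A).
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.species_pool_size
    n_groups = len(TROPHIC_GROUPS)
    # every trophic group gets at least one species; damselfish and
    # elasmobranch species are added only once the pool allows it
    n_damsel = min(max(1, round(_DAMSEL_FRACTION * n)), max(0, (n - n_groups) // 2))
    n_elasmo = min(max(1, round(_ELASMO_FRACTION * n)), max(0, n - n_groups - n_damsel))
    n_regular = n - n_damsel - n_elasmo

    share_items = list(_GROUP_SHARE.items())
    shares = np.array([s for _, s in share_items])
    counts = np.ones(n_groups, dtype=int)
    extra = np.floor(shares / shares.sum() * (n_regular - n_groups)).astype(int)
    counts += extra
    counts[: n_regular - counts.sum()] += 1
    groups: list[str] = []
    for (g, _), c in zip(share_items, counts):
        groups += [g] * int(c)
    groups += ["planktivore"] * n_damsel + ["piscivore"] * n_elasmo
    is_damsel = np.zeros(n, bool)
    is_damsel[n_regular: n_regular + n_damsel] = True
    is_elasmo = np.zeros(n, bool)
    is_elasmo[n_regular + n_damsel:] = True

    lmax_median = np.array([_LMAX_MEDIAN[g] for g in groups])
    lmax_median[is_damsel] = 10.0
    lmax_median[is_elasmo] = 120.0
    l_max = np.clip(_lognormal(rng, lmax_median, 0.45, n), 6.0, 300.0)

    # growth coefficient declines with maximum length and carries a diet
    # effect: herbivorous/planktivorous fishes grow faster towards their
    # asymptote than piscivores of the same maximum size
    diet_k = np.array([_DIET_K_FACTOR[g] for g in groups])
    k_max = np.clip(
        0.6 * diet_k * (l_max / 10.0) ** -1.0 * np.exp(0.30 * rng.standard_normal(n)),
        0.011, 16.43,
    )
    lw_a = _lognormal(rng, 0.013, 0.25, n)
    lw_b = np.clip(rng.normal(3.0, 0.08, n), 2.7, 3.3)

    size = l_max / 20.0
    if config.nutrient_size_links:
        ca = 28.0 * size ** -0.45 * np.exp(0.30 * rng.standard_normal(n))
        fe = 0.8 * size ** -0.35 * np.exp(0.35 * rng.standard_normal(n))
        zn = 1.1 * size ** -0.40 * np.exp(0.30 * rng.standard_normal(n))
        se = 36.0 * size ** 0.25 * np.exp(0.30 * rng.standard_normal(n))
    else:
        ca = _lognormal(rng, 28.0, 0.30, n)
        fe = _lognormal(rng, 0.8, 0.35, n)
        zn = _lognormal(rng, 1.1, 0.30, n)
        se = _lognormal(rng, 36.0, 0.30, n)
    vita = _lognormal(rng, 25.0, 0.5, n)
    if config.nutrient_size_links:
        # piscivores carry markedly more vitamin A; part of the trait-linked
        # nutrient structure, so it switches off with the size links
        vita[np.array(groups) == "piscivore"] *= 3.0
    om3 = _lognormal(rng, 0.25, 0.4, n)

    df = pd.DataFrame({
        "species_id": [f"sp_{i:04d}" for i in range(n)],
        "trophic_group": groups,
        "l_max_cm": np.round(l_max, 1),
        "k_max": np.round(k_max, 4),
        "lw_a": np.round(lw_a, 5),
        "lw_b": np.round(lw_b, 3),
        "ca_mg": np.round(ca, 3),
        "fe_mg": np.round(fe, 4),
        "zn_mg": np.round(zn, 4),
        "se_ug": np.round(se, 3),
        "vita_ug": np.round(vita, 3),
        "om3_g": np.round(om3, 4),
        "is_damselfish": is_damsel,
        "is_elasmobranch": is_elasmo,
    })[TRAIT_COLUMNS]
    return load_traits(df)


def _simulate_sites(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_countries * config.sites_per_country
    countries = [f"country_{chr(65 + c)}" for c in range(config.n_countries)
                 for _ in range(config.sites_per_country)]
    management = rng.choice(MANAGEMENT_REGIMES, size=n, p=config.management_mix)
    depth = np.round(rng.uniform(2.0, 20.0, n), 1)
    regimes = rng.choice(list(_BENTHIC_REGIMES), size=n)
    covers = np.empty((n, 5))
    for i, reg in enumerate(regimes):
        total = rng.uniform(70.0, 95.0)
        covers[i] = rng.dirichlet(_BENTHIC_REGIMES[reg]) * total
    sites = pd.DataFrame({
        "site_id": [f"site_{i:04d}" for i in range(n)],
        "country": countries,
        "management": management,
        "depth_m": depth,
    })
    for j, col in enumerate(BENTHIC_COLUMNS):
        sites[col] = np.round(covers[:, j], 2)
    return sites


def _true_compositions(
    config: SimulationConfig,
    sites: pd.DataFrame,
    biomass: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Per-site 3-part target compositions from the ground-truth model.

    Country-slope and management-intercept deviations are drawn centred
    (sum-to-zero within each category) so fixed effects stay identifiable
    at small country counts.
    """
    truth = config.truth
    X = np.column_stack([
        biomass,
        *[sites[c].to_numpy(float) for c in BENTHIC_COLUMNS],
        sites["depth_m"].to_numpy(float),
    ])
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    countries = sorted(sites["country"].unique())
    cidx = sites["country"].map({c: i for i, c in enumerate(countries)}).to_numpy()
    cm = sites["country"] + ":" + sites["management"]
    cm_labels = sorted(cm.unique())
    midx = cm.map({c: i for i, c in enumerate(cm_labels)}).to_numpy()
    slope_dev = rng.normal(0.0, truth.sd_slope, (len(countries), 2))
    slope_dev -= slope_dev.mean(axis=0)
    mgmt_int = rng.normal(0.0, truth.sd_mgmt, (len(cm_labels), 2))
    mgmt_int -= mgmt_int.mean(axis=0)
    beta = np.asarray(truth.beta)            # (7, 2)
    eta = (
        np.asarray(truth.intercept)[None, :]
        + Xz @ beta
        + slope_dev[cidx] * Xz[:, [0]]
        + mgmt_int[midx]
    )
    mu = softmax_mean(eta, reference_index=1)
    if config.misspecified:
        # logistic-normal draws around the same mean structure
        logit = np.log(mu[:, [0, 2]] / mu[:, [1]])
        noisy = logit + rng.normal(0.0, 1.0 / np.sqrt(truth.phi), logit.shape)
        e = np.exp(np.column_stack([noisy[:, 0], np.zeros(len(mu)), noisy[:, 1]]))
        p = e / e.sum(axis=1, keepdims=True)
    else:
        g = rng.standard_gamma(mu * truth.phi)
        p = g / g.sum(axis=1, keepdims=True)
    p = np.clip(p, 1e-9, None)
    p /= p.sum(axis=1, keepdims=True)
    info = {
        "countries": countries, "cm_labels": cm_labels,
        "slope_dev": slope_dev.tolist(), "mgmt_int": mgmt_int.tolist(),
        "mu": mu, "standardization": {c: (float(m), float(s)) for c, m, s in
                                      zip(COVARIATES_DEFAULT, X.mean(axis=0), X.std(axis=0, ddof=1))},
    }
    return p, info


def _fill_group(rng, target_g, sp_idx, weights, lmax, lw_a, lw_b, binned):
    """Partition ``target_g`` grams into fish at natural adult sizes.

    Bulk stage: species whose largest individual stays below 30% of the
    remaining biomass contribute fish drawn from their natural
    (asymptote-skewed) size distribution. Closing stage: the remainder is
    filled by fish whose length is solved from the length-weight curve so
    the realized total lands on the target, within each species' natural
    size window; a residual smaller than the smallest attainable fish is
    left unfilled. Returns (species index, emitted length, is_binned,
    snapped length) rows; realized biomass tracks the target closely at
    any transect size.
    """
    l_lo = np.maximum(5.5, 0.4 * lmax)
    l_hi = 0.98 * lmax
    valid = l_hi >= l_lo
    if not valid.any():
        return []
    w_lo = lw_a * l_lo ** lw_b
    w_hi = lw_a * l_hi ** lw_b
    rows = []
    remaining = float(target_g)

    # bulk fill with naturally sized fish
    while True:
        mask = valid & (w_hi <= 0.3 * remaining)
        if not mask.any():
            break
        w_use = weights * mask
        w_use = w_use / w_use.sum()
        mean_w = float((w_use * (w_lo + w_hi) / 2).sum())
        n = int(np.clip(np.ceil(0.7 * remaining / max(mean_w, 1e-9)), 8, 60000))
        pick = rng.choice(len(sp_idx), size=n, p=w_use)
        u = rng.beta(6.0, 1.5, n)
        L = l_lo[pick] + u * (l_hi[pick] - l_lo[pick])
        snapped, emitted, isb = _snap(L, binned)
        w = lw_a[pick] * snapped ** lw_b[pick]
        cum = np.cumsum(w)
        take = int(np.searchsorted(cum, 0.7 * remaining)) + 1
        take = min(take, n)
        for i in range(take):
            rows.append((sp_idx[pick[i]], emitted[i], isb[i], snapped[i], float(w[i])))
        remaining -= float(cum[take - 1])

    # closing fill by stochastic rounding: fish keep natural adult sizes and
    # the last (fractional) fish is resolved by accepting a candidate with
    # probability remaining/weight, which leaves the realized biomass
    # unbiased for the target; sparse groups are then genuinely absent from
    # some transects instead of being represented by an unnaturally small fish
    w_typ = lw_a * (l_lo + 0.8 * (l_hi - l_lo)) ** lw_b
    for _ in range(1000):
        if remaining <= 0:
            break
        candidates = valid & (w_typ <= 2.0 * remaining)
        if candidates.any():
            w_use = weights * candidates
            j = int(rng.choice(len(sp_idx), p=w_use / w_use.sum()))
        else:
            j = int(np.argmin(np.where(valid, w_typ, np.inf)))
            if w_lo[j] > 4.0 * remaining:
                break  # even the smallest fish would grossly overshoot
        u = rng.beta(6.0, 1.5)
        L = l_lo[j] + u * (l_hi[j] - l_lo[j])
        snapped, emitted, isb = _snap(np.array([L]), binned)
        w = float(lw_a[j] * snapped[0] ** lw_b[j])
        fractional = w > remaining
        if not fractional or rng.uniform() < remaining / w:
            rows.append((sp_idx[j], emitted[0], isb[0], snapped[0], w))
            remaining -= w
        if fractional:
            break
    return rows


def _snap(L: np.ndarray, binned: bool):
    """Snap drawn lengths to the survey recording scheme.

    Returns (snapped analysis length, emitted table length, binned flag).
    Binned surveys record the 5-cm lower bin edge below the 40 cm cut and
    sit fish exactly at bin midpoints so the midpoint convention
    reconstructs them; above the cut (and in point surveys) lengths are
    recorded to the nearest cm.
    """
    point = np.round(L).clip(5.0, None)
    if not binned:
        return point, point, np.zeros(len(L), bool)
    lower = np.floor(L / 5.0) * 5.0
    use_bin = L <= 40.0
    snapped = np.where(use_bin, lower + 2.5, point)
    emitted = np.where(use_bin, lower, point)
    return snapped, emitted, use_bin


def simulate_survey(
    config: SimulationConfig,
    traits: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> dict:
    """Generate sites, transects, observations and ground truth.

    Returns a dict with ``sites``, ``transects``, ``survey`` DataFrames
    and a ``truth`` dict holding the generator parameters, per-site target
    fishable biomass and target compositions.
    """
    rng = rng or np.random.default_rng(config.seed)
    sites = _simulate_sites(config, rng)
    n_sites = len(sites)
    lo, hi = config.biomass_range_kg_ha
    target_b = np.exp(rng.uniform(np.log(lo), np.log(hi), n_sites))
    comp3, comp_info = _true_compositions(config, sites, target_b, rng)

    countries = sorted(sites["country"].unique())
    n_binned = round(config.binned_country_fraction * len(countries))
    binned_countries = set(countries[len(countries) - n_binned:])

    # per-group share of fishable biomass at each site
    q = config.other_group_share
    other_split = np.array([0.5, 0.35, 0.15])   # planktivore, omnivore, sessile
    fished = comp3 * (1.0 - q)
    scraper = rng.beta(20 * config.scraper_fraction, 20 * (1 - config.scraper_fraction), n_sites)
    shares = {
        "herbivore_scraper_detritivore": fished[:, 0] * scraper,
        "herbivore_browser": fished[:, 0] * (1 - scraper),
        "mobile_invertivore": fished[:, 1],
        "piscivore": fished[:, 2],
        "planktivore": np.full(n_sites, q * other_split[0]),
        "omnivore": np.full(n_sites, q * other_split[1]),
        "sessile_invertivore": np.full(n_sites, q * other_split[2]),
    }

    clean = traits[~(traits["is_damselfish"] | traits["is_elasmobranch"])]
    by_group = {g: clean[clean["trophic_group"] == g] for g in TROPHIC_GROUPS}
    damsels = traits[traits["is_damselfish"]]
    elasmos = traits[traits["is_elasmobranch"]]
    sp_ids = traits["species_id"].to_numpy()

    dims = np.array([(w, l) for w, l, _ in TRANSECT_DIMS])
    dim_p = np.array([p for _, _, p in TRANSECT_DIMS])

    transect_rows, obs_rows = [], []
    tcount = 0
    for si, site in sites.iterrows():
        site_binned = site["country"] in binned_countries
        # site-level species pools per group, up to 8 species each; pools
        # are biased towards body sizes matching the site's biomass level —
        # heavily fished low-biomass reefs are dominated by small-bodied
        # species, which also keeps per-fish granularity small relative to
        # the site's biomass target
        l_ref = float(np.clip(10.0 * (target_b[si] / 10.0) ** 0.28, 12.0, 55.0))
        pools = {}
        for g, gt in by_group.items():
            if len(gt) == 0:
                continue
            k = min(8, len(gt))
            size_w = np.exp(-0.5 * ((np.log(gt["l_max_cm"].to_numpy()) - np.log(l_ref)) / 0.35) ** 2)
            size_w = size_w + 1e-12
            idx = rng.choice(gt.index.to_numpy(), size=k, replace=False,
                             p=size_w / size_w.sum())
            # relative abundances also follow the size spectrum, so a large
            # species cannot dominate a low-biomass site's assemblage
            kern = np.exp(-0.5 * ((np.log(gt.loc[idx, "l_max_cm"].to_numpy())
                                   - np.log(l_ref)) / 0.35) ** 2) + 1e-12
            wts = rng.dirichlet(np.full(k, 1.5)) * kern
            wts = wts / wts.sum()
            pools[g] = (idx, wts)
        # one belt dimension per site; replication trades off against area
        w, l = dims[rng.choice(len(dims), p=dim_p)]
        area = w * l
        counts, count_p = TRANSECT_COUNTS_BY_AREA[area]
        n_tr = int(rng.choice(counts, p=count_p))
        # each group's unfilled residual (one-fish granularity) carries over
        # to the site's next transect, so realized site biomass tracks the
        # target to within roughly one fish regardless of transect size
        carry = {g: 0.0 for g in shares}
        site_rows: list[tuple] = []   # (tid, trait idx, length, binned, snapped, weight)
        tids = []
        for _ in range(n_tr):
            tid = f"tr_{tcount:05d}"
            tcount += 1
            tids.append(tid)
            transect_rows.append((tid, site["site_id"], w, l))
            for g, share in shares.items():
                tgt = float(share[si]) * float(target_b[si]) * 1000.0 * area / 10_000.0
                tgt += carry[g]
                if tgt <= 0 or g not in pools:
                    carry[g] = tgt  # carry the full balance, debt included
                    continue
                idx, wts = pools[g]
                sub = traits.loc[idx]
                filled = _fill_group(
                    rng, tgt, idx, wts,
                    sub["l_max_cm"].to_numpy(), sub["lw_a"].to_numpy(), sub["lw_b"].to_numpy(),
                    site_binned,
                )
                carry[g] = tgt - sum(r[4] for r in filled)
                site_rows.extend((tid, *r) for r in filled)

        # site-level reconciliation: residuals from minority groups whose
        # smallest species dwarfs their share are cancelled here (trimming
        # the best-matching fish or topping up with small-bodied ones), so
        # site biomass lands within about one small fish of the target
        def _pool_min_w(item):
            idx, _ = item[1]
            sub = traits.loc[idx]
            return (sub["lw_a"] * (0.4 * sub["l_max_cm"]).clip(lower=5.5) ** sub["lw_b"]).min()

        residual = sum(carry.values())    # positive: underfilled
        site_target_g = float(target_b[si]) * 1000.0 * n_tr * area / 10_000.0
        tol = max(0.02 * site_target_g, 2.0)
        for _ in range(3):
            if abs(residual) <= tol or not site_rows or not pools:
                break
            if residual < 0:
                # remove the fish that best match the overshoot
                for _ in range(10):
                    over = -residual
                    weights_arr = np.array([r[5] for r in site_rows])
                    fit_mask = weights_arr <= 1.3 * over
                    if not fit_mask.any() or over <= weights_arr.min() / 2:
                        break
                    cand = np.flatnonzero(fit_mask)
                    drop = int(cand[np.argmin(np.abs(weights_arr[cand] - over))])
                    residual += site_rows[drop][5]
                    site_rows.pop(drop)
            else:
                # top up with naturally small-bodied fish on the last transect
                g_small = min(pools.items(), key=_pool_min_w)[0]
                idx, wts = pools[g_small]
                sub = traits.loc[idx]
                filled = _fill_group(
                    rng, residual, idx, wts,
                    sub["l_max_cm"].to_numpy(), sub["lw_a"].to_numpy(), sub["lw_b"].to_numpy(),
                    site_binned,
                )
                if not filled:
                    break
                site_rows.extend((tids[-1], *r) for r in filled)
                residual -= sum(r[4] for r in filled)

        n_genuine_by_tid = {t: 0 for t in tids}
        for tid, t_idx, length, isb, _snap, _w in site_rows:
            n_genuine_by_tid[tid] += 1
            obs_rows.append((site["site_id"], tid, traits.at[t_idx, "species_id"],
                             float(length), bool(isb)))
        # planted filter fodder, per transect
        for tid in tids:
            n_cont = rng.poisson(config.contamination_rate * n_genuine_by_tid[tid])
            for _ in range(n_cont):
                kind = rng.integers(3)
                if kind == 0 and len(damsels):
                    sp = damsels.iloc[rng.integers(len(damsels))]
                    length = float(np.round(rng.uniform(6.0, 12.0)))
                elif kind == 1 and len(elasmos):
                    sp = elasmos.iloc[rng.integers(len(elasmos))]
                    length = float(np.round(rng.uniform(60.0, 150.0)))
                else:
                    gt = by_group["mobile_invertivore"]
                    sp = gt.iloc[rng.integers(len(gt))]
                    length = float(np.round(rng.uniform(3.0, 4.9), 1))
                obs_rows.append((site["site_id"], tid, sp["species_id"], length, False))

    survey = (
        pd.DataFrame(obs_rows, columns=["site_id", "transect_id", "species_id",
                                        "length_cm", "length_is_binned"])
        .groupby(["site_id", "transect_id", "species_id", "length_cm", "length_is_binned"],
                 observed=True)
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["site_id", "transect_id", "species_id", "length_cm"])
        .reset_index(drop=True)
    )
    transects = pd.DataFrame(transect_rows, columns=["transect_id", "site_id", "width_m", "length_m"])
    truth = {
        "config": _config_dict(config),
        "target_fishable_biomass_kg_ha": {s: float(b) for s, b in zip(sites["site_id"], target_b)},
        "target_composition": {
            s: dict(zip(CATEGORIES, map(float, row))) for s, row in zip(sites["site_id"], comp3)
        },
        "slope_dev": comp_info["slope_dev"],
        "mgmt_int": comp_info["mgmt_int"],
        "binned_countries": sorted(binned_countries),
    }
    return {"sites": sites, "transects": transects, "survey": survey, "truth": truth}


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["truth"]["beta"] = [list(b) for b in config.truth.beta]
    return d


def simulate_study(config: SimulationConfig) -> dict:
    """Species pool + full survey in one call, one seed."""
    rng = np.random.default_rng(config.seed)
    traits = simulate_species_pool(config, rng)
    out = simulate_survey(config, traits, rng)
    out["traits"] = traits
    return out


def simulate_composition_records(
    truth: DirichletTruth,
    n_sites: int = 300,
    n_countries: int = 3,
    seed: int = 0,
    biomass_range: tuple[float, float] = (10.0, 6000.0),
) -> tuple[pd.DataFrame, dict]:
    """Draw model-ready composition records directly from the Dirichlet model.

    Bypasses the survey layer: covariates are simulated, standardized, and
    compositions drawn from Dirichlet(mu * phi). Used for parameter
    recovery and calibration studies where the estimand is the model's own
    coefficient vector. Group deviations are centred so fixed effects are
    exactly identifiable. Returns the records plus a truth dict keyed by
    the fitter's parameter names.
    """
    rng = np.random.default_rng(seed)
    sites = pd.DataFrame({
        "site_id": [f"site_{i:04d}" for i in range(n_sites)],
        "country": [f"country_{chr(65 + i % n_countries)}" for i in range(n_sites)],
        "management": rng.choice(MANAGEMENT_REGIMES, size=n_sites),
        "depth_m": rng.uniform(2.0, 20.0, n_sites),
    })
    for j, col in enumerate(BENTHIC_COLUMNS):
        sites[col] = 0.0
    regimes = rng.choice(list(_BENTHIC_REGIMES), size=n_sites)
    for i, reg in enumerate(regimes):
        sites.loc[i, list(BENTHIC_COLUMNS)] = rng.dirichlet(_BENTHIC_REGIMES[reg]) * rng.uniform(70, 95)
    biomass = np.exp(rng.uniform(np.log(biomass_range[0]), np.log(biomass_range[1]), n_sites))
    cfg = SimulationConfig(seed=seed, truth=truth)
    p, info = _true_compositions(cfg, sites, biomass, rng)
    records = sites.copy()
    records["fishable_biomass_kg_ha"] = biomass
    records["service"] = "simulated"
    records["p_herbivore"] = p[:, 0]
    records["p_mobile_invertivore"] = p[:, 1]
    records["p_piscivore"] = p[:, 2]
    free = ("herbivore", "piscivore")
    truth_named = {f"intercept[{k}]": truth.intercept[i] for i, k in enumerate(free)}
    for c, b in zip(COVARIATES_DEFAULT, truth.beta):
        for i, k in enumerate(free):
            truth_named[f"beta[{c},{k}]"] = b[i]
    truth_named["phi"] = truth.phi
    truth_named["slope_dev"] = info["slope_dev"]
    truth_named["mgmt_int"] = info["mgmt_int"]
    return records, truth_named
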
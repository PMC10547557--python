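# reefnutro

Nutrient productivity and trophic structure of coral-reef fish assemblages,
computed from underwater visual census (UVC) surveys.

Reef fisheries feed hundreds of millions of people, yet reef monitoring is
usually summarized as standing fish biomass alone. That misses two things
that determine what a reef can actually contribute to human diets: how fast
biomass is *produced* (somatic growth), and how *nutritious* that biomass
is (concentrations of calcium, iron, zinc, selenium, vitamin A and omega-3
fatty acids in edible tissue). `reefnutro` combines these into a pipeline
for quantitative fisheries ecologists:

1. **Survey ingest** — long-format UVC tables (site, transect, species,
   length, count) are validated, lengths recorded in 5 cm bins are resolved
   to midpoints, fishery-irrelevant records (fish < 5 cm, untargeted
   damselfishes, wide-ranging elasmobranchs) are excluded, and lengths are
   converted to mass via `W = a L^b`.
2. **Growth** — each fish's maximum potential daily growth follows the von
   Bertalanffy model with the species' standardized growth coefficient
   `K_max` (the growth coefficient at the species' maximum size):
   `dL = (L_max − L) (1 − e^(−K_max/365))`, converted to grams through the
   length-weight curve.
3. **Fishery services** — per site and trophic group: standing biomass
   (kg ha⁻¹), biomass production (g d⁻¹ ha⁻¹), turnover
   (production/biomass, % yr⁻¹), and the production rate of six nutrients
   in edible tissue (production × 87% edible fraction × concentration).
4. **Trophic structure** — services are closed to 3-part compositions
   (herbivores, mobile invertivores, piscivores) and classified as
   bottom-heavy (herbivores dominate) or top-heavy (piscivores dominate).
5. **Composition model** — a hierarchical Dirichlet regression
   `y ~ Dirichlet(μ φ)` with a softmax link on standardized fishable
   biomass, five benthic covers and depth, country-varying biomass slopes
   and management-in-country intercepts. Fitting is MAP + Laplace (fast)
   or full Hamiltonian-Monte-Carlo-within-Gibbs with Rhat/ESS diagnostics.
6. **Synthetic data** — a generator that emulates a full multi-country UVC
   program (species pool with allometric growth and size-linked nutrients,
   benthic regimes, management nested in country, belt transects of
   5×50/10×50/2×30 m) with known ground truth, so every stage is testable
   without any data download.

## Worked example

```python
from reefnutro import simulate, survey, services, pyramids, model

study = simulate.simulate_study(simulate.SimulationConfig(
    seed=1, n_countries=3, sites_per_country=15, species_pool_size=150))
cleaned, log = survey.ingest(study["survey"], study["sites"],
                             study["traits"], study["transects"])
print(log)
# ExclusionLog(small=197, damselfish=208, elasmobranch=203)

site_tab = services.site_services(
    services.transect_services(cleaned, study["traits"]))
cov = services.site_covariates(cleaned, study["sites"])
records = pyramids.build_composition_records(site_tab, cov)

zinc = records[records["service"] == "zinc_mg_d_ha"]
print(pyramids.classify_sites(zinc).value_counts())
# bottom_heavy    42
# top_heavy        3

fit = model.fit(zinc, method="map", seed=0)
print(round(fit.coef("beta[fishable_biomass_kg_ha,piscivore]"), 2))
# 0.42
```

The exclusion log shows how many survey rows each filter removed. The
classification counts say that zinc production is herbivore-dominated
(bottom-heavy) on 42 of 45 simulated reefs, and the fitted standardized
biomass slope for piscivores (+0.42 here; the generator's true biomass
composition slope is +0.5) means the piscivore share of zinc production
rises along the fishable-biomass gradient.

A command-line interface mirrors the pipeline:

```bash
reefnutro simulate --seed 1 --out-dir data/
reefnutro ingest --survey data/survey.csv --sites data/sites.csv \
    --traits data/traits.csv --transects data/transects.csv --out cleaned.csv
reefnutro services --cleaned cleaned.csv --traits data/traits.csv --out services.csv
```

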
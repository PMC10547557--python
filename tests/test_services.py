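"""Fishery services: nutrient production, turnover, site averaging, shares."""

import numpy as np
import pandas as pd
import pytest

from reefnutro import services
from reefnutro.services import (
    UndefinedCompositionError,
    nutrient_production,
    relative_contributions,
    site_services,
    transect_services,
    turnover,
)
from reefnutro.traits import NutrientProfile


@pytest.fixture(scope="module")
def per_transect(small_study, small_cleaned):
    cleaned, _ = small_cleaned
    return transect_services(cleaned, small_study["traits"])


class TestNutrientProduction:
    def test_worked_example(self):
        profile = NutrientProfile(calcium=50, iron=0, zinc=0, selenium=0,
                                  vitamin_a=0, omega3=0)
        out = nutrient_production(100.0, profile)
        assert out["calcium_mg_d_ha"] == pytest.approx(43.5)

    def test_zero_production_all_zero(self):
        profile = NutrientProfile(calcium=50, iron=1, zinc=1, selenium=30,
                                  vitamin_a=20, omega3=0.3)
        assert all(v == 0.0 for v in nutrient_production(0.0, profile).values())

    def test_linearity_in_production_and_concentration(self):
        p1 = NutrientProfile(calcium=10, iron=1, zinc=1, selenium=10, vitamin_a=5, omega3=0.1)
        p2 = NutrientProfile(calcium=20, iron=2, zinc=2, selenium=20, vitamin_a=10, omega3=0.2)
        a = nutrient_production(50.0, p1)
        assert nutrient_production(100.0, p1)["iron_mg_d_ha"] == pytest.approx(2 * a["iron_mg_d_ha"])
        assert nutrient_production(50.0, p2)["iron_mg_d_ha"] == pytest.approx(2 * a["iron_mg_d_ha"])

    def test_edible_fraction_bounds(self):
        profile = NutrientProfile(calcium=1, iron=1, zinc=1, selenium=1, vitamin_a=1, omega3=1)
        with pytest.raises(ValueError):
            nutrient_production(1.0, profile, edible_fraction=0.0)
        with pytest.raises(ValueError):
            nutrient_production(1.0, profile, edible_fraction=1.2)

    def test_transect_rates_match_individual_loop(self, small_study, small_cleaned):
        """Aggregated nutrient rates equal an explicit per-fish summation."""
        from reefnutro.growth import add_production

        cleaned, _ = small_cleaned
        tid = cleaned["transect_id"].iloc[0]
        sub = cleaned[cleaned["transect_id"] == tid].copy()
        table = transect_services(sub, small_study["traits"])
        table = table[table["transect_id"] == tid]
        rows = add_production(sub, small_study["traits"])
        conc = small_study["traits"].set_index("species_id")
        area = sub["area_m2"].iloc[0]
        expected = 0.0
        for _, r in rows.iterrows():
            zn = conc.loc[r["species_id"], "zn_mg"]
            expected += r["count"] * r["prod_g_d"] * 0.87 * zn / 100.0
        expected *= 10_000.0 / area
        assert table["zinc_mg_d_ha"].sum() == pytest.approx(expected, rel=1e-9)


class TestTurnover:
    def test_annual_arithmetic(self):
        assert turnover(10.0, 100.0, basis="annual") == pytest.approx(3.65)

    def test_daily_basis(self):
        assert turnover(10.0, 100.0, basis="daily") == pytest.approx(0.01)

    def test_zero_production_zero_turnover(self):
        assert turnover(0.0, 50.0) == 0.0
        assert turnover(0.0, 0.0) == 0.0

    def test_production_without_biomass_is_impossible(self):
        with pytest.raises(ValueError):
            turnover(5.0, 0.0)

    def test_count_scaling_invariance(self):
        """Multiplying counts scales production and biomass together."""
        assert turnover(10.0, 100.0) == pytest.approx(turnover(100.0, 1000.0))

    def test_tuned_fixture_inside_observed_envelope(self):
        """Mid-gradient reefs (500 kg ha^-1) show annual turnover inside the
        1-41% range seen on real reef biomass gradients."""
        from reefnutro import simulate, survey as sv

        cfg = simulate.SimulationConfig(
            seed=4, n_countries=2, sites_per_country=5, species_pool_size=100,
            biomass_range_kg_ha=(500.0, 500.0001),
        )
        study = simulate.simulate_study(cfg)
        cleaned, _ = sv.ingest(study["survey"], study["sites"], study["traits"],
                               study["transects"])
        per_tr = transect_services(cleaned, study["traits"])
        totals = per_tr.groupby(["site_id", "transect_id"], observed=True)[
            ["production_g_d_ha", "standing_biomass_kg_ha"]
        ].sum()
        t = turnover(totals["production_g_d_ha"].to_numpy(),
                     totals["standing_biomass_kg_ha"].to_numpy())
        assert (t > 1.0).all() and (t < 41.0).all()

    def test_default_gradient_turnover_bulk_in_envelope(self, small_study, small_cleaned):
        """Across the default 10-6000 kg ha^-1 gradient the bulk of site
        turnover values falls in the observed 1-41% envelope."""
        cleaned, _ = small_cleaned
        per_tr = transect_services(cleaned, small_study["traits"])
        totals = per_tr.groupby(["site_id", "transect_id"], observed=True)[
            ["production_g_d_ha", "standing_biomass_kg_ha"]
        ].sum().reset_index()
        totals["turn"] = turnover(totals["production_g_d_ha"].to_numpy(),
                                  totals["standing_biomass_kg_ha"].to_numpy())
        site = totals.groupby("site_id")["turn"].mean()
        assert 1.0 < site.median() < 41.0
        assert (site.between(1.0, 41.0)).mean() >= 0.8


class TestSiteAveraging:
    def test_single_transect_site_equals_transect(self, per_transect):
        sid = per_transect["site_id"].iloc[0]
        tid = per_transect.loc[per_transect["site_id"] == sid, "transect_id"].iloc[0]
        one = per_transect[(per_transect["site_id"] == sid)
                           & (per_transect["transect_id"] == tid)]
        site_tab = site_services(one)
        a = site_tab.set_index("trophic_group")
        b = one.set_index("trophic_group")
        for col in services.SERVICE_COLUMNS:
            assert np.allclose(a[col], b[col])

    def test_two_value_mean(self):
        rows = pd.DataFrame({
            "site_id": ["s", "s"], "transect_id": ["t1", "t2"],
            "trophic_group": ["piscivore", "piscivore"],
            **{c: [0.0, 0.0] for c in services.SERVICE_COLUMNS},
        })
        rows.loc[0, "standing_biomass_kg_ha"] = 100.0
        rows.loc[1, "standing_biomass_kg_ha"] = 300.0
        out = site_services(rows)
        assert out["standing_biomass_kg_ha"].iloc[0] == pytest.approx(200.0)

    def test_matches_pandas_groupby_oracle(self, per_transect):
        out = site_services(per_transect).set_index(["site_id", "trophic_group"])
        oracle = per_transect.groupby(["site_id", "trophic_group"], observed=True)[
            list(services.SERVICE_COLUMNS)
        ].mean()
        pd.testing.assert_frame_equal(out.sort_index(), oracle.sort_index(),
                                      check_like=True)


class TestRelativeContributions:
    def test_single_nonzero_group_gets_all(self):
        tab = pd.DataFrame({
            "site_id": ["s"] * 3,
            "trophic_group": ["piscivore", "omnivore", "planktivore"],
            "standing_biomass_kg_ha": [40.0, 0.0, 0.0],
        })
        out = relative_contributions(tab, "standing_biomass_kg_ha")
        assert out.loc[out.trophic_group == "piscivore", "contribution_pct"].iloc[0] == 100.0

    def test_equal_groups_share_equally(self):
        groups = list(services.CONTRIBUTION_GROUPS)
        tab = pd.DataFrame({
            "site_id": ["s"] * len(groups), "trophic_group": groups,
            "standing_biomass_kg_ha": [7.0] * len(groups),
        })
        out = relative_contributions(tab, "standing_biomass_kg_ha")
        assert np.allclose(out["contribution_pct"], 100.0 / len(groups))

    def test_shares_sum_to_100_every_site(self, per_transect):
        site_tab = site_services(per_transect)
        for service in services.SERVICE_COLUMNS:
            out = relative_contributions(site_tab, service)
            sums = out.groupby("site_id")["contribution_pct"].sum()
            assert np.allclose(sums, 100.0, atol=1e-9)

    def test_shares_match_direct_ratio(self, per_transect):
        site_tab = site_services(per_transect)
        out = relative_contributions(site_tab, "production_g_d_ha")
        sub = site_tab[site_tab["trophic_group"].isin(services.CONTRIBUTION_GROUPS)]
        sid = sub["site_id"].iloc[0]
        block = sub[sub["site_id"] == sid]
        expect = 100.0 * block["production_g_d_ha"] / block["production_g_d_ha"].sum()
        got = out[out["site_id"] == sid].set_index("trophic_group")["contribution_pct"]
        for g, e in zip(block["trophic_group"], expect):
            assert got[g] == pytest.approx(e)

    def test_sessile_invertivores_excluded_by_default(self, per_transect):
        site_tab = site_services(per_transect)
        out = relative_contributions(site_tab, "standing_biomass_kg_ha")
        assert "sessile_invertivore" not in set(out["trophic_group"])

    def test_all_zero_total_raises(self):
        tab = pd.DataFrame({
            "site_id": ["s"] * 2, "trophic_group": ["piscivore", "omnivore"],
            "standing_biomass_kg_ha": [0.0, 0.0],
        })
        with pytest.raises(UndefinedCompositionError):
            relative_contributions(tab, "standing_biomass_kg_ha")

    def test_invariant_to_global_rescaling(self, per_transect):
        site_tab = site_services(per_transect)
        scaled = site_tab.copy()
        scaled["production_g_d_ha"] *= 37.5
        a = relative_contributions(site_tab, "production_g_d_ha")["contribution_pct"]
        b = relative_contributions(scaled, "production_g_d_ha")["contribution_pct"]
        assert np.allclose(a, b)


class TestCountScalingPipeline:
    def test_count_x10_scales_biomass_but_not_shares(self, small_study):
        """Multiplying every count by 10 multiplies biomass by 10 and leaves
        turnover and relative contributions unchanged."""
        from reefnutro import survey as sv

        cleaned, _ = sv.ingest(
            small_study["survey"], small_study["sites"], small_study["traits"],
            small_study["transects"],
        )
        boosted = cleaned.copy()
        boosted["count"] *= 10
        a = site_services(transect_services(cleaned, small_study["traits"]))
        b = site_services(transect_services(boosted, small_study["traits"]))
        assert np.allclose(b["standing_biomass_kg_ha"], 10 * a["standing_biomass_kg_ha"])
        assert np.allclose(b["turnover_pct"], a["turnover_pct"])
        for service in ("standing_biomass_kg_ha", "zinc_mg_d_ha"):
            ca = relative_contributions(a, service)["contribution_pct"]
            cb = relative_contributions(b, service)["contribution_pct"]
            assert np.allclose(ca, cb, atol=1e-9)
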
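"""Generative model: determinism, truth columns, calibration."""

import numpy as np
import pandas as pd
import pytest

from densnest.simulate import (
    ConfigurationError,
    SimConfig,
    gen_farms,
    gen_territories,
    simulate_dataset,
)
from densnest.survival import summarize_exposures
from densnest.territory import HABITAT_CLASSES


def tiny_config(**kw):
    base = dict(n_farms=6, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_gives_identical_tables(self):
        a = simulate_dataset(tiny_config())
        b = simulate_dataset(tiny_config())
        for name in ("farms", "boundaries", "territories", "counts",
                     "nests", "visits", "watches", "masses"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        a = simulate_dataset(tiny_config(seed=5))
        b = simulate_dataset(tiny_config(seed=6))
        assert not a.boundaries["length_m"].equals(b.boundaries["length_m"])

    def test_csv_round_trip_byte_identical(self, tmp_path):
        sim = simulate_dataset(tiny_config())
        sim.to_csv(tmp_path / "one")
        sim.to_csv(tmp_path / "two")
        for f in (tmp_path / "one").iterdir():
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()


class TestFarms:
    def test_all_habitat_classes_present(self):
        _, bounds = gen_farms(tiny_config())
        assert set(bounds["habitat_class"]) == set(HABITAT_CLASSES)

    def test_degenerate_length_range_is_exact(self):
        ranges = {"Hedge": (500.0, 500.0)}
        cfg = tiny_config(habitat_length_ranges=ranges)
        _, bounds = gen_farms(cfg)
        per_farm = bounds.groupby("farm_id")["length_m"].sum()
        assert np.allclose(per_farm, 500.0)

    def test_farms_do_not_overlap(self):
        farms, _ = gen_farms(tiny_config(n_farms=9))
        corners = farms[["origin_x", "origin_y"]].to_numpy()
        assert len(np.unique(corners, axis=0)) == len(farms)

    def test_management_pairing(self):
        farms, _ = gen_farms(tiny_config(n_farms=8))
        assert (farms["management"] == "organic").sum() == 4


class TestTerritories:
    def test_poisson_mean_without_covariate_effects(self):
        # intercept-only intensity: counts are Poisson(exp(1.1))
        cfg = tiny_config(
            n_farms=400,
            territory_intensity={"intercept": 1.1, "slopes": {}, "year": {},
                                 "landscape_organic": 0.0},
        )
        farms, bounds = gen_farms(cfg)
        _, counts = gen_territories(farms, bounds, cfg)
        lam = np.exp(1.1)
        n = len(counts)
        se = np.sqrt(lam / n)
        assert counts["n_territories"].mean() == pytest.approx(lam, abs=4 * se)

    def test_more_hedge_means_more_territories(self):
        def mean_count(lo, hi, seed):
            cfg = tiny_config(
                n_farms=120,
                seed=seed,
                habitat_length_ranges={"Hedge": (lo, hi)},
                territory_intensity={"intercept": -1.0,
                                     "slopes": {"Hedge": 0.4}},
            )
            farms, bounds = gen_farms(cfg)
            _, counts = gen_territories(farms, bounds, cfg)
            return counts["n_territories"].mean()

        assert mean_count(2500, 3000, 3) > mean_count(100, 300, 3)

    def test_zero_count_farm_years_kept_in_counts(self):
        cfg = tiny_config(
            n_farms=30,
            territory_intensity={"intercept": -4.0, "slopes": {}},
        )
        farms, bounds = gen_farms(cfg)
        terr, counts = gen_territories(farms, bounds, cfg)
        assert len(counts) == 30 * len(cfg.years)
        assert (counts["n_territories"] == 0).any()
        assert counts["n_territories"].sum() == len(terr)

    def test_points_stay_inside_their_farm_square(self):
        sim = simulate_dataset(tiny_config())
        farms = sim.farms.set_index("farm_id")
        for _, t in sim.territories.iterrows():
            f = farms.loc[t["farm_id"]]
            assert f["origin_x"] - 1e-9 <= t["x"] <= f["origin_x"] + f["extent"] + 1e-9
            assert f["origin_y"] - 1e-9 <= t["y"] <= f["origin_y"] + f["extent"] + 1e-9

    def test_extreme_intensity_rejected(self):
        cfg = tiny_config(territory_intensity={"intercept": 40.0, "slopes": {}})
        farms, bounds = gen_farms(cfg)
        with pytest.raises(ConfigurationError, match="intensity"):
            gen_territories(farms, bounds, cfg)


class TestNests:
    def test_zero_hazard_means_every_nest_fledges(self):
        cfg = tiny_config(
            daily_failure={"egg_base": 0.0, "nestling_base": 0.0,
                           "egg_coefs": {}, "nestling_coefs": {}, "centers": {}},
        )
        sim = simulate_dataset(cfg)
        assert (sim.nests["true_fate"] == "fledged").all()
        last = sim.visits.sort_values("day").groupby("nest_id").tail(1)
        assert (last["status"] == "empty-intact").all()

    def test_certain_failure_means_none_fledge(self):
        cfg = tiny_config(
            daily_failure={"egg_base": 1.0, "nestling_base": 1.0,
                           "egg_coefs": {}, "nestling_coefs": {}, "centers": {}},
        )
        sim = simulate_dataset(cfg)
        assert (sim.nests["true_fate"] == "failed-egg").all()

    def test_true_egg_failure_rate_calibrated(self):
        # per-day failure from truth columns should sit near egg_base
        cfg = tiny_config(
            n_farms=40,
            daily_failure={"egg_base": 0.03, "nestling_base": 0.0,
                           "egg_coefs": {}, "nestling_coefs": {}, "centers": {}},
        )
        sim = simulate_dataset(cfg)
        n = sim.nests
        # exact egg-stage exposure in the latent process
        end = np.where(
            n["true_fate"] == "failed-egg",
            n["true_fail_day"],
            n["true_hatch_day"],
        )
        days = (end - n["found_day"]).sum()
        fails = (n["true_fate"] == "failed-egg").sum()
        rate = fails / days
        se = np.sqrt(0.03 * 0.97 / days)
        assert rate == pytest.approx(0.03, abs=4 * se)

    def test_visit_gaps_respect_interval(self):
        sim = simulate_dataset(tiny_config())
        gaps = sim.visits.sort_values(["nest_id", "day"]).groupby("nest_id")[
            "day"].diff().dropna()
        assert (gaps >= 1).all()
        assert (gaps <= sim.config.visit_interval_max).all()

    def test_every_nest_has_a_territory_and_vice_versa_at_most_one(self):
        sim = simulate_dataset(tiny_config())
        assert sim.nests["territory_id"].isin(sim.territories["territory_id"]).all()
        assert sim.nests["territory_id"].is_unique

    def test_observed_histories_reduce_consistently_with_truth(self):
        sim = simulate_dataset(tiny_config(n_farms=12))
        hatch = dict(zip(sim.nests["nest_id"], sim.nests["hatch_day"]))
        hatch = {k: (None if not np.isfinite(v) else v) for k, v in hatch.items()}
        out = summarize_exposures(sim.visits, hatch_days=hatch).set_index("nest_id")
        truth = sim.nests.set_index("nest_id")
        both = out.join(truth["true_fate"])
        # observed fledging must only ever happen for truly fledged nests
        assert (both.loc[both["fledged"] == 1, "true_fate"] == "fledged").all()
        failed = both["true_fate"].str.startswith("failed")
        assert (
            both.loc[failed, ["egg_failed", "nestling_failed"]].sum(axis=1) == 1
        ).all()


class TestWatchesAndMasses:
    def test_noiseless_watch_rate_matches_predictor(self):
        coefs = dict(SimConfig().provisioning_coefs)
        coefs["sd"] = 0.0
        sim = simulate_dataset(tiny_config(provisioning_coefs=coefs))
        w = sim.watches
        eta = (
            coefs["intercept"]
            + coefs["nestling_age"] * w["nestling_age"]
            + coefs["brood_size"] * w["brood_size"]
            + coefs["corvid_abundance"] * w["corvid_abundance"]
            + coefs["temperature"] * w["temperature"]
            + coefs["temperature_sq"] * w["temperature_sq"]
            + coefs["year_2008"] * w["year_2008"]
            + coefs["management_organic"] * w["management_organic"]
            + coefs["nnd"] * w["nnd"]
            + coefs["nnd_x_corvid_activity"] * w["nnd"] * w["corvid_activity"]
            + coefs["nnd_x_brood_size"] * w["nnd"] * w["brood_size"]
        )
        assert np.allclose(w["trips_per_hour"], eta, atol=1e-9)

    def test_noiseless_mass_matches_predictor(self):
        mc = dict(SimConfig().mass_coefs)
        mc["sd"] = 0.0
        sim = simulate_dataset(tiny_config(mass_coefs=mc))
        m = sim.masses
        eta = (
            mc["first_mass"] * m["first_mass"]
            + mc["hours_between"] * m["hours_between"]
            + mc["age_second"] * m["age_second"]
            + mc["nnd_km"] * m["nnd"] / 1000.0
        )
        assert np.allclose(m["second_mass"], eta, atol=1e-9)

    def test_watches_reference_nests_that_reached_nestlings(self):
        sim = simulate_dataset(tiny_config(n_farms=12))
        fate = sim.nests.set_index("nest_id")["true_fate"]
        assert (fate[sim.watches["nest_id"]] != "failed-egg").all()
        assert sim.watches["nestling_age"].between(2, 7).all()

    def test_masses_have_positive_interval_and_age_order(self):
        sim = simulate_dataset(tiny_config(n_farms=12))
        m = sim.masses
        assert (m["age_second"] > m["age_first"]).all()
        assert (m["hours_between"] > 0).all()


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ConfigurationError, match="nest_prob"):
            tiny_config(nest_prob=1.2)

    def test_unknown_habitat_class(self):
        with pytest.raises(ConfigurationError, match="Motorway"):
            tiny_config(habitat_length_ranges={"Motorway": (0.0, 1.0)})

    def test_inverted_length_range(self):
        with pytest.raises(ConfigurationError, match="range"):
            tiny_config(habitat_length_ranges={"Hedge": (10.0, 1.0)})

    def test_concealment_probs_must_normalise(self):
        with pytest.raises(ConfigurationError, match="concealment"):
            tiny_config(concealment_probs=(0.5, 0.1, 0.1, 0.1, 0.1))

    def test_hazard_bounds(self):
        with pytest.raises(ConfigurationError, match="egg_base"):
            tiny_config(daily_failure={"egg_base": 1.5, "nestling_base": 0.0})
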
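"""Synthetic breeding-season data with known generative parameters.

Real territory, nest and provisioning data for this study system are not
deposited, so the package ships a simulator that emulates the
statistical structure every downstream stage assumes:

* farms carry boundary segments in six habitat classes; territory counts
  per farm-year are Poisson with a log-linear intensity in the
  log(length + 1) of each habitat class plus year and landscape terms,
  and territory centres sit on the boundary network;
* each territory holds at most one monitored nest whose true fate is a
  daily Bernoulli failure process with stage-specific, logit-linear
  hazards; the nest is observed only through a visit schedule at most
  ``visit_interval_max`` days apart (with day-7 and day-10 nestling
  checks so the fledging rule can be applied), and the failure day
  within an interval stays latent;
* provisioning watches have Gaussian noise around a linear predictor
  that includes density-by-corvid-activity and density-by-brood-size
  interactions, and nestling growth is linear with a positive
  territory-isolation (NND) slope.

True hazards, fates and coefficients are kept alongside the observed
tables so inferential code can be checked for parameter recovery.  A
fixed seed and config give byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .territory import HABITAT_CLASSES, density_metrics

__all__ = ["SimConfig", "SimulatedData", "simulate_dataset",
           "gen_farms", "gen_territories", "gen_nests", "gen_watches", "gen_masses"]


class ConfigurationError(ValueError):
    """Invalid simulator configuration."""


def _default_length_ranges():
    # plausible per-farm boundary totals in metres
    return {
        "Hedge": (500.0, 3000.0),
        "Hedge with 10-50% trees": (100.0, 1500.0),
        "Hedge with >50% trees": (100.0, 1500.0),
        "Fence with vegetation": (200.0, 2000.0),
        "Gappy hedge": (50.0, 800.0),
        "Fence or wall": (200.0, 2000.0),
    }


def _default_intensity():
    # generative counterpart of the fitted territory-count model
    return {
        "intercept": -1.231,
        "slopes": {"Hedge": 0.394, "Fence with vegetation": 0.065},
        "year": {2008: -0.748},
        "landscape_organic": 0.364,
    }


def _default_daily_failure():
    return {
        "egg_base": 0.03,
        "nestling_base": 0.03,
        # logit-scale coefficients applied to centred covariates
        "egg_coefs": {},
        "nestling_coefs": {"nnd": -0.007},
        "centers": {"nnd": 300.0, "concealment": 3.0},
    }


def _default_provisioning():
    # trips per hour; NND enters in metres
    return {
        "intercept": 0.319,
        "nestling_age": 0.083,
        "brood_size": 0.465,
        "corvid_activity": 0.0,
        "corvid_abundance": 0.011,
        "invertebrates": 0.0,
        "temperature": -0.033,
        "temperature_sq": -0.001,
        "time_of_day": 0.0,
        "time_of_day_sq": 0.0,
        "year_2008": 0.563,
        "management_organic": -0.380,
        "nnd": 0.003,
        "nnd_x_corvid_activity": -0.001,
        "nnd_x_brood_size": -0.001,
        "nnd_x_invertebrates": 0.0,
        "nnd_x_management_organic": 0.0,
        "sd": 2.0,
    }


def _default_mass():
    # grams; NND enters in kilometres so the slope is g per km of isolation
    return {
        "intercept": 0.0,
        "first_mass": 1.0,
        "hours_between": 0.064,
        "age_second": 0.8,
        "time_of_day_second": 0.0,
        "year_2008": 0.0,
        "nnd_km": 2.0,
        "sd": 0.4,
    }


def _default_covariates():
    return {
        "temperature_mean": 15.0,
        "temperature_sd": 3.0,
        "invertebrates_logmean": np.log(5.0),
        "invertebrates_logsd": 0.5,
        "corvid_activity_mean": 3.0,
        "corvid_abundance_logmean": np.log(12.0),
        "corvid_abundance_logsd": 0.4,
    }


@dataclass
class SimConfig:
    """All tunable parameters of the simulator; see module docstring.

    Defaults give 18 farms over two years, a ~3% daily failure hazard in
    both stages, a 3-day visit interval, and linear predictors whose
    structure mirrors the provisioning and mass-gain analyses.
    """

    n_farms: int = 18
    years: tuple = (2007, 2008)
    farm_extent: float = 1500.0
    habitat_length_ranges: dict = field(default_factory=_default_length_ranges)
    territory_intensity: dict = field(default_factory=_default_intensity)
    daily_failure: dict = field(default_factory=_default_daily_failure)
    visit_interval_max: int = 3
    nest_prob: float = 0.6
    clutch_probs: dict = field(default_factory=lambda: {3: 0.68, 4: 0.32})
    hatch_fail_prob: float = 0.12
    concealment_probs: tuple = (0.10, 0.20, 0.30, 0.25, 0.15)
    incubation_remaining: tuple = (2, 9)  # days from finding to hatch (uniform)
    nestling_period: int = 9  # true fledging age in days
    brood_reduction_daily: float = 0.02
    provisioning_coefs: dict = field(default_factory=_default_provisioning)
    mass_coefs: dict = field(default_factory=_default_mass)
    covariate_params: dict = field(default_factory=_default_covariates)
    seed: int = 0

    def __post_init__(self):
        if self.n_farms < 1:
            raise ConfigurationError("n_farms must be >= 1")
        if self.farm_extent <= 0:
            raise ConfigurationError("farm_extent must be positive")
        if self.visit_interval_max < 1:
            raise ConfigurationError("visit_interval_max must be >= 1")
        for cls, (lo, hi) in self.habitat_length_ranges.items():
            if cls not in HABITAT_CLASSES:
                raise ConfigurationError(f"unknown habitat class {cls!r}")
            if lo > hi or lo < 0:
                raise ConfigurationError(
                    f"invalid length range for {cls!r}: ({lo}, {hi})"
                )
        for key in ("egg_base", "nestling_base"):
            p = self.daily_failure[key]
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"daily_failure[{key!r}] must be in [0, 1]")
        for name, p in (
            ("nest_prob", self.nest_prob),
            ("hatch_fail_prob", self.hatch_fail_prob),
            ("brood_reduction_daily", self.brood_reduction_daily),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if abs(sum(self.concealment_probs) - 1.0) > 1e-9:
            raise ConfigurationError("concealment_probs must sum to 1")
        if abs(sum(self.clutch_probs.values()) - 1.0) > 1e-9:
            raise ConfigurationError("clutch_probs must sum to 1")


# ---------------------------------------------------------------------------
# farms and boundaries


def gen_farms(config: SimConfig, rng=None):
    """Farm table and boundary-segment table.

    Farms come in organic/conventional pairs nested in organic or
    conventional landscapes, spread over six geographic clusters, on a
    grid of non-overlapping squares.  Each habitat class present in the
    config contributes at least one segment per farm; a farm's total
    length per class is drawn uniformly from the configured range and
    split over one to three segments.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    E = config.farm_extent
    grid = int(np.ceil(np.sqrt(config.n_farms)))
    farm_rows, seg_rows = [], []
    for i in range(config.n_farms):
        fid = f"F{i + 1:02d}"
        management = "organic" if i % 2 == 0 else "conventional"
        landscape = "organic" if (i // 2) % 2 == 0 else "conventional"
        cluster = f"C{i % 6 + 1}"
        ox = (i % grid) * 2.0 * E
        oy = (i // grid) * 2.0 * E
        farm_rows.append(
            {
                "farm_id": fid,
                "management": management,
                "landscape": landscape,
                "cluster": cluster,
                "origin_x": ox,
                "origin_y": oy,
                "extent": E,
            }
        )
        s = 0
        for cls, (lo, hi) in config.habitat_length_ranges.items():
            total = float(rng.uniform(lo, hi))
            n_seg = int(rng.integers(1, 4))
            cuts = np.sort(rng.uniform(0, 1, n_seg - 1))
            parts = np.diff(np.concatenate([[0.0], cuts, [1.0]])) * total
            for L in parts:
                s += 1
                axis = "h" if rng.random() < 0.5 else "v"
                seg_rows.append(
                    {
                        "farm_id": fid,
                        "segment_id": f"{fid}-S{s:02d}",
                        "habitat_class": cls,
                        "length_m": float(L),
                        "axis": axis,
                        "start_x": float(rng.uniform(0, E)),
                        "start_y": float(rng.uniform(0, E)),
                    }
                )
    return pd.DataFrame(farm_rows), pd.DataFrame(seg_rows)


def _fold(x, extent):
    """Reflect a coordinate into [0, extent] (triangle wave)."""
    t = np.mod(x, 2.0 * extent)
    return np.where(t > extent, 2.0 * extent - t, t)


# ---------------------------------------------------------------------------
# territories


def gen_territories(farms: pd.DataFrame, boundaries: pd.DataFrame, config: SimConfig,
                    rng=None):
    """Territory point table and farm-year count table.

    Counts are Poisson with log intensity intercept + sum of per-class
    slopes on log(length + 1) + year + landscape terms; points are
    placed uniformly along boundary segments (segment chosen with
    probability proportional to its length), folded into the farm
    square, re-drawn on exact coordinate duplicates.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    inten = config.territory_intensity
    terr_rows, count_rows = [], []
    tid = 0
    for _, farm in farms.iterrows():
        segs = boundaries[boundaries["farm_id"] == farm["farm_id"]]
        lengths = segs.groupby("habitat_class")["length_m"].sum()
        for year in config.years:
            eta = float(inten["intercept"])
            for cls, slope in inten.get("slopes", {}).items():
                eta += slope * np.log(lengths.get(cls, 0.0) + 1.0)
            eta += inten.get("year", {}).get(year, 0.0)
            if farm["landscape"] == "organic":
                eta += inten.get("landscape_organic", 0.0)
            if abs(eta) > 30:
                raise ConfigurationError(
                    f"log intensity {eta:.1f} out of range for farm "
                    f"{farm['farm_id']} year {year}"
                )
            n = int(rng.poisson(np.exp(eta)))
            row = {"farm_id": farm["farm_id"], "year": year, "n_territories": n,
                   "management": farm["management"], "landscape": farm["landscape"],
                   "cluster": farm["cluster"]}
            for cls in HABITAT_CLASSES:
                row[f"length_{cls}"] = float(lengths.get(cls, 0.0))
            count_rows.append(row)
            if n == 0 or len(segs) == 0:
                continue
            p = segs["length_m"].to_numpy()
            p = p / p.sum()
            seen = set()
            placed = 0
            while placed < n:
                j = rng.choice(len(segs), p=p)
                seg = segs.iloc[j]
                d = rng.uniform(0, seg["length_m"])
                if seg["axis"] == "h":
                    x = float(_fold(seg["start_x"] + d, farm["extent"]))
                    y = float(seg["start_y"])
                else:
                    x = float(seg["start_x"])
                    y = float(_fold(seg["start_y"] + d, farm["extent"]))
                if (x, y) in seen:
                    continue  # re-draw exact duplicates
                seen.add((x, y))
                tid += 1
                terr_rows.append(
                    {
                        "territory_id": f"T{tid:04d}",
                        "farm_id": farm["farm_id"],
                        "year": year,
                        "x": farm["origin_x"] + x,
                        "y": farm["origin_y"] + y,
                    }
                )
                placed += 1
    territories = pd.DataFrame(
        terr_rows, columns=["territory_id", "farm_id", "year", "x", "y"]
    )
    return territories, pd.DataFrame(count_rows)


# ---------------------------------------------------------------------------
# nests and visits


def _hazard(base, coefs, centers, cov):
    eta = logit(np.clip(base, 1e-12, 1 - 1e-12))
    for name, c in coefs.items():
        eta += c * (cov[name] - centers.get(name, 0.0))
    return float(expit(eta)) if np.isscalar(eta) or np.ndim(eta) == 0 else expit(eta)


def gen_nests(territories: pd.DataFrame, config: SimConfig, rng=None):
    """Nest table and visit table from a daily failure process.

    At most one nest per territory.  True fate is simulated day by day
    at stage-specific hazards (logit-linear in centred covariates, NND
    included); observation happens only at visits every
    ``visit_interval_max`` days plus mandated checks at nestling ages 7
    and 10, so the failure day is interval censored.  Truth columns
    (``true_*``) carry the latent fate and hazards for recovery tests.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    df = config.daily_failure
    centers = df.get("centers", {})
    metrics = (
        density_metrics(territories).set_index("territory_id")
        if len(territories)
        else pd.DataFrame()
    )
    # grouping must match the farm-year structure territories come in
    terr = territories.merge(
        metrics[["nnd", "ntnd"]], left_on="territory_id", right_index=True, how="left"
    ) if len(territories) else territories.assign(nnd=[], ntnd=[])

    clutch_vals = sorted(config.clutch_probs)
    clutch_p = [config.clutch_probs[v] for v in clutch_vals]
    conceal_vals = np.arange(1, 6)

    nest_rows, visit_rows = [], []
    nid = 0
    for _, t in terr.iterrows():
        if rng.random() >= config.nest_prob:
            continue
        nid += 1
        nest_id = f"N{nid:04d}"
        concealment = int(rng.choice(conceal_vals, p=config.concealment_probs))
        clutch = int(rng.choice(clutch_vals, p=clutch_p))
        nest_height = float(rng.uniform(0.3, 1.5))  # metres above ground
        found_day = int(rng.integers(10, 41))
        lo, hi = config.incubation_remaining
        hatch_day = found_day + int(rng.integers(lo, hi + 1))
        fledge_day = hatch_day + config.nestling_period
        cov = {"nnd": float(t["nnd"]), "concealment": float(concealment)}
        h_egg = _hazard(df["egg_base"], df.get("egg_coefs", {}), centers, cov)
        h_nest = _hazard(df["nestling_base"], df.get("nestling_coefs", {}), centers, cov)

        # latent daily failure process
        fail_day = np.nan
        day = found_day
        while day < fledge_day:
            h = h_egg if day < hatch_day else h_nest
            if rng.random() < h:
                fail_day = day + 1.0  # nest lost during this day
                break
            day += 1
        failed = np.isfinite(fail_day)
        fail_at_egg = failed and fail_day <= hatch_day

        # brood: hatching success then daily partial reduction (floor 1)
        brood_initial = 0
        daily_counts = {}
        if not fail_at_egg:
            brood_initial = int(rng.binomial(clutch, 1.0 - config.hatch_fail_prob))
            brood_initial = max(brood_initial, 1)
            count = brood_initial
            end = int(fail_day) if failed else fledge_day
            for d in range(hatch_day, max(hatch_day, end) + 1):
                if count > 1 and rng.random() < config.brood_reduction_daily * count:
                    count -= 1
                daily_counts[d] = count
        fail_status = "depredated" if rng.random() < 0.7 else "damaged"

        # visit schedule: every visit_interval_max days + day-7/10 checks
        sched = set(range(found_day, fledge_day + 2, config.visit_interval_max))
        sched.update({hatch_day + 7, hatch_day + 10})
        end_obs = fail_day if failed else fledge_day
        days = sorted(d for d in sched if d < end_obs)
        after = [d for d in sched if d >= end_obs]
        if after:
            days.append(min(after))
        nest_visits = []
        for d in days:
            if failed and d >= fail_day:
                status, ne, nn = fail_status, np.nan, np.nan
            elif d < hatch_day:
                status, ne, nn = "active-eggs", clutch, np.nan
            elif d < fledge_day:
                c = daily_counts.get(d, brood_initial)
                status, ne, nn = "active-nestlings", np.nan, c
            else:
                status, ne, nn = "empty-intact", np.nan, np.nan
            nest_visits.append(
                {"nest_id": nest_id, "day": d, "status": status,
                 "n_eggs": ne, "n_nestlings": nn}
            )
        visit_rows.extend(nest_visits)

        # observed hatch estimate: midpoint of the straddling visits
        vdays = [v["day"] for v in nest_visits]
        vstat = [v["status"] for v in nest_visits]
        obs_hatch = np.nan
        for i2, s2 in enumerate(vstat):
            if s2 == "active-nestlings":
                obs_hatch = (
                    0.5 * (vdays[i2 - 1] + vdays[i2])
                    if i2 > 0 and vstat[i2 - 1] == "active-eggs"
                    else float(vdays[i2])
                )
                break

        if failed:
            fate = "failed-egg" if fail_at_egg else "failed-nestling"
        else:
            fate = "fledged"
        nest_rows.append(
            {
                "nest_id": nest_id,
                "territory_id": t["territory_id"],
                "farm_id": t["farm_id"],
                "year": t["year"],
                "found_day": found_day,
                "hatch_day": obs_hatch,
                "concealment": concealment,
                "clutch": clutch,
                "nest_height": nest_height,
                "brood_initial": brood_initial if not fail_at_egg else np.nan,
                "nnd": float(t["nnd"]),
                "ntnd": float(t["ntnd"]),
                "true_hatch_day": hatch_day,
                "true_fail_day": fail_day,
                "true_fate": fate,
                "true_egg_hazard": h_egg,
                "true_nestling_hazard": h_nest,
                "n_alive_fledge": daily_counts.get(fledge_day - 1, np.nan)
                if fate == "fledged"
                else np.nan,
            }
        )
    nests = pd.DataFrame(nest_rows)
    visits = pd.DataFrame(
        visit_rows, columns=["nest_id", "day", "status", "n_eggs", "n_nestlings"]
    )
    return nests, visits


# ---------------------------------------------------------------------------
# provisioning watches and nestling masses


def _watch_predictor(coefs, row):
    eta = coefs.get("intercept", 0.0)
    for name, c in coefs.items():
        if name in ("intercept", "sd") or c == 0.0:
            continue
        if name.startswith("nnd_x_"):
            other = name[len("nnd_x_"):]
            eta += c * row["nnd"] * row[other]
        else:
            eta += c * row[name]
    return eta


def gen_watches(nests: pd.DataFrame, farms: pd.DataFrame, config: SimConfig, rng=None):
    """Provisioning-watch table for nests with nestlings aged 2-7 days."""
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    cp = config.covariate_params
    coefs = config.provisioning_coefs
    mgmt = farms.set_index("farm_id")["management"]
    # farm-year corvid abundance, one draw per farm-year
    abund = {}
    rows = []
    for _, nest in nests.iterrows():
        if nest["true_fate"] == "failed-egg":
            continue
        hatch = nest["true_hatch_day"]
        last_age = (
            config.nestling_period
            if nest["true_fate"] == "fledged"
            else int(nest["true_fail_day"] - hatch)
        )
        max_age = min(7, last_age - 1)
        if max_age < 2:
            continue
        ages = sorted(
            rng.choice(np.arange(2, max_age + 1),
                       size=min(int(rng.integers(1, 4)), max_age - 1),
                       replace=False)
        )
        key = (nest["farm_id"], nest["year"])
        if key not in abund:
            abund[key] = float(
                rng.lognormal(cp["corvid_abundance_logmean"],
                              cp["corvid_abundance_logsd"])
            )
        for age in ages:
            row = {
                "nest_id": nest["nest_id"],
                "farm_id": nest["farm_id"],
                "year": nest["year"],
                "day": hatch + age,
                "nestling_age": float(age),
                "brood_size": float(nest["brood_initial"]),
                "nnd": nest["nnd"],
                "corvid_activity": float(rng.poisson(cp["corvid_activity_mean"])),
                "corvid_abundance": abund[key],
                "invertebrates": float(
                    rng.lognormal(cp["invertebrates_logmean"], cp["invertebrates_logsd"])
                ),
                "temperature": float(
                    rng.normal(cp["temperature_mean"], cp["temperature_sd"])
                ),
                "time_of_day": float(rng.uniform(6.0, 12.0)),
                "management": mgmt[nest["farm_id"]],
            }
            row["temperature_sq"] = (row["temperature"] - 15.0) ** 2
            row["time_of_day_sq"] = (row["time_of_day"] - 9.0) ** 2
            row["year_2008"] = float(row["year"] == 2008)
            row["management_organic"] = float(row["management"] == "organic")
            eta = _watch_predictor(coefs, row)
            row["trips_per_hour"] = eta + float(rng.normal(0.0, coefs.get("sd", 0.0)))
            rows.append(row)
    if not rows:
        warnings.warn("no nests eligible for provisioning watches; empty table")
        return pd.DataFrame(
            columns=["nest_id", "farm_id", "year", "day", "nestling_age",
                     "brood_size", "nnd", "corvid_activity", "corvid_abundance",
                     "invertebrates", "temperature", "time_of_day", "management",
                     "temperature_sq", "time_of_day_sq", "year_2008",
                     "management_organic", "trips_per_hour"]
        )
    return pd.DataFrame(rows)


def gen_masses(nests: pd.DataFrame, config: SimConfig, rng=None):
    """Two timed mass measurements per nestling (linear growth phase).

    Second mass follows the configured linear predictor — first mass,
    hours elapsed, age and NND (in km) — plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    mc = config.mass_coefs
    rows = []
    for _, nest in nests.iterrows():
        if nest["true_fate"] == "failed-egg":
            continue
        hatch = nest["true_hatch_day"]
        last_age = (
            config.nestling_period
            if nest["true_fate"] == "fledged"
            else int(nest["true_fail_day"] - hatch)
        )
        if last_age < 5:
            continue  # needs both measurements inside ages 2-7
        n_young = int(nest["brood_initial"]) if np.isfinite(nest["brood_initial"]) else 0
        for j in range(n_young):
            age1 = int(rng.integers(2, 4))
            age2 = min(age1 + int(rng.integers(2, 4)), min(7, last_age - 1))
            if age2 <= age1:
                continue
            hours = 24.0 * (age2 - age1) + float(rng.uniform(-2.0, 2.0))
            tod2 = float(rng.uniform(6.0, 18.0))
            first = 4.0 + 1.6 * age1 + float(rng.normal(0.0, 0.6))
            row = {
                "nest_id": nest["nest_id"],
                "nestling_id": f"{nest['nest_id']}-{j + 1}",
                "year": nest["year"],
                "age_first": float(age1),
                "age_second": float(age2),
                "hours_between": hours,
                "time_of_day_second": tod2,
                "first_mass": first,
                "nnd": nest["nnd"],
                "year_2008": float(nest["year"] == 2008),
            }
            eta = (
                mc.get("intercept", 0.0)
                + mc.get("first_mass", 0.0) * first
                + mc.get("hours_between", 0.0) * hours
                + mc.get("age_second", 0.0) * age2
                + mc.get("time_of_day_second", 0.0) * tod2
                + mc.get("year_2008", 0.0) * row["year_2008"]
                + mc.get("nnd_km", 0.0) * nest["nnd"] / 1000.0
            )
            row["second_mass"] = eta + float(rng.normal(0.0, mc.get("sd", 0.0)))
            rows.append(row)
    if not rows:
        warnings.warn("no nestlings eligible for mass measurements; empty table")
        return pd.DataFrame(
            columns=["nest_id", "nestling_id", "year", "age_first", "age_second",
                     "hours_between", "time_of_day_second", "first_mass", "nnd",
                     "year_2008", "second_mass"]
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


@dataclass
class SimulatedData:
    """All generated tables plus the configuration that produced them."""

    config: SimConfig
    farms: pd.DataFrame
    boundaries: pd.DataFrame
    territories: pd.DataFrame
    counts: pd.DataFrame
    nests: pd.DataFrame
    visits: pd.DataFrame
    watches: pd.DataFrame
    masses: pd.DataFrame

    def to_csv(self, outdir) -> None:
        """Write every table as CSV with a seed comment header line."""
        from .io import write_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("farms", "boundaries", "territories", "counts", "nests",
                     "visits", "watches", "masses"):
            write_table(getattr(self, name), outdir / f"{name}.csv",
                        seed=self.config.seed)


def simulate_dataset(config: SimConfig | None = None) -> SimulatedData:
    """Run the full generative chain under one seed."""
    config = SimConfig() if config is None else config
    farms, boundaries = gen_farms(config)
    territories, counts = gen_territories(farms, boundaries, config)
    nests, visits = gen_nests(territories, config)
    if len(nests):
        watches = gen_watches(nests, farms, config)
        masses = gen_masses(nests, config)
    else:  # pragma: no cover - degenerate config
        warnings.warn("no nests generated")
        watches = gen_watches(nests.assign(true_fate=[]), farms, config)
        masses = gen_masses(nests.assign(true_fate=[]), config)
    return SimulatedData(config, farms, boundaries, territories, counts,
                         nests, visits, watches, masses)
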
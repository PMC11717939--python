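"""Grid-cell orchestration: the daily crop-grass-livestock loop.

One simulation covers one grid cell.  Land is split into grass-, crop-,
tree- and settlement-dominated shares; each cropped crop and the grassland
run on their own soil column.  The daily loop is fixed:

    weather -> reference ET -> per-activity soil water & N -> grass growth and
    season transitions -> crop phenology/growth/harvest -> feed-store update ->
    energy demand/supply/stress -> concentrate purchase -> herd demography,
    weights and production -> sell-out -> manure routing (fertilizes next day)

Everything is deterministic given the scenario config and seed.  Results are
a daily table and an annual table (yields, biomass, herd, milk, meat, CH4,
leached N, sWSI).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import crop as crop_mod
from . import feed as feed_mod
from . import grassland as grass_mod
from . import herd as herd_mod
from . import metrics as metrics_mod
from . import soil as soil_mod
from .forcing import (ClimateDelta, ZoneClimateSpec, ZONE_SPECS,
                      apply_climate_delta, generate_weather, read_weather_csv)

KG_PER_HA_PER_G_M2 = 10.0  # g DM m-2 -> kg DM ha-1

#: Background net N mineralization (kg N ha-1 day-1).
DEFAULT_MINERALIZATION = 0.05
#: N content of consumed feed DM (kg N per kg DM), for manure accounting.
DEFAULT_FEED_N_CONTENT = 0.012

PRODUCTION_LEVELS = ("potential", "water_limited", "nutrient_limited")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CellConfig:
    """Land-use shares of the cell and crop shares of the cropland."""

    share_grass: float = 0.5
    share_crop: float = 0.3
    share_tree: float = 0.1
    share_settlement: float = 0.05
    share_other: float = 0.05
    cell_area_ha: float = 1000.0

    def __post_init__(self) -> None:
        shares = (self.share_grass, self.share_crop, self.share_tree,
                  self.share_settlement, self.share_other)
        if any(s < 0 for s in shares):
            raise ConfigError("land-use shares must be >= 0")
        if abs(sum(shares) - 1.0) > 1e-6:
            raise ConfigError(f"land-use shares sum to {sum(shares)}, expected 1")


@dataclass
class CropActivityConfig:
    cultivar: str = "millet"
    area_share: float = 1.0          # share of the cropland area
    window: crop_mod.SowingWindow = field(
        default_factory=lambda: crop_mod.SowingWindow(160, 210))
    fertilizer_n: float = 0.0        # kg N ha-1 applied at sowing


@dataclass
class Scenario:
    """Full configuration of a single-cell run."""

    zone: str = "sahelian"
    years: int = 10
    seed: int = 1
    start_year: int = 2001
    latitude: float = 13.0
    climate: ZoneClimateSpec | None = None
    delta: ClimateDelta = field(default_factory=ClimateDelta)
    weather_file: str | None = None      # overrides the synthetic generator
    production_level: str = "nutrient_limited"
    cell: CellConfig = field(default_factory=CellConfig)
    crops: dict = field(default_factory=dict)   # name -> CropActivityConfig
    grass: grass_mod.GrassParams | None = None
    demography: herd_mod.DemographyParams = field(
        default_factory=herd_mod.DemographyParams)
    market: feed_mod.MarketParams = field(default_factory=feed_mod.MarketParams)
    herd_counts: tuple = (15.0, 10.0, 5.0, 15.0, 12.0, 20.0)
    herd_weights: tuple = (40.0, 120.0, 280.0, 40.0, 110.0, 250.0)
    initial_cash: float = 500.0
    initial_residue_dm: float = 0.0      # kg DM in store at start
    residue_decay_rate: float = 0.001
    maintenance_mj: float = feed_mod.DEFAULT_MAINTENANCE_MJ
    intake_fraction: float = feed_mod.DEFAULT_INTAKE_FRACTION
    feed_n_content: float = DEFAULT_FEED_N_CONTENT
    manure_cropland_share: float = 0.5
    mineralization: float = DEFAULT_MINERALIZATION
    p_crit: float = soil_mod.DEFAULT_P_CRIT
    leach_coeff: float = soil_mod.DEFAULT_LEACH_COEFF
    debug_invariants: bool = False

    def __post_init__(self) -> None:
        if self.production_level not in PRODUCTION_LEVELS:
            raise ConfigError(
                f"production_level must be one of {PRODUCTION_LEVELS}")
        if self.years < 1:
            raise ConfigError("years must be >= 1")
        if self.climate is None:
            self.climate = ZoneClimateSpec(
                **{**asdict(ZONE_SPECS[self.zone]), "seed": self.seed})
        if self.grass is None:
            self.grass = grass_mod.ZONE_GRASS[self.zone]
        if not self.crops:
            self.crops = default_crop_mix(self.zone)
        total = sum(c.area_share for c in self.crops.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"crop area shares sum to {total}, expected 1")


def default_crop_mix(zone: str) -> dict:
    """The zone crop mixes: millet+sorghum (Sahelian), maize+sorghum (Sudanian).

    Maize receives 15 kg N ha-1; millet and sorghum are unfertilized.
    """
    if zone == "sahelian":
        w = crop_mod.SowingWindow(160, 210)
        return {
            "millet": CropActivityConfig("millet", 0.6, w, 0.0),
            "sorghum": CropActivityConfig("sorghum", 0.4, w, 0.0),
        }
    w = crop_mod.SowingWindow(135, 185)
    return {
        "maize": CropActivityConfig("maize", 0.5, w, 15.0),
        "sorghum": CropActivityConfig("sorghum", 0.5, w, 0.0),
    }


@dataclass
class SimulationResult:
    """Daily and annual output tables plus the resolved scenario metadata."""

    daily: pd.DataFrame
    annual: pd.DataFrame
    metadata: dict


# ---------------------------------------------------------------------------
# internal per-activity bookkeeping

class _CropActivity:
    def __init__(self, name: str, cfg: CropActivityConfig, area_ha: float):
        self.name = name
        self.cfg = cfg
        self.params = crop_mod.CULTIVARS[
            crop_mod.CULTIVAR_ALIASES.get(cfg.cultivar, cfg.cultivar)]
        self.area_ha = area_ha
        self.state = crop_mod.CropState()
        self.soil = soil_mod.default_profile(initial_fraction_fc=0.5)
        self.sow_doy: int = -1


def _season_calendar(precip: np.ndarray, years: np.ndarray, doys: np.ndarray,
                     window: crop_mod.SowingWindow) -> dict:
    """Per-year rains-onset (sowing-rule) and dry-season-onset day indices."""
    out = {}
    for y in np.unique(years):
        sel = years == y
        p = precip[sel]
        onset_doy = crop_mod.determine_sowing_date(p, window)
        # dry-season onset: first post-onset 30-day window totalling < 5 mm
        dry_doy = None
        for d in range(onset_doy + 30, len(p) - 29):
            if p[d:d + 30].sum() < 5.0:
                dry_doy = d + 1
                break
        if dry_doy is None:
            dry_doy = len(p)  # last day of the year
        out[int(y)] = (onset_doy, dry_doy)
    return out


def run_simulation(scenario: Scenario) -> SimulationResult:
    """Run the integrated daily loop; see the module docstring for the order."""
    sc = scenario
    if sc.weather_file is not None:
        weather = read_weather_csv(sc.weather_file, latitude=sc.latitude)
    else:
        weather = generate_weather(sc.climate, sc.years, start_year=sc.start_year,
                                   latitude=sc.latitude)
    if (sc.delta.delta_tmax, sc.delta.delta_tmin, sc.delta.precip_factor) != (0, 0, 1):
        weather = apply_climate_delta(weather, sc.delta)

    df = weather.data
    dates = df.index
    arr = {c: df[c].to_numpy() for c in df.columns}
    years = dates.year.to_numpy()
    doys = dates.dayofyear.to_numpy()
    n_days = len(dates)

    cell = sc.cell
    crop_area = cell.share_crop * cell.cell_area_ha
    grass_area = cell.share_grass * cell.cell_area_ha

    crops = [_CropActivity(name, cfg, crop_area * cfg.area_share)
             for name, cfg in sc.crops.items()]
    grass_params = sc.grass
    grass_state = grass_mod.GrassState(root_depth=0.1, dormant=True)
    if grass_params.habit == "perennial":
        grass_state.reserve = 150.0  # carry-over reserve entering the run
    grass_soil = soil_mod.default_profile(initial_fraction_fc=0.5)
    grass_calendar = _season_calendar(
        arr["precip"], years, doys,
        crop_mod.SowingWindow(next(iter(sc.crops.values())).window.start_doy,
                              next(iter(sc.crops.values())).window.end_doy))
    herd = herd_mod.HerdState(np.array(sc.herd_counts),
                              np.array(sc.herd_weights), sc.initial_cash)
    livestock_on = herd.total_count > 0
    store = feed_mod.FeedStore(residue_dm=sc.initial_residue_dm,
                               me_grass=grass_params.me_content)
    demog = sc.demography
    market = sc.market

    manure_crop_kgha = 0.0   # produced yesterday, applied today (per crop ha)
    manure_grass_kgha = 0.0

    daily_rows = []
    harvest_log = []
    current_year = None

    days = list(weather.iter_days())
    for i in range(n_days):
        date = dates[i]
        y, doy = int(years[i]), int(doys[i])
        day = days[i]
        et0 = soil_mod.reference_et(day, sc.latitude)
        rain = float(arr["precip"][i])

        if y != current_year:
            current_year = y
            sel = years == y
            p_year = arr["precip"][sel]
            for c in crops:
                c.sow_doy = crop_mod.determine_sowing_date(p_year, c.cfg.window)

        # --- grassland activity -------------------------------------------
        onset_doy, dry_doy = grass_calendar[y]
        g_transp = 0.0
        g_hay_kgha = 0.0
        g_state = grass_state
        _, hay = grass_mod.season_transition(
            g_state, grass_params,
            dry_season_onset=(doy == dry_doy and not g_state.dormant),
            rains_onset=(doy == onset_doy))
        g_hay_kgha = hay * KG_PER_HA_PER_G_M2
        infil, runoff = soil_mod.partition_rainfall(rain, grass_soil)
        g_wf = 1.0
        if not g_state.dormant:
            if sc.production_level == "potential":
                g_wf = 1.0
            else:
                g_wf = soil_mod.drought_factor(grass_soil, g_state.root_depth,
                                               sc.p_crit)
            g_state, g_transp = grass_mod.step_grass_growth(
                g_state, day, g_wf, 1.0, grass_params, et0)
        f_int_g = crop_mod.light_interception(g_state.lai, grass_params.k_ext)
        grass_soil, g_flux = soil_mod.step_soil_water(
            grass_soil, infil, et0 * (1.0 - f_int_g), g_transp,
            g_state.root_depth)
        g_flux.runoff = runoff
        grass_soil, _, g_leach, _ = soil_mod.step_soil_nitrogen(
            grass_soil, sc.mineralization + manure_grass_kgha, 0.0,
            g_flux.drainage, sc.leach_coeff)

        # --- crop activities ----------------------------------------------
        crop_transp = 0.0
        crop_leach = 0.0
        residue_feed_in = 0.0  # kg DM into the feed store today
        for c in crops:
            infil, runoff_c = soil_mod.partition_rainfall(rain, c.soil)
            if c.state.stage is crop_mod.Stage.UNSOWN and doy == c.sow_doy:
                c.state.sow(doy, c.params.sla)
                c.soil, *_ = soil_mod.step_soil_nitrogen(
                    c.soil, c.cfg.fertilizer_n, 0.0, 0.0, sc.leach_coeff)
            transp = 0.0
            n_in = sc.mineralization + manure_crop_kgha
            if c.state.stage in (crop_mod.Stage.SOWN, crop_mod.Stage.EMERGED,
                                 crop_mod.Stage.ANTHESIS):
                crop_mod.step_phenology(c.state, day.tmean, c.params)
            if c.state.stage in (crop_mod.Stage.EMERGED, crop_mod.Stage.ANTHESIS):
                if sc.production_level == "potential":
                    wf = 1.0
                else:
                    wf = soil_mod.drought_factor(c.soil, c.state.root_depth,
                                                 sc.p_crit)
                if sc.production_level == "nutrient_limited":
                    # prospective water-limited assimilation sets the N demand
                    f_int = crop_mod.light_interception(c.state.lai,
                                                        c.params.k_ext)
                    ddm_pot = (c.params.rue * f_int
                               * crop_mod.PAR_FRACTION * day.srad * wf)
                    n_dem = ddm_pot * 10.0 * c.params.n_demand_per_dm
                    c.soil, _, _, nf = soil_mod.step_soil_nitrogen(
                        c.soil, n_in, n_dem, 0.0, sc.leach_coeff)
                    n_in = 0.0
                else:
                    nf = 1.0
                c.state, transp, _ = crop_mod.step_crop_growth(
                    c.state, day, wf, nf, c.params, et0)
                c.state.cum_transpiration += transp
            f_int = crop_mod.light_interception(c.state.lai, c.params.k_ext)
            c.soil, flux = soil_mod.step_soil_water(
                c.soil, infil, et0 * (1.0 - f_int), transp, c.state.root_depth)
            c.soil, _, leach, _ = soil_mod.step_soil_nitrogen(
                c.soil, n_in, 0.0, flux.drainage, sc.leach_coeff)
            crop_transp += flux.transpiration * c.cfg.area_share
            crop_leach += leach * c.cfg.area_share
            if c.state.stage is crop_mod.Stage.MATURE:
                yld, res_tot, res_feed, c.state = crop_mod.harvest(
                    c.state, c.params)
                harvest_log.append({"date": date, "year": y, "crop": c.name,
                                    "yield_kg_ha": yld,
                                    "agb_kg_ha": yld + res_tot,
                                    "residue_kg_ha": res_tot})
                residue_feed_in += res_feed * c.area_ha

        # --- feed store and energy balance --------------------------------
        store = feed_mod.update_feed_store(
            store, g_hay_kgha * grass_area, residue_feed_in,
            sc.residue_decay_rate)
        grazeable_kg = max(0.0, g_state.shoot - grass_params.ungrazable_residual) \
            * KG_PER_HA_PER_G_M2 * grass_area
        store.grass_dm = grazeable_kg

        milk = meat = ch4 = 0.0
        stress = 1.0
        demand = supply = 0.0
        conc_cost = 0.0
        sold_revenue = offtake_revenue = milk_revenue = 0.0
        dm_intake = 0.0
        if livestock_on:
            demand = feed_mod.energy_demand(herd, sc.maintenance_mj)
            cap = feed_mod.max_intake_dm(herd, sc.intake_fraction)
            supply, store, drawn = feed_mod.energy_supply(store, cap, demand)
            if drawn["grass"] > 0 and grass_area > 0:
                per_m2 = drawn["grass"] / (grass_area * KG_PER_HA_PER_G_M2)
                g_state, removed = grass_mod.graze(
                    g_state, per_m2, grass_params.ungrazable_residual)
            dm_intake = sum(drawn.values())
            stress = feed_mod.energy_stress(supply, demand)
            if supply < demand and herd.cash > 0:
                dm_cap_left = max(0.0, cap - dm_intake)
                bought, conc_cost, cash_left = feed_mod.concentrate_purchase(
                    demand - supply, herd.cash, market, store.me_concentrate)
                bought = min(bought, dm_cap_left)
                conc_cost = bought * market.concentrate_price
                herd.cash -= conc_cost
                supply += bought * store.me_concentrate
                dm_intake += bought
                stress = feed_mod.energy_stress(supply, demand)

            herd, flows = herd_mod.step_demography(herd, demog, stress)
            offtake_weight = float(
                (flows.offtake * herd.mean_weight).sum())
            offtake_revenue = offtake_weight * market.animal_price
            meat = herd_mod.meat_production(offtake_weight,
                                            demog.carcass_fraction)
            herd = herd_mod.update_live_weights(herd, demog, stress)
            milk = herd_mod.milk_production(herd, demog, stress)
            milk_revenue = milk * market.milk_price
            herd.cash += offtake_revenue + milk_revenue
            ch4 = herd_mod.methane_emission(dm_intake, demog.ch4_yield)
            n_intake = dm_intake * sc.feed_n_content
            manure_crop_kg, manure_grass_kg = herd_mod.manure_nitrogen(
                n_intake, demog.n_excretion_fraction, sc.manure_cropland_share)
            manure_crop_kgha = manure_crop_kg / crop_area if crop_area > 0 else 0.0
            manure_grass_kgha = (manure_grass_kg / grass_area
                                 if grass_area > 0 else 0.0)

            unmet = max(0.0, demand - supply)
            sold, sold_revenue, herd = feed_mod.sell_out_decision(
                herd, stress, unmet, market,
                feed_mod.per_head_demand(herd, sc.maintenance_mj))
            meat += herd_mod.meat_production(
                float((sold * herd.mean_weight).sum()), demog.carcass_fraction)

        grass_state = g_state
        if sc.debug_invariants:
            _audit_day(date, grass_soil, [c.soil for c in crops], herd, store,
                       g_state)
        daily_rows.append({
            "date": date, "year": y, "doy": doy,
            "precip": rain, "tmean": day.tmean, "et0": et0,
            "grass_shoot_kg_ha": g_state.shoot * KG_PER_HA_PER_G_M2,
            "grass_reserve_kg_ha": g_state.reserve * KG_PER_HA_PER_G_M2,
            "grass_dormant": int(g_state.dormant),
            "grass_transp_mm": g_flux.transpiration,
            "crop_transp_mm": crop_transp,
            "soil_water_grass_mm": grass_soil.total_water,
            "mineral_n_grass": grass_soil.mineral_n,
            "leached_n_kg_ha": crop_leach * cell.share_crop
            + g_leach * cell.share_grass,
            "residue_store_kg": store.residue_dm,
            "herd_total": herd.total_count,
            "herd_live_weight_kg": herd.total_live_weight,
            "energy_demand_mj": demand, "energy_supply_mj": supply,
            "energy_stress": stress,
            "milk_kg": milk, "meat_kg": meat, "ch4_kg": ch4,
            "dm_intake_kg": dm_intake,
            "cash": herd.cash,
            **{f"count_{cls.name.lower()}": float(herd.count[cls])
               for cls in herd_mod.HerdClass},
        })

    daily = pd.DataFrame(daily_rows).set_index("date")
    annual = _annual_table(daily, harvest_log, sc, grass_calendar)
    metadata = {"config_hash": scenario_hash(sc), "seed": sc.seed,
                "zone": sc.zone, "years": sc.years,
                "production_level": sc.production_level}
    return SimulationResult(daily, annual, metadata)


def _audit_day(date, grass_soil, crop_soils, herd, store, grass_state) -> None:
    """Invariant audit for --debug-invariants runs; raises with day and module."""
    for label, profile in [("grassland", grass_soil)] + \
            [(f"crop[{i}]", s) for i, s in enumerate(crop_soils)]:
        for j, layer in enumerate(profile.layers):
            if not (layer.wp - 1e-6 <= layer.water <= layer.sat + 1e-6):
                raise RuntimeError(
                    f"{date.date()} soil_water/{label}: layer {j} water "
                    f"{layer.water} outside [wp, sat]")
        if profile.mineral_n < -1e-9:
            raise RuntimeError(f"{date.date()} soil_n/{label}: negative N pool")
    if (herd.count < 0).any():
        raise RuntimeError(f"{date.date()} herd: negative class count")
    if min(store.grass_dm, store.residue_dm, store.concentrate_dm) < -1e-9:
        raise RuntimeError(f"{date.date()} feed: negative pool")
    if grass_state.shoot < -1e-9 or grass_state.reserve < -1e-9:
        raise RuntimeError(f"{date.date()} grassland: negative pool")


def _annual_table(daily: pd.DataFrame, harvest_log: list, sc: Scenario,
                  grass_calendar: dict) -> pd.DataFrame:
    harvests = pd.DataFrame(harvest_log)
    rows = []
    for y, g in daily.groupby("year"):
        row = {"year": int(y)}
        for name in sc.crops:
            if len(harvests):
                h = harvests[(harvests["year"] == y) & (harvests["crop"] == name)]
            else:
                h = harvests
            row[f"yield_{name}_kg_ha"] = float(h["yield_kg_ha"].sum()) if len(h) else 0.0
            row[f"agb_{name}_kg_ha"] = float(h["agb_kg_ha"].sum()) if len(h) else 0.0
        row["grass_peak_agb_kg_ha"] = float(g["grass_shoot_kg_ha"].max())
        row["rain_mm"] = float(g["precip"].sum())
        onset, dry = grass_calendar[int(y)]
        season = g[(g["doy"] >= onset) & (g["doy"] <= dry)]
        row["season_rain_mm"] = float(season["precip"].sum())
        row["season_transp_mm"] = float(
            (season["crop_transp_mm"] * sc.cell.share_crop
             + season["grass_transp_mm"] * sc.cell.share_grass).sum())
        row["herd_total_mean"] = float(g["herd_total"].mean())
        row["herd_total_end"] = float(g["herd_total"].iloc[-1])
        row["milk_kg"] = float(g["milk_kg"].sum())
        row["meat_kg"] = float(g["meat_kg"].sum())
        row["ch4_kg"] = float(g["ch4_kg"].sum())
        row["leached_n_kg_ha"] = float(g["leached_n_kg_ha"].sum())
        row["mean_energy_stress"] = float(g["energy_stress"].mean())
        rows.append(row)
    annual = pd.DataFrame(rows).set_index("year")
    if len(annual) >= 2:
        ws = annual["season_transp_mm"] - annual["season_rain_mm"]
        if ws.std(ddof=1) > 0:
            annual["swsi"] = metrics_mod.swsi(annual["season_transp_mm"],
                                              annual["season_rain_mm"])
        else:
            annual["swsi"] = 0.0
    else:
        annual["swsi"] = 0.0
    return annual


def aggregate_cell(per_activity_outputs: dict, cell: CellConfig,
                   shares: dict | None = None) -> dict:
    """Area-weighted cell aggregation of per-ha activity outputs.

    ``per_activity_outputs`` maps activity name to output per ha of that
    activity; ``shares`` maps the same names to area shares (defaults to the
    cell's grass/crop shares; inert shares contribute zero).
    """
    if shares is None:
        shares = {"grass": cell.share_grass, "crop": cell.share_crop}
    total_share = sum(shares.values()) + cell.share_tree \
        + cell.share_settlement + cell.share_other
    unused = 1.0 - sum(shares.values())
    if not (abs(total_share - 1.0) <= 1e-6 or 0 <= unused <= 1 + 1e-6):
        raise ConfigError("activity shares inconsistent with the cell")
    per_cell_ha = sum(per_activity_outputs[k] * s for k, s in shares.items())
    return {"per_cell_ha": per_cell_ha,
            "total": per_cell_ha * cell.cell_area_ha}


def scenario_hash(sc: Scenario) -> str:
    payload = json.dumps(asdict(sc), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_outputs(result: SimulationResult, out_dir) -> list[Path]:
    """Write daily.csv, annual.csv and run_metadata.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = [out / "daily.csv", out / "annual.csv", out / "run_metadata.json"]
    result.daily.to_csv(paths[0], float_format="%.6f")
    result.annual.to_csv(paths[1], float_format="%.6f")
    paths[2].write_text(json.dumps(result.metadata, indent=2, default=str))
    return paths
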
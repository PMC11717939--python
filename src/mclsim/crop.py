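"""Radiation-use-efficiency crop growth for maize, millet and sorghum.

Phenology accumulates thermal time above a base temperature and promotes the
crop through sown -> emerged -> anthesis -> mature.  Daily dry-matter gain is
RUE x intercepted PAR x min(water, nitrogen) stress and is partitioned to
leaf/stem/root/storage by a development-stage table.  Sowing follows the
regional rule: sow on the first day of the sowing window whose trailing
five-day rainfall reaches 20 mm, else on the window's last day.

The shipped cultivar parameter sets (CIVT millet, EVDT97 maize, Kadaga
sorghum) are illustrative, not field-calibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .forcing import WeatherDay

PAR_FRACTION = 0.5  # photosynthetically active fraction of global radiation

ORGANS = ("leaf", "stem", "root", "storage")


class Stage(Enum):
    UNSOWN = 0
    SOWN = 1
    EMERGED = 2
    ANTHESIS = 3
    MATURE = 4


@dataclass(frozen=True)
class SowingWindow:
    """Sowing window with the cumulative-rainfall trigger rule."""

    start_doy: int
    end_doy: int
    rain_threshold: float = 20.0  # mm over the trailing accumulation period
    accum_days: int = 5

    def __post_init__(self) -> None:
        if self.start_doy >= self.end_doy:
            raise ValueError("start_doy must precede end_doy")
        if self.rain_threshold <= 0:
            raise ValueError("rain_threshold must be > 0")


@dataclass(frozen=True)
class CropParams:
    """Cultivar parameters; partition_table maps development-stage breakpoints
    (tt_sum / tt_maturity) to (leaf, stem, root, storage) fractions summing to 1.
    """

    name: str
    t_base: float                  # degC
    tt_emergence: float            # degC day
    tt_anthesis: float
    tt_maturity: float
    rue: float                     # g DM MJ-1 PAR
    k_ext: float
    sla: float                     # m2 leaf g-1 DM
    partition_table: tuple[tuple[float, tuple[float, float, float, float]], ...]
    max_root_depth: float          # m
    root_growth_rate: float        # m per degC day
    hi_max: float
    n_demand_per_dm: float         # kg N per kg DM
    residue_feed_fraction: float = 0.5
    topt_ceiling: float | None = None  # optional cap on daily thermal time

    def __post_init__(self) -> None:
        if not 0 < self.tt_emergence < self.tt_anthesis < self.tt_maturity:
            raise ValueError("require 0 < tt_emergence < tt_anthesis < tt_maturity")
        if not 0 <= self.hi_max <= 1:
            raise ValueError("hi_max must lie in [0, 1]")
        for dvs, fr in self.partition_table:
            if abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError(f"partition fractions at dvs {dvs} must sum to 1")

    def partition_at(self, dvs: float) -> tuple[float, float, float, float]:
        for upper, fractions in self.partition_table:
            if dvs <= upper:
                return fractions
        return self.partition_table[-1][1]


# Generic vegetative/reproductive partitioning shared by the cereals.
_CEREAL_TABLE = (
    (0.30, (0.55, 0.15, 0.30, 0.00)),
    (0.55, (0.35, 0.40, 0.20, 0.05)),
    (0.75, (0.10, 0.25, 0.05, 0.60)),
    (1.00, (0.00, 0.05, 0.00, 0.95)),
)

#: Illustrative cultivar defaults (not field-calibrated).
CULTIVARS = {
    "millet": CropParams(
        name="millet", t_base=10.0, tt_emergence=60.0, tt_anthesis=700.0,
        tt_maturity=1100.0, rue=2.4, k_ext=0.55, sla=0.022,
        partition_table=_CEREAL_TABLE, max_root_depth=1.2,
        root_growth_rate=0.0012, hi_max=0.35, n_demand_per_dm=0.012),
    "sorghum": CropParams(
        name="sorghum", t_base=9.0, tt_emergence=70.0, tt_anthesis=800.0,
        tt_maturity=1250.0, rue=2.8, k_ext=0.55, sla=0.020,
        partition_table=_CEREAL_TABLE, max_root_depth=1.3,
        root_growth_rate=0.0012, hi_max=0.40, n_demand_per_dm=0.014),
    "maize": CropParams(
        name="maize", t_base=8.0, tt_emergence=80.0, tt_anthesis=850.0,
        tt_maturity=1350.0, rue=3.2, k_ext=0.60, sla=0.018,
        partition_table=_CEREAL_TABLE, max_root_depth=1.1,
        root_growth_rate=0.0012, hi_max=0.50, n_demand_per_dm=0.018),
}
#: Calibration-cultivar aliases from the study region.
CULTIVAR_ALIASES = {"CIVT": "millet", "EVDT97": "maize", "Kadaga": "sorghum"}


@dataclass
class CropState:
    """Per-field crop state; biomass pools in g DM m-2."""

    stage: Stage = Stage.UNSOWN
    tt_sum: float = 0.0
    lai: float = 0.0
    biomass: dict = field(default_factory=lambda: {o: 0.0 for o in ORGANS})
    root_depth: float = 0.0
    cum_transpiration: float = 0.0
    sowing_doy: int = -1

    @property
    def agb(self) -> float:
        """Above-ground biomass, g DM m-2."""
        return self.biomass["leaf"] + self.biomass["stem"] + self.biomass["storage"]

    def sow(self, doy: int, sla: float = 0.02) -> None:
        self.stage = Stage.SOWN
        self.tt_sum = 0.0
        self.biomass = {o: 0.0 for o in ORGANS}
        self.biomass["leaf"] = 1.0  # seed reserve starting the canopy
        self.lai = sla * self.biomass["leaf"]
        self.root_depth = 0.05
        self.cum_transpiration = 0.0
        self.sowing_doy = doy


def determine_sowing_date(precip: np.ndarray, window: SowingWindow) -> int:
    """First DOY in the window whose trailing ``accum_days`` rainfall sum
    reaches the threshold; the window's last day if none qualifies.

    ``precip`` is indexed by day-of-year starting at 1 (``precip[0]`` = DOY 1).
    """
    precip = np.asarray(precip, dtype=float)
    if len(precip) < window.end_doy:
        raise ValueError("precipitation series shorter than the sowing window")
    for d in range(window.start_doy, window.end_doy + 1):
        lo = max(0, d - window.accum_days)
        if precip[lo:d].sum() >= window.rain_threshold:
            return d
    return window.end_doy


def thermal_time_increment(tmean: float, t_base: float,
                           topt_ceiling: float | None = None) -> float:
    tt = max(0.0, tmean - t_base)
    if topt_ceiling is not None:
        tt = min(tt, topt_ceiling - t_base)
    return tt


def step_phenology(state: CropState, tmean: float, params: CropParams) -> CropState:
    """Accumulate thermal time and promote the stage; never demotes."""
    if state.stage is Stage.UNSOWN:
        raise ValueError("cannot step phenology of an unsown crop")
    state.tt_sum += thermal_time_increment(tmean, params.t_base, params.topt_ceiling)
    if state.stage is Stage.SOWN and state.tt_sum >= params.tt_emergence:
        state.stage = Stage.EMERGED
    if state.stage is Stage.EMERGED and state.tt_sum >= params.tt_anthesis:
        state.stage = Stage.ANTHESIS
    if state.stage in (Stage.EMERGED, Stage.ANTHESIS) \
            and state.tt_sum >= params.tt_maturity:
        state.stage = Stage.MATURE
    return state


def light_interception(lai: float, k_ext: float) -> float:
    """Beer-law fraction of radiation intercepted by the canopy."""
    if lai < 0:
        raise ValueError("lai must be >= 0")
    if k_ext <= 0:
        raise ValueError("k_ext must be > 0")
    return 1.0 - math.exp(-k_ext * lai)


def step_crop_growth(state: CropState, day: WeatherDay, water_factor: float,
                     n_factor: float, params: CropParams, et0: float = 0.0
                     ) -> tuple[CropState, float, float]:
    """One day of RUE growth under combined (Liebig) water/N stress.

    Returns ``(state, transp_demand_mm, n_demand_kg_ha)``; the transpiration
    demand is the canopy-intercepted share of reference ET.
    """
    if state.stage in (Stage.UNSOWN, Stage.MATURE):
        raise ValueError(f"cannot grow a crop in stage {state.stage.name}")
    if state.stage is Stage.SOWN:  # pre-emergence: no canopy, no growth
        return state, 0.0, 0.0
    f_int = light_interception(state.lai, params.k_ext)
    stress = min(water_factor, n_factor)
    ddm = params.rue * f_int * (PAR_FRACTION * day.srad) * stress  # g m-2
    dvs = state.tt_sum / params.tt_maturity
    fractions = params.partition_at(dvs)
    for organ, fr in zip(ORGANS, fractions):
        state.biomass[organ] += ddm * fr
    state.lai += params.sla * ddm * fractions[0]
    tt = thermal_time_increment(day.tmean, params.t_base, params.topt_ceiling)
    state.root_depth = min(params.max_root_depth,
                           state.root_depth + params.root_growth_rate * tt)
    transp_demand = et0 * f_int
    n_demand = ddm * 10.0 * params.n_demand_per_dm  # g m-2 -> kg ha-1 DM basis
    return state, transp_demand, n_demand


def harvest(state: CropState, params: CropParams
            ) -> tuple[float, float, float, CropState]:
    """Harvest a mature crop.

    Returns ``(yield_dm, residue_total, residue_feed)`` in kg DM ha-1 and the
    state reset to unsown.  Yield is the storage pool capped at hi_max x AGB.
    """
    if state.stage is not Stage.MATURE:
        raise ValueError("harvest requires a mature crop")
    agb = state.agb * 10.0  # g m-2 -> kg ha-1
    yield_dm = min(state.biomass["storage"] * 10.0, params.hi_max * agb)
    residue_total = agb - yield_dm
    residue_feed = residue_total * params.residue_feed_fraction
    return yield_dm, residue_total, residue_feed, CropState()
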
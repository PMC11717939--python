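"""Grassland above-ground biomass dynamics with the zonal habit distinction.

Annual grass (Sahelian zone) establishes with the rains via the same
cumulative-rainfall rule used for crop sowing, dies at the dry-season onset
and leaves its shoot as standing hay.  Perennial grass (Sudanian zone) moves
part of its shoot into a below-ground reserve at dormancy, survives the dry
season, and regrows from the reserve when the rains return; its deeper roots
reach water the annual cannot.  Grazing removes shoot down to an ungrazable
residual.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crop import PAR_FRACTION, light_interception
from .forcing import WeatherDay

#: Shoot DM that cannot be grazed (g DM m-2); prevents extinction artifacts.
DEFAULT_UNGRAZABLE_RESIDUAL = 15.0
#: Daily relative senescence of standing shoot.
DEFAULT_SENESCENCE_RATE = 0.01


@dataclass(frozen=True)
class GrassParams:
    """Zone grass parameters; ``habit`` selects annual or perennial behaviour."""

    habit: str = "annual"          # {"annual", "perennial"}
    rue: float = 2.0               # g DM MJ-1 PAR
    k_ext: float = 0.50
    t_base: float = 10.0
    sla: float = 0.020             # m2 g-1
    shoot_fraction: float = 0.65   # allocation shoot vs root
    max_root_depth: float = 0.6    # m; perennial default deeper
    reserve_fraction: float = 0.30  # shoot share moved to reserve at dormancy
    regrowth_rate: float = 3.0     # g m-2 day-1 transferred reserve -> shoot
    senescence_rate: float = DEFAULT_SENESCENCE_RATE
    ungrazable_residual: float = DEFAULT_UNGRAZABLE_RESIDUAL
    me_content: float = 8.0        # MJ ME kg-1 DM

    def __post_init__(self) -> None:
        if self.habit not in ("annual", "perennial"):
            raise ValueError("habit must be 'annual' or 'perennial'")
        if not 0 <= self.reserve_fraction <= 1:
            raise ValueError("reserve_fraction must lie in [0, 1]")
        if self.rue <= 0:
            raise ValueError("rue must be > 0")


ZONE_GRASS = {
    "sahelian": GrassParams(habit="annual", max_root_depth=0.5),
    "sudanian": GrassParams(habit="perennial", max_root_depth=1.2,
                            rue=2.2, me_content=8.5),
}


@dataclass
class GrassState:
    """Grass pools in g DM m-2; ``reserve`` is only populated for perennials."""

    shoot: float = 0.0
    reserve: float = 0.0
    lai: float = 0.0
    root_depth: float = 0.1
    dormant: bool = True

    def establish(self, params: GrassParams) -> None:
        self.dormant = False
        if params.habit == "annual":
            self.shoot = 2.0  # seedling flush
            self.lai = params.sla * self.shoot
            self.root_depth = 0.1


def step_grass_growth(state: GrassState, day: WeatherDay, water_factor: float,
                      n_factor: float, params: GrassParams, et0: float = 0.0
                      ) -> tuple[GrassState, float]:
    """One day of grass growth; returns the state and transpiration demand (mm).

    RUE growth as for crops but with shoot/root allocation only; a perennial
    additionally transfers ``regrowth_rate`` from reserve to shoot while water
    is available.  Senescence removes a fixed fraction of shoot daily.
    """
    if state.dormant:
        raise ValueError("cannot grow dormant grass")
    if params.habit == "perennial" and state.reserve > 0 and water_factor > 0:
        transfer = min(params.regrowth_rate, state.reserve)
        state.reserve -= transfer
        state.shoot += transfer
        state.lai += params.sla * transfer
    f_int = light_interception(state.lai, params.k_ext)
    stress = min(water_factor, n_factor)
    ddm = params.rue * f_int * (PAR_FRACTION * day.srad) * stress
    state.shoot += ddm * params.shoot_fraction
    state.lai += params.sla * ddm * params.shoot_fraction
    tt = max(0.0, day.tmean - params.t_base)
    state.root_depth = min(params.max_root_depth, state.root_depth + 0.002 * tt)
    # senescence shrinks shoot and canopy proportionally
    sen = params.senescence_rate * state.shoot
    if state.shoot > 0:
        state.lai *= (state.shoot - sen) / state.shoot
    state.shoot -= sen
    return state, et0 * f_int


def season_transition(state: GrassState, params: GrassParams,
                      dry_season_onset: bool, rains_onset: bool) -> tuple[GrassState, float]:
    """Handle dormancy/establishment; returns the state and standing hay (g m-2)
    released to the feed store at the dry-season onset.
    """
    if dry_season_onset and rains_onset:
        raise ValueError("contradictory season flags")
    standing_hay = 0.0
    if dry_season_onset and not state.dormant:
        if params.habit == "annual":
            standing_hay = state.shoot
            state.shoot = 0.0
            state.lai = 0.0
        else:
            to_reserve = state.shoot * params.reserve_fraction
            state.reserve += to_reserve
            standing_hay = state.shoot - to_reserve
            state.shoot = 0.0
            state.lai = 0.0
        state.dormant = True
    elif rains_onset and state.dormant:
        state.establish(params)
    return state, standing_hay


def graze(state: GrassState, demand_dm: float,
          ungrazable_residual: float = DEFAULT_UNGRAZABLE_RESIDUAL
          ) -> tuple[GrassState, float]:
    """Remove up to ``demand_dm`` g m-2 of shoot, never below the residual."""
    if demand_dm < 0:
        raise ValueError("demand_dm must be >= 0")
    grazeable = max(0.0, state.shoot - ungrazable_residual)
    removed = min(demand_dm, grazeable)
    if removed > 0:
        state.lai *= (state.shoot - removed) / state.shoot
        state.shoot -= removed
    return state, removed
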
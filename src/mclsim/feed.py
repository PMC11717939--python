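"""Feed-energy supply, the 0-1 energy-stress index, and market decisions.

Standing grass, crop residues and purchased concentrates are pooled into a
daily metabolizable-energy (ME) supply drawn against the herd's maintenance
demand (metabolic-weight scaling, W^0.75).  The stress index is the supply /
demand ratio clipped to [0, 1] — 0 means a complete feed deficit, 1 no
stress.  When supply falls short the manager first buys concentrates within
the cash on hand; if a deficit persists the sell-out rule liquidates animals
(fractional head-counts allowed) from a priority list until the remaining
herd's demand is covered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .herd import N_CLASSES, HerdClass, HerdState

#: Daily dry-matter intake capacity as a fraction of live weight.
DEFAULT_INTAKE_FRACTION = 0.025
#: Maintenance ME requirement per kg metabolic weight (MJ kg^-0.75 day-1).
DEFAULT_MAINTENANCE_MJ = 0.45

FEED_SOURCES = ("grass", "residue", "concentrate")


class FeedConfigError(ValueError):
    pass


@dataclass
class FeedStore:
    """Feed pools (kg DM) with their ME contents (MJ kg-1 DM)."""

    grass_dm: float = 0.0        # standing grazeable grass, synced by the engine
    residue_dm: float = 0.0
    concentrate_dm: float = 0.0
    me_grass: float = 8.0
    me_residue: float = 6.5
    me_concentrate: float = 11.0

    def __post_init__(self) -> None:
        if min(self.grass_dm, self.residue_dm, self.concentrate_dm) < 0:
            raise ValueError("feed pools must be >= 0")
        if min(self.me_grass, self.me_residue, self.me_concentrate) <= 0:
            raise ValueError("ME contents must be > 0")


@dataclass
class EnergyBalance:
    """One day's feed-energy accounting."""

    demand_mj: float = 0.0
    supply_mj: float = 0.0
    stress: float = 1.0


@dataclass(frozen=True)
class MarketParams:
    """Prices and the sell-out management rule."""

    concentrate_price: float = 0.25   # currency per kg DM
    animal_price: float = 1.2         # currency per kg live weight
    milk_price: float = 0.4           # currency per kg
    stress_sell_threshold: float = 0.6
    sell_priority: tuple = (HerdClass.ADULTS_MALE, HerdClass.SUBADULTS_MALE,
                            HerdClass.JUVENILES_MALE, HerdClass.SUBADULTS_FEMALE)

    def __post_init__(self) -> None:
        if min(self.concentrate_price, self.animal_price, self.milk_price) < 0:
            raise ValueError("prices must be >= 0")
        if not 0 <= self.stress_sell_threshold <= 1:
            raise ValueError("stress_sell_threshold must lie in [0, 1]")


def energy_demand(herd: HerdState,
                  maintenance_mj_per_kg075: float = DEFAULT_MAINTENANCE_MJ) -> float:
    """Herd ME demand (MJ day-1) by metabolic-weight scaling."""
    return float((herd.count * maintenance_mj_per_kg075
                  * herd.mean_weight ** 0.75).sum())


def per_head_demand(herd: HerdState,
                    maintenance_mj_per_kg075: float = DEFAULT_MAINTENANCE_MJ
                    ) -> np.ndarray:
    """Per-class ME demand per head (MJ head-1 day-1)."""
    return maintenance_mj_per_kg075 * herd.mean_weight ** 0.75


def max_intake_dm(herd: HerdState,
                  intake_fraction: float = DEFAULT_INTAKE_FRACTION) -> float:
    """Herd dry-matter intake capacity (kg DM day-1)."""
    return intake_fraction * herd.total_live_weight


def energy_supply(store: FeedStore, max_intake_dm: float, demand_mj: float
                  ) -> tuple[float, FeedStore, dict]:
    """Draw feed in order grass -> residue -> concentrate.

    Stops when the demand is met, the intake capacity is reached, or the
    pools are empty.  Returns (supply_mj, updated store, DM drawn by source).
    """
    if min(max_intake_dm, demand_mj) < 0:
        raise ValueError("inputs must be >= 0")
    pools = {"grass": store.grass_dm, "residue": store.residue_dm,
             "concentrate": store.concentrate_dm}
    me = {"grass": store.me_grass, "residue": store.me_residue,
          "concentrate": store.me_concentrate}
    drawn = {s: 0.0 for s in FEED_SOURCES}
    supply = 0.0
    dm_left = max_intake_dm
    for source in FEED_SOURCES:
        if supply >= demand_mj or dm_left <= 0:
            break
        take = min(pools[source], dm_left, (demand_mj - supply) / me[source])
        drawn[source] = take
        pools[source] -= take
        supply += take * me[source]
        dm_left -= take
    new_store = FeedStore(pools["grass"], pools["residue"], pools["concentrate"],
                          store.me_grass, store.me_residue, store.me_concentrate)
    return supply, new_store, drawn


def energy_stress(supply_mj: float, demand_mj: float) -> float:
    """Feed-energy stress index: 1 = no stress, 0 = complete deficit."""
    if supply_mj < 0 or demand_mj < 0:
        raise ValueError("inputs must be >= 0")
    if demand_mj == 0:
        return 1.0
    return min(1.0, supply_mj / demand_mj)


def concentrate_purchase(deficit_mj: float, cash: float, market: MarketParams,
                         me_concentrate: float) -> tuple[float, float, float]:
    """Buy concentrate DM covering up to ``deficit_mj``, limited by cash.

    Returns (dm_bought, cost, remaining cash); never drives cash negative.
    """
    if min(deficit_mj, cash) < 0:
        raise ValueError("inputs must be >= 0")
    if me_concentrate <= 0:
        raise ValueError("me_concentrate must be > 0")
    dm_needed = deficit_mj / me_concentrate
    if market.concentrate_price == 0:
        dm_bought = dm_needed
    else:
        dm_bought = min(dm_needed, cash / market.concentrate_price)
    cost = dm_bought * market.concentrate_price
    return dm_bought, cost, cash - cost


def sell_out_decision(herd: HerdState, stress: float, unmet_demand_mj: float,
                      market: MarketParams, per_head_demand_mj: np.ndarray
                      ) -> tuple[np.ndarray, float, HerdState]:
    """Sell animals to close a persistent feed-energy gap.

    No sale while stress sits at or above the sell threshold or there is no
    unmet demand.  Otherwise classes are liquidated in priority order, each
    selling the (possibly decimal) head-count whose removal closes the
    remaining gap; revenue at live weight x price is credited to cash.
    """
    if not 0 <= stress <= 1:
        raise ValueError("stress must lie in [0, 1]")
    sold = np.zeros(N_CLASSES)
    h = herd.copy()
    if stress >= market.stress_sell_threshold or unmet_demand_mj <= 0:
        return sold, 0.0, h
    if not market.sell_priority:
        raise FeedConfigError("unmet feed demand but empty sell_priority list")
    remaining = unmet_demand_mj
    revenue = 0.0
    for cls in market.sell_priority:
        if remaining <= 0:
            break
        phd = float(per_head_demand_mj[cls])
        if phd <= 0:
            continue
        n_sell = min(float(h.count[cls]), remaining / phd)
        sold[cls] = n_sell
        h.count[cls] -= n_sell
        revenue += n_sell * float(h.mean_weight[cls]) * market.animal_price
        remaining -= n_sell * phd
    h.cash += revenue
    return sold, revenue, h


def update_feed_store(store: FeedStore, standing_hay_in: float, residue_in: float,
                      decay_rate: float = 0.001) -> FeedStore:
    """Add hay/residue inflows to the residue pool, then apply daily decay.

    Concentrates do not decay.
    """
    if min(standing_hay_in, residue_in) < 0:
        raise ValueError("inputs must be >= 0")
    if not 0 <= decay_rate <= 1:
        raise ValueError("decay_rate must lie in [0, 1]")
    residue = (store.residue_dm + standing_hay_in + residue_in) * (1.0 - decay_rate)
    return FeedStore(store.grass_dm, residue, store.concentrate_dm,
                     store.me_grass, store.me_residue, store.me_concentrate)
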
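"""Multi-layer daily soil-water balance and a minimal mineral-nitrogen pool.

A tipping-bucket cascade over a variable number of layers: infiltration fills
each layer to field capacity, the surplus percolates downward, and whatever
leaves the bottom layer is drainage.  Evaporation is drawn from the top layer,
transpiration from the rooted layers in proportion to their plant-available
water.  The mineral-N pool supplies a nutrient-limitation factor for growth
and a proportional nitrate-leaching loss driven by drainage.

All layer water is stored in mm; volumetric fractions are converted at
construction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcing import WeatherDay

MM_PER_M = 1000.0

#: Default daily infiltration capacity (mm day-1); rain above it runs off.
DEFAULT_INFILTRATION_CAPACITY = 50.0
#: Default fraction of plant-available water below which transpiration is limited.
DEFAULT_P_CRIT = 0.5
#: Default proportional nitrate-leaching coefficient.
DEFAULT_LEACH_COEFF = 0.5


class DegenerateProfileError(ValueError):
    """Field capacity equals wilting point over the rooted zone."""


@dataclass
class SoilLayer:
    """One soil layer; water limits and current storage in mm.

    ``fc``, ``wp`` and ``sat`` are totals for the layer (volumetric fraction
    x thickness x 1000), not volumetric fractions.
    """

    thickness: float  # m
    fc: float         # mm
    wp: float         # mm
    sat: float        # mm
    water: float      # mm

    def __post_init__(self) -> None:
        if not 0 <= self.wp < self.fc <= self.sat:
            raise ValueError("require 0 <= wp < fc <= sat")
        if not 0 <= self.water <= self.sat + 1e-9:
            raise ValueError("water outside [0, sat]")

    @classmethod
    def from_volumetric(cls, thickness_m: float, fc_vol: float, wp_vol: float,
                        sat_vol: float, initial_fraction_fc: float = 1.0) -> "SoilLayer":
        mm = thickness_m * MM_PER_M
        fc, wp, sat = fc_vol * mm, wp_vol * mm, sat_vol * mm
        water = wp + initial_fraction_fc * (fc - wp)
        return cls(thickness_m, fc, wp, sat, water)


@dataclass
class SoilProfile:
    """Ordered layers (top to bottom) plus a single mineral-N pool (kg N ha-1)."""

    layers: list[SoilLayer]
    mineral_n: float = 10.0
    infiltration_capacity: float = DEFAULT_INFILTRATION_CAPACITY

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("profile needs at least one layer")
        if self.mineral_n < 0:
            raise ValueError("mineral_n must be >= 0")

    @property
    def total_water(self) -> float:
        return sum(l.water for l in self.layers)

    @property
    def total_depth(self) -> float:
        return sum(l.thickness for l in self.layers)

    @property
    def rootzone_capacity_mm(self) -> float:
        return sum(l.fc for l in self.layers)

    def rooted_fractions(self, root_depth: float) -> list[float]:
        """Fraction of each layer's thickness inside the root zone."""
        out, top = [], 0.0
        for l in self.layers:
            bottom = top + l.thickness
            if root_depth <= top:
                out.append(0.0)
            elif root_depth >= bottom:
                out.append(1.0)
            else:
                out.append((root_depth - top) / l.thickness)
            top = bottom
        return out

    def copy(self) -> "SoilProfile":
        return SoilProfile(
            [SoilLayer(l.thickness, l.fc, l.wp, l.sat, l.water) for l in self.layers],
            self.mineral_n, self.infiltration_capacity)


@dataclass
class WaterFlux:
    """Daily water fluxes (mm day-1); infiltration + runoff equals same-day rain."""

    infiltration: float = 0.0
    runoff: float = 0.0
    evaporation: float = 0.0
    transpiration: float = 0.0
    drainage: float = 0.0


def default_profile(*, infiltration_capacity: float = DEFAULT_INFILTRATION_CAPACITY,
                    mineral_n: float = 10.0,
                    initial_fraction_fc: float = 0.5) -> SoilProfile:
    """A generic three-layer sandy-loam profile (0-1.2 m)."""
    layers = [
        SoilLayer.from_volumetric(0.2, 0.22, 0.08, 0.40, initial_fraction_fc),
        SoilLayer.from_volumetric(0.4, 0.24, 0.10, 0.42, initial_fraction_fc),
        SoilLayer.from_volumetric(0.6, 0.26, 0.12, 0.44, initial_fraction_fc),
    ]
    return SoilProfile(layers, mineral_n, infiltration_capacity)


def partition_rainfall(rain: float, profile: SoilProfile) -> tuple[float, float]:
    """Split daily rain into infiltration (up to capacity) and surface runoff."""
    if rain < 0:
        raise ValueError("rain must be >= 0")
    infiltration = min(rain, profile.infiltration_capacity)
    return infiltration, rain - infiltration


def extraterrestrial_radiation(latitude: float, doy: int) -> float:
    """Daily extraterrestrial radiation Ra in mm-equivalent (FAO-56 eq. 21/20)."""
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra_mj = (24.0 * 60.0 / math.pi) * 0.0820 * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws))
    return max(0.0, ra_mj * 0.408)  # MJ m-2 d-1 -> mm d-1 evaporative equivalent


def reference_et(day: WeatherDay, latitude: float, ra: float | None = None) -> float:
    """Hargreaves-Samani reference evapotranspiration (mm day-1).

    ET0 = 0.0023 * Ra * (tmean + 17.8) * sqrt(tmax - tmin), with Ra the
    extraterrestrial radiation in mm-equivalent (computed from latitude and
    day-of-year unless supplied).
    """
    if day.tmax < day.tmin:
        raise ValueError("tmax < tmin")
    if ra is None:
        ra = extraterrestrial_radiation(latitude, day.doy)
    et0 = 0.0023 * ra * (day.tmean + 17.8) * math.sqrt(day.tmax - day.tmin)
    return max(0.0, et0)


def step_soil_water(profile: SoilProfile, infiltration: float, evap_demand: float,
                    transp_demand: float, root_depth: float
                    ) -> tuple[SoilProfile, WaterFlux]:
    """Advance the water balance one day; returns the new profile and fluxes.

    Closure |delta(storage) - (infiltration - E - T - drainage)| < 1e-6 mm holds
    by construction; demands are capped at the extractable water, never forced.
    """
    if min(infiltration, evap_demand, transp_demand, root_depth) < 0:
        raise ValueError("inputs must be >= 0")
    p = profile.copy()

    # tipping-bucket cascade: fill each layer to fc, pass the surplus down
    percolate = infiltration
    for layer in p.layers:
        layer.water += percolate
        percolate = max(0.0, layer.water - layer.fc)
        layer.water -= percolate
    drainage = percolate

    # soil evaporation from the top layer, never below wp
    top = p.layers[0]
    evaporation = min(evap_demand, max(0.0, top.water - top.wp))
    top.water -= evaporation

    # transpiration from rooted layers, weighted by plant-available water
    fracs = p.rooted_fractions(root_depth)
    avail = np.array([f * max(0.0, l.water - l.wp)
                      for f, l in zip(fracs, p.layers)])
    total_avail = float(avail.sum())
    transpiration = min(transp_demand, total_avail)
    if transpiration > 0 and total_avail > 0:
        take = avail * (transpiration / total_avail)
        for l, t in zip(p.layers, take):
            l.water -= float(t)

    return p, WaterFlux(infiltration, 0.0, evaporation, transpiration, drainage)


def drought_factor(profile: SoilProfile, root_depth: float,
                   p_crit: float = DEFAULT_P_CRIT) -> float:
    """Plant water-stress factor in [0, 1] over the rooted zone.

    1 above the critical fill fraction ``p_crit`` of plant-available water,
    declining linearly to 0 at wilting point.
    """
    if root_depth < 0:
        raise ValueError("root_depth must be >= 0")
    if not 0 < p_crit <= 1:
        raise ValueError("p_crit must lie in (0, 1]")
    fracs = profile.rooted_fractions(root_depth)
    if not any(fracs):  # roots above first layer: use top layer
        fracs = [1.0] + [0.0] * (len(profile.layers) - 1)
    w = sum(f * l.water for f, l in zip(fracs, profile.layers))
    wp = sum(f * l.wp for f, l in zip(fracs, profile.layers))
    fc = sum(f * l.fc for f, l in zip(fracs, profile.layers))
    if fc - wp <= 0:
        raise DegenerateProfileError("rooted zone has fc == wp")
    f = (w - wp) / (p_crit * (fc - wp))
    return min(1.0, max(0.0, f))


def step_soil_nitrogen(profile: SoilProfile, n_inputs: float, uptake_demand: float,
                       drainage: float, leach_coeff: float = DEFAULT_LEACH_COEFF
                       ) -> tuple[SoilProfile, float, float, float]:
    """Advance the mineral-N pool one day.

    Returns ``(profile', uptake, leached, n_factor)`` where the nutrient factor
    is uptake/demand (1 when demand is zero).  Leaching is proportional to the
    pool and to drainage relative to the profile's water-holding capacity.
    """
    if min(n_inputs, uptake_demand, drainage) < 0:
        raise ValueError("inputs must be >= 0")
    p = profile.copy()
    p.mineral_n += n_inputs
    uptake = min(uptake_demand, p.mineral_n)
    p.mineral_n -= uptake
    leached = p.mineral_n * leach_coeff * min(1.0, drainage / p.rootzone_capacity_mm)
    p.mineral_n -= leached
    n_factor = 1.0 if uptake_demand == 0 else uptake / uptake_demand
    return p, uptake, leached, n_factor
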
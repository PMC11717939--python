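"""Livestock demographic projection over six age x sex classes.

A daily-time-step herd model in the DynMod tradition: adult females produce
births at a parturition rate scaled by a prolificacy fraction; every class
loses animals to baseline mortality plus a starvation term driven by the
feed-energy stress index; juveniles and sub-adults are promoted by a "gamma"
rate combining survival probability and class residence time; offtake (sales)
and intake (entries) act at daily rates.  Counts are real-valued — a day's
sales can be a decimal fraction of an animal — and live weights respond to
energy stress through bounded daily gain and loss.

Annual rates convert to daily rates by division by 365 (no compounding), so
a constant-mortality class decays exactly as N0 * (1 - m/365)^t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

DAYS_PER_YEAR = 365.0


class HerdClass(IntEnum):
    """The six age x sex classes, in projection order."""

    JUVENILES_MALE = 0
    SUBADULTS_MALE = 1
    ADULTS_MALE = 2
    JUVENILES_FEMALE = 3
    SUBADULTS_FEMALE = 4
    ADULTS_FEMALE = 5


N_CLASSES = len(HerdClass)
#: Promotion edges (source -> destination) for each sex chain.
PROMOTION_EDGES = (
    (HerdClass.JUVENILES_MALE, HerdClass.SUBADULTS_MALE),
    (HerdClass.SUBADULTS_MALE, HerdClass.ADULTS_MALE),
    (HerdClass.JUVENILES_FEMALE, HerdClass.SUBADULTS_FEMALE),
    (HerdClass.SUBADULTS_FEMALE, HerdClass.ADULTS_FEMALE),
)


@dataclass
class HerdState:
    """Counts (head, fractional allowed), mean live weights (kg), and cash."""

    count: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    mean_weight: np.ndarray = field(
        default_factory=lambda: np.array([40.0, 120.0, 280.0, 40.0, 110.0, 250.0]))
    cash: float = 0.0

    def __post_init__(self) -> None:
        self.count = np.asarray(self.count, dtype=float).copy()
        self.mean_weight = np.asarray(self.mean_weight, dtype=float).copy()
        if self.count.shape != (N_CLASSES,) or self.mean_weight.shape != (N_CLASSES,):
            raise ValueError(f"count and mean_weight must have length {N_CLASSES}")
        if (self.count < 0).any():
            raise ValueError("counts must be >= 0")
        if (self.mean_weight <= 0).any():
            raise ValueError("weights must be > 0")

    @property
    def total_count(self) -> float:
        return float(self.count.sum())

    @property
    def total_live_weight(self) -> float:
        """Sum over classes of count x mean weight (kg)."""
        return float((self.count * self.mean_weight).sum())

    def copy(self) -> "HerdState":
        return HerdState(self.count.copy(), self.mean_weight.copy(), self.cash)


@dataclass(frozen=True)
class DemographyParams:
    """Annual demographic and production rates; arrays are per-class."""

    parturition_annual: float = 0.70   # parturitions per adult female yr-1
    prolification: float = 1.0         # offspring per parturition
    sex_ratio_male: float = 0.5
    base_mortality_annual: tuple = (0.15, 0.08, 0.05, 0.15, 0.08, 0.05)
    starvation_mortality_max_annual: tuple = (0.60, 0.40, 0.30, 0.60, 0.40, 0.30)
    class_duration_days: tuple = (365.0, 730.0, 365.0, 730.0)  # per PROMOTION_EDGES
    survival_for_gamma: tuple = (0.90, 0.95, 0.90, 0.95)
    offtake_annual: tuple = (0.02, 0.10, 0.20, 0.02, 0.05, 0.08)
    intake_annual: tuple = (0.0,) * 6  # entries/purchases, head head-1 yr-1
    carcass_fraction: float = 0.50
    milk_yield_potential: float = 2.0  # kg head-1 day-1
    lactating_fraction: float = 0.5
    weight_gain_max: tuple = (0.20, 0.25, 0.15, 0.20, 0.25, 0.15)  # kg day-1
    weight_loss_max: tuple = (0.30, 0.35, 0.40, 0.30, 0.35, 0.40)
    min_viable_weight: tuple = (15.0, 60.0, 150.0, 15.0, 55.0, 140.0)
    ch4_yield: float = 0.021           # kg CH4 per kg DM intake
    n_excretion_fraction: float = 0.8  # of N intake

    def gammas(self) -> np.ndarray:
        """Daily promotion rate per PROMOTION_EDGES."""
        return np.array([class_transition_rate(d, s) for d, s in
                         zip(self.class_duration_days, self.survival_for_gamma)])


@dataclass
class HerdFlows:
    """Per-class daily flow audit (head day-1)."""

    births: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    deaths: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    promotions_in: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    promotions_out: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    offtake: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))
    intake: np.ndarray = field(default_factory=lambda: np.zeros(N_CLASSES))


def class_transition_rate(duration_days: float, survival: float) -> float:
    """Daily promotion rate gamma = survival / residence duration."""
    if duration_days < 1:
        raise ValueError("duration_days must be >= 1")
    if not 0 < survival <= 1:
        raise ValueError("survival must lie in (0, 1]")
    return survival / duration_days


def step_demography(herd: HerdState, params: DemographyParams,
                    energy_stress: float) -> tuple[HerdState, HerdFlows]:
    """Advance counts one day: births -> mortality -> promotions -> offtake/intake.

    Each stage acts on the counts left by the previous stage; promotion flows
    for all classes are computed simultaneously from post-mortality counts so
    no animal crosses two classes in one day.  Deaths + offtake are capped at
    the available count, so counts never go negative.
    """
    if not 0 <= energy_stress <= 1:
        raise ValueError("energy_stress must lie in [0, 1]")
    h = herd.copy()
    flows = HerdFlows()
    n = h.count

    # births from start-of-day adult females, split by sex ratio
    births = n[HerdClass.ADULTS_FEMALE] * (params.parturition_annual / DAYS_PER_YEAR) \
        * params.prolification
    flows.births[HerdClass.JUVENILES_MALE] = births * params.sex_ratio_male
    flows.births[HerdClass.JUVENILES_FEMALE] = births * (1 - params.sex_ratio_male)
    n = n + flows.births

    # mortality: baseline plus starvation scaled by (1 - stress)
    mort_daily = (np.asarray(params.base_mortality_annual)
                  + np.asarray(params.starvation_mortality_max_annual)
                  * (1.0 - energy_stress)) / DAYS_PER_YEAR
    flows.deaths = np.minimum(n, n * mort_daily)
    n = n - flows.deaths

    # promotions, synchronous from post-mortality counts
    for (src, dst), gamma in zip(PROMOTION_EDGES, params.gammas()):
        moved = n[src] * gamma
        flows.promotions_out[src] += moved
        flows.promotions_in[dst] += moved
    n = n - flows.promotions_out + flows.promotions_in

    # offtake (sales/slaughter, capped at what remains) and intake (entries)
    flows.offtake = np.minimum(n, n * np.asarray(params.offtake_annual) / DAYS_PER_YEAR)
    flows.intake = n * np.asarray(params.intake_annual) / DAYS_PER_YEAR
    n = n - flows.offtake + flows.intake

    h.count = np.maximum(n, 0.0)
    return h, flows


def projection_matrix(params: DemographyParams, energy_stress: float = 1.0
                      ) -> np.ndarray:
    """The 6x6 linear daily update matrix implied by ``step_demography``.

    Valid while no capping binds (counts stay positive); the stage maps
    (births, mortality, promotions, offtake/intake) compose left to right in
    the order the step applies them.
    """
    eye = np.eye(N_CLASSES)
    b = eye.copy()
    daily_births = (params.parturition_annual / DAYS_PER_YEAR) * params.prolification
    b[HerdClass.JUVENILES_MALE, HerdClass.ADULTS_FEMALE] += \
        daily_births * params.sex_ratio_male
    b[HerdClass.JUVENILES_FEMALE, HerdClass.ADULTS_FEMALE] += \
        daily_births * (1 - params.sex_ratio_male)
    mort = (np.asarray(params.base_mortality_annual)
            + np.asarray(params.starvation_mortality_max_annual)
            * (1.0 - energy_stress)) / DAYS_PER_YEAR
    m = np.diag(1.0 - mort)
    p = eye.copy()
    for (src, dst), gamma in zip(PROMOTION_EDGES, params.gammas()):
        p[src, src] -= gamma
        p[dst, src] += gamma
    o = np.diag(1.0 - np.asarray(params.offtake_annual) / DAYS_PER_YEAR
                + np.asarray(params.intake_annual) / DAYS_PER_YEAR)
    return o @ p @ m @ b


def update_live_weights(herd: HerdState, params: DemographyParams,
                        energy_stress: float) -> HerdState:
    """Daily weight change: gain scaled by stress, loss by (1 - stress)."""
    if not 0 <= energy_stress <= 1:
        raise ValueError("energy_stress must lie in [0, 1]")
    h = herd.copy()
    dw = (np.asarray(params.weight_gain_max) * energy_stress
          - np.asarray(params.weight_loss_max) * (1.0 - energy_stress))
    h.mean_weight = np.maximum(h.mean_weight + dw,
                               np.asarray(params.min_viable_weight))
    return h


def meat_production(live_weight_kg: float, carcass_fraction: float) -> float:
    """Carcass mass (kg) from live weight sold or slaughtered."""
    if live_weight_kg < 0:
        raise ValueError("live weight must be >= 0")
    if not 0 <= carcass_fraction <= 1:
        raise ValueError("carcass_fraction must lie in [0, 1]")
    return live_weight_kg * carcass_fraction


def milk_production(herd: HerdState, params: DemographyParams,
                    energy_stress: float) -> float:
    """Daily milk offtake (kg): lactating adult females at potential x stress."""
    if not 0 <= energy_stress <= 1:
        raise ValueError("energy_stress must lie in [0, 1]")
    return float(herd.count[HerdClass.ADULTS_FEMALE] * params.lactating_fraction
                 * params.milk_yield_potential * energy_stress)


def methane_emission(dm_intake_kg: float, ch4_yield: float) -> float:
    """Enteric CH4 (kg day-1), linear in dry-matter intake."""
    if dm_intake_kg < 0 or ch4_yield < 0:
        raise ValueError("inputs must be >= 0")
    return dm_intake_kg * ch4_yield


def manure_nitrogen(n_intake_kg: float, excretion_fraction: float,
                    cropland_share: float = 0.5) -> tuple[float, float]:
    """Excreted manure N (kg day-1) split between cropland and grassland."""
    if n_intake_kg < 0:
        raise ValueError("n_intake must be >= 0")
    if not 0 <= excretion_fraction <= 1:
        raise ValueError("excretion_fraction must lie in [0, 1]")
    if not 0 <= cropland_share <= 1:
        raise ValueError("cropland_share must lie in [0, 1]")
    excreted = n_intake_kg * excretion_fraction
    return excreted * cropland_share, excreted * (1.0 - cropland_share)
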
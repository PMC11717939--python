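"""Feed-energy supply chain, stress index, purchases and sell-out rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mclsim.feed import (FeedConfigError, FeedStore, MarketParams,
                         concentrate_purchase, energy_demand, energy_stress,
                         energy_supply, per_head_demand, sell_out_decision,
                         update_feed_store)
from mclsim.herd import HerdClass, HerdState, N_CLASSES


def herd_of(cls: HerdClass, n: float, weight: float) -> HerdState:
    counts = np.zeros(N_CLASSES)
    counts[cls] = n
    weights = np.full(N_CLASSES, 100.0)
    weights[cls] = weight
    return HerdState(counts, weights)


class TestEnergyDemand:
    def test_empty_herd(self):
        assert energy_demand(HerdState(np.zeros(N_CLASSES))) == 0.0

    def test_metabolic_weight_arithmetic(self):
        # 10 head x 256 kg at 0.5 MJ kg^-0.75: 10 * 0.5 * 64
        herd = herd_of(HerdClass.ADULTS_MALE, 10.0, 256.0)
        assert energy_demand(herd, 0.5) == pytest.approx(320.0)

    def test_linear_in_count(self):
        h1 = herd_of(HerdClass.ADULTS_MALE, 3.0, 256.0)
        h2 = herd_of(HerdClass.ADULTS_MALE, 6.0, 256.0)
        assert energy_demand(h2, 0.5) == pytest.approx(2 * energy_demand(h1, 0.5))


class TestEnergySupply:
    def test_empty_store(self):
        supply, store, drawn = energy_supply(FeedStore(), 100.0, 500.0)
        assert supply == 0.0 and sum(drawn.values()) == 0.0

    def test_intake_cap_limits_draw(self):
        store = FeedStore(residue_dm=100.0, me_residue=7.0)
        supply, store2, drawn = energy_supply(store, 50.0, 1000.0)
        assert supply == pytest.approx(350.0)
        assert store2.residue_dm == pytest.approx(50.0)
        assert drawn["residue"] == pytest.approx(50.0)

    def test_demand_limited_draw(self):
        store = FeedStore(grass_dm=100.0, me_grass=8.0)
        supply, store2, drawn = energy_supply(store, 1000.0, 80.0)
        assert drawn["grass"] == pytest.approx(10.0)
        assert supply == pytest.approx(80.0)

    def test_draw_order_grass_residue_concentrate(self):
        store = FeedStore(grass_dm=5.0, residue_dm=5.0, concentrate_dm=5.0,
                          me_grass=8.0, me_residue=6.5, me_concentrate=11.0)
        supply, store2, drawn = energy_supply(store, 100.0, 8.0 * 5 + 6.5 * 2)
        assert drawn["grass"] == pytest.approx(5.0)
        assert drawn["residue"] == pytest.approx(2.0)
        assert drawn["concentrate"] == 0.0

    @settings(max_examples=80, deadline=None)
    @given(grass=st.floats(0, 200), residue=st.floats(0, 200),
           conc=st.floats(0, 50), cap=st.floats(0, 100), demand=st.floats(0, 3000))
    def test_dm_balance_and_bounds(self, grass, residue, conc, cap, demand):
        store = FeedStore(grass, residue, conc)
        supply, store2, drawn = energy_supply(store, cap, demand)
        assert sum(drawn.values()) <= cap + 1e-9
        assert supply <= demand + max(store.me_grass, store.me_residue,
                                      store.me_concentrate) + 1e-9
        for pool, src in [(store2.grass_dm, "grass"), (store2.residue_dm, "residue"),
                          (store2.concentrate_dm, "concentrate")]:
            assert pool >= -1e-12
            assert pool == pytest.approx(getattr(store, f"{src}_dm") - drawn[src])


class TestEnergyStress:
    def test_endpoints(self):
        assert energy_stress(0.0, 100.0) == 0.0
        assert energy_stress(150.0, 100.0) == 1.0
        assert energy_stress(0.0, 0.0) == 1.0

    def test_ratio(self):
        assert energy_stress(50.0, 100.0) == pytest.approx(0.5)

    @settings(max_examples=60, deadline=None)
    @given(s1=st.floats(0, 1000), s2=st.floats(0, 1000), d=st.floats(1e-6, 1000))
    def test_monotone_in_supply(self, s1, s2, d):
        lo, hi = sorted((s1, s2))
        assert energy_stress(lo, d) <= energy_stress(hi, d)


class TestConcentratePurchase:
    def test_zero_deficit(self):
        assert concentrate_purchase(0.0, 100.0, MarketParams(), 10.0) == (0, 0, 100.0)

    def test_cash_rich(self):
        market = MarketParams(concentrate_price=1.0)
        dm, cost, cash = concentrate_purchase(100.0, 100.0, market, 10.0)
        assert (dm, cost, cash) == (10.0, 10.0, 90.0)

    def test_cash_cap(self):
        market = MarketParams(concentrate_price=1.0)
        dm, cost, cash = concentrate_purchase(100.0, 4.0, market, 10.0)
        assert (dm, cost, cash) == (4.0, 4.0, 0.0)

    def test_zero_me_rejected(self):
        with pytest.raises(ValueError):
            concentrate_purchase(10.0, 10.0, MarketParams(), 0.0)


class TestSellOut:
    def test_no_sale_without_stress(self):
        herd = herd_of(HerdClass.ADULTS_MALE, 10.0, 300.0)
        sold, revenue, h = sell_out_decision(
            herd, 1.0, 500.0, MarketParams(), per_head_demand(herd))
        assert sold.sum() == 0 and revenue == 0

    def test_decimal_sale_closes_gap(self):
        herd = herd_of(HerdClass.ADULTS_MALE, 10.0, 300.0)
        market = MarketParams(stress_sell_threshold=0.6, animal_price=1.0,
                              sell_priority=(HerdClass.ADULTS_MALE,))
        phd = np.full(N_CLASSES, 30.0)
        sold, revenue, h = sell_out_decision(herd, 0.3, 60.0, market, phd)
        assert sold[HerdClass.ADULTS_MALE] == pytest.approx(2.0)
        assert h.count[HerdClass.ADULTS_MALE] == pytest.approx(8.0)
        assert revenue == pytest.approx(2.0 * 300.0)
        sold, revenue, _ = sell_out_decision(herd, 0.3, 45.0, market, phd)
        assert sold[HerdClass.ADULTS_MALE] == pytest.approx(1.5)
        assert revenue == pytest.approx(1.5 * 300.0)

    def test_priority_order_respected(self):
        counts = np.zeros(N_CLASSES)
        counts[HerdClass.ADULTS_MALE] = 1.0
        counts[HerdClass.SUBADULTS_MALE] = 5.0
        herd = HerdState(counts)
        market = MarketParams(
            stress_sell_threshold=0.6,
            sell_priority=(HerdClass.ADULTS_MALE, HerdClass.SUBADULTS_MALE))
        phd = np.full(N_CLASSES, 10.0)
        sold, _, _ = sell_out_decision(herd, 0.2, 25.0, market, phd)
        assert sold[HerdClass.ADULTS_MALE] == pytest.approx(1.0)
        assert sold[HerdClass.SUBADULTS_MALE] == pytest.approx(1.5)

    def test_empty_priority_with_gap_is_config_error(self):
        herd = herd_of(HerdClass.ADULTS_MALE, 10.0, 300.0)
        market = MarketParams(sell_priority=())
        with pytest.raises(FeedConfigError):
            sell_out_decision(herd, 0.2, 60.0, market, per_head_demand(herd))


class TestUpdateFeedStore:
    def test_noop(self):
        store = FeedStore(residue_dm=100.0)
        out = update_feed_store(store, 0.0, 0.0, decay_rate=0.0)
        assert out.residue_dm == 100.0

    def test_decay(self):
        out = update_feed_store(FeedStore(residue_dm=1000.0), 0.0, 0.0, 0.001)
        assert out.residue_dm == pytest.approx(999.0)

    def test_harvest_coupling_adds_exactly(self):
        out = update_feed_store(FeedStore(residue_dm=10.0), 5.0, 20.0, 0.0)
        assert out.residue_dm == pytest.approx(35.0)

    def test_concentrates_never_decay(self):
        store = FeedStore(concentrate_dm=50.0)
        out = update_feed_store(store, 0.0, 0.0, 0.5)
        assert out.concentrate_dm == 50.0
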
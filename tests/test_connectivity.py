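import numpy as np
import pandas as pd
import pytest

from hydroconn import (
    ConnectivityResult,
    Link,
    PassabilityPolicy,
    cci,
    cumulative_passability,
    rci,
    rcisuit,
    summarize,
)

from conftest import random_riverscape, uniform_suit
from helpers import oracle_rci


class TestCumulativePassability:
    def test_self_is_unity(self, six_reach):
        net, policy, _ = six_reach
        assert cumulative_passability(net, policy, "r2", "r2") == 1.0

    def test_one_dam_upstream_uses_upstream_default(self, toy):
        net, policy, _ = toy
        assert cumulative_passability(net, policy, "out", "up") == pytest.approx(0.1)

    def test_waterfall_down_then_dam_up(self, sisters):
        """Crossing a waterfall downstream then a dam upstream: 0.7 * 0.1."""
        net, policy = sisters
        c = cumulative_passability(net, policy, "left", "right")
        assert c == pytest.approx(0.07)

    def test_symmetric_mode_uses_geometric_mean_both_ways(self, toy):
        net, _, _ = toy
        policy = PassabilityPolicy(directionality_mode="symmetric")
        up = cumulative_passability(net, policy, "up", "out")
        down = cumulative_passability(net, policy, "out", "up")
        assert up == down == pytest.approx(np.sqrt(0.1 * 0.4))

    def test_removed_barrier_is_transparent(self, toy):
        net, policy, _ = toy
        assert cumulative_passability(
            net, policy, "out", "up", removed=frozenset({"dam1"})
        ) == 1.0

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_adding_a_barrier_never_raises_passability(self, seed):
        net, policy = random_riverscape(seed, n_reaches=15, n_dams=0, n_waterfalls=0)
        conf = [lk for lk in net.links if not lk.is_barrier][0]
        dammed = net.add_barrier(
            Link(
                link_id="new",
                kind="anthropogenic",
                upstream_reach=conf.upstream_reach,
                downstream_reach=conf.downstream_reach,
            )
        )
        for i in net.reach_ids[::2]:
            for j in net.reach_ids[::3]:
                assert (
                    cumulative_passability(dammed, policy, i, j)
                    <= cumulative_passability(net, policy, i, j) + 1e-15
                )


class TestRCI:
    def test_barrier_free_network_scores_one_everywhere(self):
        net, policy = random_riverscape(7, n_reaches=20, n_dams=0, n_waterfalls=0)
        assert rci(net, policy).to_numpy() == pytest.approx(np.ones(20))

    def test_two_reach_dam_hand_values(self, toy):
        net, policy, _ = toy
        r = rci(net, policy)
        assert r["up"] == pytest.approx(0.70)
        assert r["out"] == pytest.approx(0.55)

    def test_impassable_barriers_leave_only_self_term(self, toy):
        net, _, _ = toy
        policy = PassabilityPolicy(overrides={"dam1": (0.0, 0.0)})
        r = rci(net, policy)
        W = net.total_length_km()
        for rid in net.reach_ids:
            assert r[rid] == pytest.approx(net.reach(rid).length_km / W)

    @pytest.mark.parametrize("seed", [21, 22, 23, 24])
    def test_matches_brute_force_oracle(self, seed):
        net, policy = random_riverscape(seed, n_reaches=25, n_dams=4, n_waterfalls=2)
        assert (rci(net, policy) - oracle_rci(net, policy)).abs().max() < 1e-12

    def test_symmetric_passabilities_make_cij_symmetric(self, six_reach):
        net, _, _ = six_reach
        policy = PassabilityPolicy(
            overrides={lk.link_id: (0.3, 0.3) for lk in net.barriers}
        )
        for i in net.reach_ids:
            for j in net.reach_ids:
                assert cumulative_passability(net, policy, i, j) == pytest.approx(
                    cumulative_passability(net, policy, j, i)
                )

    def test_length_scaling_invariance(self, six_reach):
        from hydroconn import Reach, RiverNetwork
        from dataclasses import replace

        net, policy, _ = six_reach
        scaled = RiverNetwork(
            [replace(r, length_km=r.length_km * 7.3) for r in net.reaches],
            net.links,
        )
        assert (rci(net, policy) - rci(scaled, policy)).abs().max() < 1e-12

    def test_multi_catchment_networks_are_handled_independently(self):
        import pandas as pd
        from hydroconn import build_network

        reaches = pd.DataFrame(
            {
                "reach_id": ["A", "B", "X"],
                "length_km": [1.0, 1.0, 4.0],
                "catchment_id": ["C0", "C0", "C1"],
                "next_down": ["B", None, None],
            }
        )
        barriers = pd.DataFrame(
            [{"barrier_id": "d", "kind": "anthropogenic", "up_reach": "A", "down_reach": "B"}]
        )
        net = build_network(reaches, barriers)
        r = rci(net, PassabilityPolicy())
        assert r["X"] == pytest.approx(1.0)
        assert r["A"] == pytest.approx(0.70)


class TestRCIsuit:
    def test_direct_product(self):
        r = pd.Series({"a": 0.55})
        s = pd.Series({"a": 0.8})
        assert rcisuit(r, s)["a"] == pytest.approx(0.44)

    def test_zero_and_identity_suitability(self, toy):
        net, policy, _ = toy
        r = rci(net, policy)
        assert (rcisuit(r, uniform_suit(net, 0.0)) == 0).all()
        assert (rcisuit(r, uniform_suit(net, 1.0)) == r).all()

    def test_out_of_range_suitability_rejected(self, toy):
        net, policy, _ = toy
        r = rci(net, policy)
        with pytest.raises(ValueError):
            rcisuit(r, uniform_suit(net, 1.2))

    def test_mismatched_reach_sets_rejected(self, toy):
        net, policy, _ = toy
        r = rci(net, policy)
        with pytest.raises(ValueError):
            rcisuit(r, pd.Series({"up": 0.5}))

    @pytest.mark.parametrize("seed", [31, 32])
    def test_bounded_by_rci_and_suitability(self, seed):
        net, policy = random_riverscape(seed, n_reaches=30, n_dams=5)
        rng = np.random.default_rng(seed)
        s = pd.Series(rng.uniform(0, 1, len(net)), index=net.reach_ids)
        r = rci(net, policy)
        rs = rcisuit(r, s)
        assert ((rs >= 0) & (rs <= 1)).all()
        assert (rs <= np.minimum(r, s) + 1e-15).all()


class TestCCI:
    def test_uniform_suitability_reduces_to_mean_rci(self, six_reach):
        net, policy, _ = six_reach
        c = cci(net, policy, uniform_suit(net))
        assert c["C0"] == pytest.approx(rci(net, policy).mean())

    def test_two_reach_weighted_hand_value(self, toy):
        net, policy, _ = toy
        s = pd.Series({"up": 0.5, "out": 1.0})
        assert cci(net, policy, s)["C0"] == pytest.approx(
            (0.5 * 0.70 + 1.0 * 0.55) / 1.5
        )

    def test_barrier_free_network_scores_one(self):
        net, policy = random_riverscape(8, n_reaches=10, n_dams=0, n_waterfalls=0)
        s = pd.Series(
            np.random.default_rng(0).uniform(0.1, 1, len(net)), index=net.reach_ids
        )
        assert cci(net, policy, s)["C0"] == pytest.approx(1.0)

    def test_all_zero_weights_rejected(self, toy):
        net, policy, _ = toy
        with pytest.raises(ValueError):
            cci(net, policy, uniform_suit(net, 0.0))

    def test_missing_suitability_counts_as_zero_weight(self, six_reach):
        net, policy, _ = six_reach
        partial = pd.Series({"r0": 1.0, "r1": 1.0})  # other reaches omitted
        c = cci(net, policy, partial)
        r = rci(net, policy)
        assert c["C0"] == pytest.approx((r["r0"] + r["r1"]) / 2)

    def test_length_weighting_option(self, toy):
        net, policy, _ = toy
        s = pd.Series({"up": 0.5, "out": 1.0})
        c = cci(net, policy, s, weighting="suitability_length")
        # equal lengths: same as suitability weighting here
        assert c["C0"] == pytest.approx(cci(net, policy, s)["C0"])


class TestSummarize:
    def test_hand_vector(self):
        res = ConnectivityResult(
            rci=pd.Series([1, 1, 1.0]),
            rcisuit=pd.Series([0.1, 0.2, 0.6]),
            cci=pd.Series({"C0": 0.3}),
        )
        assert summarize(res) == pytest.approx(
            {"mean": 0.3, "median": 0.2, "max": 0.6}
        )

    def test_constant_vector(self):
        res = ConnectivityResult(
            rci=pd.Series([1.0] * 4),
            rcisuit=pd.Series([0.4] * 4),
            cci=pd.Series({"C0": 0.4}),
        )
        assert set(summarize(res).values()) == {0.4}

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0, 1, 101)
        res = ConnectivityResult(
            rci=pd.Series(np.ones(101)), rcisuit=pd.Series(v), cci=pd.Series({"C0": 1.0})
        )
        s = summarize(res)
        assert s["mean"] == pytest.approx(float(np.sum(v) / len(v)))
        assert s["median"] == pytest.approx(float(sorted(v)[50]))
        assert s["max"] == pytest.approx(float(sorted(v)[-1]))


@pytest.mark.parametrize("seed", [41, 42])
def test_adding_a_barrier_weakly_decreases_rci_and_cci(seed):
    net, policy = random_riverscape(seed, n_reaches=20, n_dams=2, n_waterfalls=1)
    confluences = [lk for lk in net.links if not lk.is_barrier]
    rng = np.random.default_rng(seed)
    conf = confluences[rng.integers(len(confluences))]
    dammed = net.add_barrier(
        Link(
            link_id="extra",
            kind="anthropogenic",
            upstream_reach=conf.upstream_reach,
            downstream_reach=conf.downstream_reach,
        )
    )
    s = pd.Series(rng.uniform(0.1, 1, len(net)), index=net.reach_ids)
    assert (rci(dammed, policy) <= rci(net, policy) + 1e-12).all()
    assert (
        cci(dammed, policy, s)["C0"] <= cci(net, policy, s)["C0"] + 1e-12
    )
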
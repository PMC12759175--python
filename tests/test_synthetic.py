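import numpy as np
import pandas as pd
import pytest

from hydroconn import (
    NetworkError,
    RiverscapeConfig,
    generate_network,
    generate_riverscape,
    generate_suitability,
    place_barriers,
    six_reach_fixture,
    toy_fixture,
)
from hydroconn.synthetic import _subtree_lengths, mainstem


class TestGenerateNetwork:
    def test_single_reach(self):
        net = generate_network(RiverscapeConfig(n_reaches=1, seed=0))
        assert len(net) == 1
        assert net.links == []

    def test_same_seed_reproduces_network_bitwise(self):
        a = generate_network(RiverscapeConfig(n_reaches=40, seed=9))
        b = generate_network(RiverscapeConfig(n_reaches=40, seed=9))
        assert [r.reach_id for r in a.reaches] == [r.reach_id for r in b.reaches]
        assert [r.length_km for r in a.reaches] == [r.length_km for r in b.reaches]
        assert [
            (l.link_id, l.upstream_reach) for l in a.links
        ] == [(l.link_id, l.upstream_reach) for l in b.links]

    def test_fifty_reaches_forty_nine_links(self):
        net = generate_network(RiverscapeConfig(n_reaches=50, seed=1))
        assert len(net) == 50
        assert len(net.links) == 49
        net.validate()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            RiverscapeConfig(n_reaches=0)
        with pytest.raises(ValueError):
            RiverscapeConfig(branching_prob=1.5)

    def test_mainstem_length_grows_with_network_size(self):
        means = []
        for n in (20, 80, 320):
            lens = []
            for seed in range(8):
                net = generate_network(RiverscapeConfig(n_reaches=n, seed=seed))
                lens.append(sum(net.reach(r).length_km for r in mainstem(net)))
            means.append(np.mean(lens))
        assert means[0] < means[1] < means[2]


class TestPlaceBarriers:
    def test_zero_barriers_leave_network_unchanged(self):
        cfg = RiverscapeConfig(
            n_reaches=20, n_waterfalls=0, n_dams_existing=0, n_dams_planned=0, seed=2
        )
        net = generate_network(cfg)
        assert place_barriers(net, cfg) is net

    def test_requested_counts_are_placed(self):
        cfg = RiverscapeConfig(
            n_reaches=30, n_waterfalls=2, n_dams_existing=5, n_dams_planned=3, seed=3
        )
        net = place_barriers(generate_network(cfg), cfg)
        kinds = [(lk.kind, lk.status) for lk in net.barriers]
        assert kinds.count(("waterfall", "existing")) == 2
        assert kinds.count(("anthropogenic", "existing")) == 5
        assert kinds.count(("anthropogenic", "planned")) == 3
        net.validate()

    def test_counts_beyond_capacity_rejected(self):
        cfg = RiverscapeConfig(
            n_reaches=3, n_waterfalls=2, n_dams_existing=5, n_dams_planned=0, seed=4
        )
        with pytest.raises(NetworkError):
            place_barriers(generate_network(cfg), cfg)

    def test_mainstem_bias_raises_mainstem_hit_rate(self):
        base = RiverscapeConfig(n_reaches=40, seed=10)
        net = generate_network(base)
        stem_prefixes = set(mainstem(net))
        hits = {"uniform": 0, "mainstem_biased": 0}
        trials = 120
        for placement in hits:
            for seed in range(trials):
                cfg = RiverscapeConfig(
                    n_reaches=40,
                    n_waterfalls=0,
                    n_dams_existing=1,
                    n_dams_planned=0,
                    placement=placement,
                    seed=seed,
                )
                dammed = place_barriers(net, cfg)
                (dam,) = dammed.barriers
                base_id = dam.upstream_reach.split(".")[0]
                if base_id in stem_prefixes:
                    hits[placement] += 1
        assert hits["mainstem_biased"] > hits["uniform"]

    def test_super_barrier_sits_on_most_balanced_cut(self):
        cfg = RiverscapeConfig(
            n_reaches=25, n_waterfalls=0, n_dams_existing=0, n_dams_planned=0,
            super_barrier=True, seed=5,
        )
        clean = generate_network(cfg)
        net = place_barriers(clean, cfg)
        (dam,) = net.barriers
        assert dam.link_id == "super_dam"
        sub = _subtree_lengths(clean)
        total = clean.total_length_km()
        # exhaustive check over all possible cut edges
        best = max(
            sub[v] * (total - sub[v])
            for v in clean.reach_ids
            if clean.reach(v).downstream_reach_id
        )
        assert sub[dam.upstream_reach] * (total - sub[dam.upstream_reach]) == pytest.approx(best)


class TestGenerateSuitability:
    def cfg(self, **kw):
        kw.setdefault("n_reaches", 60)
        kw.setdefault("seed", 7)
        return RiverscapeConfig(**kw)

    def test_layers_bounded_and_complete(self):
        cfg = self.cfg()
        net = generate_network(cfg)
        suit = generate_suitability(net, cfg)
        assert len(suit.keys()) == 3 * 9  # 3 groups x (current + 2 climates x 4 epochs)
        for key in suit.keys():
            layer = suit.get(*key)
            assert ((layer >= 0) & (layer <= 1)).all()
            assert list(layer.index) == net.reach_ids

    def test_pessimistic_decline_is_monotone_and_steepest(self):
        cfg = self.cfg()
        net = generate_network(cfg)
        suit = generate_suitability(net, cfg)
        cur = suit.get("combined", "current", "current").mean()
        mod = [suit.get("combined", "moderate", e).mean() for e in ("2030", "2050", "2070", "2090")]
        pes = [suit.get("combined", "pessimistic", e).mean() for e in ("2030", "2050", "2070", "2090")]
        assert all(np.diff([cur] + mod) < 0)
        assert all(np.diff([cur] + pes) < 0)
        assert all(p < m for p, m in zip(pes, mod))

    def test_autocorrelation_zero_gives_independent_values(self):
        cfg0 = self.cfg(suitability_autocorrelation=0.0, n_reaches=200)
        cfg8 = self.cfg(suitability_autocorrelation=0.8, n_reaches=200)
        net = generate_network(cfg0)

        def adjacent_corr(cfg):
            suit, species = generate_suitability(net, cfg, return_species=True)
            pairs = [
                (lk.upstream_reach, lk.downstream_reach) for lk in net.links
            ]
            xs, ys = [], []
            for sp in list({k[0] for k in species})[:10]:
                layer = species[(sp, "current", "current")]
                xs.extend(layer[a] for a, _ in pairs)
                ys.extend(layer[b] for _, b in pairs)
            return np.corrcoef(xs, ys)[0, 1]

        assert adjacent_corr(cfg8) > adjacent_corr(cfg0) + 0.2

    def test_adjacent_beats_distant_correlation(self):
        cfg = self.cfg(suitability_autocorrelation=0.8, n_reaches=150)
        net = generate_network(cfg)
        suit, species = generate_suitability(net, cfg, return_species=True)
        ids = net.reach_ids
        layers = [
            species[(sp, "current", "current")] for sp in sorted({k[0] for k in species})
        ]
        mat = np.array([l.to_numpy() for l in layers])
        adj, far = [], []
        rng = np.random.default_rng(0)
        for lk in net.links:
            a, b = ids.index(lk.upstream_reach), ids.index(lk.downstream_reach)
            adj.append(np.corrcoef(mat[:, a], mat[:, b])[0, 1])
        for _ in range(len(adj)):
            a, b = rng.integers(len(ids), size=2)
            far.append(np.corrcoef(mat[:, a], mat[:, b])[0, 1])
        assert np.nanmean(adj) > np.nanmean(far)

    def test_bit_reproducible(self):
        cfg = self.cfg()
        net = generate_network(cfg)
        a = generate_suitability(net, cfg).get("combined", "pessimistic", "2090")
        b = generate_suitability(net, cfg).get("combined", "pessimistic", "2090")
        assert (a == b).all()

    def test_group_sizes_default_to_species_assemblage(self):
        cfg = self.cfg()
        net = generate_network(cfg)
        _, species = generate_suitability(net, cfg, return_species=True)
        sp = {k[0] for k in species}
        assert sum(s.startswith("mig_") for s in sp) == 27
        assert sum(s.startswith("sed_") for s in sp) == 25


class TestFixtures:
    def test_toy_fixture_round_trips_through_csv(self, tmp_path):
        from hydroconn import io

        net, policy, suit = toy_fixture()
        io.write_network(net, tmp_path)
        io.write_suitability(suit, tmp_path)
        net2, policy2, suit2 = io.read_inputs(tmp_path)
        assert sorted(net2.reach_ids) == sorted(net.reach_ids)
        assert [lk.link_id for lk in net2.barriers] == ["dam1"]
        assert (
            suit2.get("combined", "current", "current")
            .sort_index()
            .equals(suit.get("combined", "current", "current").sort_index())
        )

    def test_six_reach_fixture_matches_oracle(self):
        from helpers import oracle_rci
        from hydroconn.connectivity import rci

        net, policy, _ = six_reach_fixture()
        assert (rci(net, policy) - oracle_rci(net, policy)).abs().max() < 1e-12

    def test_generate_riverscape_end_to_end(self):
        net, policy, suit = generate_riverscape(
            RiverscapeConfig(n_reaches=30, n_waterfalls=1, n_dams_existing=3,
                             n_dams_planned=2, seed=11)
        )
        net.validate()
        assert ("combined", "current", "current") in suit
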
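"""Region-set statistics, RS/CLS randomizers and the circular permutation
test, checked against brute-force enumeration oracles."""

import numpy as np
import pytest

from nucleoidgcc import (
    RegionSet,
    SynthConfig,
    circular_distance,
    clustering_test,
    digest_genome,
    empirical_p,
    make_genome,
    plant_regions,
    randomize_cls,
    randomize_rs,
    region_stats,
    simulate_network,
)
from nucleoidgcc.clustering import read_bed, write_bed
from .conftest import make_net


# ---------------------------------------------------------------------------
# independent oracle: explicit circular-interval overlap + per-pair loop

def circ_overlap(s1, l1, s2, l2, L):
    return (s2 - s1) % L < l1 or (s1 - s2) % L < l2


def brute_force_stats(net, regions, gmap, exclusions=("self", "short"),
                      threshold=800):
    L = gmap.length
    lengths = regions.lengths
    total = 0
    clustering = 0
    for (i, j), c in net.counts.items():
        if "self" in exclusions and i == j:
            continue
        fi, fj = gmap.fragments[i], gmap.fragments[j]
        if "short" in exclusions and i != j:
            if circular_distance(fi.midpoint, fj.midpoint, L) < threshold:
                continue
        ra = {
            k for k in range(regions.n)
            if circ_overlap(fi.start, fi.length, regions.intervals[k, 0],
                            int(lengths[k]), L)
        }
        rb = {
            k for k in range(regions.n)
            if circ_overlap(fj.start, fj.length, regions.intervals[k, 0],
                            int(lengths[k]), L)
        }
        if ra or rb:
            total += c
        if any(a != b for a in ra for b in rb):
            clustering += c
    return total, clustering


class TestRegionStats:
    def test_direct_tally_example(self):
        """Two regions; one inter-region interaction (count 4) and one
        region-to-outside interaction (count 2): total 6, clustering 4."""
        seq = "".join("GCGC" + "A" * 996 for _ in range(10))  # 10 x 1 kb
        gmap = digest_genome(seq)
        # fragments k: [1000k+3, 1000k+1003); regions inside fragments 0 and 5
        regions = RegionSet("r", np.array([[100, 300], [5100, 5300]]), 10_000)
        net = make_net(gmap, {(0, 5): 4, (0, 8): 2})
        stats = region_stats(net, regions, gmap)
        assert (stats.total, stats.clustering) == (6, 4)

    def test_untouched_regions_zero(self, toy_map):
        regions = RegionSet("r", np.array([[0, 3], [16, 19]]), 20)
        net = make_net(toy_map, {})
        stats = region_stats(net, regions, toy_map)
        assert (stats.total, stats.clustering) == (0, 0)

    def test_self_interaction_excluded(self):
        seq = "".join("GCGC" + "A" * 996 for _ in range(10))
        gmap = digest_genome(seq)
        regions = RegionSet("r", np.array([[100, 300], [5100, 5300]]), 10_000)
        net = make_net(gmap, {(0, 0): 7})
        stats = region_stats(net, regions, gmap)
        assert (stats.total, stats.clustering) == (0, 0)
        incl = region_stats(net, regions, gmap, exclusions=())
        assert (incl.total, incl.clustering) == (7, 0)

    def test_same_region_both_ends_counts_total_not_clustering(self):
        seq = "".join("GCGC" + "A" * 396 for _ in range(10))  # 10 x 400 bp
        gmap = digest_genome(seq)
        # one region spanning fragments 2 and 3; they are adjacent but far
        # enough on midpoints? midpoint distance 400 < 800 -> use exclusions
        # without "short" to isolate the same-region rule
        regions = RegionSet("r", np.array([[810, 1590], [3000, 3100]]), 4000)
        net = make_net(gmap, {(2, 3): 5})
        stats = region_stats(net, regions, gmap, exclusions=("self",))
        assert stats.total == 5
        assert stats.clustering == 0

    def test_empty_region_set_rejected(self, toy_map):
        with pytest.raises(ValueError):
            region_stats(make_net(toy_map, {}),
                         RegionSet("r", np.empty((0, 2)), 20), toy_map)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_enumeration(self, seed):
        """Vectorized region statistics equal exhaustive pair enumeration
        with explicit circular-interval overlap on small genomes."""
        rng = np.random.default_rng(seed)
        cfg = SynthConfig(genome_length=3000, mean_spacing=250, seed=seed,
                          lambda0=3.0, region_beta=1.0)
        _, gmap = make_genome(cfg)
        assert gmap.n_fragments <= 20
        net, _ = simulate_network(cfg, gmap)
        m = int(rng.integers(2, 5))
        starts = rng.integers(3000, size=m)
        lens = rng.integers(50, 400, size=m)
        regions = RegionSet(
            "rand", np.stack([starts, (starts + lens) % 3000], axis=1), 3000
        )
        for excl in [("self", "short"), ("self",), ()]:
            got = region_stats(net, regions, gmap, exclusions=excl, short_long_threshold=300)
            exp_total, exp_clus = brute_force_stats(
                net, regions, gmap, exclusions=excl, threshold=300
            )
            assert (got.total, got.clustering) == (exp_total, exp_clus)

    def test_binary_mode_ignores_counts(self):
        seq = "".join("GCGC" + "A" * 996 for _ in range(10))
        gmap = digest_genome(seq)
        regions = RegionSet("r", np.array([[100, 300], [5100, 5300]]), 10_000)
        net = make_net(gmap, {(0, 5): 4, (0, 8): 2})
        stats = region_stats(net, regions, gmap, mode="binary")
        assert (stats.total, stats.clustering) == (2, 1)


class TestRandomizers:
    def test_rs_preserves_length_multiset_no_overlap(self, rng):
        regions = RegionSet(
            "r", np.array([[10, 110], [300, 350], [900, 1100]]), 2000
        )
        for _ in range(200):
            rand = randomize_rs(regions, 2000, rng)
            assert sorted(rand.lengths) == sorted(regions.lengths)
            assert rand.n == regions.n
            iv = rand.intervals
            for a in range(rand.n):
                for b in range(a + 1, rand.n):
                    assert not circ_overlap(
                        iv[a, 0], int(rand.lengths[a]),
                        iv[b, 0], int(rand.lengths[b]), 2000
                    )

    def test_rs_deterministic_under_seed(self):
        regions = RegionSet("r", np.array([[10, 110], [300, 350]]), 2000)
        a = randomize_rs(regions, 2000, np.random.default_rng(7))
        b = randomize_rs(regions, 2000, np.random.default_rng(7))
        assert (a.intervals == b.intervals).all()

    def test_rs_impossible_placement_rejected(self, rng):
        # total region length fills the whole circle: no non-overlapping draw
        regions = RegionSet("r", np.array([[0, 1000], [1000, 2000]]), 2000)
        with pytest.raises(ValueError, match="too long"):
            randomize_rs(regions, 2000, rng)

    def test_cls_modular_shift_example(self):
        """L=100, regions [0,10) and [50,60), offset 70 -> [70,80) and
        [20,30); the 50 bp gap is preserved."""
        regions = RegionSet("r", np.array([[0, 10], [50, 60]]), 100)

        class FixedRng:
            def integers(self, n):
                return 70

        shifted = randomize_cls(regions, 100, FixedRng())
        assert shifted.intervals.tolist() == [[70, 80], [20, 30]]

    def test_cls_preserves_all_pairwise_gaps(self, rng):
        starts = np.array([5, 400, 900, 1500])
        regions = RegionSet(
            "r", np.stack([starts, starts + 50], axis=1), 2000
        )
        gaps = (starts[None, :] - starts[:, None]) % 2000
        for _ in range(300):
            rand = randomize_cls(regions, 2000, rng)
            s2 = rand.intervals[:, 0]
            assert ((s2[None, :] - s2[:, None]) % 2000 == gaps).all()

    def test_cls_zero_offset_identity(self):
        regions = RegionSet("r", np.array([[5, 15]]), 100)

        class ZeroRng:
            def integers(self, n):
                return 0

        assert (randomize_cls(regions, 100, ZeroRng()).intervals
                == regions.intervals).all()


class TestEmpiricalP:
    def test_tail_counting(self):
        assert empirical_p(5, [3, 4, 5, 6], "high") == 0.5
        assert empirical_p(5, [3, 4, 5, 6], "low") == 0.75

    def test_extremes(self):
        null = list(range(1000))
        assert empirical_p(2000, null, "high") == 0.0
        assert empirical_p(-1, null, "high") == 1.0
        assert empirical_p(-1, null, "low") == 0.0

    def test_plus_one_correction(self):
        assert empirical_p(2000, list(range(999)), "high", plus_one=True) == 1 / 1000

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(1, [], "high")


class TestClusteringTest:
    def test_exact_p_from_enumerated_nulls(self):
        """With n_random=4 and a fixed seed the p-values equal hand counts
        over the four reproduced null draws (brute-force statistics)."""
        seq = "".join("GCGC" + "A" * 996 for _ in range(12))
        gmap = digest_genome(seq)
        L = gmap.length
        net = make_net(gmap, {(0, 5): 4, (0, 8): 2, (2, 7): 3, (1, 9): 1})
        regions = RegionSet("r", np.array([[100, 300], [5100, 5300]]), L)
        seed = 99
        res = clustering_test(net, regions, gmap, n_random=4, seed=seed)
        for method, randomize, idx in (
            ("RS", randomize_rs, 0), ("CLS", randomize_cls, 1),
        ):
            rng = np.random.default_rng([seed, idx])
            nulls = []
            for _ in range(4):
                rand = randomize(regions, L, rng)
                nulls.append(brute_force_stats(net, rand, gmap))
            obs_total, obs_clus = brute_force_stats(net, regions, gmap)
            assert (res.observed.total, res.observed.clustering) == (
                obs_total, obs_clus
            )
            assert np.array_equal(
                res.nulls[method]["total"], [t for t, _ in nulls]
            )
            assert np.array_equal(
                res.nulls[method]["clustering"], [c for _, c in nulls]
            )
            for stat, obs in (("total", obs_total), ("clustering", obs_clus)):
                vals = res.nulls[method][stat]
                assert res.p[method][stat]["high"] == sum(
                    v >= obs for v in vals
                ) / 4
                assert res.p[method][stat]["low"] == sum(
                    v <= obs for v in vals
                ) / 4

    def test_planted_clusters_detected(self):
        cfg = SynthConfig(genome_length=200_000, region_beta=10.0,
                          ori_alpha=1.0, copy_ratio=1.0, seed=17)
        _, gmap = make_genome(cfg)
        regions = plant_regions(cfg)
        net, _ = simulate_network(cfg, gmap, regions=regions)
        res = clustering_test(net, regions, gmap, n_random=200, seed=5)
        assert res.p["RS"]["clustering"]["high"] <= 0.01
        assert res.p["CLS"]["clustering"]["high"] <= 0.01

    def test_reproducible_under_seed(self, small_genome):
        cfg, _, gmap = small_genome
        net, _ = simulate_network(cfg, gmap)
        regions = RegionSet("r", np.array([[100, 300], [25_000, 25_200]]),
                            cfg.genome_length)
        r1 = clustering_test(net, regions, gmap, n_random=20, seed=3)
        r2 = clustering_test(net, regions, gmap, n_random=20, seed=3)
        for m in ("RS", "CLS"):
            assert np.array_equal(r1.nulls[m]["clustering"],
                                  r2.nulls[m]["clustering"])

    def test_invariants_and_frame(self, small_genome):
        cfg, _, gmap = small_genome
        net, _ = simulate_network(cfg, gmap)
        regions = RegionSet("r", np.array([[100, 300], [25_000, 25_200]]),
                            cfg.genome_length)
        res = clustering_test(net, regions, gmap, n_random=50, seed=1)
        assert 0 <= res.observed.clustering <= res.observed.total
        for m in ("RS", "CLS"):
            assert len(res.nulls[m]["total"]) == 50
            assert (res.nulls[m]["clustering"] <= res.nulls[m]["total"]).all()
            for stat in ("total", "clustering"):
                for tail in ("high", "low"):
                    assert 0 <= res.p[m][stat][tail] <= 1
        df = res.to_frame()
        assert len(df) == 4
        assert set(df.columns) >= {"observed", "null_mean", "p_high", "p_low"}

    def test_single_region_rejected(self, toy_map):
        with pytest.raises(ValueError, match="fewer than 2"):
            clustering_test(make_net(toy_map, {}),
                            RegionSet("r", np.array([[0, 5]]), 20), toy_map)


class TestBedIO:
    def test_roundtrip_and_flank_expansion(self, tmp_path):
        regions = RegionSet("sites", np.array([[100, 300], [900, 1000]]), 2000)
        path = tmp_path / "sites.bed"
        write_bed(regions, path)
        back = read_bed(path, 2000)
        assert (back.intervals == regions.intervals).all()
        flanked = read_bed(path, 2000, flank=50)
        # midpoints 200 and 950 expanded +/-50
        assert flanked.intervals.tolist() == [[150, 250], [900, 1000]]

    def test_wrapping_interval_split(self, tmp_path):
        regions = RegionSet("r", np.array([[1900, 100]]), 2000)
        path = tmp_path / "wrap.bed"
        write_bed(regions, path)
        lines = [l.split("\t") for l in path.read_text().splitlines()]
        assert [(l[1], l[2]) for l in lines] == [("1900", "2000"), ("0", "100")]
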
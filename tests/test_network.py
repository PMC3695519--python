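"""Network assembly, ligation-control cutoff, interaction classes,
condition comparison and replicate concordance."""

import numpy as np
import pytest

from nucleoidgcc import (
    MappedPair,
    SynthConfig,
    assemble_network,
    classify_interaction,
    compare_conditions,
    derive_cutoff,
    make_genome,
    replicate_kappa,
    simulate_network,
)
from nucleoidgcc.network import (
    InteractionNetwork,
    control_quantile_cutoff,
    presence_vectors,
    read_network_tsv,
    read_pairs_sam,
    read_pairs_tsv,
    write_network_tsv,
    write_pairs_tsv,
)
from .conftest import make_net


def pair(p1, p2, unique=(True, True), control=False, condition="EXP"):
    return MappedPair(p1, "+", unique[0], p2, "-", unique[1],
                      condition=condition, is_control=control)


class TestAssembly:
    def test_canonicalization_and_self(self, toy_map):
        # fragments: 0=[7,15), 1=[15,7)
        pairs = [pair(8, 16), pair(16, 8), pair(2, 3)]
        res = assemble_network(pairs, toy_map, "EXP")
        assert res.network.counts == {(0, 1): 2, (1, 1): 1}

    def test_nonunique_dropped_and_controls_routed(self, toy_map):
        pairs = [
            pair(8, 16),
            pair(8, 16, unique=(False, True)),
            pair(8, 16, control=True),
        ]
        res = assemble_network(pairs, toy_map, "EXP")
        assert res.network.total_count == 1
        assert res.control.total_count == 1
        assert res.n_dropped == 1

    def test_count_conservation(self, small_genome, rng):
        cfg, seq, gmap = small_genome
        from nucleoidgcc import pairs_from_network, simulate_controls

        net, _ = simulate_network(cfg, gmap)
        pairs = pairs_from_network(net, gmap, rng)[:2000]
        pairs += simulate_controls(cfg, gmap, rng)
        # corrupt some ends to non-unique
        pairs = [
            p if k % 7 else MappedPair(p.pos1, p.strand1, False, p.pos2,
                                       p.strand2, p.unique2, p.sample,
                                       p.condition, p.is_control)
            for k, p in enumerate(pairs)
        ]
        res = assemble_network(pairs, gmap, "EXP")
        assert (res.network.total_count + res.control.total_count
                + res.n_dropped) == res.n_input == len(pairs)

    def test_position_and_condition_errors(self, toy_map):
        with pytest.raises(ValueError, match="outside genome"):
            assemble_network([pair(25, 0)], toy_map, "EXP")
        with pytest.raises(ValueError, match="condition"):
            assemble_network([pair(1, 2, condition="SHX")], toy_map, "EXP")


class TestCutoff:
    def test_max_control_count_rule(self, toy_map):
        ctrl = make_net(toy_map, {(0, 0): 1, (0, 1): 2}, cutoff_applied=False)
        assert derive_cutoff(ctrl) == 2
        genomic = make_net(toy_map, {(0, 0): 3, (0, 1): 2, (1, 1): 1},
                           cutoff_applied=False)
        kept = genomic.apply_cutoff(2)
        assert kept.counts == {(0, 0): 3}
        assert kept.cutoff_applied and kept.cutoff == 2

    def test_empty_control_means_cutoff_zero(self, toy_map):
        assert derive_cutoff(make_net(toy_map, {}, cutoff_applied=False)) == 0

    def test_all_below_cutoff_gives_empty_network(self, toy_map):
        net = make_net(toy_map, {(0, 1): 2}, cutoff_applied=False)
        assert net.apply_cutoff(5).counts == {}

    def test_cutoff_monotonicity(self, small_genome):
        cfg, _, gmap = small_genome
        net, _ = simulate_network(cfg, gmap)
        sizes = [net.apply_cutoff(c).n_interactions for c in range(0, 6)]
        assert sizes == sorted(sizes, reverse=True)

    def test_quantile_alternative(self, toy_map):
        ctrl = make_net(toy_map, {(0, 0): 1, (0, 1): 2, (1, 1): 4},
                        cutoff_applied=False)
        assert control_quantile_cutoff(ctrl, 0.5) == 2
        assert control_quantile_cutoff(ctrl, 1.0) == 4 == derive_cutoff(ctrl)


class TestClassify:
    def test_self_and_adjacent(self, toy_map):
        assert classify_interaction((0, 0), toy_map) == "self"
        assert classify_interaction((0, 1), toy_map) == "adjacent"

    def test_short_long_boundary_at_threshold(self):
        cfg = SynthConfig(genome_length=20_000, seed=3)
        _, gmap = make_genome(cfg)
        mids = gmap.midpoints
        # find a non-adjacent pair with midpoint distance >= 800 and one < 800
        n = gmap.n_fragments
        d02 = min(abs(mids[0] - mids[2]) % 20_000, (mids[2] - mids[0]) % 20_000)
        expected = "short" if d02 < 800 else "long"
        assert classify_interaction((0, 2), gmap) == expected
        far = (0, n // 2)
        assert classify_interaction(far, gmap) == "long"

    def test_threshold_boundary_is_long(self, small_genome):
        """A pair exactly at the threshold distance is long (>= rule)."""
        from nucleoidgcc import circular_distance

        cfg, _, gmap = small_genome
        mids = gmap.midpoints
        d = int(circular_distance(int(mids[0]), int(mids[5]), gmap.length))
        assert classify_interaction((0, 5), gmap, short_long_threshold=d) == "long"
        assert classify_interaction((0, 5), gmap, short_long_threshold=d + 1) == "short"

    def test_unknown_fragment(self, toy_map):
        with pytest.raises(KeyError):
            classify_interaction((0, 9), toy_map)


class TestCompare:
    def test_shared_and_specific(self, toy_map):
        a = make_net(toy_map, {(0, 1): 5, (0, 0): 2})
        b = make_net(toy_map, {(0, 1): 3, (1, 1): 7})
        cmp = compare_conditions(a, b)
        assert cmp.shared == {(0, 1): (5, 3)}
        assert cmp.specific_to_a == {(0, 0): 2}
        assert cmp.specific_to_b == {(1, 1): 7}

    def test_empty_side(self, toy_map):
        a = make_net(toy_map, {})
        b = make_net(toy_map, {(0, 1): 3})
        cmp = compare_conditions(a, b)
        assert cmp.specific_to_b == b.counts and not cmp.shared

    def test_partition_property_random_networks(self, small_genome):
        cfg, _, gmap = small_genome
        net_a, _ = simulate_network(cfg, gmap)
        cfg_b = SynthConfig(genome_length=50_000, seed=43)
        net_b, _ = simulate_network(cfg_b, gmap)
        cmp = compare_conditions(net_a, net_b)
        sa, sb, sh = (set(cmp.specific_to_a), set(cmp.specific_to_b),
                      set(cmp.shared))
        assert not (sa & sb or sa & sh or sb & sh)
        assert sa | sb | sh == set(net_a.counts) | set(net_b.counts)

    def test_requires_cutoff_applied(self, toy_map):
        a = make_net(toy_map, {(0, 1): 1}, cutoff_applied=False)
        with pytest.raises(ValueError, match="cutoff"):
            compare_conditions(a, a)


class TestKappa:
    def test_worked_2x2_example(self):
        """a=20 both-present, b=5, c=10, d=15 both-absent:
        p_o = 0.7, p_e = 0.5, kappa = 0.4 exactly."""
        a = [1] * 20 + [1] * 5 + [0] * 10 + [0] * 15
        b = [1] * 20 + [0] * 5 + [1] * 10 + [0] * 15
        assert replicate_kappa(a, b) == pytest.approx(0.4, abs=1e-12)

    def test_identical_vectors(self):
        assert replicate_kappa([1, 0, 1, 0], [1, 0, 1, 0]) == 1.0

    def test_complementary_balanced(self):
        assert replicate_kappa([1, 1, 0, 0], [0, 0, 1, 1]) == -1.0

    def test_constant_equal_raters_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            replicate_kappa([1, 1, 1], [1, 1, 1])

    def test_matches_sklearn_on_random_vectors(self, rng):
        from sklearn.metrics import cohen_kappa_score

        a = rng.integers(2, size=200)
        b = (a ^ (rng.random(200) < 0.3)).astype(int)
        assert replicate_kappa(a, b) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12
        )

    def test_presence_universe_is_union_of_detected_pairs(self, toy_map):
        a = make_net(toy_map, {(0, 1): 5})
        b = make_net(toy_map, {(0, 1): 3, (1, 1): 7})
        universe, mat = presence_vectors([a, b])
        assert universe == [(0, 1), (1, 1)]
        assert mat.tolist() == [[True, False], [True, True]]


class TestIO:
    def test_pairs_tsv_roundtrip(self, tmp_path):
        pairs = [pair(8, 16), pair(1, 2, control=True)]
        path = tmp_path / "pairs.tsv"
        write_pairs_tsv(pairs, path)
        assert read_pairs_tsv(path) == pairs

    def test_network_tsv_roundtrip(self, toy_map, tmp_path):
        net = make_net(toy_map, {(0, 1): 5, (1, 1): 2})
        path = tmp_path / "net.tsv"
        write_network_tsv(net, path)
        back = read_network_tsv(path, toy_map, "EXP")
        assert back.counts == net.counts

    def test_sam_reader_pairs_mates_and_flags_uniqueness(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\n"
            "@SQ\tSN:chrom\tLN:20\n"
            "@SQ\tSN:spike\tLN:20\n"
            "r1\t99\tchrom\t9\t60\t4M\t=\t17\t8\tACGT\t####\n"
            "r1\t147\tchrom\t17\t60\t4M\t=\t9\t-8\tACGT\t####\n"
            "r2\t99\tchrom\t3\t5\t4M\t=\t9\t6\tACGT\t####\n"
            "r2\t147\tchrom\t9\t60\t4M\t=\t3\t-6\tACGT\t####\n"
            "r3\t99\tspike\t1\t60\t4M\t=\t5\t4\tACGT\t####\n"
            "r3\t147\tspike\t5\t60\t4M\t=\t1\t-4\tACGT\t####\n"
        )
        got = read_pairs_sam(sam, control_references={"spike"})
        assert len(got) == 3
        by_pos = {p.pos1: p for p in got}
        assert by_pos[8].unique1 and by_pos[8].unique2  # SAM 1-based -> 0-based
        assert not by_pos[2].unique1  # mapq 5 below threshold
        assert by_pos[0].is_control
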
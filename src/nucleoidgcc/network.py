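"""Fragment-pair interaction networks from mapped read pairs.

Proximity-ligation read pairs are aggregated into counts over unordered
restriction-fragment pairs, one network per condition (e.g. exponential
growth ``EXP`` vs stringent-response-induced ``SHX``). Exogenous
ligation-control pairs, spiked before ligation to measure random
inter-molecular ligation, are routed to a separate control network; the
maximum count seen among control interactions defines the significance
cutoff, and only genomic interactions strictly above it are retained.

Read pairs with a non-uniquely-mapped end are discarded. Duplicate read
pairs are counted, not collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .genome import GenomeMap, circular_distance

__all__ = [
    "MappedPair",
    "InteractionNetwork",
    "AssemblyResult",
    "ConditionComparison",
    "assemble_network",
    "derive_cutoff",
    "classify_interaction",
    "compare_conditions",
    "replicate_kappa",
    "presence_vectors",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_pairs_sam",
    "read_network_tsv",
    "write_network_tsv",
]

INTERACTION_CLASSES = ("self", "adjacent", "short", "long")


@dataclass(frozen=True)
class MappedPair:
    """One mapped paired-end ligation product.

    Positions are 0-based genome coordinates of the two read ends;
    ``unique1``/``unique2`` flag unambiguous mapping; ``is_control`` marks
    ligation-control (spiked) pairs.
    """

    pos1: int
    strand1: str
    unique1: bool
    pos2: int
    strand2: str
    unique2: bool
    sample: str = "S1"
    condition: str = "EXP"
    is_control: bool = False


@dataclass
class InteractionNetwork:
    """Counts over unordered fragment pairs for one condition.

    Keys are canonical ``(idA, idB)`` with ``idA <= idB``. ``cutoff`` is
    the ligation-control significance threshold; once ``cutoff_applied``
    every retained count is strictly greater than it.
    """

    genome: GenomeMap
    condition: str
    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    cutoff: int | None = None
    cutoff_applied: bool = False

    def add(self, i: int, j: int, count: int = 1) -> None:
        key = (i, j) if i <= j else (j, i)
        self.counts[key] = self.counts.get(key, 0) + count

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    @property
    def n_interactions(self) -> int:
        return len(self.counts)

    def apply_cutoff(self, cutoff: int) -> "InteractionNetwork":
        """Retain interactions with count strictly greater than ``cutoff``."""
        kept = {k: c for k, c in self.counts.items() if c > cutoff}
        return InteractionNetwork(
            self.genome, self.condition, kept, cutoff=cutoff, cutoff_applied=True
        )

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interaction table as (idA, idB, count) arrays (canonical order)."""
        if not self.counts:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        keys = sorted(self.counts)
        ia = np.array([k[0] for k in keys], dtype=np.int64)
        ib = np.array([k[1] for k in keys], dtype=np.int64)
        c = np.array([self.counts[k] for k in keys], dtype=np.int64)
        return ia, ib, c

    def same_genome(self, other: "InteractionNetwork") -> bool:
        return (
            self.genome is other.genome
            or (
                self.genome.length == other.genome.length
                and self.genome.cut_positions == other.genome.cut_positions
            )
        )


@dataclass
class AssemblyResult:
    """Outcome of network assembly: genomic network, control network and the
    non-unique-pair tally. Conservation holds by construction:
    ``network.total_count + control.total_count + n_dropped == n_input``."""

    network: InteractionNetwork
    control: InteractionNetwork
    n_dropped: int
    n_input: int


@dataclass
class ConditionComparison:
    """Set algebra over two cutoff-applied networks: pairs specific to each
    condition and pairs shared (with both counts retained)."""

    specific_to_a: dict[tuple[int, int], int]
    specific_to_b: dict[tuple[int, int], int]
    shared: dict[tuple[int, int], tuple[int, int]]


def assemble_network(
    pairs: Iterable[MappedPair], gmap: GenomeMap, condition: str
) -> AssemblyResult:
    """Aggregate mapped pairs into an interaction network.

    Pairs with any non-unique end are dropped; control-flagged pairs go to
    the control network. Both ends in one fragment record a self-interaction
    on ``(f, f)``.
    """
    net = InteractionNetwork(gmap, condition)
    ctrl = InteractionNetwork(gmap, condition + "_control")
    n_dropped = 0
    n_input = 0
    L = gmap.length
    for p in pairs:
        n_input += 1
        if p.condition != condition:
            raise ValueError(
                f"pair labeled condition {p.condition!r}, expected {condition!r}"
            )
        if not (0 <= p.pos1 < L and 0 <= p.pos2 < L):
            raise ValueError(
                f"pair position ({p.pos1}, {p.pos2}) outside genome [0, {L})"
            )
        if not (p.unique1 and p.unique2):
            n_dropped += 1
            continue
        i = gmap.locate_id(p.pos1)
        j = gmap.locate_id(p.pos2)
        (ctrl if p.is_control else net).add(i, j)
    return AssemblyResult(net, ctrl, n_dropped, n_input)


def derive_cutoff(control_network: InteractionNetwork) -> int:
    """Significance cutoff from the ligation control: the maximum count among
    control-derived interactions (0 if the control network is empty).
    Genomic interactions are retained only when strictly above it.
    """
    if not control_network.counts:
        return 0
    return max(control_network.counts.values())


def control_quantile_cutoff(control_network: InteractionNetwork, q: float) -> int:
    """Alternative cutoff rule: the ``q``-quantile of control interaction
    counts (ceil), for sensitivity analysis against the max rule."""
    if not control_network.counts:
        return 0
    vals = np.array(sorted(control_network.counts.values()))
    return int(np.ceil(np.quantile(vals, q)))


def classify_interaction(
    pair: tuple[int, int],
    gmap: GenomeMap,
    short_long_threshold: int = 800,
) -> str:
    """Classify a fragment pair as self / adjacent / short / long.

    Self = same fragment; adjacent = circularly consecutive fragment ids;
    otherwise the circular midpoint distance decides: below the threshold
    (800 bp by default) short, at or above it long.
    """
    i, j = pair
    n = gmap.n_fragments
    if not (0 <= i < n and 0 <= j < n):
        raise KeyError(f"unknown fragment id in {pair}")
    if i == j:
        return "self"
    if gmap.are_adjacent(i, j):
        return "adjacent"
    d = circular_distance(
        gmap.fragments[i].midpoint, gmap.fragments[j].midpoint, gmap.length
    )
    return "short" if d < short_long_threshold else "long"


def compare_conditions(
    net_a: InteractionNetwork, net_b: InteractionNetwork
) -> ConditionComparison:
    """Partition the union of two cutoff-applied networks into
    condition-specific and shared interaction sets."""
    if not net_a.same_genome(net_b):
        raise ValueError("networks built on different genomes")
    if not (net_a.cutoff_applied and net_b.cutoff_applied):
        raise ValueError("apply the ligation-control cutoff before comparing")
    keys_a = set(net_a.counts)
    keys_b = set(net_b.counts)
    shared_keys = keys_a & keys_b
    return ConditionComparison(
        specific_to_a={k: net_a.counts[k] for k in keys_a - shared_keys},
        specific_to_b={k: net_b.counts[k] for k in keys_b - shared_keys},
        shared={k: (net_a.counts[k], net_b.counts[k]) for k in shared_keys},
    )


def presence_vectors(
    networks: Iterable[InteractionNetwork],
    universe: Iterable[tuple[int, int]] | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Binary presence matrix over a universe of fragment pairs.

    By default the universe is every pair detected in ANY of the supplied
    networks — including all possible pairs would inflate agreement through
    absent–absent cells. Returns (ordered universe, bool matrix of shape
    n_networks x n_pairs).
    """
    nets = list(networks)
    if universe is None:
        keys: set[tuple[int, int]] = set()
        for net in nets:
            keys.update(net.counts)
        universe = sorted(keys)
    else:
        universe = list(universe)
    mat = np.zeros((len(nets), len(universe)), dtype=bool)
    for r, net in enumerate(nets):
        for c, key in enumerate(universe):
            mat[r, c] = key in net.counts
    return universe, mat


def replicate_kappa(presence_a, presence_b) -> float:
    """Cohen's kappa for two binary presence vectors over a shared universe.

    kappa = (p_o - p_e) / (1 - p_e) in the standard two-rater binary form.
    Undefined (raises) when both raters are constant and identical
    (chance agreement p_e = 1).
    """
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("presence vectors must be equal-length and non-empty")
    p_o = float(np.mean(a == b))
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        raise ValueError("kappa undefined: both raters constant and equal")
    return (p_o - p_e) / (1 - p_e)


# ---------------------------------------------------------------------------
# I/O

_PAIR_COLUMNS = [
    "pos1", "strand1", "unique1",
    "pos2", "strand2", "unique2",
    "sample", "condition", "is_control",
]


def write_pairs_tsv(pairs: Iterable[MappedPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_PAIR_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.pos1}\t{p.strand1}\t{int(p.unique1)}\t"
                f"{p.pos2}\t{p.strand2}\t{int(p.unique2)}\t"
                f"{p.sample}\t{p.condition}\t{int(p.is_control)}\n"
            )


def read_pairs_tsv(path) -> list[MappedPair]:
    """Read the TSV pair dialect (header: pos1 strand1 unique1 pos2 strand2
    unique2 sample condition is_control)."""
    pairs = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _PAIR_COLUMNS:
            raise ValueError(f"unexpected pair-file header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pairs.append(
                MappedPair(
                    int(f[0]), f[1], bool(int(f[2])),
                    int(f[3]), f[4], bool(int(f[5])),
                    f[6], f[7], bool(int(f[8])),
                )
            )
    return pairs


def read_pairs_sam(
    path,
    sample: str = "S1",
    condition: str = "EXP",
    min_mapq: int = 30,
    control_references: frozenset[str] | set[str] = frozenset(),
) -> list[MappedPair]:
    """Read paired records from SAM.

    Uniqueness policy: an end is uniquely mapped when it is mapped with
    mapping quality >= ``min_mapq``. Records aligned to a reference named in
    ``control_references`` are flagged as ligation-control pairs. SAM is
    1-based; positions are converted to 0-based on read.
    """
    import pysam

    mates: dict[str, object] = {}
    pairs: list[MappedPair] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in mates:
                first = mates.pop(rec.query_name)
                ctrl = (
                    first.reference_name in control_references
                    or rec.reference_name in control_references
                )
                pairs.append(
                    MappedPair(
                        pos1=first.reference_start if not first.is_unmapped else 0,
                        strand1="-" if first.is_reverse else "+",
                        unique1=(not first.is_unmapped)
                        and first.mapping_quality >= min_mapq,
                        pos2=rec.reference_start if not rec.is_unmapped else 0,
                        strand2="-" if rec.is_reverse else "+",
                        unique2=(not rec.is_unmapped)
                        and rec.mapping_quality >= min_mapq,
                        sample=sample,
                        condition=condition,
                        is_control=ctrl,
                    )
                )
            else:
                mates[rec.query_name] = rec
    return pairs


def write_network_tsv(net: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write("fragment_a\tfragment_b\tcount\n")
        for (i, j), c in sorted(net.counts.items()):
            fh.write(f"{i}\t{j}\t{c}\n")


def read_network_tsv(path, gmap: GenomeMap, condition: str) -> InteractionNetwork:
    net = InteractionNetwork(gmap, condition)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fragment_a"):
            raise ValueError(f"unexpected network header in {path}")
        for line in fh:
            i, j, c = line.split("\t")
            net.add(int(i), int(j), int(c))
    return net
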
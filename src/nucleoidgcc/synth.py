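"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes on a
circular bacterial chromosome:

* a genome carrying 4-cutter recognition sites at geometric spacing
  (~256 bp mean, the expectation for a 4-base motif) and a sinusoidal GC
  composition wave;
* an Ori:Ter copy-number gradient ``cn(x) = R**(1 - d_ori(x)/(L/2))`` —
  monotone decay from origin to terminus with exact endpoint ratio R,
  emulating overlapping replication rounds in fast-growing cells;
* contact counts with power-law distance decay, multiplicative copy-number
  dosage, an Ori-domain enrichment factor and a planted clustered region
  set with pairwise enrichment;
* uniformly random spiked ligation-control pairs;
* read depth following the copy-number gradient with optional GC bias;
* gene-order-autocorrelated (AR(1)) expression log-ratios with planted
  up/down blocks.

Counts are Poisson by default; the downstream statistics are count sums
and ranks, insensitive to mild overdispersion, but a gamma-mixture
overdispersion knob exists. Every generator is deterministic under a
fixed seed, and each returns a truth record of the factors it used.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .clustering import RegionSet, randomize_rs
from .expression import ExpressionTable
from .genome import GenomeMap, circular_distance, digest_genome
from .network import InteractionNetwork, MappedPair

__all__ = [
    "SynthConfig",
    "make_genome",
    "simulate_network",
    "simulate_controls",
    "simulate_depth",
    "simulate_expression",
    "pairs_from_network",
    "plant_regions",
    "copy_number_gradient",
    "write_fasta",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthConfig:
    """Ground-truth parameters of the synthetic chromosome.

    Lengths are bp. ``mean_spacing`` is the mean inter-site distance of the
    restriction motif (256 bp, the 4-cutter expectation). ``ori`` defaults
    to L/4 with the terminus antipodal. ``copy_ratio`` is the exact
    Ori:Ter endpoint ratio of the copy-number gradient (3 emulates fast
    growth; 1 switches the gradient off). ``decay_gamma`` is the contact
    distance-decay exponent, ``lambda0`` the base contact intensity,
    ``ori_alpha`` the Ori-domain contact enrichment within
    ``ori_radius``. ``region_beta`` is the pairwise contact enrichment
    between the ``n_regions`` planted regions of ``region_length`` bp.
    ``depth_mu`` is the mean read depth per ``depth_window`` at copy
    number 1. Expression: ``n_genes`` genes with AR(1) log2 ratios of
    lag-1 correlation ``expr_rho`` and stationary s.d. ``expr_sd``, with
    planted contiguous up/down blocks of ``block_size`` genes shifted by
    ``+-block_delta`` log2 units, measured with ``n_reps`` replicates of
    multiplicative noise ``rep_sd`` (log2 scale).
    """

    genome_length: int = 500_000
    mean_spacing: int = 256
    motif: str = "GCGC"
    cut_offset: int = 3
    gc_amplitude: float = 0.1
    gc_period: int = 50_000
    ori: int | None = None
    copy_ratio: float = 3.0
    decay_gamma: float = 0.5
    lambda0: float = 20.0
    ori_alpha: float = 4.0
    ori_radius: int | None = None
    n_regions: int = 10
    region_length: int = 200
    region_beta: float = 10.0
    n_control_pairs: int = 500
    depth_mu: float = 50.0
    depth_window: int = 1000
    gc_bias_slope: float = 0.0
    overdispersion: float = 0.0
    n_genes: int = 4000
    expr_rho: float = 0.85
    expr_sd: float = 1.0
    n_reps: int = 2
    rep_sd: float = 0.2
    block_size: int = 20
    block_delta: float = 3.0
    n_up_blocks: int = 1
    n_down_blocks: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copy_ratio < 1:
            raise ValueError("copy_ratio must be >= 1")
        if self.decay_gamma < 0:
            raise ValueError("decay_gamma must be >= 0")
        if self.ori_alpha < 1 or self.region_beta < 1:
            raise ValueError("enrichment factors must be >= 1")
        if self.mean_spacing >= self.genome_length:
            raise ValueError("mean site spacing must be below the genome length")

    @property
    def ori_position(self) -> int:
        return self.genome_length // 4 if self.ori is None else self.ori

    @property
    def ter_position(self) -> int:
        return (self.ori_position + self.genome_length // 2) % self.genome_length

    @property
    def ori_domain_radius(self) -> int:
        return self.genome_length // 8 if self.ori_radius is None else self.ori_radius

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, *stream])


def copy_number_gradient(cfg: SynthConfig, positions) -> np.ndarray:
    """True relative copy number at the given coordinates:
    ``R**(1 - d_ori/(L/2))``, so cn(ori) = R and cn(ter) = 1."""
    d = circular_distance(np.asarray(positions), cfg.ori_position, cfg.genome_length)
    return cfg.copy_ratio ** (1.0 - d / (cfg.genome_length / 2))


# ---------------------------------------------------------------------------
# genome

def make_genome(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[str, GenomeMap]:
    """Random circular sequence with restriction-motif instances at
    geometric spacing around the configured mean and motif-free gaps
    otherwise (accidental occurrences are scrubbed), plus its digest."""
    if rng is None:
        rng = cfg.rng(0)
    L = cfg.genome_length
    motif = cfg.motif.upper()
    mlen = len(motif)
    # kb-scale sinusoidal GC composition wave, decorrelated from the
    # genome-scale replication gradient
    x = np.arange(L)
    p_gc = 0.5 + cfg.gc_amplitude * np.sin(2 * np.pi * x / min(cfg.gc_period, L))
    u = rng.random(L)
    strong = u < p_gc  # G or C
    pick = rng.integers(2, size=L)
    seq = np.where(strong, np.where(pick == 0, ord("G"), ord("C")),
                   np.where(pick == 0, ord("A"), ord("T"))).astype(np.uint8)
    # motif sites at geometric gaps (mean spacing includes the motif itself)
    mean_gap = max(cfg.mean_spacing - mlen, 1)
    sites: list[int] = []
    pos = int(rng.integers(mean_gap))
    while pos + mlen <= L:
        sites.append(pos)
        pos += mlen + int(rng.geometric(1.0 / mean_gap))
    motif_bytes = np.frombuffer(motif.encode(), dtype=np.uint8)
    for s in sites:
        seq[s : s + mlen] = motif_bytes
    _scrub_accidental_motifs(seq, motif, sites, rng)
    text = seq.tobytes().decode()
    return text, digest_genome(text, motif, cfg.cut_offset)


def _scrub_accidental_motifs(
    seq: np.ndarray, motif: str, sites: list[int], rng: np.random.Generator
) -> None:
    """Mutate one base of every motif occurrence not in ``sites`` (circular
    scan) until only the intended occurrences remain."""
    L = len(seq)
    mlen = len(motif)
    intended = set(sites)
    spans = sorted(sites)
    for _ in range(50):
        text = seq.tobytes().decode()
        ext = text + text[: mlen - 1]
        dirty = False
        start = 0
        while True:
            i = ext.find(motif, start)
            if i == -1 or i >= L:
                break
            start = i + 1
            if i in intended:
                continue
            # pick a position of this occurrence outside every intended span
            for off in range(mlen):
                p = (i + off) % L
                k = bisect_right(spans, p) - 1
                inside = k >= 0 and p - spans[k] < mlen
                # wrap: a span near L-1 can cover position p near 0
                if not inside and spans and spans[-1] + mlen > L:
                    inside = p < (spans[-1] + mlen) % L
                if not inside:
                    seq[p] = ord("A") if seq[p] != ord("A") else ord("T")
                    dirty = True
                    break
        if not dirty:
            return
    raise RuntimeError("could not scrub accidental motif occurrences")


def write_fasta(seq: str, path, name: str = "synthetic_chromosome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for k in range(0, len(seq), 70):
            fh.write(seq[k : k + 70] + "\n")


# ---------------------------------------------------------------------------
# contact network

def plant_regions(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> RegionSet:
    """Disjoint uniformly placed regions whose pairwise contacts will be
    enriched by ``region_beta``."""
    if rng is None:
        rng = cfg.rng(1)
    template = RegionSet(
        "planted",
        np.array(
            [[0, cfg.region_length]] * cfg.n_regions, dtype=np.int64
        ),
        cfg.genome_length,
        source="custom",
    )
    placed = randomize_rs(template, cfg.genome_length, rng)
    return RegionSet("planted", placed.intervals, cfg.genome_length, "custom")


def simulate_network(
    cfg: SynthConfig,
    gmap: GenomeMap,
    rng: np.random.Generator | None = None,
    regions: RegionSet | None = None,
    condition: str = "EXP",
) -> tuple[InteractionNetwork, dict]:
    """Draw a contact network over all fragment pairs.

    Intensity for pair (i, j):
    ``lambda0 * cn_i * cn_j * (d_ij+1)**(-gamma) * alpha^[both in Ori
    domain] * beta^[endpoints in two distinct planted regions]``; counts
    are Poisson (gamma-mixed when ``overdispersion > 0``). The returned
    truth record stores every factor. The network is marked
    cutoff-applied (cutoff 0): it is a ground-truth network, not raw
    ligation output.
    """
    if rng is None:
        rng = cfg.rng(2)
    n = gmap.n_fragments
    if n * (n + 1) > 6e7:
        raise ValueError(f"{n} fragments: pair enumeration would overflow memory")
    mids = gmap.midpoints
    L = gmap.length
    iu, ju = np.triu_indices(n)
    d = circular_distance(mids[iu], mids[ju], L).astype(float)
    cn = copy_number_gradient(cfg, mids)
    lam = cfg.lambda0 * cn[iu] * cn[ju] * (d + 1.0) ** (-cfg.decay_gamma)
    in_ori = circular_distance(mids, cfg.ori_position, L) <= cfg.ori_domain_radius
    lam[in_ori[iu] & in_ori[ju]] *= cfg.ori_alpha
    if regions is None and cfg.region_beta > 1 and cfg.n_regions > 0:
        regions = plant_regions(cfg, rng)
    frag_region = np.full(n, -1, dtype=np.int64)
    if regions is not None:
        from .clustering import _fragment_region_labels

        _, frag_region = _fragment_region_labels(gmap, regions)
        ra, rb = frag_region[iu], frag_region[ju]
        lam[(ra >= 0) & (rb >= 0) & (ra != rb)] *= cfg.region_beta
    if not np.all(np.isfinite(lam)):
        raise OverflowError("non-finite contact intensity; check parameters")
    if cfg.overdispersion > 0:
        shape = 1.0 / cfg.overdispersion
        lam = lam * rng.gamma(shape, 1.0 / shape, size=lam.shape)
    counts = rng.poisson(lam)
    nz = counts > 0
    net = InteractionNetwork(
        gmap,
        condition,
        {
            (int(i), int(j)): int(c)
            for i, j, c in zip(iu[nz], ju[nz], counts[nz])
        },
        cutoff=0,
        cutoff_applied=True,
    )
    truth = {
        "cn": cn,
        "ori_domain": in_ori,
        "fragment_region": frag_region,
        "regions": regions,
        "lambda0": cfg.lambda0,
        "decay_gamma": cfg.decay_gamma,
        "ori_alpha": cfg.ori_alpha,
        "region_beta": cfg.region_beta if regions is not None else 1.0,
        "copy_ratio": cfg.copy_ratio,
    }
    return net, truth


def pairs_from_network(
    net: InteractionNetwork,
    gmap: GenomeMap,
    rng: np.random.Generator,
    sample: str = "S1",
) -> list[MappedPair]:
    """Expand a count network into mapped read pairs (one pair per count,
    positions uniform within the endpoint fragments)."""
    L = gmap.length
    pairs = []
    strands = "+-"
    for (i, j), c in sorted(net.counts.items()):
        fi, fj = gmap.fragments[i], gmap.fragments[j]
        for _ in range(c):
            pairs.append(
                MappedPair(
                    pos1=(fi.start + int(rng.integers(fi.length))) % L,
                    strand1=strands[int(rng.integers(2))],
                    unique1=True,
                    pos2=(fj.start + int(rng.integers(fj.length))) % L,
                    strand2=strands[int(rng.integers(2))],
                    unique2=True,
                    sample=sample,
                    condition=net.condition,
                )
            )
    return pairs


def simulate_controls(
    cfg: SynthConfig,
    gmap: GenomeMap,
    rng: np.random.Generator | None = None,
    condition: str = "EXP",
) -> list[MappedPair]:
    """Spiked ligation-control read pairs: uniformly random fragment pairs,
    so per-pair multiplicities are low Poisson-like counts."""
    if rng is None:
        rng = cfg.rng(3)
    L = gmap.length
    n = gmap.n_fragments
    out = []
    for _ in range(cfg.n_control_pairs):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        fi, fj = gmap.fragments[i], gmap.fragments[j]
        out.append(
            MappedPair(
                pos1=(fi.start + int(rng.integers(fi.length))) % L,
                strand1="+",
                unique1=True,
                pos2=(fj.start + int(rng.integers(fj.length))) % L,
                strand2="+",
                unique2=True,
                sample="ctrl",
                condition=condition,
                is_control=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# read depth

def simulate_depth(
    cfg: SynthConfig, seq: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Read-start positions whose windowed counts follow
    ``Poisson(mu * cn(window) * gc_bias(window))`` with positions uniform
    within each window. ``gc_bias = exp(slope * (gc - 0.5))``."""
    if rng is None:
        rng = cfg.rng(4)
    from .copynumber import depth_windows

    L = len(seq)
    w = cfg.depth_window
    gc = depth_windows([], seq, w).gc
    starts = np.arange(len(gc), dtype=np.int64) * w
    lens = np.minimum(starts + w, L) - starts
    centers = starts + lens // 2
    lam = (
        cfg.depth_mu
        * copy_number_gradient(cfg, centers)
        * np.exp(cfg.gc_bias_slope * (gc - 0.5))
        * (lens / w)
    )
    counts = rng.poisson(lam)
    reads = np.repeat(starts, counts) + (
        rng.random(int(counts.sum())) * np.repeat(lens, counts)
    ).astype(np.int64)
    return reads


# ---------------------------------------------------------------------------
# expression

def simulate_expression(
    cfg: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionTable, dict]:
    """Genes at uniform positions with AR(1) log2 SHX/EXP ratios over gene
    order, planted contiguous up/down blocks and replicate noise."""
    if rng is None:
        rng = cfg.rng(5)
    L = cfg.genome_length
    n = cfg.n_genes
    starts = np.sort(rng.choice(L, size=n, replace=False))
    lengths = rng.integers(500, 1500, size=n)
    ends = np.minimum(starts + lengths, L)  # genes kept clear of the wrap
    rho, sd = cfg.expr_rho, cfg.expr_sd
    eps = rng.normal(0.0, sd * np.sqrt(max(1 - rho**2, 1e-12)), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    blocks: dict[str, list[tuple[int, int]]] = {"up": [], "down": []}
    taken = np.zeros(n, dtype=bool)
    for kind, n_blocks, delta in (
        ("up", cfg.n_up_blocks, cfg.block_delta),
        ("down", cfg.n_down_blocks, -cfg.block_delta),
    ):
        for _ in range(n_blocks):
            for _attempt in range(1000):
                s = int(rng.integers(max(n - cfg.block_size, 1)))
                sl = slice(s, s + cfg.block_size)
                if not taken[sl].any():
                    x[sl] += delta
                    taken[sl] = True
                    blocks[kind].append((s, s + cfg.block_size))
                    break
            else:
                raise RuntimeError("could not place non-overlapping blocks")
    base = 2.0 ** rng.normal(8.0, 1.0, size=n)
    exp_levels = np.empty((n, cfg.n_reps))
    shx_levels = np.empty((n, cfg.n_reps))
    for rep in range(cfg.n_reps):
        exp_levels[:, rep] = base * 2.0 ** rng.normal(0, cfg.rep_sd, size=n)
        shx_levels[:, rep] = base * 2.0 ** (x + rng.normal(0, cfg.rep_sd, size=n))
    genes = pd.DataFrame(
        {
            "id": [f"g{k:05d}" for k in range(n)],
            "start": starts,
            "end": ends,
            "strand": np.where(rng.integers(2, size=n) == 0, "+", "-"),
        }
    )
    table = ExpressionTable(genes, {"EXP": exp_levels, "SHX": shx_levels}, L)
    truth = {"log2_ratio": x, "blocks": blocks, "rho": rho, "sd": sd}
    return table, truth
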
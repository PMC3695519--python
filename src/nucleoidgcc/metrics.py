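"""Contact matrices, crossing profiles, loop lengths, partner counts and
peak calling on binned interaction profiles."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap, circular_distance
from .network import InteractionNetwork

__all__ = [
    "ContactMatrix",
    "contact_matrix",
    "crossing_profile",
    "LoopLengthDistribution",
    "loop_lengths",
    "partner_counts",
    "find_peaks",
    "write_matrix_tsv",
    "write_matrix_triplets",
]


@dataclass
class ContactMatrix:
    """Symmetric binned contact-count matrix. The diagonal holds intra-bin
    (including self) interactions; the sum of the upper triangle plus the
    diagonal equals the network's total count."""

    bin_size: int
    matrix: np.ndarray
    genome_length: int
    condition: str

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def total(self) -> float:
        return float(np.triu(self.matrix).sum())


def contact_matrix(
    net: InteractionNetwork, gmap: GenomeMap, bin_size: int
) -> ContactMatrix:
    """Bin a network into a genome-wide contact matrix (fragment -> bin by
    midpoint; counts accumulated symmetrically)."""
    if bin_size > gmap.length:
        raise ValueError("bin size exceeds genome length")
    if not net.cutoff_applied:
        raise ValueError("apply the ligation-control cutoff before binning")
    n_bins = math.ceil(gmap.length / bin_size)
    frag_bin = gmap.midpoints // bin_size
    mat = np.zeros((n_bins, n_bins), dtype=np.int64)
    for (i, j), c in net.counts.items():
        b1, b2 = frag_bin[i], frag_bin[j]
        mat[b1, b2] += c
        if b1 != b2:
            mat[b2, b1] += c
    return ContactMatrix(bin_size, mat, gmap.length, net.condition)


def crossing_profile(
    net: InteractionNetwork,
    gmap: GenomeMap,
    ori: int = 0,
    weight_by_counts: bool = True,
) -> pd.DataFrame:
    """Frequency of interactions crossing each restriction fragment.

    An interaction crosses fragment f when f's midpoint lies strictly
    inside the shorter arc between the two endpoint midpoints (the
    maximum-likelihood loop path on a circle). When the endpoints are
    antipodal the two arcs tie and both are counted at half weight.
    Self-interactions cross nothing. Rows are ordered by circular distance
    of the fragment midpoint from the origin of replication.

    ``weight_by_counts=False`` counts each distinct interaction once
    instead of weighting by its read count.
    """
    if not net.cutoff_applied:
        raise ValueError("apply the ligation-control cutoff first")
    L = gmap.length
    mids = gmap.midpoints
    order = np.argsort(mids)
    sorted_mids = mids[order]
    freq = np.zeros(gmap.n_fragments, dtype=float)

    def _add_arc(start: int, end: int, w: float) -> None:
        """Add w to fragments with midpoint strictly inside the forward arc
        (start, end)."""
        if start < end:
            lo = np.searchsorted(sorted_mids, start, side="right")
            hi = np.searchsorted(sorted_mids, end, side="left")
            freq[order[lo:hi]] += w
        else:  # wraps the coordinate origin
            lo = np.searchsorted(sorted_mids, start, side="right")
            freq[order[lo:]] += w
            hi = np.searchsorted(sorted_mids, end, side="left")
            freq[order[:hi]] += w

    for (i, j), c in net.counts.items():
        if i == j:
            continue
        w = float(c) if weight_by_counts else 1.0
        ma, mb = int(mids[i]), int(mids[j])
        fwd = (mb - ma) % L
        if 2 * fwd == L:  # antipodal tie: both arcs at half weight
            _add_arc(ma, mb, w / 2)
            _add_arc(mb, ma, w / 2)
        elif fwd < L - fwd:
            _add_arc(ma, mb, w)
        else:
            _add_arc(mb, ma, w)

    dist_ori = circular_distance(mids, ori % L, L)
    df = pd.DataFrame(
        {
            "fragment_id": np.arange(gmap.n_fragments),
            "midpoint": mids,
            "distance_from_ori": dist_ori,
            "crossing_freq": freq,
        }
    )
    return df.sort_values("distance_from_ori", kind="stable").reset_index(drop=True)


@dataclass
class LoopLengthDistribution:
    """Count-weighted distribution of circular midpoint distances."""

    distances: np.ndarray
    weights: np.ndarray
    genome_length: int

    def mean(self) -> float:
        return float(np.average(self.distances, weights=self.weights))

    def quantiles(self, q=(0.25, 0.5, 0.75)) -> np.ndarray:
        order = np.argsort(self.distances)
        d = self.distances[order]
        cw = np.cumsum(self.weights[order])
        return np.interp(np.asarray(q) * cw[-1], cw, d)

    def histogram(self, bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(
            self.distances,
            bins=bins,
            range=(0, self.genome_length / 2),
            weights=self.weights,
        )


def loop_lengths(net: InteractionNetwork, gmap: GenomeMap) -> LoopLengthDistribution:
    """Distribution of interaction loop lengths (circular midpoint
    distances, weighted by read counts). Self-interactions contribute
    distance 0."""
    if not net.counts:
        raise ValueError("empty network has no loop-length distribution")
    mids = gmap.midpoints
    ia, ib, c = net.arrays()
    d = circular_distance(mids[ia], mids[ib], gmap.length)
    return LoopLengthDistribution(np.asarray(d, dtype=float), c.astype(float), gmap.length)


def partner_counts(net: InteractionNetwork, gmap: GenomeMap) -> np.ndarray:
    """Distinct interaction partners per fragment. A self-interaction makes
    the fragment its own partner (one partner); an uninvolved fragment has
    zero. Read counts do not matter."""
    partners: list[set[int]] = [set() for _ in range(gmap.n_fragments)]
    for i, j in net.counts:
        partners[i].add(j)
        partners[j].add(i)
    return np.array([len(s) for s in partners], dtype=np.int64)


def find_peaks(
    values,
    bin_size: int | None = None,
    min_covered: int = 10,
    n_mads: float = 3.0,
    circular: bool = True,
) -> list[dict]:
    """Call peaks on a binned profile.

    Peak bins exceed median + ``n_mads`` x MAD of the covered (finite)
    bins; adjacent peak bins (circularly, including the wrap join) merge
    into one interval. Returns a list of dicts with bin and bp coordinates
    (half-open; ``end_bp`` may be <= ``start_bp`` for a wrapping interval).
    Refuses profiles with fewer than ``min_covered`` covered bins.
    """
    v = np.asarray(values, dtype=float)
    covered = np.isfinite(v)
    if covered.sum() < min_covered:
        raise ValueError(
            f"only {int(covered.sum())} covered bins; need >= {min_covered}"
        )
    med = np.median(v[covered])
    mad = np.median(np.abs(v[covered] - med))
    thr = med + n_mads * mad
    is_peak = covered & (v > thr)
    if not is_peak.any():
        return []
    n = len(v)
    idx = np.flatnonzero(is_peak)
    runs: list[list[int]] = [[int(idx[0])]]
    for k in idx[1:]:
        if k == runs[-1][-1] + 1:
            runs[-1].append(int(k))
        else:
            runs.append([int(k)])
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][-1] == n - 1:
        runs[0] = runs.pop() + runs[0]
    out = []
    for run in runs:
        first, last = run[0], run[-1]
        peak = {
            "start_bin": first,
            "end_bin": last,
            "n_bins": len(run),
            "max_value": float(np.max(v[run])),
            "threshold": float(thr),
        }
        if bin_size is not None:
            peak["start_bp"] = first * bin_size
            peak["end_bp"] = (last + 1) * bin_size
        out.append(peak)
    return out


def write_matrix_tsv(cm: ContactMatrix, path) -> None:
    np.savetxt(path, cm.matrix, fmt="%d", delimiter="\t")


def write_matrix_triplets(cm: ContactMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tcount\n")
        for i in range(cm.n_bins):
            for j in range(i, cm.n_bins):
                if cm.matrix[i, j]:
                    fh.write(f"{i}\t{j}\t{cm.matrix[i, j]}\n")
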
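"""Windowed, GC-normalized relative copy number and copy-number correction.

In fast-growing cells with overlapping replication rounds the DNA dosage
rises from the terminus toward the origin of replication. Read depth in
tiling windows (1 kb by default) is normalized by the median depth of its
GC-content bin — controlling for amplification/sequencing GC bias — and
rescaled so the genome-wide median copy number is 1. The Ori:Ter ratio and
per-bin correction of interaction frequencies are derived from this
relative profile; no absolute ploidy or segmentation is attempted, since
only the relative profile enters the downstream arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import GenomeMap, circular_distance
from .network import InteractionNetwork, classify_interaction

__all__ = [
    "DepthProfile",
    "CopyNumberProfile",
    "depth_windows",
    "copy_number_profile",
    "ori_ter_ratio",
    "correct_binned_interactions",
    "write_copy_number_tsv",
]


@dataclass
class DepthProfile:
    """Read-start counts and GC fraction per tiling window (last window may
    be short)."""

    window: int
    genome_length: int
    counts: np.ndarray
    gc: np.ndarray

    @property
    def covered(self) -> np.ndarray:
        return self.counts > 0

    @property
    def window_starts(self) -> np.ndarray:
        return np.arange(len(self.counts), dtype=np.int64) * self.window

    @property
    def window_centers(self) -> np.ndarray:
        starts = self.window_starts
        ends = np.minimum(starts + self.window, self.genome_length)
        return (starts + ends) // 2


@dataclass
class CopyNumberProfile:
    """Per-window relative copy number, median scaled to 1; uncovered
    windows are NaN."""

    window: int
    genome_length: int
    cn: np.ndarray

    def __post_init__(self) -> None:
        covered = np.isfinite(self.cn)
        if covered.any():
            med = np.nanmedian(self.cn)
            if not math.isclose(med, 1.0, rel_tol=1e-9):
                raise ValueError("copy-number profile median must be 1")
            if np.any(self.cn[covered] <= 0):
                raise ValueError("covered windows must have positive cn")

    @classmethod
    def from_values(cls, window: int, genome_length: int, values) -> "CopyNumberProfile":
        """Build a profile from raw positive per-window values, rescaling so
        the median over covered windows is 1."""
        v = np.asarray(values, dtype=float).copy()
        med = np.nanmedian(v)
        if not np.isfinite(med) or med <= 0:
            raise ValueError("cannot rescale: non-positive median")
        return cls(window, genome_length, v / med)

    @property
    def window_centers(self) -> np.ndarray:
        starts = np.arange(len(self.cn), dtype=np.int64) * self.window
        ends = np.minimum(starts + self.window, self.genome_length)
        return (starts + ends) // 2

    def bin_means(self, bin_size: int) -> np.ndarray:
        """Mean cn of the windows whose centers fall in each tiling bin
        (NaN-aware)."""
        n_bins = math.ceil(self.genome_length / bin_size)
        idx = self.window_centers // bin_size
        out = np.full(n_bins, np.nan)
        for b in range(n_bins):
            vals = self.cn[idx == b]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[b] = vals.mean()
        return out


def depth_windows(read_starts, seq: str, window: int) -> DepthProfile:
    """Count read starts per tiling window and compute each window's GC
    fraction from the genome sequence."""
    L = len(seq)
    if window > L:
        raise ValueError("window exceeds genome length")
    starts = np.asarray(read_starts, dtype=np.int64)
    if starts.size and (starts.min() < 0 or starts.max() >= L):
        raise ValueError("read start outside genome")
    n = math.ceil(L / window)
    counts = np.bincount(starts // window, minlength=n)
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (is_gc == ord("G")) | (is_gc == ord("C"))
    cum = np.concatenate([[0], np.cumsum(is_gc)])
    w_starts = np.arange(n) * window
    w_ends = np.minimum(w_starts + window, L)
    gc = (cum[w_ends] - cum[w_starts]) / (w_ends - w_starts)
    return DepthProfile(window, L, counts, gc)


def _gc_groups(gc: np.ndarray, width: float, min_windows: int) -> list[np.ndarray]:
    """Group window indices by GC bins of the given width over the observed
    GC range, merging bins with fewer than ``min_windows`` members into
    their neighbor."""
    lo = np.floor(gc.min() / width) * width
    idx = ((gc - lo) / width).astype(int)
    occupied = sorted(set(idx.tolist()))
    groups = [np.flatnonzero(idx == b) for b in occupied]
    i = 0
    while len(groups) > 1 and i < len(groups):
        if len(groups[i]) < min_windows:
            j = i + 1 if i + 1 < len(groups) else i - 1
            groups[j] = np.concatenate([groups[j], groups[i]])
            del groups[i]
            i = 0  # restart: merged neighbor may itself have grown past min
        else:
            i += 1
    return groups


def copy_number_profile(
    depth: DepthProfile,
    gc_bin_width: float = 0.05,
    min_windows_per_bin: int = 10,
) -> CopyNumberProfile:
    """GC-normalized relative copy number.

    Each covered window's count is divided by the median count of its GC
    bin (bins of ``gc_bin_width`` over the observed GC range; bins with
    fewer than ``min_windows_per_bin`` covered windows are merged with
    neighbors), then the profile is rescaled to genome-wide median 1.
    Uncovered windows come out NaN.
    """
    covered = depth.covered
    if not covered.any():
        raise ValueError("all-zero depth profile")
    cn = np.full(len(depth.counts), np.nan)
    cov_idx = np.flatnonzero(covered)
    groups = _gc_groups(depth.gc[cov_idx], gc_bin_width, min_windows_per_bin)
    for g in groups:
        windows = cov_idx[g]
        med = np.median(depth.counts[windows])
        cn[windows] = depth.counts[windows] / med
    cn /= np.nanmedian(cn)
    return CopyNumberProfile(depth.window, depth.genome_length, cn)


def ori_ter_ratio(
    cnp: CopyNumberProfile,
    ori: int,
    ter: int,
    flank: int = 100_000,
) -> float:
    """Mean copy number within +/-flank of the origin divided by the mean
    within +/-flank of the terminus (uncovered windows excluded)."""
    centers = cnp.window_centers
    L = cnp.genome_length

    def _mean_near(pos: int) -> float:
        mask = circular_distance(centers, pos % L, L) <= flank
        vals = cnp.cn[mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"no covered windows within {flank} bp of {pos}")
        return float(vals.mean())

    return _mean_near(ori) / _mean_near(ter)


def correct_binned_interactions(
    net: InteractionNetwork,
    cnp: CopyNumberProfile,
    gmap: GenomeMap,
    bin_size: int = 10_000,
    class_filter: str | None = "long",
    short_long_threshold: int = 800,
    pairwise_cn: bool = False,
) -> np.ndarray:
    """Copy-number-corrected per-bin interaction frequency.

    Interactions (optionally restricted to one distance class, long-range
    by default) are tallied into tiling bins by endpoint-fragment midpoint;
    an interaction with endpoints in two different bins contributes its
    count to both. Each bin's tally is divided by (number of fragment
    midpoints in the bin x mean copy number of the bin). Bins containing no
    fragment midpoint are NaN.

    With ``pairwise_cn`` each interaction count is instead divided by the
    product of both endpoint-bin copy numbers before tallying, and the bin
    division uses only the fragment count — the matrix-style product
    correction rather than the 1-D endpoint-bin form.
    """
    if not net.cutoff_applied:
        raise ValueError("apply the ligation-control cutoff before correcting")
    L = gmap.length
    n_bins = math.ceil(L / bin_size)
    frag_bin = gmap.midpoints // bin_size
    frags_per_bin = np.bincount(frag_bin, minlength=n_bins)
    cn_bins = cnp.bin_means(bin_size)
    tally = np.zeros(n_bins, dtype=float)
    for (i, j), c in net.counts.items():
        if class_filter is not None:
            if classify_interaction((i, j), gmap, short_long_threshold) != class_filter:
                continue
        b1, b2 = frag_bin[i], frag_bin[j]
        w = c / (cn_bins[b1] * cn_bins[b2]) if pairwise_cn else c
        tally[b1] += w
        if b2 != b1:
            tally[b2] += w
    with np.errstate(divide="ignore", invalid="ignore"):
        if pairwise_cn:
            values = tally / frags_per_bin
        else:
            values = tally / (frags_per_bin * cn_bins)
    values[frags_per_bin == 0] = np.nan
    return values


def write_copy_number_tsv(cnp: CopyNumberProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("window_start\tcn\n")
        for k, v in enumerate(cnp.cn):
            fh.write(f"{k * cnp.window}\t{'' if np.isnan(v) else f'{v:.6g}'}\n")
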
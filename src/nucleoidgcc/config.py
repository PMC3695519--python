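"""Named numeric parameters shared across the analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Analysis-wide knobs.

    short_long_threshold
        Midpoint distance (bp) separating short- from long-range
        interactions; must stay below half the genome length.
    n_random_sets
        Number of randomized region sets per null method in permutation
        tests.
    region_flank
        Bases added either side of a point binding site when expanding it
        to a region.
    cn_window
        Window (bp) for read-depth / copy-number profiling.
    matrix_bins
        Contact-matrix bin sizes (bp) used for genome-wide maps.
    profile_bin
        Bin size (bp) for 1-D interaction profiles and their copy-number
        correction.
    expression_bin
        Bin size (bp) for binned expression means.
    ori_position / ter_position
        Replication origin and terminus coordinates (bp).
    """

    short_long_threshold: int = 800
    n_random_sets: int = 1000
    region_flank: int = 100
    cn_window: int = 1000
    matrix_bins: tuple[int, ...] = (20_000, 50_000)
    profile_bin: int = 10_000
    expression_bin: int = 50_000
    ori_position: int = 0
    ter_position: int | None = None
    rng_seed: int = 0

    def validate(self, genome_length: int) -> None:
        if not 0 < self.short_long_threshold < genome_length / 2:
            raise ValueError(
                "short/long threshold must lie in (0, genome_length/2)"
            )
        if self.cn_window > genome_length:
            raise ValueError("copy-number window exceeds genome length")
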
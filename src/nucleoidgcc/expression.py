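"""Expression ratios, regulated-gene calling and linear-genome clustering
diagnostics.

Per-gene expression levels for two conditions (exponential growth and
SHX-induced stringent response) are combined across replicates by
geometric mean, floored, and turned into log2 SHX/EXP ratios. Regulated
genes are called by a symmetric log2 threshold with a replicate
sign-consistency requirement. Two diagnostics probe structure along the
genome: binned mean expression against a gene-position shuffle null, and
the sample autocorrelation of ratios in gene order. Up/down gene sets can
be handed to :mod:`nucleoidgcc.clustering` as region sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.tsa.stattools import acf as _sm_acf

from .clustering import RegionSet

__all__ = [
    "ExpressionTable",
    "log2_ratios",
    "replicate_log2_ratios",
    "call_regulated",
    "BinnedExpression",
    "binned_expression_null",
    "expression_acf",
    "gc_expression_correlation",
    "genes_to_regions",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionTable:
    """Per-gene annotation plus expression levels per condition x replicate.

    ``genes`` holds columns id, start, end, strand (0-based half-open
    coordinates on the circular genome); ``levels[condition]`` is an
    (n_genes, n_replicates) array of positive expression values.
    """

    genes: pd.DataFrame
    levels: dict[str, np.ndarray]
    genome_length: int

    def __post_init__(self) -> None:
        n = len(self.genes)
        for cond, arr in self.levels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                arr = arr[:, None]
            if arr.shape[0] != n:
                raise ValueError(f"levels[{cond!r}] rows != gene count")
            self.levels[cond] = arr

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def order_by_start(self) -> np.ndarray:
        return np.argsort(self.genes["start"].to_numpy(), kind="stable")


def _geometric_mean(levels: np.ndarray) -> np.ndarray:
    return np.exp(np.log(np.maximum(levels, 1e-300)).mean(axis=1))


def log2_ratios(
    table: ExpressionTable,
    numerator: str = "SHX",
    denominator: str = "EXP",
    floor: float = 1.0,
) -> np.ndarray:
    """Per-gene log2 ratio of condition levels.

    Replicates are combined by geometric mean (ratios are multiplicative);
    the combined values are floored at a small positive constant before
    forming log2(numerator/denominator).
    """
    for cond in (numerator, denominator):
        if cond not in table.levels:
            raise KeyError(f"missing condition {cond!r}")
    num = np.maximum(_geometric_mean(table.levels[numerator]), floor)
    den = np.maximum(_geometric_mean(table.levels[denominator]), floor)
    return np.log2(num / den)


def replicate_log2_ratios(
    table: ExpressionTable,
    numerator: str = "SHX",
    denominator: str = "EXP",
    floor: float = 1.0,
) -> np.ndarray:
    """Per-replicate log2 ratios, pairing replicates by index (truncated to
    the smaller replicate count). Shape (n_genes, n_pairs)."""
    num = table.levels[numerator]
    den = table.levels[denominator]
    k = min(num.shape[1], den.shape[1])
    return np.log2(
        np.maximum(num[:, :k], floor) / np.maximum(den[:, :k], floor)
    )


def call_regulated(
    table: ExpressionTable,
    threshold: float = 1.0,
    numerator: str = "SHX",
    denominator: str = "EXP",
    floor: float = 1.0,
) -> pd.Series:
    """Call each gene up / down / unchanged.

    Up: combined log2 ratio >= threshold and every replicate-pair ratio
    positive; down symmetrically. Replicate sign disagreement forces
    "unchanged" regardless of the combined ratio.
    """
    ratio = log2_ratios(table, numerator, denominator, floor)
    reps = replicate_log2_ratios(table, numerator, denominator, floor)
    up = (ratio >= threshold) & np.all(reps > 0, axis=1)
    down = (ratio <= -threshold) & np.all(reps < 0, axis=1)
    call = np.where(up, "up", np.where(down, "down", "unchanged"))
    return pd.Series(call, index=table.genes["id"].to_numpy(), name="call")


@dataclass
class BinnedExpression:
    """Observed per-bin mean expression plus a shuffle-null envelope."""

    bin_size: int
    observed: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_genes_per_bin: np.ndarray

    @property
    def empty_bins(self) -> np.ndarray:
        return self.n_genes_per_bin == 0

    def exceeds_upper(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.observed > self.upper, nan=False)


def binned_expression_null(
    table: ExpressionTable,
    values: np.ndarray | None = None,
    bin_size: int = 50_000,
    n_shuffles: int = 1000,
    rng: np.random.Generator | None = None,
    envelope: tuple[float, float] = (2.5, 97.5),
) -> BinnedExpression:
    """Per-bin mean expression against a randomized-genome null.

    Genes map to tiling bins by start coordinate. The null shuffles the
    per-gene values over the fixed gene positions ``n_shuffles`` times;
    the envelope holds the per-bin 2.5/97.5 percentiles of the shuffled
    bin means. Bins with no genes are NaN (flagged via
    ``n_genes_per_bin``). By default ``values`` are the log2 SHX/EXP
    ratios; absolute levels can be supplied instead.
    """
    if rng is None:
        rng = np.random.default_rng()
    if values is None:
        values = log2_ratios(table)
    values = np.asarray(values, dtype=float)
    L = table.genome_length
    n_bins = -(-L // bin_size)
    gene_bin = table.genes["start"].to_numpy() // bin_size
    counts = np.bincount(gene_bin, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.bincount(gene_bin, weights=values, minlength=n_bins) / counts
    null = np.empty((n_shuffles, n_bins))
    v = values.copy()
    for t in range(n_shuffles):
        rng.shuffle(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            null[t] = np.bincount(gene_bin, weights=v, minlength=n_bins) / counts
    lower = np.full(n_bins, np.nan)
    upper = np.full(n_bins, np.nan)
    occupied = counts > 0
    lower[occupied] = np.percentile(null[:, occupied], envelope[0], axis=0)
    upper[occupied] = np.percentile(null[:, occupied], envelope[1], axis=0)
    return BinnedExpression(bin_size, observed, lower, upper, counts)


def expression_acf(table_or_values, max_lag: int = 32) -> np.ndarray:
    """Sample autocorrelation of log2 ratios in gene order along the
    genome, at lags 0..max_lag.

    Genes are ordered by start coordinate; the series is treated as linear
    (the circular wrap is negligible for lags far below the gene count).
    """
    if isinstance(table_or_values, ExpressionTable):
        order = table_or_values.order_by_start()
        values = log2_ratios(table_or_values)[order]
    else:
        values = np.asarray(table_or_values, dtype=float)
    if len(values) < max_lag + 2:
        raise ValueError("need at least max_lag + 2 genes")
    if np.ptp(values) == 0:
        raise ValueError("zero-variance expression series")
    return _sm_acf(values, nlags=max_lag, fft=True)


def gc_expression_correlation(
    table: ExpressionTable, seq: str, values: np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation between per-gene GC fraction and log2 ratio.

    Returns (r, p-value). Refuses fewer than 3 genes (undefined degrees of
    freedom) and degenerate (zero-variance) inputs.
    """
    if values is None:
        values = log2_ratios(table)
    if table.n_genes < 3:
        raise ValueError("need at least 3 genes for a correlation")
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(is_gc)])
    L = len(seq)
    gc = np.empty(table.n_genes)
    starts = table.genes["start"].to_numpy()
    ends = table.genes["end"].to_numpy()
    for g, (s, e) in enumerate(zip(starts, ends)):
        ln = (e - s) % L or L
        if s + ln <= L:
            gc[g] = (cum[s + ln] - cum[s]) / ln
        else:  # gene wraps the origin of coordinates
            gc[g] = (cum[L] - cum[s] + cum[(s + ln) % L]) / ln
    if np.ptp(gc) == 0 or np.ptp(values) == 0:
        raise ValueError("degenerate variance in GC or expression values")
    r, p = sps.pearsonr(gc, values)
    return float(r), float(p)


def genes_to_regions(
    table: ExpressionTable, calls: pd.Series, which: str, label: str | None = None
) -> RegionSet:
    """Region set of the gene bodies with a given regulation call, for
    hand-off to the clustering permutation test."""
    mask = (calls == which).to_numpy()
    if not mask.any():
        raise ValueError(f"no genes called {which!r}")
    iv = table.genes.loc[mask, ["start", "end"]].to_numpy()
    return RegionSet(label or f"{which}_genes", iv, table.genome_length, "genes")


# ---------------------------------------------------------------------------
# I/O (long format: id, start, end, strand, condition, replicate, level)

def read_expression_tsv(path, genome_length: int) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "start", "end", "strand", "condition", "replicate", "level"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression TSV missing columns {required - set(df.columns)}")
    genes = (
        df[["id", "start", "end", "strand"]]
        .drop_duplicates("id")
        .reset_index(drop=True)
    )
    gene_idx = {g: k for k, g in enumerate(genes["id"])}
    levels: dict[str, np.ndarray] = {}
    for cond, sub in df.groupby("condition"):
        reps = sorted(sub["replicate"].unique())
        arr = np.full((len(genes), len(reps)), np.nan)
        for c, rep in enumerate(reps):
            rsub = sub[sub["replicate"] == rep]
            arr[[gene_idx[g] for g in rsub["id"]], c] = rsub["level"].to_numpy()
        if np.isnan(arr).any():
            raise ValueError(f"missing levels for condition {cond!r}")
        levels[str(cond)] = arr
    return ExpressionTable(genes, levels, genome_length)


def write_expression_tsv(table: ExpressionTable, path) -> None:
    rows = []
    for cond, arr in table.levels.items():
        for rep in range(arr.shape[1]):
            for g in range(table.n_genes):
                rec = table.genes.iloc[g]
                rows.append(
                    (rec["id"], rec["start"], rec["end"], rec["strand"],
                     cond, rep + 1, arr[g, rep])
                )
    pd.DataFrame(
        rows, columns=["id", "start", "end", "strand", "condition", "replicate", "level"]
    ).to_csv(path, sep="\t", index=False)
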
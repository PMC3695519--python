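# Methods

`nucleoidgcc` analyses proximity-ligation (genome conformation capture)
data from a circular bacterial chromosome. This note documents the models
and procedures it implements, the parameters that matter, the synthetic
data the test suite runs on, and the numerical choices made where the
design was genuinely open.

## Coordinate model and digestion

All coordinates are 0-based, half-open and circular; file readers convert
at the boundary (BED is native; SAM is 1-based and shifted on read). An
in-silico digest places one cut per motif occurrence at
`(occurrence_start + cut_offset) mod L`. The default enzyme is HhaI
(`GCGC`, cut offset 3, i.e. `GCG^C`). Three deliberate choices:

* Occurrences wrapping the coordinate origin are cut like any other.
* Overlapping occurrences (`GCGCGC`) both cut.
* The enzyme's 2-nt 3′ overhang is ignored: a single blunt cut coordinate
  defines fragment boundaries, because downstream analyses use fragment
  identity, never end chemistry.

With `k >= 1` cuts the circle splits into exactly `k` fragments numbered
in coordinate order; an uncut genome is one fragment `[0, L)`. Fragment
midpoints (circular) are the reference points for distances and binning
throughout.

## Interaction networks and the ligation-control cutoff

Read pairs with any non-uniquely-mapped end are discarded (SAM policy:
mapped with MAPQ ≥ 30 by default, configurable). Retained pairs increment
the count of their unordered fragment pair; duplicates are counted, not
collapsed, since the upstream protocol gives no deduplication step.
Spiked ligation-control pairs measure the background of random
inter-molecular ligation; they are routed to a separate control network.

The significance cutoff is the **maximum count observed among control
interactions**, and genomic interactions are retained only when strictly
above it. Rationale: the control bounds the count a purely random
inter-molecular ligation can reach in this library, and the maximum is
the conservative envelope of that bound. A quantile-based alternative
(`control_quantile_cutoff`) is exposed for sensitivity analysis, as is a
per-million normalization question: the cutoff here is global (raw
counts), which is correct when control spikes scale with library size.

Interaction classes: `self` (same fragment), `adjacent` (circularly
consecutive fragment ids), otherwise `short`/`long` split at a circular
midpoint distance of 800 bp (configurable; must stay below L/2).

Replicate concordance uses Cohen's kappa on binary presence vectors. The
universe of pairs is **every pair detected in any compared sample**, not
all possible pairs — the latter inflates agreement through the vast
number of absent–absent cells. The universe is an explicit argument so
either convention can be tested.

## Copy number

Fast-growing cells initiate overlapping replication rounds, producing an
Ori-to-Ter DNA dosage gradient. The estimator is intentionally simple:
read-start counts in 1-kb tiling windows, each covered window divided by
the median count of its GC bin (bins of width 0.05 over the observed GC
range, bins with fewer than 10 covered windows merged with neighbors),
then rescaled to genome-wide median 1. No segmentation or absolute ploidy
is attempted: only the relative profile enters downstream arithmetic
(Ori:Ter ratio, per-bin correction), so a median-per-GC-bin normalization
suffices. Uncovered windows are NaN and excluded everywhere.

The Ori:Ter ratio averages copy number within ±100 kb (configurable) of
each locus. The copy-number correction of a binned interaction profile
divides each 10-kb bin's tally by (number of fragment midpoints in the
bin × mean bin copy number); an interaction spanning two bins contributes
its count to both. This matches 1-D per-bin profiles; a product-form
(`cn_i * cn_j`) pairwise option exists for matrix-style correction.

## Contact metrics

* Contact matrices accumulate counts symmetrically over midpoint bins;
  the upper triangle plus diagonal conserves the network total exactly.
* The crossing profile asks which fragments an interaction loops over:
  a fragment is crossed when its midpoint lies strictly inside the
  **shorter arc** between the endpoint midpoints. The shorter arc is the
  maximum-likelihood loop path on a circle; antipodal ties count both
  arcs at half weight. Counts weight the profile by default, with a
  binary per-interaction option.
* Loop lengths are count-weighted circular midpoint distances.
* Partner counts are distinct partners per fragment; a self-interaction
  makes a fragment its own (single) partner.
* Peak calling on a corrected profile marks bins above median + 3×MAD of
  covered bins and merges adjacent peak bins (circularly). The rule is a
  robust-outlier convention chosen here; it needs at least 10 covered
  bins to be meaningful and refuses fewer.

## Region clustering: the circular permutation test

For a set of m ≥ 2 regions, two statistics are computed on the
exclusion-filtered network (self-interactions and midpoint distances
< 800 bp removed first, configurable):

* **total interaction frequency** — summed counts of interactions with at
  least one endpoint fragment overlapping a region, each interaction
  counted once however many regions it touches;
* **clustering frequency** — summed counts of interactions whose
  endpoints overlap two *different* regions. An interaction confined to
  one region (e.g. two fragments inside one interval) counts toward
  total but not clustering.

"Frequency" is summed read counts; a binary distinct-interaction mode is
available for sensitivity analysis.

Null models, 1000 draws each by default:

* **RS (random spacing)**: each region is placed independently and
  uniformly, lengths preserved. Randomized regions may not overlap one
  another (real binding-site sets are disjoint); placement is sequential
  rejection sampling with a 10 000-attempt cap, and the constraint can
  be switched off.
* **CLS (conserved linear spacing)**: the whole configuration is rotated
  by a single uniform offset. A rotation (without reflection) is exactly
  the transformation that preserves every pairwise circular gap, so the
  invariant holds by construction and is asserted per draw in tests.

Empirical p-values use the plain frequency convention: `p_high` is the
fraction of null values ≥ observed, `p_low` the fraction ≤ observed. The
`(r+1)/(N+1)` estimator is available (`plus_one=True`) and is the right
choice when exact zeros are a problem, e.g. calibration studies. The
randomization streams are seeded per method (`[seed, 0]` for RS,
`[seed, 1]` for CLS) so results are bit-reproducible and the draws can be
replayed through the public randomizers.

## Expression and space

Replicate expression levels are combined by geometric mean (ratios are
multiplicative), floored at 1 unit of the expression scale, and turned
into log2 SHX/EXP ratios. Regulation calls use a symmetric threshold
(default |log2| ≥ 1) plus a replicate sign-consistency requirement; the
threshold is a knob, not a claim about any particular platform's
significance rule. Diagnostics of spatial structure along the genome:

* per-50-kb-bin mean expression against a null that shuffles values over
  the fixed gene positions (1000 shuffles; 2.5/97.5 percentile
  envelope); empty bins are flagged, not imputed;
* sample autocorrelation of ratios in gene order (linear ordering; the
  circular wrap is negligible at lags far below the gene count);
* Pearson correlation of per-gene GC fraction with the ratio.

Up/down gene sets convert to region sets and feed the clustering
permutation test unchanged; this hand-off is exercised end-to-end in the
test suite.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, with recorded
ground truth:

* **Genome**: motif sites at geometric spacing (mean 256 bp, the 4-cutter
  expectation), motif-free elsewhere; a sinusoidal GC wave (amplitude
  0.1, period 50 kb). The short period mimics the kb-scale compositional
  variation of real genomes and keeps GC statistically decoupled from
  the genome-scale replication gradient, which is what makes GC
  normalization identifiable.
* **Copy number**: `cn(x) = R^(1 − d_ori(x)/(L/2))` with R = 3 by
  default — a monotone Ori→Ter decay with exact endpoint ratio R,
  emulating overlapping replication rounds. The functional form is a
  modeling choice; only monotonicity and the endpoint ratio matter
  downstream.
* **Contacts**: pair intensity
  `λ0·cn_i·cn_j·(d+1)^(−γ)·α^[both endpoints in the Ori domain]·β^[endpoints
  in two distinct planted regions]`, Poisson counts. Defaults λ0 = 20,
  γ = 0.5, α = 4 (Ori domain = ±L/8), β = 10 over ten 200-bp planted
  regions. The shallow decay exponent keeps long-range contacts an
  appreciable share of the library, as ligation libraries of the
  condensed nucleoid show; a steep polymer-like decay would leave
  essentially no long-range signal at 256-bp fragment resolution.
* **Controls**: uniformly random fragment pairs (500 read pairs), giving
  the low Poisson-like multiplicities a ligation spike produces.
* **Depth**: per-window Poisson with mean μ·cn·exp(slope·(GC−0.5)),
  μ = 50 per kb window.
* **Expression**: AR(1) log2 ratios over gene order (ρ = 0.85, unit
  stationary s.d.), planted 20-gene up/down blocks of ±3 log2 units,
  two replicates with 0.2 log2 units of multiplicative noise.

Not emulated: sequence-level read errors and mapping ambiguity,
PCR-duplicate structure, replication-fork dynamics, overdispersion beyond
the optional gamma-mixture knob, and any biological correlation between
expression and contacts. Passing tests therefore demonstrate the
correctness and calibration of the *statistics* under a known generating
process, not the biological conclusions one would draw from real
libraries.

## Experiment design in the acceptance checks

Parameter-recovery experiments isolate the effect under test: the
planted-cluster recovery runs with the Ori enrichment and copy gradient
switched off (α = 1, R = 1), and the calibration experiment additionally
sets β = 1, so that each check measures exactly one generator feature
against its estimator. Null calibration draws the observed region set
from the same distribution as the null draws (uniform disjoint
placement), which makes the empirical p-value exactly exchangeable and
its sub-0.05 rate interpretable.

Problem sizes: recovery and calibration use 50–500-kb genomes (a few
hundred to ~2000 fragments) with 200–1000 randomizations; copy-number and
expression experiments use the natural 4.64-Mb chromosome scale, where
they are cheap. These sizes give the quoted tolerances comfortable
sampling margins.

## Known limitations

* The cutoff rule is a conservative envelope; with very few control
  pairs it degenerates to low cutoffs and retains more noise.
* The GC normalization assumes depth bias is a smooth function of window
  GC; it cannot separate a bias that is genuinely collinear with the
  replication gradient.
* RS placement is sequential, so for region sets filling a large
  fraction of the circle the draw is not exactly uniform over
  non-overlapping configurations (and may fail outright); the sets this
  test is designed for occupy well under 1% of the genome.
* `region_stats` assigns an interaction to a region via endpoint
  *fragment* overlap, so region resolution is bounded by fragment size.
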
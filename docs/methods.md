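# Methods

This note documents the models and procedures implemented in `tmtpipe`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Data model and filtering

A dataset is a proteins × channels matrix of reporter-ion intensities with
per-protein flags (decoy/"reverse", contaminant, only-identified-by-site)
and per-channel metadata (plex, channel index, role, sex, treatment).
Channels are either `experimental` or `pooled_reference`; a pooled channel
carries an equal mix of the plex's experimental samples.

Zero or blank reporter intensities are stored as missing rather than as
numeric zero: a zero reporter intensity is an absent measurement, and
treating it as a value would produce −∞ under the log2 transform. Row
filtering removes flagged protein groups and then every protein with any
missing value across the table's channels, so all downstream stages operate
on complete data. Filtering happens before normalization; because every
normalization factor is estimated on complete rows only, this ordering does
not change the factor estimates, and it keeps each stage free of NaN
handling. Gene symbols are matched case-insensitively across tables, and a
protein group with several gene names is represented by the first listed
symbol (recorded in the matrix metadata).

## Normalization

Stages run in the fixed order SL → TMM → batch correction.

**Sample loading (SL).** Within each plex, channel totals are equalized to
the plex mean. This removes global pipetting/labeling differences and the
per-plex loading shift. Factors are computed on proteins present in all
channels of the plex; a channel with zero total is a hard error.

**TMM.** Within each plex, the reference channel is the one whose upper
quartile is closest to the mean upper quartile. Per channel, M-values
`log2(x_j/x_ref)` and A-values `½·log2(x_j·x_ref)` are trimmed (30 % of M
and 5 % of A from each tail, by rank) and the factor is 2 to the
precision-weighted mean of the surviving M, with delta-method weights
`1/(1/x_j + 1/x_ref)`. Factors are anchored so they multiply to 1 within the
plex (geometric-mean anchoring); the un-anchored factors, for which the
reference channel is exactly 1, are available via `rescale=False`. TMM is
computed within plex rather than across all channels because the plexes have
not been aligned yet at this stage.

**Batch correction.** Two interchangeable methods:

- *IRS* (intensity scale): per protein, the plex reference is the geometric
  mean of its pooled channels, the target the geometric mean of the
  references across plexes, and every channel of the plex is multiplied by
  `target/ref`. Geometric means keep the correction symmetric on the log
  scale; after IRS the pooled references are identical across plexes, and
  the operation is idempotent. Proteins with a zero or missing pool value in
  any plex cannot be scaled and are dropped (the count is reported).
- *Linear model* (log2 scale): per protein, an additive model
  `value = group mean + batch offset` with sum-to-zero batch coding is fit
  by least squares and the fitted batch offsets subtracted. Group-mean
  differences are unchanged by construction; pooled channels form their own
  group so they are preserved. The design must not confound batch with
  group (every group observed in more than one plex). This is used for
  noisier datasets where per-protein IRS factors would propagate pool noise.

SL and TMM are positive per-channel scalings and therefore preserve ranks
within each channel; IRS is a positive per-protein scaling and preserves the
ordering of channels within each protein row inside a plex.

**QC.** Coefficients of variation are computed per group per protein on the
intensity (2^x) scale as `100·sd/mean` with the sample (n−1) standard
deviation, then averaged per group — on this scale a replicate log2-sd of σ
implies CV ≈ `sqrt(exp((σ ln 2)²) − 1)`. Pairwise Pearson correlations are
computed on log2 values over shared proteins, and PCA on protein-centered
log2 sample profiles by SVD (no unit-variance scaling).

## Differential testing

The moderated statistic is the SAM form `d = diff / (se + s0)` with pooled
two-sample standard error (a Welch variant is available behind a flag). At
`s0 = 0` this is exactly the classic pooled t statistic; `s0 > 0` (default
0.5, on the log2 scale) forces small-variance proteins to also show a
minimum fold change. Testing is two-sided throughout.

FDR is estimated by label permutation with group sizes preserved. With four
replicates per group there are C(8,4) = 70 distinct assignments, so the 250
requested randomizations collapse to exhaustive enumeration of the 69
non-identity assignments — the default analysis is therefore fully
deterministic given the data. When sampling is needed, distinct assignments
are drawn uniformly without replacement from a seeded generator. For a
threshold t, `FDR(t) = π0 · mean_perm #{|d*| ≥ t} / #{|d| ≥ t}` with π0
fixed at 1 (conservative; no π0 estimation is attempted). A protein's
q-value is the minimum estimated FDR over the rejection thresholds that
would call it (t ≤ its |d|), which makes q monotone non-increasing in |d|.
The mean false-positive count is the default aggregator; the median is
available behind a flag. Proteins constant across all samples are dropped
before testing (both F and d are undefined there).

The optional ANOVA prefilter runs a one-way fixed-effects F-test across the
four sex × treatment groups with Benjamini–Hochberg adjustment across
proteins and keeps q < 0.05; the filtered universe is what the pairwise
permutation tests see. The prefilter is intended for lower-coverage, noisier
datasets; the deep dataset skips it. No correction is applied across the
three pairwise contrasts (a deliberate, documented property of the original
analysis style).

## Overlap accounting

Two directional significant lists are intersected by case-normalized gene
symbol (accession fallback for empty symbols; if several protein groups map
to one symbol, the smallest-q entry represents it). The summary reports
unique and common counts, the same-/opposite-direction split of the common
set, the overlap as a percentage of each list, and the same-direction
percentage of the overlap. Percentages are reported rounded half away from
zero to one decimal — the convention that reproduces printed values exactly
— while the integer counts are retained.

## Over-representation analysis

One-sided hypergeometric upper tail `P[X ≥ k]` per gene set, with the
universe defined as all proteins quantified in the dataset after filtering
(the natural background for a quantified-proteome experiment; a
genome-scale background, as web services default to, can be supplied by
passing a larger universe). Sets are intersected with the universe first;
sets with empty intersection are skipped and therefore excluded from the
BH denominator. Up- and down-regulated lists are tested separately, and the
report keeps at most the top five sets below q < 0.05 per run — possibly
fewer, possibly none.

## Complex detection

Networks keep edges with combined score ≥ 0.7 (the high-confidence STRING
threshold; the separate 1 % FDR setting of web-based network viewers
concerns their enrichment display and does not gate edge inclusion here).
MCODE-style detection then:

1. weights each vertex by `k_max × density(core)` where `k_max` is the
   highest k-core order of the vertex's closed neighborhood and `core` that
   k-core's subgraph; vertices with degree < 4 weigh 0;
2. expands complexes outward from seeds in decreasing weight order,
   admitting unassigned neighbors with weight ≥ seed_weight × (1 − 0.2), to
   a maximum depth of 100;
3. haircut: the complex is reduced to the 2-edge-connected component
   containing the seed. This removes singly-connected material — the classic
   pendant-vertex haircut is the special case of a one-vertex attachment —
   and also prevents a single bridge edge between two dense complexes from
   fusing them into one diluted cluster; vertices stripped here return to
   the unassigned pool and can form their own complex. An optional fluff
   step (off by default) adds boundary vertices by neighborhood density;
4. discards complexes whose induced subgraph lacks a k-core of order ≥ 4,
   scores the rest as density × node count, and ranks by score, then size,
   with the lexicographically smallest member as the deterministic
   tie-break.

On graphs of up to 12 nodes the implementation is verified against an
independent brute-force reference implementing the same admission rules
with its own graph primitives.

## Synthetic data

The generator emulates the target study design: 2 plexes × 10 channels,
each plex holding 2 replicates of each of the four groups plus 2 pooled
channels. Per protein and experimental channel,
`log2 signal = base + group effects + batch(protein, plex) + N(0, σ_within)`
and `intensity = plex_loading × channel_loading × 2^signal`. Pooled channels
carry the arithmetic mean of the plex's eight realized pre-loading
intensities, times their own loading factor and measurement noise — so with
noise and loading disabled a pool equals the channel mean exactly.

Defaults, chosen as plausible conventions where no empirical value exists
(they are synthetic conventions, not measured claims): base abundances
log-normal (log2 mean 18, sd 2, mimicking reporter-ion dynamic range);
σ_within = 0.25 (implying ~17 % intensity-scale replicate CV); per-channel
loading uniform in [0.7, 1.3] plus a per-plex loading shift in [0.8, 1.25];
per-protein per-plex batch shifts N(0, 0.5) on the log2 scale (what IRS
removes); 10 % of proteins carry sex effects and 10 % per-sex treatment
effects of mean |log2| 1.0 (sd 0.3, random sign); 1 % decoy and 1 %
contaminant rows, 0.5 % only-by-site rows; 2 % of cells missing completely
at random. Missingness is MCAR only — intensity-dependent missingness is
not modeled, because the row filter removes all incomplete rows anyway.

What the synthetic benchmarks show: that the pipeline controls its nominal
FDR and recovers effects of the stated size under the design's replication,
and that every deterministic transformation is exact. What they do not
show: performance under ratio compression, peptide-to-protein rollup
artifacts, intensity-dependent missingness, or non-additive batch effects —
none of which the generator models.

## Determinism and numerics

All randomness flows from one root seed through named substreams (per
dataset, per stage, per comparison), so re-running with the same
configuration and seed gives byte-identical numeric outputs (TSVs are
written with a fixed `%.10g` float format). Degenerate inputs fail loudly:
zero-total channels, confounded batch designs, insufficient replicates and
empty queries raise typed errors with distinct CLI exit codes. Default
problem sizes in the packaged configuration (a few hundred proteins per
dataset) keep a full orchestrated run in the seconds range; all statistical
behavior scales to larger tables without algorithmic change, since the
permutation test is vectorized across proteins.

## Known limitations

- Exact per-protein results of any specific published dataset are not
  reproduced here; that requires the original raw data and database search.
- π0 = 1 makes the permutation FDR conservative when many proteins are
  truly differential.
- The ANOVA prefilter changes the multiple-testing universe of the pairwise
  tests; with it enabled, a pure-null dataset usually yields no tested
  proteins at all.
- The enrichment background and the complex-detection expansion details are
  configurable precisely because the field's web tools leave them
  under-specified; results with bundled synthetic gene sets are
  illustrative, not biological findings.
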
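# tmtpipe

Quantitative analysis of multi-batch TMT (tandem mass tag) proteomics with
pooled reference channels: normalization across channels and plexes,
s0-moderated differential testing with permutation-based FDR, overlap
accounting between differential lists, gene-set over-representation, and
dense-complex detection on protein–protein interaction networks.

## Who this is for

Isobaric-labeling experiments quantify up to ten samples per mass-spectrometry
run ("plex") through reporter-ion intensities. Intensities are comparable
within a plex but not across plexes, so multi-run studies carry pooled
reference channels — equal mixes of the experimental samples — that anchor a
batch correction. `tmtpipe` implements the full downstream analysis for such
designs, exemplified by a two-plex study of four experimental groups (male and
female mice, control and nicotine treatment; groups `MC`, `FC`, `MN`, `FN`,
two biological replicates of each per plex, plus two pooled channels per
plex). Every stage is also exercisable on a built-in synthetic-data generator
with known ground truth, so the pipeline's error rates can be measured.

## Methods at a glance

- **Normalization** (three stages, in order):
  1. *Sample loading (SL)*: per channel `j` within a plex,
     `f_j = mean(totals) / total_j`, equalizing total reporter intensity.
  2. *Trimmed mean of M-values (TMM)*: per channel against a reference
     channel (upper quartile closest to the plex mean), with
     `M = log2(x_j / x_ref)`, `A = ½·log2(x_j · x_ref)`; the top/bottom 30 %
     of M and 5 % of A are trimmed and the factor is `2^(weighted mean M)`,
     anchored to multiply to 1 across the plex.
  3. *Batch correction*: either **internal reference scaling (IRS)** — per
     protein `i`, `f_i(plex) = target_i / ref_i(plex)` where `ref_i` is the
     geometric mean of the plex's pooled channels and `target_i` the
     geometric mean of the `ref_i` across plexes — or least-squares removal
     of additive per-plex offsets on the log2 scale (for noisier datasets).
- **Differential testing**: SAM-style moderated statistic
  `d = (mean_A − mean_B) / (se + s0)` with pooled standard error and
  `s0 = 0.5`; FDR estimated from label permutations (250 by default,
  exhaustive when fewer distinct assignments exist):
  `FDR(t) = π0 · E_perm[#{|d*| ≥ t}] / #{|d| ≥ t}`, q-values monotonized.
  An optional one-way ANOVA prefilter (BH, FDR < 0.05) restricts the tested
  universe for low-coverage datasets. The three standard contrasts are
  `MC vs FC`, `FN vs FC`, `MN vs MC` (second group = reference).
- **Overlap accounting**: unique/common proteins between two directional
  significant lists, with same-/opposite-direction breakdown and percentages.
- **Enrichment**: one-sided hypergeometric over-representation
  `P[X ≥ k]` against GMT gene sets, BH across sets, top-5 reporting, up- and
  down-regulated lists tested separately.
- **PPI complexes**: edges kept at combined score ≥ 0.7; MCODE vertex
  weighting (highest k-core of the closed neighborhood × its density),
  seeded expansion (node score cutoff 0.2, degree 4, k-core 4, max depth
  100), haircut, complex score = density × nodes.

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

```python
import tmtpipe as tp

design = tp.SyntheticDesign(n_proteins=300, seed=1)   # 2 plexes, 4 groups
matrix, truth = tp.generate_dataset(design)
filtered = tp.filter_rows(matrix)                     # flags + missing rows
norm, factors = tp.normalize_pipeline(filtered, batch_method="irs")
results, _ = tp.run_pairwise_suite(
    norm, tp.TestConfig(seed=3, anova_enabled=False))
for label, res in results.items():
    print(label, res.counts())
print(tp.truth_confusion(truth, results["MC_vs_FC"]))
```

prints

```
MC_vs_FC {'n_tested': 192, 'n_significant': 19, 'n_up': 8, 'n_down': 11}
FN_vs_FC {'n_tested': 192, 'n_significant': 14, 'n_up': 9, 'n_down': 5}
MN_vs_MC {'n_tested': 192, 'n_significant': 19, 'n_up': 9, 'n_down': 10}
{'tp': 19, 'fp': 0, 'tn': 171, 'fn': 2, 'fdr': 0.0, 'sensitivity': 0.9047...}
```

Of the 300 simulated proteins, 192 survive the decoy/contaminant and
missing-value filters; at `s0 = 0.5` and FDR < 0.05 the male-vs-female
contrast calls 19 proteins, all of them truly differential (empirical FDR 0,
sensitivity 0.90 against the generator's ground truth).

The full orchestrated analysis (four datasets, QC, overlaps, enrichment,
complexes, manifest) runs with

```sh
tmtpipe run --out out/ --seed 7
```

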
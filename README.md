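# segmeta

Segment-wise case/control GWAS enrichment scanning with permutation-based
significance and multi-cohort combination.

Instead of hunting for single genome-wide-significant SNPs, `segmeta` tiles
the autosomes with large, 50%-overlapping windows (2–32 Mbp), counts the
nominally significant per-SNP trend-test associations inside each window, and
asks — via case/control label permutation, which preserves linkage
disequilibrium — whether that count is larger than chance ("metasignificance").
Evidence is then combined over independent cohorts two ways: a compound
replication rule (the segment must pass a per-sample threshold in every
cohort) and Fisher's combined probability test. A synthetic-cohort generator
with haplotype-block LD, optional population stratification, and a planted
segment of many weak-effect risk SNPs supports end-to-end validation.

## Package layout

| module | contents |
|---|---|
| `segmeta.genotype_io` | PLINK 1 binary (`.bed/.bim/.fam`) and plain-text cohort I/O |
| `segmeta.association` | Armitage trend test (`N·r²` form); EIGENSTRAT-style PC residualization |
| `segmeta.segmentwise` | segment lattice, nominal counts, permutation metasignificance, targeted-region test |
| `segmeta.multicohort` | Fisher's combined probability, compound/Bonferroni thresholds, cross-cohort alignment |
| `segmeta.geneset` | set-based gene test (greedy LD-pruned selection + permutation) |
| `segmeta.synthdata` | synthetic cohort generator and fixture writer |
| `segmeta.cli` | `segmeta` command-line interface |

## Command-line usage

Every permutation command requires an explicit `--seed`; identical seeds give
identical outputs.

```bash
# three cohorts with an enriched 8 Mbp interval planted at chr1:16-24 Mbp
for i in 0 1 2; do
  segmeta simulate --out-dir cohorts --cohort-id c$i \
    --chrom-length-mbp 1:40 --snp-spacing-bp 25000 \
    --planted-interval 1:16:24 --planted-or 1.08 --seed $((100 + i))
done

# per-cohort segment scans (widths in Mbp; TSV per width + Manhattan export)
for i in 0 1 2; do
  segmeta scan cohorts/c$i.bed --out-prefix scans/c$i \
    --widths-mbp 2,4,8,16,32 --n-permutations 1000 --seed $((7 + i))
done

# cross-cohort combination for one width
segmeta combine scans/c0.w8.tsv scans/c1.w8.tsv scans/c2.w8.tsv \
  --out combined_w8.tsv --per-sample-threshold 0.0264

# targeted test of an ad-hoc interval
segmeta region cohorts/c0.bed --chrom 1 --start-bp 16000000 --end-bp 24000000 \
  --n-permutations 1000 --seed 7

# set-based gene test (genes.tsv: name, chrom, start, end; 1-based inclusive)
segmeta geneset cohorts/c0.bed --genes genes.tsv --out genes_c0.tsv --seed 7
```

Stratification-adjusted scans: add `--eigenstrat-components 10` to `scan` or
`region` to residualize case/control status on the top genotype principal
components before testing.

## Conventions

- SNP positions are 1-based base pairs; segment and gene intervals are
  half-open `[start, end)` internally.
- Segments of width *w* start at every multiple of *w/2* from position 0.
- Nominal significance is strict (`p < alpha`); permutation p-values use the
  `(1 + exceedances) / (n_permutations + 1)` estimator, so the floor with
  1000 permutations is ≈ 0.001.
- Dosages count the A1 allele as stored; the trend statistic is invariant
  under allele flips. Missing dosages are pairwise-deleted per SNP.

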
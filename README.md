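# amplikit

Batch primer design with built-in specificity screening, optimised for
targeted amplicon sequencing (TAS) on 150 bp paired-end platforms.

Given a table of genomic target sites (`CHROM`, `POS`, `PROJ`) and a
reference genome FASTA, amplikit designs one primer pair per site, predicts
every place in the genome that pair could amplify (including
forward–forward and reverse–reverse mispriming), scores and classifies the
off-targets, and merges everything back onto the input as an annotated,
tab-delimited report. It is aimed at labs running tens to thousands of
parallel PCRs — TAS panels, mosaicism validation, variant confirmation —
where manual per-primer specificity review does not scale.

## How it works

**1. Design waterfall.** For each site, primers are first sought in the
*TAS-opt* geometry: both primer 3′ ends 60–100 bp from the target,
product optimum 190 bp, so the target base is covered by *both* 150 bp
reads of a paired-end fragment. Sites that cannot host this strict
geometry fall back to *Relaxed-right* (forward primer stays anchored at
60–100 bp, reverse side free, product ≤ 500 bp), then *Relaxed-left* (the
mirror image). Fallback triggers only on design failure; a designed pair
that later shows concerning off-targets is reported as-is.

**2. In-silico PCR.** Each pair (as FR, FF and RR query pairings) is
scanned against the whole reference with a gapless seed-and-extend
matcher: a locus is considered when an exact 11-mer tile of the primer
(sampled every 5 bases) occurs there, and accepted when the 3′-terminal
base matches exactly and the 3′-most 15 bases hold at least two matches
per mismatch. Convergent bindings within 800 bp become predicted products
with a 0–1000 viability score — 1000 for a perfect match, with mismatches
in the five 3′-most bases penalised twice as heavily as 5′ ones.

**3. Off-target evaluation.** Hits on decoy contigs are dropped, as are
hits scoring below 750. Each surviving off-target product is globally
aligned to the on-target product (match +1, mismatch 0, free gaps, i.e.
the best co-linear match count) and normalised twice — by the off-target
length and by the on-target length. An off-target reaching 80 % on either
denominator is a high-quality (concerning) off-target, HQ; anything lower
is low-quality, LQ. The report records `primer_count` (1 + number of
retained off-targets) and a boolean `concerning_off_targets` flag.

A small statistics helper computes the mutant allelic fraction
MAF = alt/depth and its Wilson 95 % score interval for downstream TAS
read-count analysis.

## Worked example

The fixture generator builds fully synthetic, seeded mini-genomes, so the
whole pipeline runs without downloads:

```python
from amplikit import FixtureSpec, PlantSpec, make_genome, make_target_table

spec = FixtureSpec(
    seed=42,
    contigs=(("chr1", 60_000), ("chr2", 40_000)),
    targets=(("chr1", 20_000, "demo"), ("chr2", 15_000, "demo")),
    planted_offtargets=(PlantSpec(0, "chr1", 50_000, 0.0),),  # exact duplicate
)
make_genome(spec, "demo")
make_target_table(spec, "demo/targets.csv")
```

```bash
$ amplikit design --input demo/targets.csv --reference demo/fixture.fa --outdir demo/out
sites: 2  designed: 2  with concerning off-targets: 1
report: demo/out/report.tsv
```

`demo/out/report.tsv` (selected columns):

| variant_ID | primer_name | forward_primer_sequence | amplicon_length | primer_count | concerning_off_targets |
|---|---|---|---|---|---|
| demo_chr1_20000 | demo_chr1_20000_TAS-opt | GTTCGTGGACCCTAGTGATCACATAT | 196 | 2 | True |
| demo_chr2_15000 | demo_chr2_15000_TAS-opt | GGTTTCACGTGCGAGGGTG | 195 | 1 | False |

The first site's neighbourhood was planted a second time at chr1:50 000,
so its pair amplifies twice: `primer_count` 2 means one off-target, and
because the duplicate is exact (normalised match 1.0 ≥ 0.80) it is HQ and
the pair is flagged concerning. The second site amplifies only its own
locus. `demo/out/offtarget_details.tsv` holds the per-off-target detail:

```
variant_ID       chrom  start  end    query_pairing  score  ...  normalized_match_to_test_amplicon  class
demo_chr1_20000  chr1   50141  50337  FR             1000   ...  1.0                                HQ
```

Audit files `products.fa` (predicted product sequences) and `hits.bed`
(0-based half-open product intervals with scores) are written alongside.

MAF statistics:

```bash
$ amplikit maf counts.tsv        # TSV with 'alt' and 'depth' columns
alt  depth  maf  ci_lower   ci_upper
5    10     0.5  0.236645   0.763355
```

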
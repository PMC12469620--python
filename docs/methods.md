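# Methods

## Problem and scope

amplikit automates the design–screen–annotate loop for panel-scale PCR:
one primer pair per genomic target site, a genome-wide prediction of what
else each pair might amplify, and a per-site verdict a bench scientist can
act on. The package covers design, in-silico PCR, off-target evaluation,
reporting, allele-fraction statistics, and a synthetic-fixture generator;
read alignment, pileup analysis and wet-lab concerns are out of scope.

## Design geometries

The default layout serves 150 bp paired-end targeted amplicon sequencing.
A fragment of ~190 bp sequenced from both ends covers its midpoint twice,
so the *TAS-opt* geometry demands both primer 3′ ends 60–100 bp from the
target base, roughly equidistant, with product optimum 190 bp and an
accepted range of 150–200 bp. When no such pair exists, *Relaxed-right*
keeps the forward primer anchored (60–100 bp) and frees the reverse side
up to a 500 bp product; *Relaxed-left* mirrors it. Only one read then
covers the target — half the theoretical depth, traded for designability.
The three modes run as a waterfall (TAS-opt → Relaxed-right →
Relaxed-left), each stage attempted only for sites the previous stage
failed; this ordering between the two relaxed modes is a convention, not a
preference of one side's biology. Fallback is triggered by design failure
only: a pair rejected later for concerning off-targets is reported with
that verdict rather than re-designed, so the report always reflects the
best geometry that was designable.

The published distance band (60–100 bp) and the 190/500 bp product
figures are the geometry's defining constants; the accepted product range
150–200 bp for TAS-opt is this package's concrete encoding of "both 3′
ends 60–100 bp out with ~20 nt primers" and is configurable.

## The built-in design engine

Candidate primers of 18–27 nt are enumerated at every admissible 3′
position, filtered on hard constraints — A/C/G/T only, GC 20–80 %,
homopolymer runs ≤ 5, nearest-neighbour melting temperature within
50–66 °C (SantaLucia parameters, 50 nM primer, 50 mM Na⁺, via Biopython's
`MeltingTemp.Tm_NN`) — and ranked by |Tm − 58 °C|. The 50 best per side
are paired; a pair's penalty adds the two primer penalties, the Tm
imbalance |Tm_F − Tm_R|, 0.05·|product − optimum|, and, for TAS-opt,
0.2·|d_F − d_R| for equidistance. The single best pair is retained;
alternates are discarded because the report schema carries one pair per
site. The Tm window is set wider than classical 57–63 °C interactive
practice because it is an *acceptance band*, not a ranking target: on
near-50 % GC genomic sequence, nearest-neighbour Tm of 18–27-mers at these
salt/primer conditions spans roughly 48–66 °C, and the penalty still
steers selection toward balanced, 58 °C-ish pairs.

Windows of ±500 bp are extracted around each target (covering the 500 bp
relaxed product on either side); primers overlapping N are rejected by the
hard constraints, so poly-N stretches make a geometry infeasible rather
than erroring.

## In-silico PCR matcher

Binding search is gapless seed-and-extend. Seeds are exact 11-mers of the
primer sampled every 5 bases (the final tile is always included so the 3′
end is seedable); a genomic locus is examined only if one seed occurs
there in register. An alignment is accepted when (a) the 3′-terminal
`min_perfect` = 1 base matches exactly and (b) the 3′-most `min_good` = 15
bases contain at least two matches per mismatch. Convergent
(plus-strand/minus-strand) accepted bindings on one contig with outer span
≤ `max_size` = 800 bp become predicted products. Each designed pair is
screened as three query pairings — FR, FF, RR — because a single primer
binding in both orientations amplifies on its own.

Scoring is anchored at 1000 for a perfect duplex and decreases with
mismatch load:

    score = round(1000 · (1 − (w_left + w_right)/2)),
    w = Σ_mismatches (2 if within the 3′-most 5 bases else 1) / primer_length

clipped to [0, 1000]. The two published anchors — 1000 for perfect
on-targets and the 750 retention threshold — are honoured; the
interpolation between them is this package's documented convention, since
no standard formula exists for mismatch-laden priming viability.

Approximations, stated plainly: bindings are gapless (no primer/template
indels), products never span contigs, and no thermodynamic (ΔG) duplex or
primer-dimer model is applied. At the default settings the seed
requirement makes the matcher slightly conservative for primers whose
mismatches break every sampled tile; the brute-force oracle in the test
suite applies the identical rules, so equivalence checks compare
like with like. An adapter can ingest FASTA/BED output of an external
in-silico PCR binary into the same hit records; it is disabled by default
and every shipped analysis uses the internal engine.

## Off-target evaluation

Hits on decoy contigs are removed first (default name patterns `_alt`,
`_random`, `_decoy`, `chrUn`, `_fix`, `HLA-`; configurable, since decoy
nomenclature varies by reference release). Hits scoring below 750 are then
discarded — 750 itself is retained. Each surviving off-target product is
globally aligned to the on-target ("gold") product with match +1,
mismatch 0, gap 0 via Biopython's `PairwiseAligner`; under that scoring
the alignment score equals the best co-linear match count (the LCS
length), so normalising by the test (off-target) length keeps values in
[0, 1] while normalising by the gold length may slightly exceed 1 for
longer off-targets. Classification uses the larger of the two normalised
values — the conservative, more-flagging choice, recorded per call so
users can re-threshold — with HQ at ≥ 0.80 and LQ below. When every hit
for a site is filtered away (no on-target), off-targets are still
assessed against the design-predicted amplicon slice of the reference so
the report row is complete, and the site's `ISPCR` flag is False.

`primer_count` is 1 + the number of retained off-targets; `concerning` is
true when any off-target is HQ.

## Allele statistics

MAF = alt/depth; the Wilson score interval uses the exact closed form
with z from the normal quantile (so any confidence level works), no
continuity correction. At alt = 0 and alt = depth the bounds are exactly
0 and 1 by construction, avoiding float round-off at the extremes.

## Synthetic fixtures

The generator emulates what the method needs from a reference: long
uniform-random A/C/G/T background (near-unique 11-mers at 20 kb+, hence
designable and scannable), planted target sites, optional decoy contigs,
and planted off-target copies at exact substitution divergence
(`round(d·L)` substitutions, positions recorded in a JSON manifest).
Copies can preserve or corrupt primer footprints independently of interior
divergence, separating "will it amplify" from "does it resemble the
amplicon". It does not emulate repeat families, segmental duplications,
GC heterogeneity or sequencing reads — so green tests demonstrate
correctness of the machinery, not off-target prevalence in real genomes,
where repetitive sequence makes multi-hit pairs far more common.

Fixture sizes in the shipped tests and acceptance checks (20–100 kb
genomes, 1–4 sites, 100 randomized matcher-equivalence trials) were chosen
as the smallest scales at which every code path — seeding, mismatch
acceptance, pairing, both relaxed fallbacks, HQ/LQ boundaries — is
exercised with non-degenerate probability.

## Numerical and tie-break conventions

- Coordinates: input POS is 1-based (VCF/ClinVar convention); everything
  internal and all BED output is 0-based half-open.
- On-target assignment: among FR hits containing the target position, the
  highest score wins, ties broken by smaller product. FF/RR hits are never
  on-target.
- Report ordering: chromosomes sort naturally (1–22, X, Y, M, others
  lexicographically; an optional `chr` prefix is ignored for ranking but
  never rewritten), then by position; the sort is stable, so re-running on
  sorted input is idempotent.
- Duplicate input rows (same CHROM, POS, PROJ) collapse to one with a
  warning — their derived variant IDs would collide in every output.
- The reverse primer name carries the `_R` suffix, forward `_F`.

## Known limitations

- No multiplex cross-pair compatibility checking, no adapter tails, no
  exon/gene-boundary awareness (genomic PCR only).
- The mismatch-viability score is a calibrated stand-in, not a
  thermodynamic model; treat mid-range scores (750–950) as qualitative.
- The whole reference is held in memory as strings during scanning —
  appropriate for panel references and fixtures, not for whole mammalian
  genomes in constrained memory.
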
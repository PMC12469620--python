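"""In-silico PCR: genome-wide, mismatch-tolerant amplicon prediction.

For a designed primer pair the scanner asks: where in the genome could this
pair plausibly produce a PCR product? Binding sites are found by gapless
seed-and-extend matching — an exact ``tile_size``-mer sampled every
``step_size`` along the primer must occur at a locus before it is examined
— and a candidate binding is accepted when

* the 3'-terminal ``min_perfect`` bases match the template exactly, and
* within the 3'-most ``min_good`` bases there are at least two matches for
  every mismatch.

Accepted bindings on opposite strands of one contig that converge within
``max_size`` bp form an :class:`AmpliconHit`. Because mispriming can also
occur between two copies of the *same* primer, each pair is screened as
three query pairings: forward–reverse (FR), forward–forward (FF) and
reverse–reverse (RR).

Each hit gets a 0–1000 viability score: 1000 for a perfect match, with
penalties per mismatch that weigh 3'-proximal mismatches (the 5 bases
nearest the 3' end) twice as heavily as 5'-proximal ones::

    score = round(1000 * (1 - (w_left + w_right) / 2)),
    w = sum(2 if offset in 3'-most 5 bases else 1 for each mismatch) / len

No indels are modelled (bindings are gapless), and products never span
contigs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Seq import Seq

from .design import PrimerPair

logger = logging.getLogger(__name__)

#: Number of 3'-terminal bases whose mismatches incur a doubled penalty.
THREE_PRIME_WEIGHT_SPAN = 5

QUERY_PAIRINGS = ("FR", "FF", "RR")


@dataclass(frozen=True)
class MatcherParams:
    """Seed-and-extend matcher settings.

    Defaults mirror a permissive off-target screen: a single exact 3' base
    suffices (``min_perfect=1``), the 3'-most 15 bases need two matches per
    mismatch (``min_good=15``), exact 11-mers every 5 bases seed candidate
    loci, and products are capped at 800 bp.
    """

    min_perfect: int = 1
    min_good: int = 15
    tile_size: int = 11
    step_size: int = 5
    max_size: int = 800

    def __post_init__(self) -> None:
        if min(self.min_perfect, self.min_good, self.tile_size,
               self.step_size, self.max_size) < 1:
            raise ValueError("all matcher parameters must be positive")
        if self.tile_size < self.step_size:
            raise ValueError("tile_size must be >= step_size")


@dataclass(frozen=True)
class PrimerBinding:
    """One gapless primer/genome match.

    ``site_start``/``site_end`` are 0-based half-open on the contig;
    ``mismatch_positions`` are offsets from the primer 5' end.
    """

    primer_role: str  # "left" or "right" within its query pairing
    strand: str  # "+" or "-"
    chrom: str
    site_start: int
    site_end: int
    mismatch_positions: tuple[int, ...]

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def length(self) -> int:
        return self.site_end - self.site_start


@dataclass
class AmpliconHit:
    """One predicted PCR product."""

    query_pairing: str  # FR, FF or RR
    chrom: str
    start: int
    end: int
    left_binding: PrimerBinding
    right_binding: PrimerBinding
    product_seq: str
    score: int = 0
    is_on_target: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_query_pairings(pair: PrimerPair) -> list[tuple[str, str, str]]:
    """The three (left, right, label) query pairings screened per pair."""
    f, r = pair.fwd_seq, pair.rev_seq
    return [(f, r, "FR"), (f, f, "FF"), (r, r, "RR")]


# ---------------------------------------------------------------------------
# Binding search


def _accept(primer: str, template: str, params: MatcherParams
            ) -> Optional[tuple[int, ...]]:
    """Apply the 3'-anchored acceptance rules to one gapless alignment.

    ``template`` is the genome slice oriented 5'→3' of the primer. Returns
    mismatch offsets (from the primer 5' end) or None if rejected.
    """
    L = len(primer)
    mismatches = tuple(i for i in range(L) if primer[i] != template[i])
    # exact 3'-terminal stretch
    for i in range(L - params.min_perfect, L):
        if primer[i] != template[i]:
            return None
    # two matches per mismatch inside the 3'-most min_good window
    w = min(params.min_good, L)
    mm = sum(1 for i in range(L - w, L) if primer[i] != template[i])
    if (w - mm) < 2 * mm:
        return None
    return mismatches


def _has_seed(primer: str, template: str, params: MatcherParams) -> bool:
    """At least one sampled exact tile of the primer occurs in register."""
    L = len(primer)
    offsets = list(range(0, L - params.tile_size + 1, params.step_size))
    # always sample the final tile so the 3' end is seedable
    last = L - params.tile_size
    if offsets and offsets[-1] != last:
        offsets.append(last)
    for o in offsets:
        if primer[o:o + params.tile_size] == template[o:o + params.tile_size]:
            return True
    return False


def _scan_oriented(primer: str, text: str, params: MatcherParams) -> list[tuple[int, tuple[int, ...]]]:
    """Seed-and-extend scan of ``text`` for ``primer`` in one orientation.

    Returns (start, mismatch_offsets) for accepted loci, both in ``text``
    coordinates / primer orientation.
    """
    L = len(primer)
    n = len(text)
    tile = params.tile_size
    offsets = list(range(0, L - tile + 1, params.step_size))
    last = L - tile
    if offsets and offsets[-1] != last:
        offsets.append(last)
    candidates: set[int] = set()
    for o in offsets:
        seed = primer[o:o + tile]
        pos = text.find(seed)
        while pos != -1:
            start = pos - o
            if 0 <= start <= n - L:
                candidates.add(start)
            pos = text.find(seed, pos + 1)
    hits = []
    for start in sorted(candidates):
        template = text[start:start + L]
        mm = _accept(primer, template, params)
        if mm is not None:
            hits.append((start, mm))
    return hits


def find_bindings(
    primer_seq: str,
    genome: Mapping[str, str],
    params: MatcherParams = MatcherParams(),
    primer_role: str = "left",
) -> list[PrimerBinding]:
    """All accepted binding loci of one primer, both strands, all contigs.

    ``genome`` maps contig name → uppercase sequence. Plus-strand bindings
    have the primer 3' end at ``site_end - 1``; minus-strand bindings at
    ``site_start``.
    """
    primer_seq = primer_seq.upper()
    if len(primer_seq) < params.tile_size:
        raise ValueError(
            f"primer ({len(primer_seq)} nt) shorter than tile_size "
            f"({params.tile_size})"
        )
    out: list[PrimerBinding] = []
    for chrom, seq in genome.items():
        n = len(seq)
        for start, mm in _scan_oriented(primer_seq, seq, params):
            out.append(PrimerBinding(primer_role, "+", chrom,
                                     start, start + len(primer_seq), mm))
        # minus strand: scan the reverse complement, map back
        rc = revcomp(seq)
        for start, mm in _scan_oriented(primer_seq, rc, params):
            s = n - (start + len(primer_seq))
            out.append(PrimerBinding(primer_role, "-", chrom,
                                     s, s + len(primer_seq), mm))
    return out


def pair_bindings(
    left_bindings: Iterable[PrimerBinding],
    right_bindings: Iterable[PrimerBinding],
    genome: Mapping[str, str],
    params: MatcherParams = MatcherParams(),
    query_pairing: str = "FR",
) -> list[AmpliconHit]:
    """Convergent (plus-left, minus-right) binding pairs within max_size.

    Product coordinates span from the left binding's start to the right
    binding's end; the two primer footprints must not overlap.
    """
    lefts = [b for b in left_bindings if b.strand == "+"]
    rights = [b for b in right_bindings if b.strand == "-"]
    hits: list[AmpliconHit] = []
    for lb in lefts:
        for rb in rights:
            if lb.chrom != rb.chrom:
                continue
            if rb.site_start < lb.site_end:
                continue  # overlapping or divergent
            length = rb.site_end - lb.site_start
            if length > params.max_size:
                continue
            hits.append(
                AmpliconHit(
                    query_pairing=query_pairing,
                    chrom=lb.chrom,
                    start=lb.site_start,
                    end=rb.site_end,
                    left_binding=lb,
                    right_binding=rb,
                    product_seq=genome[lb.chrom][lb.site_start:rb.site_end],
                )
            )
    return hits


# ---------------------------------------------------------------------------
# Scoring


def _primer_weight(binding: PrimerBinding) -> float:
    """Per-primer mismatch weight: 3'-most 5 bases count double.

    Mismatch offsets are 5'-anchored, so a mismatch is 3'-proximal when its
    offset falls in the last THREE_PRIME_WEIGHT_SPAN positions.
    """
    L = binding.length
    w = 0.0
    for off in binding.mismatch_positions:
        w += 2.0 if off >= L - THREE_PRIME_WEIGHT_SPAN else 1.0
    return w / L


def score_hit(hit: AmpliconHit) -> int:
    """0–1000 viability score; 1000 iff zero total mismatches."""
    w = (_primer_weight(hit.left_binding) + _primer_weight(hit.right_binding)) / 2
    return int(max(0, min(1000, round(1000 * (1 - w)))))


# ---------------------------------------------------------------------------
# Whole-pair scan


def scan(
    pair: PrimerPair,
    genome: Mapping[str, str],
    params: MatcherParams = MatcherParams(),
    target_chrom: Optional[str] = None,
    target_pos0: Optional[int] = None,
) -> list[AmpliconHit]:
    """Scored hits over all three query pairings for one primer pair.

    When the design target (contig, 0-based position) is given, the FR hit
    containing it with the highest score (ties: smallest product) is
    flagged ``is_on_target``.
    """
    binding_cache: dict[tuple[str, str], list[PrimerBinding]] = {}

    def bindings(seq: str, role: str) -> list[PrimerBinding]:
        key = (seq, role)
        if key not in binding_cache:
            found = find_bindings(seq, genome, params, primer_role=role)
            binding_cache[key] = found
        return binding_cache[key]

    hits: list[AmpliconHit] = []
    for left_seq, right_seq, label in build_query_pairings(pair):
        left = bindings(left_seq, "left")
        right = bindings(right_seq, "right")
        hits.extend(pair_bindings(left, right, genome, params, label))
    for h in hits:
        h.score = score_hit(h)

    if target_chrom is not None and target_pos0 is not None:
        candidates = [
            h for h in hits
            if h.query_pairing == "FR" and h.chrom == target_chrom
            and h.start <= target_pos0 < h.end
        ]
        if candidates:
            best = max(candidates, key=lambda h: (h.score, -h.length))
            best.is_on_target = True
    return hits


# ---------------------------------------------------------------------------
# Audit output (FASTA of products, BED of hits)


def write_products_fasta(hits: Iterable[AmpliconHit], pair: PrimerPair,
                         path: str | Path) -> None:
    """Products as FASTA; headers carry locus, pairing, primer names, score."""
    with open(path, "a") as fh:
        for h in hits:
            fh.write(
                f">{h.chrom}:{h.start}-{h.end} {h.query_pairing} "
                f"{pair.fwd_name} {pair.rev_name} {h.score}\n{h.product_seq}\n"
            )


def write_hits_bed(hits: Iterable[AmpliconHit], pair: PrimerPair,
                   path: str | Path) -> None:
    """Hits as BED5 (0-based half-open): chrom, start, end, name, score."""
    with open(path, "a") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t"
                f"{pair.pair_name}|{h.query_pairing}\t{h.score}\n"
            )


# ---------------------------------------------------------------------------
# External-binary adapter (optional, disabled by default)

_FASTA_HEADER = re.compile(
    r"^>(?P<chrom>[^:\s]+):(?P<start>\d+)[-+](?P<end>\d+)"
    r"(?:\s+(?P<rest>.*))?$"
)


def parse_external_output(fasta_path: str | Path, bed_path: str | Path,
                          pair: PrimerPair) -> list[AmpliconHit]:
    """Parse FASTA+BED written by an external in-silico PCR tool (or by the
    writers above) into :class:`AmpliconHit` records.

    Mismatch details are not recoverable from these files; bindings are
    reconstructed as zero-mismatch placeholders of the primers' lengths and
    the BED score column is taken as authoritative.
    """
    scores: dict[tuple[str, int, int], int] = {}
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, score = line.rstrip("\n").split("\t")[:5]
            scores[(chrom, int(start), int(end))] = int(float(score))
    hits: list[AmpliconHit] = []
    with open(fasta_path) as fh:
        header, seq_parts = None, []

        def flush():
            if header is None:
                return
            m = _FASTA_HEADER.match(header)
            if not m:
                raise ValueError(f"unparsable product header: {header!r}")
            chrom = m.group("chrom")
            start, end = int(m.group("start")), int(m.group("end"))
            rest = (m.group("rest") or "").split()
            pairing = rest[0] if rest and rest[0] in QUERY_PAIRINGS else "FR"
            lb = PrimerBinding("left", "+", chrom, start,
                               start + len(pair.fwd_seq), ())
            rb = PrimerBinding("right", "-", chrom, end - len(pair.rev_seq),
                               end, ())
            hits.append(AmpliconHit(
                query_pairing=pairing, chrom=chrom, start=start, end=end,
                left_binding=lb, right_binding=rb,
                product_seq="".join(seq_parts),
                score=scores.get((chrom, start, end), 0),
            ))

        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header, seq_parts = line, []
            elif line:
                seq_parts.append(line.strip().upper())
        flush()
    return hits
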
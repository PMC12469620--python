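"""Off-target evaluation: filter, localize, score similarity, classify.

Hits from the in-silico PCR scan are reduced to a per-site verdict:

1. hits on decoy contigs (alt/random/unplaced/decoy/fix/HLA by default)
   are dropped;
2. hits scoring below 750 are dropped (score == 750 is retained);
3. each remaining off-target product is globally aligned to the on-target
   ("gold") product with match = +1, mismatch = 0, gap = 0 — the score is
   then the size of the best co-linear match set — and normalized twice:
   by the off-target length (``to_test``) and by the on-target length
   (``to_gold``);
4. an off-target with max(to_test, to_gold) >= 0.80 is a high-quality
   (concerning) off-target, HQ; below 0.80 it is low-quality, LQ.

The per-site summary counts primers as 1 + number of retained off-targets
and flags the site as concerning when any off-target is HQ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .design import PrimerPair
from .ispcr import AmpliconHit, revcomp
from .targets import TargetSite

logger = logging.getLogger(__name__)

#: Hits scoring below this are discarded before similarity assessment.
DEFAULT_MIN_SCORE = 750

#: Normalized-match threshold at and above which an off-target is HQ.
DEFAULT_HQ_THRESHOLD = 0.80

#: Contig-name substrings marking decoy/non-primary contigs.
DEFAULT_DECOY_PATTERNS = ("_alt", "_random", "_decoy", "chrUn", "_fix", "HLA-")

HQ = "HQ"
LQ = "LQ"


@dataclass(frozen=True)
class NormalizedMatch:
    """Alignment score normalized by each amplicon length.

    ``to_test`` divides by the off-target (test) product length and stays
    in [0, 1] under the match-count scoring; ``to_gold`` divides by the
    on-target (gold) product length and can slightly exceed 1 when the
    off-target is longer than the gold amplicon.
    """

    to_test: float
    to_gold: float

    @property
    def statistic(self) -> float:
        """The value driving HQ/LQ classification (the larger of the two)."""
        return max(self.to_test, self.to_gold)


@dataclass
class OffTargetCall:
    hit: AmpliconHit
    nm: NormalizedMatch
    klass: str  # HQ or LQ


@dataclass
class SiteAssessment:
    """Evaluation verdict for one site's primer pair."""

    site: TargetSite
    pair: PrimerPair
    on_target: Optional[AmpliconHit]
    off_targets: list[OffTargetCall] = field(default_factory=list)

    @property
    def ispcr_ok(self) -> bool:
        return self.on_target is not None

    @property
    def primer_count(self) -> int:
        return 1 + len(self.off_targets)

    @property
    def concerning(self) -> bool:
        return any(c.klass == HQ for c in self.off_targets)


def filter_decoys(
    hits: Sequence[AmpliconHit],
    decoy_patterns: Sequence[str] = DEFAULT_DECOY_PATTERNS,
) -> list[AmpliconHit]:
    """Drop hits whose contig name contains any decoy pattern."""
    return [h for h in hits
            if not any(p in h.chrom for p in decoy_patterns)]


def filter_low_score(
    hits: Sequence[AmpliconHit], min_score: int = DEFAULT_MIN_SCORE
) -> list[AmpliconHit]:
    """Drop hits with score strictly below ``min_score``."""
    return [h for h in hits if h.score >= min_score]


def locate_mismatches(hit: AmpliconHit, pair: PrimerPair
                      ) -> dict[str, tuple[int, list[int]]]:
    """Mismatch count and 5'-anchored offsets for each primer of a hit.

    The product's left terminus is compared to the left query primer and
    the reverse complement of its right terminus to the right query primer,
    so offsets always count from each primer's 5' end regardless of which
    genome strand hosted the product.
    """
    left_seq = pair.fwd_seq if hit.query_pairing in ("FR", "FF") else pair.rev_seq
    right_seq = pair.rev_seq if hit.query_pairing in ("FR", "RR") else pair.fwd_seq
    product = hit.product_seq.upper()
    if len(product) < max(len(left_seq), len(right_seq)):
        raise ValueError(
            f"malformed hit: product ({len(product)} bp) shorter than primer"
        )
    out: dict[str, tuple[int, list[int]]] = {}
    left_tpl = product[: len(left_seq)]
    right_tpl = revcomp(product[-len(right_seq):])
    for role, primer, tpl in (("F", left_seq, left_tpl),
                              ("R", right_seq, right_tpl)):
        positions = [i for i, (a, b) in enumerate(zip(primer, tpl)) if a != b]
        out[role] = (len(positions), positions)
    return out


def _match_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = 0
    aligner.extend_gap_score = 0
    return aligner


_ALIGNER = _match_aligner()


def normalized_match(off_product: str, gold_product: str) -> NormalizedMatch:
    """Align an off-target product to the gold (on-target) product and
    normalize the score by both lengths.

    With match = +1, mismatch = 0 and free gaps the global alignment score
    equals the length of the longest common subsequence, so identical
    sequences score 1.0 on both denominators.
    """
    if not off_product or not gold_product:
        raise ValueError("normalized_match requires non-empty sequences")
    score = float(_ALIGNER.score(gold_product.upper(), off_product.upper()))
    return NormalizedMatch(
        to_test=score / len(off_product),
        to_gold=score / len(gold_product),
    )


def classify(nm: NormalizedMatch,
             hq_threshold: float = DEFAULT_HQ_THRESHOLD) -> str:
    """HQ when the classification statistic reaches the threshold, else LQ."""
    return HQ if nm.statistic >= hq_threshold else LQ


def assess_site(
    site: TargetSite,
    pair: PrimerPair,
    hits: Sequence[AmpliconHit],
    reference_gold: Optional[str] = None,
    hq_threshold: float = DEFAULT_HQ_THRESHOLD,
) -> SiteAssessment:
    """Summarize filtered hits for one site.

    ``hits`` must already be decoy- and score-filtered. When no on-target
    hit survived, similarity is computed against ``reference_gold`` — the
    design-predicted amplicon slice of the reference — so the report stays
    complete.
    """
    on_target = next((h for h in hits if h.is_on_target), None)
    gold = on_target.product_seq if on_target is not None else reference_gold
    calls: list[OffTargetCall] = []
    for h in hits:
        if h is on_target:
            continue
        if gold is None:
            logger.warning(
                "%s: no gold amplicon available; off-target at %s:%d-%d "
                "left unclassified", site.variant_id, h.chrom, h.start, h.end)
            continue
        nm = normalized_match(h.product_seq, gold)
        calls.append(OffTargetCall(hit=h, nm=nm,
                                   klass=classify(nm, hq_threshold)))
    return SiteAssessment(site=site, pair=pair, on_target=on_target,
                          off_targets=calls)
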
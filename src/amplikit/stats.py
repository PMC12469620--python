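"""Allele-count statistics for targeted amplicon sequencing readouts.

Pure formulas on (alt, depth) counts: the mutant allelic fraction (MAF)
and its Wilson score confidence interval. The Wilson interval is the
score-based binomial interval

    (p + z²/2n ± z·sqrt(p(1−p)/n + z²/4n²)) / (1 + z²/n)

with p = alt/n and z the standard-normal quantile for the requested
confidence. It behaves well at extreme counts: at alt = 0 the lower bound
is exactly 0, at alt = depth the upper bound is exactly 1. No continuity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm


@dataclass(frozen=True)
class AlleleCounts:
    """Reads supporting the variant allele (``alt``) out of ``depth``."""

    alt: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if not (0 <= self.alt <= self.depth):
            raise ValueError(f"alt must be in [0, depth], got {self.alt}")


def maf(counts: AlleleCounts) -> float:
    """Mutant allelic fraction alt / depth."""
    return counts.alt / counts.depth


def wilson_ci(counts: AlleleCounts,
              confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for the MAF at the given confidence level."""
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    n = counts.depth
    p = counts.alt / n
    z = float(norm.ppf(0.5 + confidence / 2.0))
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = p + z2 / (2.0 * n)
    half = z * (p * (1.0 - p) / n + z2 / (4.0 * n * n)) ** 0.5
    lower = max(0.0, (centre - half) / denom)
    upper = min(1.0, (centre + half) / denom)
    # at the extremes the bound is exactly 0 or 1; avoid float round-off
    if counts.alt == 0:
        lower = 0.0
    if counts.alt == n:
        upper = 1.0
    return lower, upper
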
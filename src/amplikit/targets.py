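"""Target-site table parsing and reference-window extraction.

The pipeline's input is a CSV of genomic positions to amplify, with required
columns ``CHROM``, ``POS`` and ``PROJ`` (case-sensitive; POS is 1-based,
VCF/ClinVar convention). Each row becomes a :class:`TargetSite` carrying a
derived ``variant_id`` of the form ``PROJ_CHROM_POS`` that keys every
downstream artifact (primer names, report rows). Template sequence for
primer design is pulled from an indexed FASTA as a :class:`TemplateWindow`.

All internal coordinates are 0-based half-open; only POS (input) and the
1-based convenience accessors are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("CHROM", "POS", "PROJ")

#: Default half-window pulled around each target; covers the 500 bp relaxed
#: maximum product on either side.
DEFAULT_FLANK = 500


class TargetTableError(ValueError):
    """Raised for malformed target tables (missing columns, bad POS)."""


def make_variant_id(proj: str, chrom: str, pos: int) -> str:
    """Derive the canonical variant identifier ``PROJ_CHROM_POS``.

    >>> make_variant_id("clinvar", "1", 944041)
    'clinvar_1_944041'
    """
    return f"{proj}_{chrom}_{pos}"


@dataclass(frozen=True)
class TargetSite:
    """One genomic position to amplify.

    ``chrom`` is stored verbatim (no "chr" normalization); ``pos`` is the
    1-based coordinate of the variant; ``proj`` is a free-form project label
    without whitespace. ``extra`` carries any additional input columns for
    pass-through to the final report.
    """

    chrom: str
    pos: int
    proj: str
    extra: tuple = field(default_factory=tuple, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"POS must be >= 1, got {self.pos}")
        if any(c.isspace() for c in self.proj):
            raise ValueError(f"PROJ may not contain whitespace: {self.proj!r}")

    @property
    def variant_id(self) -> str:
        return make_variant_id(self.proj, self.chrom, self.pos)

    @property
    def pos0(self) -> int:
        """0-based coordinate of the target base."""
        return self.pos - 1


@dataclass(frozen=True)
class TemplateWindow:
    """A slice of reference sequence centred (up to clipping) on a target.

    ``seq`` is uppercase A/C/G/T/N; ``window_start`` is the 0-based start of
    ``seq`` on the contig; ``target_offset`` indexes the target base within
    ``seq``, so ``window_start + target_offset + 1 == site.pos``.
    """

    site: TargetSite
    seq: str
    window_start: int
    target_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.target_offset < len(self.seq)):
            raise ValueError("target_offset outside window sequence")
        if self.window_start + self.target_offset + 1 != self.site.pos:
            raise ValueError("window coordinates inconsistent with site.pos")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise ValueError(f"window contains non-ACGTN characters: {bad}")

    @property
    def window_end(self) -> int:
        return self.window_start + len(self.seq)


def parse_target_table(path: str | Path) -> list[TargetSite]:
    """Parse the input CSV into a list of :class:`TargetSite`, input order
    preserved.

    Duplicate (CHROM, POS, PROJ) rows collapse to one (logged warning):
    identical variant IDs would collide in every downstream output. Extra
    columns are retained on each site as ``extra`` (name, value) pairs.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TargetTableError(
            f"target table {path} is missing required column(s): "
            f"{', '.join(missing)} (header must contain CHROM, POS, PROJ)"
        )
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    sites: list[TargetSite] = []
    seen: set[tuple[str, int, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            pos = int(rec["POS"])
        except (TypeError, ValueError):
            raise TargetTableError(
                f"row {i}: POS must be an integer, got {rec['POS']!r}"
            ) from None
        key = (rec["CHROM"], pos, rec["PROJ"])
        if key in seen:
            logger.warning(
                "duplicate target row collapsed: %s",
                make_variant_id(rec["PROJ"], rec["CHROM"], pos),
            )
            continue
        seen.add(key)
        sites.append(
            TargetSite(
                chrom=rec["CHROM"],
                pos=pos,
                proj=rec["PROJ"],
                extra=tuple((c, rec[c]) for c in extra_cols),
            )
        )
    return sites


def open_reference(path: str | Path) -> Fasta:
    """Open an indexed FASTA (builds the .fai sidecar if absent)."""
    return Fasta(str(path), sequence_always_upper=True)


def extract_window(
    reference: Fasta, site: TargetSite, flank: int = DEFAULT_FLANK
) -> TemplateWindow:
    """Extract ``[pos-1-flank, pos+flank)`` around the target, clipped to
    contig bounds, as an uppercase :class:`TemplateWindow`.
    """
    if site.chrom not in reference:
        available = ", ".join(list(reference.keys())[:20])
        raise KeyError(
            f"contig {site.chrom!r} not in reference (available: {available})"
        )
    contig = reference[site.chrom]
    contig_len = len(contig)
    if site.pos > contig_len:
        raise ValueError(
            f"POS {site.pos} beyond end of contig {site.chrom} ({contig_len} bp)"
        )
    start = max(0, site.pos0 - flank)
    end = min(contig_len, site.pos0 + flank + 1)
    seq = str(contig[start:end]).upper()
    return TemplateWindow(
        site=site, seq=seq, window_start=start, target_offset=site.pos0 - start
    )


def fetch_base(reference: Fasta, chrom: str, pos: int) -> str:
    """Single-base fetch at a 1-based position (independent of windows)."""
    return str(reference[chrom][pos - 1]).upper()
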
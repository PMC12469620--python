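"""Final report assembly: merge design + evaluation back onto the input.

One row per input site, sorted by (chromosome, position) with natural
chromosome ordering (1..22, X, Y, M, then others lexicographically;
an optional "chr" prefix is ignored for ranking only — names are never
rewritten). Output is UTF-8 tab-delimited with booleans serialized as
``True``/``False`` and empty strings for fields of undesigned sites.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .design import DesignModeName, DesignOutcome
from .evaluate import SiteAssessment, locate_mismatches
from .targets import TargetSite

#: Columns appended after the pass-through input columns, in order.
REPORT_COLUMNS = [
    "variant_ID",
    "Primer3",
    "ISPCR",
    "primer_name",
    "TAS-opt",
    "forward_primer_name",
    "forward_primer_sequence",
    "forward_primer_melting_temperature",
    "reverse_primer_name",
    "reverse_primer_sequence",
    "reverse_primer_melting_temperature",
    "amplicon_start_position",
    "amplicon_end_position",
    "amplicon_length",
    "primer_count",
    "concerning_off_targets",
]

_CHROM_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple:
    """Natural chromosome order: 1..22, X, Y, M/MT, then lexicographic."""
    base = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if re.fullmatch(r"\d+", base):
        return (0, int(base), "")
    if base.upper() in _CHROM_SPECIAL:
        return (0, _CHROM_SPECIAL[base.upper()], "")
    return (1, 0, chrom)


def build_report_frame(
    sites: Sequence[TargetSite],
    outcomes: Mapping[str, DesignOutcome],
    assessments: Mapping[str, SiteAssessment],
) -> pd.DataFrame:
    """Assemble the merged report as a DataFrame (pre-serialization).

    ``outcomes``/``assessments`` are keyed by variant_ID. A designed site
    missing its assessment is a pipeline inconsistency and a hard error.
    """
    rows = []
    extra_cols: list[str] = []
    for site in sites:
        for name, _ in site.extra:
            if name not in extra_cols:
                extra_cols.append(name)
    for site in sites:
        vid = site.variant_id
        outcome = outcomes.get(vid)
        designed = outcome is not None and outcome.pair is not None
        if designed and vid not in assessments:
            raise RuntimeError(
                f"pipeline inconsistency: {vid} was designed but has no "
                "evaluation result"
            )
        row: dict = {"CHROM": site.chrom, "POS": site.pos, "PROJ": site.proj}
        row.update(dict(site.extra))
        row["variant_ID"] = vid
        row["Primer3"] = designed
        if designed:
            pair = outcome.pair
            a = assessments[vid]
            row.update({
                "ISPCR": a.ispcr_ok,
                "primer_name": pair.pair_name,
                "TAS-opt": pair.mode == DesignModeName.TAS_OPT,
                "forward_primer_name": pair.fwd_name,
                "forward_primer_sequence": pair.fwd_seq,
                "forward_primer_melting_temperature": pair.fwd_tm,
                "reverse_primer_name": pair.rev_name,
                "reverse_primer_sequence": pair.rev_seq,
                "reverse_primer_melting_temperature": pair.rev_tm,
                "amplicon_start_position": pair.amplicon_start,
                "amplicon_end_position": pair.amplicon_end,
                "amplicon_length": pair.amplicon_end - pair.amplicon_start,
                "primer_count": a.primer_count,
                "concerning_off_targets": a.concerning,
            })
        else:
            row["ISPCR"] = False
        rows.append(row)
    columns = ["CHROM", "POS", "PROJ"] + extra_cols + REPORT_COLUMNS
    df = pd.DataFrame(rows).reindex(columns=columns)
    df["_ck"] = df["CHROM"].map(chrom_sort_key)
    df = df.sort_values(["_ck", "POS"], kind="mergesort").drop(columns="_ck")
    return df.reset_index(drop=True)


def write_report(
    sites: Sequence[TargetSite],
    outcomes: Mapping[str, DesignOutcome],
    assessments: Mapping[str, SiteAssessment],
    path: str | Path,
) -> Path:
    """Write the merged, sorted, tab-delimited report."""
    df = build_report_frame(sites, outcomes, assessments)
    out = df.copy()
    bool_cols = ("Primer3", "ISPCR", "TAS-opt", "concerning_off_targets")
    int_cols = ("amplicon_start_position", "amplicon_end_position",
                "amplicon_length", "primer_count")
    for col in bool_cols:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(bool(v)))
    for col in int_cols:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else int(v))
    out.to_csv(path, sep="\t", index=False, na_rep="")
    return Path(path)


def write_offtarget_details(
    assessments: Mapping[str, SiteAssessment], path: str | Path
) -> Path:
    """Per-site off-target detail table for advanced users.

    One row per retained off-target: locus, pairing, score, per-primer
    mismatch counts, both normalized matches, and the HQ/LQ class.
    """
    rows = []
    for vid in sorted(assessments):
        a = assessments[vid]
        for call in a.off_targets:
            h = call.hit
            try:
                mm = locate_mismatches(h, a.pair)
                mm_f, mm_r = mm["F"][0], mm["R"][0]
            except ValueError:
                mm_f = mm_r = ""
            rows.append({
                "variant_ID": vid,
                "chrom": h.chrom,
                "start": h.start,
                "end": h.end,
                "query_pairing": h.query_pairing,
                "score": h.score,
                "mismatches_left_primer": mm_f,
                "mismatches_right_primer": mm_r,
                "normalized_match_to_test_amplicon": round(call.nm.to_test, 6),
                "normalized_match_to_gold_amplicon": round(call.nm.to_gold, 6),
                "class": call.klass,
            })
    pd.DataFrame(rows, columns=[
        "variant_ID", "chrom", "start", "end", "query_pairing", "score",
        "mismatches_left_primer", "mismatches_right_primer",
        "normalized_match_to_test_amplicon",
        "normalized_match_to_gold_amplicon", "class",
    ]).to_csv(path, sep="\t", index=False)
    return Path(path)
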
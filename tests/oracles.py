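"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the package's seed-and-extend / aligner code:
the binding oracle checks every offset of every strand with numpy, and the
alignment oracle is a longest-common-subsequence dynamic program.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _tile_offsets(L: int, tile: int, step: int) -> list[int]:
    offsets = list(range(0, L - tile + 1, step))
    last = L - tile
    if offsets and offsets[-1] != last:
        offsets.append(last)
    return offsets


def brute_force_bindings(primer: str, genome: dict[str, str], params):
    """Every accepted binding locus, by exhaustive all-offsets scan.

    Applies the same acceptance rules as the engine: exact 3'-terminal
    min_perfect stretch, two matches per mismatch in the 3'-most min_good
    window, and at least one exact sampled tile. Returns a set of
    (chrom, strand, start, end, mismatch_offsets).
    """
    L = len(primer)
    pm = np.frombuffer(primer.encode(), dtype="S1")
    out = set()
    for chrom, seq in genome.items():
        n = len(seq)
        if n < L:
            continue
        for strand, text in (("+", seq), ("-", rc(seq))):
            arr = np.frombuffer(text.encode(), dtype="S1")
            win = sliding_window_view(arr, L)
            mm = win != pm  # (n-L+1, L)
            perfect3 = ~mm[:, L - params.min_perfect:].any(axis=1)
            w = min(params.min_good, L)
            mmw = mm[:, L - w:].sum(axis=1)
            good = (w - mmw) >= 2 * mmw
            seeded = np.zeros(mm.shape[0], dtype=bool)
            for o in _tile_offsets(L, params.tile_size, params.step_size):
                seeded |= ~mm[:, o:o + params.tile_size].any(axis=1)
            for idx in np.flatnonzero(perfect3 & good & seeded):
                offs = tuple(np.flatnonzero(mm[idx]).tolist())
                if strand == "+":
                    start = int(idx)
                else:
                    start = n - (int(idx) + L)
                out.add((chrom, strand, start, start + L, offs))
    return out


def lcs_score(a: str, b: str) -> int:
    """Longest common subsequence length — equals the global alignment
    score under match=+1, mismatch=0, gap=0."""
    la, lb = len(a), len(b)
    prev = [0] * (lb + 1)
    for i in range(1, la + 1):
        cur = [0] * (lb + 1)
        ai = a[i - 1]
        for j in range(1, lb + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
            else:
                cur[j] = max(prev[j], cur[j - 1])
        prev = cur
    return prev[lb]


def score_oracle(left_mm, left_len, right_mm, right_len, span=5) -> int:
    """Re-implementation of the hit score from its documented definition."""
    def w(mms, L):
        return sum(2.0 if off >= L - span else 1.0 for off in mms) / L
    val = 1000 * (1 - (w(left_mm, left_len) + w(right_mm, right_len)) / 2)
    return int(max(0, min(1000, round(val))))
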
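"""Deterministic synthetic fixtures: mini genomes with planted features.

Everything downstream of this module is exercised against genomes built
here: uniform-random A/C/G/T contigs (10 kb–2 Mb scale) with target sites,
optional decoy contigs, and planted off-target copies of on-target regions
at controlled sequence divergence. A fixed seed yields byte-identical FASTA
output, and a JSON manifest records every planted feature and every
mutated position, so tests can check detection and classification against
ground truth.

Two planting routes exist:

* :func:`make_genome` plants copies of a fixed-half-width region around a
  source target *before* design, so any amplicon realized inside that
  region is duplicated;
* :func:`plant_offtarget_after_design` copies the realized amplicon of a
  designed pair, with control over whether primer footprints are
  preserved, diverged, or killed at the 3' terminus — separating binding
  survival from amplicon similarity.

Divergence is substitution-only (the matcher models no indels): a copy of
length L at divergence d carries exactly ``round(d * L)`` substitutions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from pyfaidx import Faidx

from .design import PrimerPair

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

FASTA_LINE_WIDTH = 60


@dataclass(frozen=True)
class PlantSpec:
    """One pre-design planted off-target copy.

    ``source_target`` indexes into ``FixtureSpec.targets``; the copied
    region is the source target ± ``FixtureSpec.copy_halfwidth``.
    ``dest_pos`` is the 0-based start of the copy on ``dest_contig``.
    ``mode`` is ``"full"`` (substitutions anywhere in the copy) or
    ``"ends_protected"`` (the outer ``protect_bp`` bases on each side stay
    exact, keeping peripheral primer sites intact).
    """

    source_target: int
    dest_contig: str
    dest_pos: int
    divergence: float = 0.0
    mode: str = "full"
    protect_bp: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.mode not in ("full", "ends_protected"):
            raise ValueError(f"unknown plant mode {self.mode!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic fixture genome."""

    seed: int
    contigs: tuple[tuple[str, int], ...]
    targets: tuple[tuple[str, int, str], ...] = ()  # (contig, 1-based pos, proj)
    planted_offtargets: tuple[PlantSpec, ...] = ()
    decoy_contigs: tuple[tuple[str, int], ...] = ()
    copy_halfwidth: int = 250
    gc_content: float = 0.5


@dataclass
class FixtureGenome:
    """In-memory fixture genome plus its ground-truth manifest."""

    sequences: dict[str, str]
    manifest: dict
    fasta_path: Optional[Path] = None


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _substitute(seq: list[str], positions: Sequence[int],
                rng: np.random.Generator) -> None:
    for p in positions:
        seq[p] = _OTHER[seq[p]][rng.integers(0, 3)]


def diverge(seq: str, divergence: float, rng: np.random.Generator,
            protected: Sequence[tuple[int, int]] = ()) -> tuple[str, list[int]]:
    """Apply exactly ``round(divergence * len(seq))`` substitutions.

    ``protected`` intervals (half-open, sequence-local) are never mutated.
    Returns the mutated sequence and the sorted mutated positions.
    """
    n_mut = round(divergence * len(seq))
    blocked = np.zeros(len(seq), dtype=bool)
    for s, e in protected:
        blocked[max(0, s):max(0, e)] = True
    allowed = np.flatnonzero(~blocked)
    if n_mut > len(allowed):
        raise ValueError(
            f"cannot place {n_mut} substitutions in {len(allowed)} free bases"
        )
    positions = sorted(rng.choice(allowed, size=n_mut, replace=False).tolist())
    chars = list(seq)
    _substitute(chars, positions, rng)
    return "".join(chars), positions


def _check_no_overlap(intervals: list[tuple[str, int, int, str]]) -> None:
    by_contig: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, label in intervals:
        by_contig.setdefault(chrom, []).append((s, e, label))
    for chrom, ivs in by_contig.items():
        ivs.sort()
        for (s1, e1, l1), (s2, e2, l2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(
                    f"planted features overlap on {chrom}: {l1} and {l2}"
                )


def make_genome(spec: FixtureSpec, outdir: Optional[str | Path] = None,
                name: str = "fixture") -> FixtureGenome:
    """Synthesize the fixture genome described by ``spec``.

    When ``outdir`` is given, writes ``<name>.fa`` (+ ``.fai`` index) and
    ``<name>.manifest.json`` there. Same spec → byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: dict[str, str] = {}
    for cname, length in list(spec.contigs) + list(spec.decoy_contigs):
        if cname in sequences:
            raise ValueError(f"duplicate contig name {cname!r}")
        sequences[cname] = _random_seq(rng, length, spec.gc_content)

    manifest: dict = {
        "seed": spec.seed,
        "contigs": {c: len(s) for c, s in sequences.items()},
        "decoy_contigs": [c for c, _ in spec.decoy_contigs],
        "targets": [],
        "planted_offtargets": [],
    }
    for contig, pos, proj in spec.targets:
        if contig not in sequences or not (1 <= pos <= len(sequences[contig])):
            raise ValueError(f"target {contig}:{pos} outside genome")
        manifest["targets"].append(
            {"contig": contig, "pos": pos, "proj": proj,
             "ref_base": sequences[contig][pos - 1]}
        )

    claimed: list[tuple[str, int, int, str]] = []
    for contig, pos, proj in spec.targets:
        s = max(0, pos - 1 - spec.copy_halfwidth)
        e = min(len(sequences[contig]), pos + spec.copy_halfwidth)
        claimed.append((contig, s, e, f"source:{proj}_{contig}_{pos}"))

    for i, plant in enumerate(spec.planted_offtargets):
        contig, pos, proj = spec.targets[plant.source_target]
        src_start = max(0, pos - 1 - spec.copy_halfwidth)
        src_end = min(len(sequences[contig]), pos + spec.copy_halfwidth)
        source = sequences[contig][src_start:src_end]
        protected: list[tuple[int, int]] = []
        if plant.mode == "ends_protected" and plant.protect_bp > 0:
            protected = [(0, plant.protect_bp),
                         (len(source) - plant.protect_bp, len(source))]
        copy, mutated = diverge(source, plant.divergence, rng, protected)
        dest = sequences[plant.dest_contig]
        d0, d1 = plant.dest_pos, plant.dest_pos + len(copy)
        if d0 < 0 or d1 > len(dest):
            raise ValueError(f"plant {i} outside contig {plant.dest_contig}")
        claimed.append((plant.dest_contig, d0, d1, f"plant:{i}"))
        sequences[plant.dest_contig] = dest[:d0] + copy + dest[d1:]
        manifest["planted_offtargets"].append(
            {"index": i, "source": asdict(plant),
             "source_interval": [contig, src_start, src_end],
             "dest_interval": [plant.dest_contig, d0, d1],
             "mutated_positions": mutated}
        )
    _check_no_overlap(claimed)

    fg = FixtureGenome(sequences=sequences, manifest=manifest)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / f"{name}.fa"
        write_fasta(sequences, fasta)
        Faidx(str(fasta))  # build sidecar .fai
        (outdir / f"{name}.manifest.json").write_text(
            json.dumps(manifest, indent=1) + "\n"
        )
        fg.fasta_path = fasta
    return fg


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for cname, seq in sequences.items():
            fh.write(f">{cname}\n")
            for i in range(0, len(seq), FASTA_LINE_WIDTH):
                fh.write(seq[i:i + FASTA_LINE_WIDTH] + "\n")
    return path


def make_target_table(spec: FixtureSpec, path: str | Path) -> Path:
    """Write the fixture's targets as the pipeline's input CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("CHROM,POS,PROJ\n")
        for contig, pos, proj in spec.targets:
            fh.write(f"{contig},{pos},{proj}\n")
    return path


def plant_offtarget_after_design(
    genome: FixtureGenome,
    pair: PrimerPair,
    dest_contig: str,
    dest_pos: int,
    divergence: float = 0.0,
    mode: str = "full",
    preserve_primer_footprints: bool = True,
    kill_three_prime: bool = False,
    seed: int = 0,
) -> FixtureGenome:
    """Plant a copy of a designed pair's realized amplicon.

    ``mode="full"`` copies the amplicon and applies ``round(d*L)``
    substitutions, by default sparing the primer footprints so binding
    survives independently of interior similarity. ``mode="primer_sites"``
    keeps only the primer footprints and redraws the interior at random
    (maximal interior dissimilarity with guaranteed binding).
    ``kill_three_prime`` substitutes the 3'-terminal base of each footprint
    in the copy, which defeats the matcher's exact-3'-end rule.
    Returns a new :class:`FixtureGenome`; the input is not modified.
    """
    rng = np.random.default_rng(seed)
    src = genome.sequences[pair.chrom][pair.amplicon_start:pair.amplicon_end]
    L = len(src)
    lf, lr = len(pair.fwd_seq), len(pair.rev_seq)
    footprints = [(0, lf), (L - lr, L)]
    if mode == "primer_sites":
        interior = _random_seq(rng, L - lf - lr, 0.5)
        copy = src[:lf] + interior + src[L - lr:]
        mutated = [i for i in range(lf, L - lr) if copy[i] != src[i]]
    elif mode == "full":
        protected = footprints if preserve_primer_footprints else []
        copy, mutated = diverge(src, divergence, rng, protected)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if kill_three_prime:
        chars = list(copy)
        # forward primer 3' end is the footprint's last base; the reverse
        # primer's 3' end maps to the first base of the right footprint
        _substitute(chars, [lf - 1, L - lr], rng)
        copy = "".join(chars)
        mutated = sorted(set(mutated) | {lf - 1, L - lr})

    dest = genome.sequences[dest_contig]
    d0, d1 = dest_pos, dest_pos + L
    if d0 < 0 or d1 > len(dest):
        raise ValueError("plant destination outside contig")
    if dest_contig == pair.chrom and not (
        d1 <= pair.amplicon_start or d0 >= pair.amplicon_end
    ):
        raise ValueError("plant destination overlaps the source amplicon")
    sequences = dict(genome.sequences)
    sequences[dest_contig] = dest[:d0] + copy + dest[d1:]
    manifest = json.loads(json.dumps(genome.manifest))
    manifest.setdefault("planted_offtargets", []).append(
        {"source_pair": pair.pair_name, "mode": mode,
         "divergence": divergence,
         "dest_interval": [dest_contig, d0, d1],
         "mutated_positions": mutated,
         "kill_three_prime": kill_three_prime}
    )
    return FixtureGenome(sequences=sequences, manifest=manifest)
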
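import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from amplikit import FixtureSpec, PlantSpec, make_genome, make_target_table


def random_genome(seed: int, lengths: dict[str, int]) -> dict[str, str]:
    """Plain uniform-random genome dict (no plants, no files)."""
    spec = FixtureSpec(seed=seed, contigs=tuple(lengths.items()))
    return make_genome(spec).sequences


@pytest.fixture
def basic_fixture(tmp_path):
    """50 kb single-contig genome with one centred target, on disk."""
    spec = FixtureSpec(
        seed=7,
        contigs=(("chr1", 50_000),),
        targets=(("chr1", 25_000, "test"),),
    )
    fg = make_genome(spec, tmp_path)
    table = make_target_table(spec, tmp_path / "targets.csv")
    return spec, fg, table


@pytest.fixture
def duplicate_fixture(tmp_path):
    """One target plus one exact planted duplicate of its neighbourhood."""
    spec = FixtureSpec(
        seed=11,
        contigs=(("chr1", 50_000),),
        targets=(("chr1", 25_000, "test"),),
        planted_offtargets=(PlantSpec(0, "chr1", 40_000, 0.0),),
    )
    fg = make_genome(spec, tmp_path)
    table = make_target_table(spec, tmp_path / "targets.csv")
    return spec, fg, table


def plant_exact(seq: str, insert: str, pos: int) -> str:
    """Overwrite seq[pos:pos+len(insert)] with insert."""
    assert pos + len(insert) <= len(seq)
    return seq[:pos] + insert + seq[pos + len(insert):]


def random_primer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
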
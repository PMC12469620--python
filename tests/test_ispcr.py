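"""Seed-and-extend matcher, binding pairing, scoring, and the whole scan."""

import numpy as np
import pytest

from amplikit import (
    MatcherParams,
    PrimerPair,
    build_query_pairings,
    find_bindings,
    pair_bindings,
    scan,
    score_hit,
)
from amplikit.ispcr import (
    AmpliconHit,
    PrimerBinding,
    parse_external_output,
    write_hits_bed,
    write_products_fasta,
)

from conftest import random_genome, plant_exact, random_primer
from oracles import brute_force_bindings, rc, score_oracle

PARAMS = MatcherParams()


def make_pair(fwd, rev, chrom="chr1", start=0, end=100):
    return PrimerPair(
        pair_name="p_chr1_1_TAS-opt", fwd_name="F", rev_name="R",
        fwd_seq=fwd, rev_seq=rev, fwd_tm=60.0, rev_tm=60.0,
        mode="TAS_OPT", predicted_product=end - start,
        amplicon_start=start, amplicon_end=end, chrom=chrom,
    )


def binding_set(bindings):
    return {(b.chrom, b.strand, b.site_start, b.site_end,
             b.mismatch_positions) for b in bindings}


class TestQueryPairings:
    def test_three_pairings_with_labels(self):
        pair = make_pair("ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAATTTT")
        pairings = build_query_pairings(pair)
        assert [lab for _, _, lab in pairings] == ["FR", "FF", "RR"]
        assert pairings[1][0] == pairings[1][1] == pair.fwd_seq

    def test_degenerate_identical_primers(self):
        s = "ACGTACGTACGTACGTACGT"
        pairs = build_query_pairings(make_pair(s, s))
        assert all(a == b == s for a, b, _ in pairs)


class TestFindBindings:
    def test_planted_primer_found_exactly_once(self):
        genome = random_genome(41, {"chr1": 50_000})
        rng = np.random.default_rng(1)
        primer = random_primer(rng, 20)
        genome["chr1"] = plant_exact(genome["chr1"], primer, 30_000)
        found = [b for b in find_bindings(primer, genome, PARAMS)
                 if b.n_mismatches == 0]
        plus = [b for b in found if b.strand == "+"]
        assert len(plus) == 1
        assert (plus[0].site_start, plus[0].site_end) == (30_000, 30_020)

    def test_three_prime_terminal_mismatch_rejects_locus(self):
        genome = random_genome(43, {"chr1": 20_000})
        rng = np.random.default_rng(2)
        primer = random_primer(rng, 20)
        broken = primer[:-1] + ("A" if primer[-1] != "A" else "C")
        genome["chr1"] = plant_exact(genome["chr1"], broken, 10_000)
        assert not any(
            b.site_start == 10_000 and b.strand == "+"
            for b in find_bindings(primer, genome, PARAMS)
        )

    def test_min_good_two_matches_per_mismatch(self):
        # 3 mismatches in the 3'-most 15 of a 20-mer: 12 matches >= 2*3,
        # so the locus is accepted (given a seedable exact 5' tile)
        genome = random_genome(45, {"chr1": 20_000})
        rng = np.random.default_rng(3)
        primer = random_primer(rng, 20)
        copy = list(primer)
        # inside window [5, 20), away from the 3' base, and leaving the
        # 5'-anchored 11-mer tile exact so the locus is seedable
        for off in (11, 14, 17):
            copy[off] = "ACGT"[("ACGT".index(copy[off]) + 1) % 4]
        genome["chr1"] = plant_exact(genome["chr1"], "".join(copy), 10_000)
        hits = [b for b in find_bindings(primer, genome, PARAMS)
                if b.site_start == 10_000 and b.strand == "+"]
        assert len(hits) == 1 and hits[0].mismatch_positions == (11, 14, 17)
        # six mismatches break the 2:1 rule (9 matches < 2*6)
        for off in (12, 13, 15):
            copy[off] = "ACGT"[("ACGT".index(copy[off]) + 1) % 4]
        genome["chr1"] = plant_exact(genome["chr1"], "".join(copy), 10_000)
        assert not any(
            b.site_start == 10_000 and b.strand == "+"
            for b in find_bindings(primer, genome, PARAMS)
        )

    def test_primer_shorter_than_tile_errors(self):
        with pytest.raises(ValueError, match="tile_size"):
            find_bindings("ACGTACGT", {"chr1": "ACGT" * 100}, PARAMS)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        """Engine == exhaustive all-offsets matcher on planted genomes."""
        rng = np.random.default_rng(100 + seed)
        genome = random_genome(200 + seed, {"c1": 30_000, "c2": 10_000})
        primer = random_primer(rng, int(rng.integers(18, 26)))
        # plant copies at 0-4 mismatches, either strand
        for k in range(int(rng.integers(1, 5))):
            copy = list(primer)
            for _ in range(int(rng.integers(0, 5))):
                i = int(rng.integers(0, len(copy)))
                copy[i] = "ACGT"[int(rng.integers(0, 4))]
            s = "".join(copy)
            if rng.random() < 0.5:
                s = rc(s)
            contig = "c1" if rng.random() < 0.7 else "c2"
            pos = int(rng.integers(0, len(genome[contig]) - len(s)))
            genome[contig] = plant_exact(genome[contig], s, pos)
        got = binding_set(find_bindings(primer, genome, PARAMS))
        expected = brute_force_bindings(primer, genome, PARAMS)
        assert got == expected


class TestPairBindings:
    def _binding(self, strand, start, length=20, chrom="chr1", role="left"):
        return PrimerBinding(role, strand, chrom, start, start + length, ())

    def _genome(self):
        return random_genome(47, {"chr1": 2_000})

    def test_convergent_190bp_span(self):
        g = self._genome()
        left = [self._binding("+", 100)]
        right = [self._binding("-", 270, role="right")]
        [hit] = pair_bindings(left, right, g, PARAMS)
        assert (hit.start, hit.end, hit.length) == (100, 290, 190)
        assert hit.product_seq == g["chr1"][100:290]

    def test_span_801_exceeds_max_size(self):
        g = self._genome()
        left = [self._binding("+", 100)]
        right = [self._binding("-", 881, role="right")]  # end 901, span 801
        assert pair_bindings(left, right, g, PARAMS) == []
        right = [self._binding("-", 880, role="right")]  # span 800: kept
        assert len(pair_bindings(left, right, g, PARAMS)) == 1

    def test_divergent_orientation_rejected(self):
        g = self._genome()
        left = [self._binding("+", 500)]
        right = [self._binding("-", 100, role="right")]  # upstream of left
        assert pair_bindings(left, right, g, PARAMS) == []

    def test_cross_contig_never_pairs(self):
        g = random_genome(49, {"c1": 1_000, "c2": 1_000})
        left = [self._binding("+", 100, chrom="c1")]
        right = [self._binding("-", 400, chrom="c2", role="right")]
        assert pair_bindings(left, right, g, PARAMS) == []


class TestScoreHit:
    def _hit(self, left_mm=(), right_mm=(), L=20):
        g = random_genome(51, {"chr1": 1_000})
        lb = PrimerBinding("left", "+", "chr1", 100, 100 + L, tuple(left_mm))
        rb = PrimerBinding("right", "-", "chr1", 270, 270 + L, tuple(right_mm))
        return AmpliconHit("FR", "chr1", 100, 270 + L, lb, rb,
                           g["chr1"][100:270 + L])

    def test_perfect_match_scores_1000(self):
        assert score_hit(self._hit()) == 1000

    def test_score_1000_only_for_zero_mismatches(self):
        assert score_hit(self._hit(left_mm=[0])) < 1000

    def test_additional_mismatch_never_raises_score(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            mm = sorted(rng.choice(19, size=rng.integers(0, 4),
                                   replace=False).tolist())
            extra = next(i for i in range(20) if i not in mm)
            base = score_hit(self._hit(left_mm=mm))
            more = score_hit(self._hit(left_mm=sorted(mm + [extra])))
            assert more <= base

    def test_exhaustive_single_mismatch_agrees_with_oracle(self):
        for pos in range(20):
            hit = self._hit(left_mm=[pos])
            assert score_hit(hit) == score_oracle([pos], 20, [], 20)

    def test_three_prime_mismatches_at_least_as_costly(self):
        assert score_hit(self._hit(left_mm=[19])) <= score_hit(
            self._hit(left_mm=[0])
        )


class TestScan:
    def _designed_fixture(self, seed=61, n=50_000, extra_copy_at=None):
        genome = random_genome(seed, {"chr1": n})
        rng = np.random.default_rng(seed)
        fwd = random_primer(rng, 20)
        rev = random_primer(rng, 20)
        template = fwd + "".join(rng.choice(list("ACGT"), size=150)) + rc(rev)
        genome["chr1"] = plant_exact(genome["chr1"], template, 20_000)
        if extra_copy_at is not None:
            genome["chr1"] = plant_exact(genome["chr1"], template, extra_copy_at)
        pair = make_pair(fwd, rev, start=20_000, end=20_000 + len(template))
        return genome, pair, 20_000 + len(template) // 2

    def test_single_template_on_target_1000(self):
        genome, pair, tpos = self._designed_fixture()
        hits = scan(pair, genome, PARAMS, target_chrom="chr1", target_pos0=tpos)
        assert len(hits) == 1
        assert hits[0].is_on_target and hits[0].score == 1000

    def test_exact_duplicate_gives_two_perfect_hits(self):
        genome, pair, tpos = self._designed_fixture(extra_copy_at=40_000)
        hits = scan(pair, genome, PARAMS, target_chrom="chr1", target_pos0=tpos)
        assert len(hits) == 2
        assert sorted(h.score for h in hits) == [1000, 1000]
        assert sum(h.is_on_target for h in hits) == 1
        on = next(h for h in hits if h.is_on_target)
        assert on.start <= tpos < on.end

    def test_product_seq_equals_reference_slice(self):
        genome, pair, tpos = self._designed_fixture(extra_copy_at=40_000)
        for h in scan(pair, genome, PARAMS):
            assert h.product_seq == genome[h.chrom][h.start:h.end]

    def test_contig_split_invariance(self):
        genome, pair, tpos = self._designed_fixture()
        whole = scan(pair, genome, PARAMS)
        split_at = 30_000  # outside the planted product
        split = scan(pair, {
            "a": genome["chr1"][:split_at],
            "b": genome["chr1"][split_at:],
        }, PARAMS)
        assert len(whole) == len(split)
        w, s = whole[0], split[0]
        assert (w.end - w.start, w.score) == (s.end - s.start, s.score)
        assert w.product_seq == s.product_seq

    def test_pairing_labels_round_trip_through_hits(self):
        genome, pair, tpos = self._designed_fixture()
        # plant a reverse-complement copy of the forward primer downstream
        # so the FF pairing can also produce a product
        genome["chr1"] = plant_exact(genome["chr1"], rc(pair.fwd_seq), 20_300)
        hits = scan(pair, genome, PARAMS)
        assert {h.query_pairing for h in hits} <= {"FR", "FF", "RR"}
        assert any(h.query_pairing == "FF" for h in hits)


class TestAuditOutputs:
    def test_fasta_bed_round_trip_through_adapter(self, tmp_path):
        """The external-tool adapter parses files in the writers' format
        back into hits with identical product intervals and scores."""
        genome = random_genome(61, {"chr1": 50_000})
        rng = np.random.default_rng(61)
        fwd, rev = random_primer(rng, 20), random_primer(rng, 20)
        template = fwd + "".join(rng.choice(list("ACGT"), size=150)) + rc(rev)
        genome["chr1"] = plant_exact(genome["chr1"], template, 20_000)
        pair = make_pair(fwd, rev, start=20_000, end=20_000 + len(template))
        hits = scan(pair, genome, PARAMS)
        fa, bed = tmp_path / "p.fa", tmp_path / "h.bed"
        fa.write_text(""), bed.write_text("")
        write_products_fasta(hits, pair, fa)
        write_hits_bed(hits, pair, bed)
        parsed = parse_external_output(fa, bed, pair)
        assert [(h.chrom, h.start, h.end, h.score, h.product_seq)
                for h in parsed] == [
            (h.chrom, h.start, h.end, h.score, h.product_seq) for h in hits
        ]
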
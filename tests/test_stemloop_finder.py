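import numpy as np
import pytest

import oracles
from crucivir.genome_io import CircularGenome, rotate
from crucivir.stemloop_finder import (
    DEFAULT_PATTERNS,
    MotifHit,
    StemLoopConfig,
    find_stemloops,
    fold_window,
    hairpin_scan,
    iupac_regex,
    matches_iupac,
    nonanucleotide_frequencies,
    nussinov_pairs,
    scan_nonanucleotides,
    score_stemloop,
)


def _hairpin_genome(stem="GCGCGCGCGCG", loop_pad="C", motif="TAGTATTAC",
                    background="A" * 200):
    """Planted hairpin with inert flanks: background A's cannot pair with
    the GC-only stem, and the pads keep the loop at 11 bases."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    rstem = "".join(comp[b] for b in reversed(stem))
    loop = loop_pad + motif + loop_pad
    seq = background + stem + loop + rstem + background
    start = len(background) + len(stem) + len(loop_pad)
    return CircularGenome(id="hp", seq=seq), start


class TestIupac:
    def test_canonical_motif_matches_nantantan(self):
        assert matches_iupac("TAGTATTAC", "NANTANTAN")

    def test_positionwise_failure(self):
        assert not matches_iupac("TAGTATTAC", "TAWWDHWAN")  # G fails W at position 3

    def test_bad_pattern_character(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            iupac_regex("NANTAXTAN")


class TestScan:
    def test_hit_across_origin(self):
        seq = "TTAC" + "A" * 300 + "TAGTA"  # motif wraps the origin
        genome = CircularGenome(id="w", seq=seq)
        hits = scan_nonanucleotides(genome, ["NANTANTAN"])
        assert any(h.start % genome.length == 304 and h.strand == "+" for h in hits)

    def test_minus_strand_coordinates(self):
        from crucivir.stemloop_finder import revcomp

        motif = "TAGTATTAC"
        seq = "A" * 50 + revcomp(motif) + "A" * 50
        hits = scan_nonanucleotides(CircularGenome(id="m", seq=seq), ["NANTANTAN"])
        minus = [h for h in hits if h.strand == "-"]
        assert minus and minus[0].matched_seq == motif
        assert minus[0].start == 50 and minus[0].position == 58

    def test_deterministic_order(self, planted):
        genome, _ = planted
        hits = scan_nonanucleotides(genome)
        keys = [(h.start % genome.length, h.strand, h.pattern) for h in hits]
        assert keys == sorted(keys)


class TestScore:
    @pytest.mark.parametrize("stem,loop,expected", [(11, 11, 0), (5, 7, 10), (20, 20, 18)])
    def test_examples(self, stem, loop, expected):
        assert score_stemloop(stem, loop) == expected

    def test_symmetric_and_zero_iff_ideal(self):
        for s in range(0, 31):
            for l in range(0, 31):
                score = score_stemloop(s, l)
                assert score == abs(s - 11) + abs(l - 11)
                assert (score == 0) == (s == 11 and l == 11)


class TestFolding:
    def test_maximum_pairing_hairpin_of_reference_window(self):
        window = "GGGGGAAAAAAACCCCC"
        best = max(hairpin_scan(window), key=lambda c: c[2])
        assert (best[2], best[3]) == (5, 7)
        assert (best[0], best[1], best[2], best[3]) in oracles.brute_force_hairpins(window)

    def test_all_a_window_has_no_structure(self):
        assert hairpin_scan("A" * 20) == []

    def test_scan_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 31))
            window = "".join(rng.choice(list("ACGT"), size=n))
            got = set(hairpin_scan(window))
            assert got == oracles.brute_force_hairpins(window)

    def test_nussinov_matches_interval_recursion(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(8, 31))
            window = "".join(rng.choice(list("ACGT"), size=n))
            assert len(nussinov_pairs(window)) == oracles.max_nested_pairs(window)

    def test_fold_window_recovers_perfect_hairpin(self):
        genome, start = _hairpin_genome()
        hit = MotifHit(pattern="NANTANTAN", position=start, strand="+", matched_seq="TAGTATTAC")
        hp = fold_window(genome, hit)
        assert (hp.stem_len, hp.loop_len) == (11, 11)

    def test_linear_record_window_error(self):
        genome = CircularGenome(id="lin", seq="TAGTATTAC" + "A" * 50, circular=False)
        hit = MotifHit(pattern="NANTANTAN", position=0, strand="+", matched_seq="TAGTATTAC")
        with pytest.raises(ValueError, match="linear"):
            fold_window(genome, hit)

    def test_flank_bounds(self, planted):
        genome, truth = planted
        hit = MotifHit(pattern="NANTANTAN", position=truth.ori_position,
                       strand="+", matched_seq=truth.nonanucleotide)
        with pytest.raises(ValueError):
            fold_window(genome, hit, flank=10)


class TestFindStemloops:
    def test_planted_ideal_hairpin_scores_zero(self):
        genome, start = _hairpin_genome()
        anns = [a for a in find_stemloops(genome) if a.accepted]
        mine = [a for a in anns if a.motif.start == start]
        assert len(mine) == 1
        assert mine[0].score == 0 and mine[0].motif.strand == "+"

    def test_short_stem_rejected_as_geometry(self):
        genome, start = _hairpin_genome(stem="GCGC")  # stem 4: not "longer than 4 bp"
        anns = find_stemloops(genome)
        at_truth = [a for a in anns if a.motif.start == start]
        assert at_truth and not at_truth[0].accepted
        assert at_truth[0].rejection_reason == "geometry"

    def test_duplicate_first_base_keeps_single_annotation(self):
        genome, start = _hairpin_genome()
        anns = find_stemloops(genome)
        same_hp = [a for a in anns if a.hairpin is not None
                   and a.hairpin.start == next(x for x in anns if x.accepted).hairpin.start]
        assert sum(a.accepted for a in same_hp) == 1
        assert all(a.rejection_reason == "duplicate_first_base"
                   for a in same_hp if not a.accepted and a.score ==
                   min(x.score for x in same_hp))

    def test_accepted_set_invariant_under_rotation(self, planted):
        genome, _ = planted
        base = {((a.motif.start % genome.length), a.motif.strand, a.score)
                for a in find_stemloops(genome) if a.accepted}
        shift = 1234
        rotated = rotate(genome, shift)
        moved = {((a.motif.start + shift) % genome.length, a.motif.strand, a.score)
                 for a in find_stemloops(rotated) if a.accepted}
        assert base == moved


class TestFrequencies:
    def _ann(self, seq):
        from crucivir.stemloop_finder import Hairpin, StemLoopAnnotation

        hp = Hairpin(stem_len=11, loop_len=11, start=0, end=33, pairs=())
        return StemLoopAnnotation(
            motif=MotifHit(pattern="NANTANTAN", position=0, strand="+", matched_seq=seq),
            hairpin=hp, score=0, accepted=True)

    def test_uniform_input(self):
        freq = nonanucleotide_frequencies([self._ann("TAGTATTAC")] * 64)
        assert freq.loc[1, "T"] == 1.0

    def test_even_mixture(self):
        anns = [self._ann("TAGTATTAC"), self._ann("AAGTATTAC")]
        freq = nonanucleotide_frequencies(anns)
        assert freq.loc[1, "T"] == pytest.approx(0.5)
        assert freq.loc[1, "A"] == pytest.approx(0.5)

    def test_rows_are_stochastic(self):
        anns = [self._ann(s) for s in ("TAGTATTAC", "TAATATTAC", "CAGTATTAC")]
        freq = nonanucleotide_frequencies(anns)
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            nonanucleotide_frequencies([])
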
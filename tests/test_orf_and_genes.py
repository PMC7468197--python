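import numpy as np
import pytest

import oracles
from crucivir.genome_io import CircularGenome, rotate
from crucivir.orf_and_genes import (
    AlignmentHit,
    GeneAnnotation,
    SpliceConfig,
    classify_orientation,
    classify_orfs,
    detect_splice_candidates,
    find_orfs,
    screen_capsid_candidates,
    smith_waterman,
    translate,
)
from crucivir.synthetic_data import SyntheticSpec, generate_genome

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestTranslate:
    @pytest.mark.parametrize("dna,code,expected", [
        ("ATGTAA", "standard", "M*"),
        ("ATGTAA", "ciliate", "MQ"),
        ("ATGTGA", "ciliate", "M*"),
    ])
    def test_codes(self, dna, code, expected):
        assert translate(dna, code) == expected

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            translate("ATGT")

    def test_unknown_code(self):
        with pytest.raises(ValueError):
            translate("ATG", "mitochondrial")


class TestFindOrfs:
    def test_no_atg_means_no_orfs(self):
        assert find_orfs(CircularGenome(id="t", seq="T" * 400), 30) == []

    def test_planted_cds_coordinates_exact(self, planted):
        genome, truth = planted
        segs = [o.segments[0] for o in find_orfs(genome, 300)]
        assert truth.capsid_segments[0] in segs
        assert truth.rep_segments[0] in segs

    def test_orf_spanning_origin_found_after_rotation(self, planted):
        genome, truth = planted
        cs, ce, _ = truth.capsid_segments[0]
        shift = (cs + ce) // 2  # origin now falls inside the capsid CDS
        rotated = rotate(genome, shift)
        expected = ((cs - shift) % genome.length, (ce - shift) % genome.length, "+")
        assert expected in [o.segments[0] for o in find_orfs(rotated, 300)]

    def test_orf_set_invariant_under_rotation(self, planted):
        genome, _ = planted
        L = genome.length
        base = {(o.segments[0][0], o.segments[0][1], o.segments[0][2]) for o in find_orfs(genome, 300)}
        shift = 777
        moved = {((s + shift) % L, (e + shift) % L, st)
                 for s, e, st in ((o.segments[0]) for o in find_orfs(rotate(genome, shift), 300))}
        assert base == moved


class TestSmithWaterman:
    def test_identical_sequences_full_identity(self):
        rng = np.random.default_rng(0)
        prot = "".join(rng.choice(list(AA), size=100))
        hit = smith_waterman(prot, prot)
        assert hit.percent_identity == 100.0
        assert hit.alignment_length == 100

    def test_two_residue_score_is_sum_of_matrix_entries(self):
        # BLOSUM62: S(A,A)=4, S(W,W)=11
        assert smith_waterman("AW", "AW").raw_score == 15.0

    def test_bit_score_follows_karlin_altschul(self):
        import math

        hit = smith_waterman("AW", "AW")
        assert hit.bits == pytest.approx((0.267 * 15 - math.log(0.041)) / math.log(2))

    def test_reversed_sequence_scores_far_below_self(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            prot = "".join(rng.choice(list(AA), size=100))
            self_score = smith_waterman(prot, prot).raw_score
            rev_score = smith_waterman(prot, prot[::-1]).raw_score
            assert rev_score < 0.5 * self_score

    def test_matches_textbook_dp_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=int(rng.integers(5, 51))))
            b = "".join(rng.choice(list(AA), size=int(rng.integers(5, 51))))
            assert smith_waterman(a, b).raw_score == pytest.approx(oracles.gotoh_local_score(a, b))

    def test_unknown_matrix_and_empty_input(self):
        with pytest.raises(ValueError):
            smith_waterman("AW", "AW", matrix="NOSUCH62")
        with pytest.raises(ValueError):
            smith_waterman("", "AW")


class TestCapsidScreen:
    def test_planted_capsid_retained_random_not(self, refs):
        genome, _ = generate_genome(SyntheticSpec(seed=2))
        rng = np.random.default_rng(3)
        randoms = [CircularGenome(id=f"r{i}", seq="".join(rng.choice(list("ACGT"), size=3000)))
                   for i in range(20)]
        hits = screen_capsid_candidates([genome] + randoms, refs["capsid"])
        retained = {cid for cid, _ in hits}
        assert genome.id in retained
        assert not retained & {r.id for r in randoms}

    def test_retention_monotone_in_threshold(self, refs):
        genome, _ = generate_genome(SyntheticSpec(seed=2))
        counts = [len(screen_capsid_candidates([genome], refs["capsid"], thr))
                  for thr in (10, 50, 200, 1e6)]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            screen_capsid_candidates([], {})


class TestSplicing:
    def test_planted_intron_recovered_exactly(self, refs):
        for orientation in ("unisense", "ambisense"):
            genome, truth = generate_genome(
                SyntheticSpec(seed=11, include_intron=True, orientation=orientation))
            strand = truth.rep_segments[0][2]
            lo = min(s for s, _, _ in truth.rep_segments)
            hi = max(e for _, e, _ in truth.rep_segments)
            ann = detect_splice_candidates(genome, [(lo, hi, strand)])
            assert ann is not None and ann.spliced
            assert ann.segments == truth.rep_segments
            assert ann.protein == truth.rep_protein

    def test_minimal_intron_preferred(self):
        # region with nested valid introns of 120 and 300 nt: the excised
        # ORF is valid either way, so the shorter intron must win
        rng = np.random.default_rng(5)
        codons = ["GCC", "GAA", "GAC", "TGC", "TCC"]
        exon1 = "ATG" + "".join(rng.choice(codons) for _ in range(40))
        exon2 = "".join(rng.choice(codons) for _ in range(40)) + "TAA"
        inner = "GT" + "C" * 10 + "TAA" + "C" * 103 + "AG"      # 120 nt
        intron300 = "GT" + "C" * 88 + inner + "C" * 88 + "AG"   # no other GT/AG
        assert len(inner) == 120 and len(intron300) == 300
        seq = "TAA" + exon1 + intron300 + exon2
        genome = CircularGenome(id="spl", seq=seq + "A" * 400)
        region = [(3, len(seq), "+")]
        ann = detect_splice_candidates(genome, region,
                                       config=SpliceConfig(min_intron=40, max_intron=400))
        assert ann is not None
        intron_len = ann.segments[1][0] - ann.segments[0][1]
        assert intron_len == 120

    def test_single_frame_rep_needs_no_splice(self, refs, fast_config):
        from crucivir.pipeline import annotate_genome

        genome, _ = generate_genome(SyntheticSpec(seed=6))
        row = annotate_genome(genome, refs, fast_config)
        assert row["has_rep"] and not row["rep_spliced"]


class TestOrientation:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("+", "+", "unisense"), ("+", "-", "ambisense"), ("-", "-", "unisense")])
    def test_strand_combinations(self, s1, s2, expected):
        cap = GeneAnnotation(id="c", genome_id="g", segments=[(0, 30, s1)])
        rep = GeneAnnotation(id="r", genome_id="g", segments=[(40, 70, s2)])
        assert classify_orientation(cap, rep) == expected

    def test_missing_rep(self):
        cap = GeneAnnotation(id="c", genome_id="g", segments=[(0, 30, "+")])
        assert classify_orientation(cap, None) == "not_applicable"


class TestClassification:
    def test_planted_proteins_classified_by_homology(self, refs, planted):
        genome, truth = planted
        orfs = find_orfs(genome, 300)
        classify_orfs(orfs, refs)
        by_class = {}
        for o in orfs:
            by_class.setdefault(o.product_class, []).append(o)
        assert truth.capsid_segments[0] in [o.segments[0] for o in by_class.get("capsid", [])]
        assert truth.rep_segments[0] in [o.segments[0] for o in by_class.get("rep", [])]
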
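import numpy as np
import pytest

from crucivir.genome_io import (
    CircularGenome,
    DuplicateIdError,
    canonical_rotation,
    detect_terminal_redundancy,
    gc_content,
    read_fasta,
    read_genbank_features,
    rotate,
    to_gff3,
    write_genbank,
)
from crucivir.orf_and_genes import GeneAnnotation
from crucivir.stemloop_finder import revcomp


def _write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_uppercases_and_maps_u_to_t(self, tmp_path):
        coll = read_fasta(_write(tmp_path, ">a\nacgu\n"))
        assert coll.records[0].seq == "ACGT"

    def test_duplicate_ids_rejected_with_name(self, tmp_path):
        p = _write(tmp_path, ">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(DuplicateIdError, match="a"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(_write(tmp_path, ""))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGGG", 100.0), ("ATNNAT", 0.0)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_rotation_and_revcomp_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=100))
            g = CircularGenome(id="x", seq=seq)
            assert gc_content(rotate(g, 37)) == pytest.approx(gc_content(g))
            assert gc_content(revcomp(seq)) == pytest.approx(gc_content(seq))


class TestTerminalRedundancy:
    def test_matches_brute_force_oracle_on_constructed_contigs(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(200, 2001))
            s = "".join(rng.choice(list("ACGT"), size=n))
            k = int(rng.integers(10, n // 2))
            contig = s + s[:k]
            overlap, genome = detect_terminal_redundancy(contig)
            # brute-force longest prefix == suffix
            m = len(contig)
            oracle = max((kk for kk in range(10, m // 2 + 1) if contig[:kk] == contig[m - kk:]),
                         default=0)
            assert overlap == oracle >= k
            assert genome is not None and genome.length == m - overlap
            assert genome.redundancy_trimmed == overlap

    def test_non_redundant_contig_returns_none(self):
        assert detect_terminal_redundancy("ACGTACGTTTACGTACG")[1] is None

    def test_short_contig_returns_none(self):
        overlap, genome = detect_terminal_redundancy("ACGTACGTACGTACG")  # 15 < 2*10
        assert (overlap, genome) == (0, None)

    def test_min_overlap_floor(self):
        with pytest.raises(ValueError):
            detect_terminal_redundancy("A" * 100, min_overlap=5)


class TestCanonicalRotation:
    def test_simple(self):
        assert canonical_rotation(CircularGenome(id="x", seq="CGA")).seq == "ACG"

    def test_idempotent_and_matches_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 60))))
            g = CircularGenome(id="x", seq=seq)
            once = canonical_rotation(g)
            assert canonical_rotation(once).seq == once.seq
            expected = min(seq[i:] + seq[:i] for i in range(len(seq)))
            assert once.seq == expected

    def test_all_rotations_converge(self):
        seq = "TTAGGA"
        canon = {canonical_rotation(CircularGenome(id="x", seq=seq[i:] + seq[:i])).seq
                 for i in range(len(seq))}
        assert len(canon) == 1

    def test_features_shift_with_rotation(self):
        g = CircularGenome(id="x", seq="ACGTACGTACGT")
        g.features.append(GeneAnnotation(id="f", genome_id="x", segments=[(2, 8, "+")]))
        r = rotate(g, 2)
        assert r.features[0].segments == [(0, 6, "+")]


class TestGenBankRoundTrip:
    def _genome(self):
        rng = np.random.default_rng(5)
        g = CircularGenome(id="gb1", seq="".join(rng.choice(list("ACGT"), size=600)))
        g.features = [
            GeneAnnotation(id="cap", genome_id="gb1", segments=[(30, 150, "+")],
                           product_class="capsid", product="capsid protein"),
            GeneAnnotation(id="rep", genome_id="gb1", segments=[(200, 290, "-"), (320, 410, "-")],
                           spliced=True, product_class="rep", product="replication-associated protein",
                           genetic_code="ciliate"),
            GeneAnnotation(id="wrap", genome_id="gb1", segments=[(550, 40, "+")],
                           product_class="putative_orf", product="putative ORF"),
        ]
        return g

    def test_features_round_trip(self, tmp_path):
        g = self._genome()
        path = tmp_path / "out.gbk"
        write_genbank([g], path)
        coll = read_genbank_features(path)
        rec = coll.records[0]
        assert rec.seq == g.seq and rec.circular
        by_product = {f.product_class: f for f in rec.features}
        assert by_product["capsid"].segments == [(30, 150, "+")]
        rep = by_product["rep"]
        assert rep.spliced and rep.genetic_code == "ciliate"
        assert sorted(s[:2] for s in rep.segments) == [(200, 290), (320, 410)]
        assert all(s[2] == "-" for s in rep.segments)
        wrap = by_product["putative_orf"]
        assert wrap.segments == [(550, 40, "+")]

    def test_gff3_export(self, tmp_path):
        g = self._genome()
        out = tmp_path / "out.gff3"
        to_gff3([g], out)
        text = out.read_text()
        assert text.startswith("##gff-version 3")
        assert "\tCDS\t31\t150\t" in text  # 1-based inclusive
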
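"""ORF calling on circular genomes, homology classification, and splicing.

ORFs are called on all six frames with full wrap across the origin of the
circle.  Candidate proteins are classified as capsid, Rep, or "putative
ORF" by local alignment against a reference protein library, with the
screening threshold expressed as a Karlin-Altschul bit score.  Genomes
whose Rep cannot be read in a single frame are rescued by canonical
GT..AG splice-site search or by re-translation under the ciliate genetic
code (translation table 6, in which TAA/TAG encode glutamine).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from crucivir import _align
from crucivir.genome_io import CircularGenome
from crucivir.stemloop_finder import revcomp

GENETIC_CODES = {"standard": 1, "ciliate": 6}

#: Homology-classification thresholds (identity %, fraction of ref covered).
MIN_CLASS_IDENTITY = 25.0
MIN_CLASS_COVERAGE = 0.5


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    reference_id: str
    raw_score: float
    bits: float
    evalue: float
    percent_identity: float
    alignment_length: int
    query_span: tuple[int, int] = (0, 0)
    ref_span: tuple[int, int] = (0, 0)


@dataclass
class GeneAnnotation:
    """A CDS/ORF call; possibly origin-spanning, possibly spliced.

    ``segments`` are (start, end, strand) forward-strand intervals in
    coding order; ``end < start`` denotes wrap across the origin.
    """

    id: str
    genome_id: str
    segments: list[tuple[int, int, str]]
    frame: Optional[int] = None
    genetic_code: str = "standard"
    spliced: bool = False
    product_class: str = "unknown"  # capsid | rep | putative_orf | unknown
    protein: str = ""
    best_hit: Optional[AlignmentHit] = None
    product: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.segments[0][2]

    def nucleotide_length(self, genome_length: int) -> int:
        total = 0
        for start, end, _ in self.segments:
            total += (end - start) % genome_length or genome_length
        return total

    def shifted(self, delta: int, length: int) -> "GeneAnnotation":
        segs = [((s + delta) % length, (e + delta) % length, st) for s, e, st in self.segments]
        return replace(self, segments=segs)


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate(dna: str, code: str = "standard") -> str:
    """Translate a coding sequence; stops appear as '*'.

    Under the ciliate code (table 6) TAA and TAG encode glutamine and only
    TGA terminates.
    """
    if len(dna) % 3 != 0:
        raise ValueError(f"coding sequence length {len(dna)} not divisible by 3")
    table = GENETIC_CODES.get(code)
    if table is None:
        raise ValueError(f"unknown genetic code {code!r}")
    return str(Seq(dna).translate(table=table))


def _stop_codons(code: str) -> frozenset[str]:
    table = CodonTable.unambiguous_dna_by_id[GENETIC_CODES[code]]
    return frozenset(table.stop_codons)


# ---------------------------------------------------------------------------
# ORF finding on the circle
# ---------------------------------------------------------------------------

def find_orfs(genome: CircularGenome, min_len: int = 300, code: str = "standard") -> list[GeneAnnotation]:
    """All maximal ATG-to-stop ORFs longer than ``min_len`` nucleotides.

    Both strands, all frames, scanning across the origin (an ORF may
    wrap).  Length counts the stop codon.  Returned in deterministic
    order (strand, forward start coordinate).
    """
    L = genome.length
    stops = _stop_codons(code)
    results: dict[tuple[str, int], GeneAnnotation] = {}
    for strand in ("+", "-"):
        s = genome.seq if strand == "+" else revcomp(genome.seq)
        s2 = s + s if genome.circular else s
        for f in range(3):
            stop_positions = [p for p in range(f, len(s2) - 2, 3) if s2[p:p + 3] in stops]
            for prev, nxt in zip(stop_positions, stop_positions[1:]):
                atg = None
                for p in range(prev + 3, nxt, 3):
                    if s2[p:p + 3] == "ATG":
                        atg = p
                        break
                if atg is None:
                    continue
                nlen = nxt + 3 - atg
                if nlen <= min_len or nlen > L:
                    continue
                key = (strand, atg % L)
                if key in results:
                    continue
                seg = _strandlocal_to_forward(atg % L, nlen, strand, L)
                cds = s2[atg:nxt + 3]
                ann = GeneAnnotation(
                    id=f"{genome.id}_orf_{strand}{atg % L}",
                    genome_id=genome.id,
                    segments=[seg],
                    frame=atg % 3,
                    genetic_code=code,
                    protein=translate(cds, code)[:-1],
                )
                if "N" in cds:
                    ann.flags.append("ambiguous")
                results[key] = ann
    anns = list(results.values())
    anns.sort(key=lambda a: (a.strand, a.segments[0][0]))
    return anns


def _strandlocal_to_forward(start: int, nlen: int, strand: str, L: int) -> tuple[int, int, str]:
    if strand == "+":
        return start, (start + nlen) % L, "+"
    end_local = start + nlen
    return (L - end_local) % L, (L - start) % L, "-"


def extract_cds(genome: CircularGenome, ann: GeneAnnotation) -> str:
    """Concatenated coding nucleotides of an annotation, 5'->3'."""
    parts = []
    for start, end, strand in ann.segments:
        frag = genome.fragment(start, end)
        parts.append(frag if strand == "+" else revcomp(frag))
    if ann.segments and ann.segments[0][2] == "-" and len(ann.segments) > 1:
        # segments are stored in coding order already
        pass
    return "".join(parts)


# ---------------------------------------------------------------------------
# Local alignment and homology screening
# ---------------------------------------------------------------------------

def smith_waterman(
    query: str,
    ref: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
    query_id: str = "query",
    ref_id: str = "ref",
) -> AlignmentHit:
    """Optimal local alignment with affine gaps; Karlin-Altschul statistics."""
    if not query or not ref:
        raise ValueError("sequences must be nonempty")
    aligner = _align.get_aligner("local", matrix, gap_open, gap_extend)
    aln = aligner.align(query, ref)[0]
    row_q, row_r = aln[0], aln[1]
    ncols = len(row_q)
    ident = sum(1 for a, b in zip(row_q, row_r) if a == b and a != "-")
    (qspans, rspans) = aln.aligned
    qspan = (int(qspans[0][0]), int(qspans[-1][1])) if len(qspans) else (0, 0)
    rspan = (int(rspans[0][0]), int(rspans[-1][1])) if len(rspans) else (0, 0)
    return AlignmentHit(
        query_id=query_id,
        reference_id=ref_id,
        raw_score=float(aln.score),
        bits=_align.bit_score(float(aln.score)),
        evalue=_align.e_value(float(aln.score), len(query), len(ref)),
        percent_identity=100.0 * ident / ncols if ncols else 0.0,
        alignment_length=ncols,
        query_span=qspan,
        ref_span=rspan,
    )


def sixframe_segments(seq: str, min_aa: int = 20):
    """Stop-free translated segments of all six frames of a DNA string.

    Yields (strand, frame, nt_start, nt_end, protein) with nucleotide
    coordinates on the forward strand of ``seq``.
    """
    L = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else revcomp(seq)
        for f in range(3):
            prot = translate(s[f:f + 3 * ((L - f) // 3)], "standard")
            for m in re.finditer(r"[^*]+", prot):
                if m.end() - m.start() < min_aa:
                    continue
                nt_a, nt_b = f + 3 * m.start(), f + 3 * m.end()
                if strand == "+":
                    yield strand, f, nt_a, nt_b, m.group(0)
                else:
                    yield strand, f, L - nt_b, L - nt_a, m.group(0)


def screen_capsid_candidates(
    contigs: Sequence, capsid_refs: dict[str, str], bit_threshold: float = 50.0
) -> list[tuple[str, AlignmentHit]]:
    """Six-frame translated search of contigs against capsid references.

    A contig is retained iff its best local-alignment bit score against any
    reference reaches ``bit_threshold``; results are sorted by bit score,
    descending.
    """
    if not capsid_refs:
        raise ValueError("capsid reference set is empty")
    retained = []
    for contig in contigs:
        seq = contig.seq if hasattr(contig, "seq") else str(contig)
        cid = contig.id if hasattr(contig, "id") else "contig"
        best: Optional[AlignmentHit] = None
        for _, _, _, _, prot in sixframe_segments(seq):
            for ref_id, ref_seq in capsid_refs.items():
                hit = smith_waterman(prot, ref_seq, query_id=cid, ref_id=ref_id)
                if best is None or hit.raw_score > best.raw_score:
                    best = hit
        if best is not None and best.bits >= bit_threshold:
            retained.append((cid, best))
    retained.sort(key=lambda t: (-t[1].bits, t[0]))
    return retained


def classify_orfs(
    orfs: list[GeneAnnotation],
    refs: dict[str, dict[str, str]],
    min_identity: float = MIN_CLASS_IDENTITY,
    min_coverage: float = MIN_CLASS_COVERAGE,
) -> None:
    """Assign product classes by best qualifying homology hit (in place).

    ``refs`` maps class name ("capsid", "rep") to {ref_id: protein}.  A hit
    qualifies when identity >= ``min_identity`` percent over at least
    ``min_coverage`` of the reference length; the best qualifying hit (by
    bit score) sets the class.  Several ORFs per genome may receive the
    same class (dual-capsid genomes occur).
    """
    for orf in orfs:
        best: Optional[AlignmentHit] = None
        best_class = None
        for cls, lib in refs.items():
            for ref_id, ref_seq in lib.items():
                hit = smith_waterman(orf.protein, ref_seq, query_id=orf.id, ref_id=ref_id)
                coverage = (hit.ref_span[1] - hit.ref_span[0]) / len(ref_seq)
                if hit.percent_identity >= min_identity and coverage >= min_coverage:
                    if best is None or hit.raw_score > best.raw_score:
                        best, best_class = hit, cls
        if best is not None:
            orf.product_class = best_class
            orf.best_hit = best


def mark_putative_orfs(
    orfs: list[GeneAnnotation], genome_length: int, min_len: int = 300
) -> None:
    """Label unclassified ORFs longer than ``min_len`` nt as putative ORFs,
    unless they overlap a capsid/Rep annotation (in place)."""
    classified = [o for o in orfs if o.product_class in ("capsid", "rep")]
    for orf in orfs:
        if orf.product_class != "unknown":
            continue
        if orf.nucleotide_length(genome_length) <= min_len:
            continue
        if any(_segments_overlap(orf, other, genome_length) for other in classified):
            continue
        orf.product_class = "putative_orf"


def _segments_overlap(a: GeneAnnotation, b: GeneAnnotation, L: int) -> bool:
    def covered(ann):
        pos = set()
        for s, e, _ in ann.segments:
            n = (e - s) % L or L
            pos.update((s + i) % L for i in range(n))
        return pos

    return bool(covered(a) & covered(b))


# ---------------------------------------------------------------------------
# Splice-candidate rescue
# ---------------------------------------------------------------------------

@dataclass
class SpliceConfig:
    donor: str = "GT"
    acceptor: str = "AG"
    min_intron: int = 40
    max_intron: int = 1500
    # context bonus: exon ending in AG before the donor, G after the acceptor
    donor_context: str = "AG"
    acceptor_context: str = "G"


def detect_splice_candidates(
    genome: CircularGenome,
    rep_regions: list[tuple[int, int, str]],
    anchors: Optional[list[tuple[int, int]]] = None,
    config: SpliceConfig | None = None,
    margin: int = 60,
) -> Optional[GeneAnnotation]:
    """Search donor/acceptor pairs whose excision yields a stop-free Rep ORF.

    ``rep_regions`` are forward-strand (start, end, strand) intervals with
    Rep homology (all on one strand); ``anchors`` are strand-local
    intervals within the merged region that the spliced ORF must cover
    (e.g. the endonuclease- and helicase-motif hit regions).  Solutions
    are ranked by intron length (minimal first), then by splice-site
    context score; the first valid solution is returned, or None.
    """
    config = config or SpliceConfig()
    if not rep_regions:
        return None
    strand = rep_regions[0][2]
    L = genome.length
    lo = min(s for s, _, _ in rep_regions)
    hi = max(e for _, e, _ in rep_regions)
    lo, hi = max(0, lo - margin), min(L, hi + margin)
    span = genome.seq[lo:hi]
    if strand == "-":
        span = revcomp(span)
    if anchors is None:
        anchors = [(max(0, s - lo), min(hi, e) - lo) if strand == "+" else
                   ((hi - e), (hi - s)) for s, e, _ in rep_regions]

    donors = [m.start() for m in re.finditer(f"(?={config.donor})", span)]
    acceptors = [m.start() for m in re.finditer(f"(?={config.acceptor})", span)]
    candidates = []
    for d in donors:
        for a in acceptors:
            ilen = a + 2 - d
            if not config.min_intron <= ilen <= config.max_intron:
                continue
            ctx = 0
            if span[max(0, d - 2):d] == config.donor_context:
                ctx += 1
            if span[a + 2:a + 3] == config.acceptor_context:
                ctx += 1
            candidates.append((ilen, -ctx, d, a))
    candidates.sort()

    for ilen, _, d, a in candidates:
        spliced = span[:d] + span[a + 2:]
        orf = _best_orf_covering(spliced, d, ilen, anchors)
        if orf is None:
            continue
        o_start, o_end = orf
        segs_local = [(o_start, d), (a + 2, o_end + ilen)]
        segments = []
        for s_loc, e_loc in segs_local:
            if strand == "+":
                segments.append((lo + s_loc, lo + e_loc, "+"))
            else:
                segments.append((hi - e_loc, hi - s_loc, "-"))
        cds = spliced[o_start:o_end]
        return GeneAnnotation(
            id=f"{genome.id}_rep_spliced",
            genome_id=genome.id,
            segments=segments,
            genetic_code="standard",
            spliced=True,
            product_class="rep",
            protein=translate(cds, "standard")[:-1],
        )
    return None


def _best_orf_covering(
    spliced: str, junction: int, ilen: int, anchors: list[tuple[int, int]]
) -> Optional[tuple[int, int]]:
    """Longest ATG..stop ORF in ``spliced`` that spans ``junction`` and
    covers all anchors (anchor coords are pre-splice, strand-local)."""
    stops = _stop_codons("standard")

    def to_spliced(p: int) -> int:
        return p if p < junction else p - ilen

    mapped = []
    for (a, b) in anchors:
        a2, b2 = to_spliced(a), to_spliced(b)
        if a2 > b2:
            a2, b2 = b2, a2
        mapped.append((a2, b2))

    best = None
    for f in range(3):
        prev_stop = f - 3
        atg = None
        for p in range(f, len(spliced) - 2, 3):
            codon = spliced[p:p + 3]
            if codon == "ATG" and atg is None:
                atg = p
            if codon in stops:
                if atg is not None:
                    start, end = atg, p + 3
                    if start < junction <= end and all(
                        start <= a and b <= end for a, b in mapped
                    ):
                        if best is None or end - start > best[1] - best[0]:
                            best = (start, end)
                atg = None
                prev_stop = p
    return best


def classify_orientation(capsid: Optional[GeneAnnotation], rep: Optional[GeneAnnotation]) -> str:
    """unisense when capsid and Rep are co-oriented, ambisense otherwise."""
    if capsid is None or rep is None:
        return "not_applicable"
    return "unisense" if capsid.strand == rep.strand else "ambisense"
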
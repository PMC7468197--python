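"""Sequence I/O and circular-genome resolution.

Assembled contigs that derive from a circular template carry *terminal
redundancy*: the assembler walks around the circle and re-emits the first
bases of the contig at its end.  :func:`detect_terminal_redundancy` trims
that exact repeat and promotes the contig to a :class:`CircularGenome`.

Coordinate conventions (used throughout the package):

- 0-based, half-open, anchored on the forward strand;
- a feature with ``end < start`` wraps across the origin;
- conversion to 1-based inclusive happens only at GenBank/GFF3
  serialization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_DNA_ALPHABET = set("ACGTN")

#: Default keyword → product-class mapping applied to GenBank /product strings.
DEFAULT_PRODUCT_KEYWORDS = {
    "capsid": "capsid",
    "coat protein": "capsid",
    "cp": "capsid",
    "rep": "rep",
    "replication": "rep",
    "putative orf": "putative_orf",
    "hypothetical": "putative_orf",
}


class DuplicateIdError(ValueError):
    """Two records in one collection share an id."""


def _clean_seq(raw: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq


@dataclass
class CircularGenome:
    """A resolved (or putatively) circular DNA genome with its annotations.

    ``redundancy_trimmed`` records how many bases of exact terminal repeat
    were removed from the originating contig; 0 for finished records.
    """

    id: str
    seq: str
    redundancy_trimmed: int = 0
    source: str = "finished_record"  # assembled_contig | finished_record
    circular: bool = True
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = _clean_seq(self.seq)
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.redundancy_trimmed < 0:
            raise ValueError("redundancy_trimmed must be >= 0")

    @property
    def length(self) -> int:
        return len(self.seq)

    def fragment(self, start: int, end: int) -> str:
        """Subsequence [start, end) with circular wrap when end <= start."""
        L = self.length
        start %= L
        end %= L
        if end > start:
            return self.seq[start:end]
        if not self.circular:
            raise ValueError(f"wrap-around fragment on linear record {self.id!r}")
        return self.seq[start:] + self.seq[:end]


@dataclass
class SequenceCollection:
    """An ordered, id-unique set of genome records."""

    records: list[CircularGenome] = field(default_factory=list)
    format_origin: str = "fasta"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate record id: {rec.id!r}")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[CircularGenome]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rec_id: str) -> CircularGenome:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


def read_fasta(path, *, circular: bool = True, source: str = "finished_record") -> SequenceCollection:
    """Read a FASTA file into a :class:`SequenceCollection`.

    Sequences are uppercased and U is mapped to T.  An empty file or a
    duplicated header id is an error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            CircularGenome(id=rec.id, seq=str(rec.seq), source=source, circular=circular)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceCollection(records=records, format_origin="fasta")


def write_fasta(collection: Iterable[CircularGenome], path) -> None:
    recs = [SeqRecord(Seq(g.seq), id=g.id, description="") for g in collection]
    SeqIO.write(recs, str(path), "fasta")


def gc_content(genome: CircularGenome | str) -> float:
    """G+C percentage over unambiguous bases (N excluded from denominator)."""
    seq = genome.seq if isinstance(genome, CircularGenome) else _clean_seq(genome)
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / denom


def detect_terminal_redundancy(
    contig: str, min_overlap: int = 10, *, contig_id: str = "contig"
) -> tuple[int, Optional[CircularGenome]]:
    """Find the longest exact suffix of ``contig`` equal to its prefix.

    Overlap lengths from ``len(contig) // 2`` down to ``min_overlap`` are
    tested; on a hit the suffix is trimmed and the remainder returned as a
    :class:`CircularGenome` with ``redundancy_trimmed`` set.  Returns
    ``(0, None)`` when no redundancy is found or the contig is too short.
    """
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    contig = _clean_seq(contig)
    n = len(contig)
    if n < 2 * min_overlap:
        logger.warning("contig %s shorter than 2*min_overlap; cannot assess circularity", contig_id)
        return 0, None
    for k in range(n // 2, min_overlap - 1, -1):
        if contig[:k] == contig[n - k:]:
            genome = CircularGenome(
                id=contig_id,
                seq=contig[: n - k],
                redundancy_trimmed=k,
                source="assembled_contig",
            )
            return k, genome
    return 0, None


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    ss = s + s
    n = len(s)
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
        if k + n <= j:
            break
    return k


def canonical_rotation(genome: CircularGenome) -> CircularGenome:
    """Rotate to the lexicographically least forward-strand rotation.

    Feature coordinates are shifted accordingly (features implementing a
    ``shifted(delta, length)`` method are carried over).  Idempotent.
    """
    shift = _least_rotation(genome.seq)
    return rotate(genome, shift)


def rotate(genome: CircularGenome, shift: int) -> CircularGenome:
    """Rotate so that current position ``shift`` becomes the new origin."""
    L = genome.length
    shift %= L
    new_seq = genome.seq[shift:] + genome.seq[:shift]
    new_features = []
    for feat in genome.features:
        if hasattr(feat, "shifted"):
            new_features.append(feat.shifted(-shift, L))
        else:
            new_features.append(feat)
    return CircularGenome(
        id=genome.id,
        seq=new_seq,
        redundancy_trimmed=genome.redundancy_trimmed,
        source=genome.source,
        circular=genome.circular,
        features=new_features,
    )


# ---------------------------------------------------------------------------
# GenBank flat files
# ---------------------------------------------------------------------------

def _classify_product(product: str, keyword_map: dict[str, str]) -> str:
    low = product.lower()
    for key, cls in keyword_map.items():
        if key in low:
            return cls
    return "unknown"


def read_genbank_features(path, *, keyword_map: dict[str, str] | None = None) -> SequenceCollection:
    """Read GenBank flat files, mapping CDS features to gene annotations.

    ``join()`` locations become spliced multi-segment annotations;
    ``/transl_table=6`` selects the ciliate code; ``/product`` strings are
    mapped to a product class through ``keyword_map`` (see
    :data:`DEFAULT_PRODUCT_KEYWORDS`).  A feature whose location cannot be
    interpreted is skipped with a warning; coordinates beyond the sequence
    are an error.
    """
    from crucivir.orf_and_genes import GeneAnnotation

    keyword_map = keyword_map if keyword_map is not None else DEFAULT_PRODUCT_KEYWORDS
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        circular = rec.annotations.get("topology", "linear") == "circular"
        genome = CircularGenome(
            id=rec.id if rec.id != "<unknown id>" else rec.name,
            seq=str(rec.seq),
            source="finished_record",
            circular=circular,
        )
        n_cds = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            try:
                segments = _segments_from_location(feat.location, genome.length)
            except ValueError as exc:
                if "beyond sequence" in str(exc):
                    raise
                logger.warning("skipping unparseable CDS in %s: %s", genome.id, exc)
                continue
            n_cds += 1
            if _is_origin_join(segments, genome.length):
                # a join() that abuts the origin is a wrapping CDS, not a
                # splice: store it as one (start, end<start) segment
                (s1, e1, st), (s2, e2, _) = segments
                segments = [(s1, e2, st) if st == "+" else (s2, e1, st)]
            table = int(feat.qualifiers.get("transl_table", ["1"])[0])
            product = feat.qualifiers.get("product", [""])[0]
            ann = GeneAnnotation(
                id=feat.qualifiers.get("locus_tag", [f"{genome.id}_cds{n_cds}"])[0],
                genome_id=genome.id,
                segments=segments,
                genetic_code="ciliate" if table == 6 else "standard",
                spliced=len(segments) > 1,
                product_class=_classify_product(product, keyword_map),
                product=product,
            )
            genome.features.append(ann)
        records.append(genome)
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    return SequenceCollection(records=records, format_origin="genbank")


def _segments_from_location(location, length: int) -> list[tuple[int, int, str]]:
    strand = "-" if location.strand == -1 else "+"
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    segments = []
    for part in parts:
        start, end = int(part.start), int(part.end)
        if end > length or start > length:
            raise ValueError(f"CDS coordinates beyond sequence length {length}: {location}")
        segments.append((start, end, strand))
    # Biopython lists complement(join()) parts in transcription order; keep
    # segments in 5'->3' order of the coding sequence.
    return segments


def _is_origin_join(segments: list[tuple[int, int, str]], length: int) -> bool:
    """A two-part join that abuts the origin encodes a wrapping CDS, not a splice."""
    if len(segments) != 2:
        return False
    (s1, e1, st), (s2, e2, _) = segments
    if st == "+":
        return e1 == length and s2 == 0
    return s1 == 0 and e2 == length


def write_genbank(collection: Iterable[CircularGenome], path) -> None:
    """Serialize genomes with their gene and stem-loop annotations."""
    from crucivir.orf_and_genes import GeneAnnotation
    from crucivir.stemloop_finder import StemLoopAnnotation

    recs = []
    for g in collection:
        rec = SeqRecord(Seq(g.seq), id=g.id, name=g.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        for feat in g.features:
            if isinstance(feat, GeneAnnotation):
                loc = _location_from_segments(feat.segments, g.length)
                quals = {
                    "locus_tag": [feat.id],
                    "product": [feat.product or feat.product_class],
                    "transl_table": ["6" if feat.genetic_code == "ciliate" else "1"],
                }
                rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
            elif isinstance(feat, StemLoopAnnotation):
                hp = feat.hairpin
                loc = _location_from_segments([(hp.start, hp.end, feat.motif.strand)], g.length)
                quals = {
                    "note": [f"nonanucleotide {feat.motif.matched_seq}; score {feat.score}"],
                }
                rec.features.append(SeqFeature(loc, type="stem_loop", qualifiers=quals))
        recs.append(rec)
    SeqIO.write(recs, str(path), "genbank")


def _location_from_segments(segments: list[tuple[int, int, str]], length: int):
    locs = []
    for start, end, strand in segments:
        s = -1 if strand == "-" else 1
        if end > start:
            locs.append(SimpleLocation(start, end, strand=s))
        else:  # wrap-around: serialize as join() across the origin
            if s == 1:
                locs.extend([SimpleLocation(start, length, strand=1), SimpleLocation(0, end, strand=1)])
            else:
                locs.extend([SimpleLocation(0, end, strand=-1), SimpleLocation(start, length, strand=-1)])
    if len(locs) == 1:
        return locs[0]
    return CompoundLocation(locs)


# ---------------------------------------------------------------------------
# GFF3 export
# ---------------------------------------------------------------------------

def to_gff3(collection: Iterable[CircularGenome], path) -> None:
    """Write all annotations as GFF3 (1-based inclusive coordinates)."""
    from crucivir.orf_and_genes import GeneAnnotation
    from crucivir.stemloop_finder import StemLoopAnnotation

    lines = ["##gff-version 3"]
    for g in collection:
        lines.append(f"##sequence-region {g.id} 1 {g.length}")
        for feat in g.features:
            if isinstance(feat, GeneAnnotation):
                for start, end, strand in feat.segments:
                    end1 = end if end > start else g.length  # wrap: report 5' part
                    attrs = f"ID={feat.id};product_class={feat.product_class}"
                    if feat.spliced:
                        attrs += ";spliced=true"
                    lines.append(
                        "\t".join(
                            [g.id, "crucivir", "CDS", str(start + 1), str(end1), ".", strand, "0", attrs]
                        )
                    )
            elif isinstance(feat, StemLoopAnnotation):
                hp = feat.hairpin
                end1 = hp.end if hp.end > hp.start else g.length
                attrs = (
                    f"ID={g.id}_stemloop_{hp.start};nonanucleotide={feat.motif.matched_seq};"
                    f"accepted={str(feat.accepted).lower()}"
                )
                lines.append(
                    "\t".join(
                        [g.id, "crucivir", "stem_loop", str(hp.start + 1), str(end1),
                         str(feat.score), feat.motif.strand, ".", attrs]
                    )
                )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
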
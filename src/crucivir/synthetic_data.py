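"""Crucivirus-like synthetic genomes with fully known ground truth.

Every genome is built from an explicit :class:`SyntheticSpec`: a circular
background sequence at a target GC content carrying (i) a planted hairpin
with a conserved nonanucleotide at its loop apex, (ii) a capsid-like CDS
derived from a fixed ancestral capsid (R/Gly-tract/S/P architecture), and
(iii) optionally a Rep-like CDS derived from a fixed ancestral Rep with
the requested motif-II triad, Walker/SF3 motifs, and an optional
GT..AG intron carrying an in-frame stop.  The accompanying
:class:`TruthRecord` pins down every planted element so detector recall,
strand accuracy and classification accuracy can be scored exactly.

Two guarantees shape the construction:

- protein background is random *except* at motif positions, and any
  spurious occurrence of a default motif pattern outside its planted span
  is resampled away, so motif detectors are tested against noise but the
  truth is unambiguous;
- coding regions are encoded with GC-weighted codon choice and the
  non-coding background GC is adjusted so the *genome-level* GC matches
  the requested target.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from crucivir.genome_io import CircularGenome, SequenceCollection
from crucivir.protein_motifs import AMINO_ACIDS, load_motif_defs
from crucivir.stemloop_finder import DEFAULT_PATTERNS, iupac_regex, revcomp

_STD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in sorted(_STD_TABLE.forward_table):
    CODONS_BY_AA.setdefault(_STD_TABLE.forward_table[_codon], []).append(_codon)

#: concrete nonanucleotides used by the default dataset sampler, with
#: their reverse complements verified not to match the default patterns
NONANUCLEOTIDE_POOL = ("TAGTATTAC", "TAATATTAC", "CAGTATTAC", "TAGTGTTAC", "TATTACAAG")

#: motif-II triad instantiations per class
MOTIF2_INSTANCE = {"HUH": "HVH", "HUQ": "HLQ", "HYQ": "HYQ", "other_alt": "HNQ"}

# --- ancestral protein architecture (absolute residue offsets) -------------
CAPSID_R = (0, 34)
CAPSID_GLY = (20, 34)
CAPSID_S = (34, 184)
CAPSID_P = (184, 264)
CAPSID_CA_OFFSET = 74  # within the S-domain
CA_MOTIF_SEQ = "DIDGGD"

REP_LEN = 300
REP_MOTIFS = {
    "motif_I": (20, "FTLNN"),
    "motif_II": (60, "HVH"),
    "motif_III": (100, "YAGK"),
    "walker_A": (170, "GPSRTGKT"),
    "walker_B": (210, "LLDDF"),
    "motif_C": (240, "LNTSN"),
    "arg_finger": (252, "R"),
}
REP_INTRON_CODON = 130  # intron inserted between codons at this residue

#: per-residue substitution rates applied to the ancestral proteins; the
#: Rep diverges faster than the capsid, whose shell domain is under
#: structural constraint — the hallmark contrast of this viral group
CAPSID_MUTATION_RATE = 0.10
REP_MUTATION_RATE = 0.22


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome (see module docstring)."""

    length: int = 3000
    gc: float = 43.0
    nonanucleotide: str = "TAGTATTAC"
    stem_len: int = 11
    loop_len: int = 11
    ori_strand: str = "+"
    orientation: str = "unisense"  # unisense | ambisense
    motif2_class: str = "HUQ"  # HUH | HUQ | HYQ | other_alt | absent
    include_walker: bool = True
    include_intron: bool = False
    include_ca_motif: bool = False
    include_rep: bool = True
    use_ciliate_q: bool = False
    intron_length: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.nonanucleotide) != 9:
            raise ValueError("nonanucleotide must be 9 bases")
        if self.stem_len < 1 or self.loop_len < 3:
            raise ValueError("stem_len >= 1 and loop_len >= 3 required")
        if self.motif2_class not in (*MOTIF2_INSTANCE, "absent"):
            raise ValueError(f"unknown motif2_class {self.motif2_class!r}")


@dataclass
class TruthRecord:
    """Ground truth for every planted element of one genome."""

    genome_id: str
    ori_position: int  # forward coordinate of the motif's 5' base
    ori_start: int  # leftmost forward coordinate of the motif
    ori_strand: str
    stem_len: int
    loop_len: int
    nonanucleotide: str
    capsid_segments: list[tuple[int, int, str]]
    rep_segments: list[tuple[int, int, str]] = field(default_factory=list)
    orientation: str = "not_applicable"
    motif2_class: str = "absent"
    motif2_position: Optional[int] = None  # residue offset within the Rep
    intron: Optional[tuple[int, int]] = None  # forward-strand interval
    genetic_code: str = "standard"
    capsid_protein: str = ""
    rep_protein: str = ""


# ---------------------------------------------------------------------------
# Ancestral proteins and the reference library
# ---------------------------------------------------------------------------

_ANCESTOR_SEED = 797
_ancestors_cache: Optional[tuple[str, str]] = None


def _rand_aa(rng: np.random.Generator) -> str:
    return AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]


def _random_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [_rand_aa(rng) for _ in range(n)]


def _rep_scrub_patterns() -> list[str]:
    defs = load_motif_defs()
    return [defs[name].regex for name in
            ("motif_I", "motif_II", "motif_III", "walker_A", "walker_B", "motif_C")]


def _scrub(seq: list[str], rng: np.random.Generator, patterns: list[str], protected: set[int]) -> None:
    """Resample residues until no pattern matches outside protected spans.

    For each spurious match a free residue is replaced with a random
    amino acid, verified to actually break the match at that offset
    (wildcard positions cannot); matches that cannot be broken without
    touching protected residues are left alone.
    """
    compiled = [re.compile(p) for p in patterns]
    lookahead = [re.compile(f"(?=({p}))") for p in patterns]

    def try_break(rx: re.Pattern, start: int, end: int) -> bool:
        free = [i for i in range(start, end) if i not in protected and i != 0]
        rng.shuffle(free)
        for i in free:
            old = seq[i]
            candidates = [a for a in AMINO_ACIDS if a != old]
            rng.shuffle(candidates)
            for aa in candidates:
                seq[i] = aa
                if rx.match("".join(seq[start:end + 8])) is None:
                    return True
            seq[i] = old
        return False

    for _ in range(2000):
        s = "".join(seq)
        dirty = False
        for rx, la in zip(compiled, lookahead):
            for m in la.finditer(s):
                span = range(m.start(1), m.end(1))
                if all(i in protected for i in span):
                    continue
                if try_break(rx, m.start(1), m.end(1)):
                    dirty = True
                    break
            if dirty:
                break
        if not dirty:
            return
    raise RuntimeError("failed to scrub spurious motif matches")


def ancestral_proteins() -> tuple[str, str]:
    """The fixed (capsid, rep) ancestors all synthetic CDSs derive from."""
    global _ancestors_cache
    if _ancestors_cache is not None:
        return _ancestors_cache
    rng = np.random.default_rng(_ANCESTOR_SEED)
    # capsid: basic R-domain, Gly-rich tract, S core, P tail
    cap = _random_protein(rng, CAPSID_P[1])
    for i in range(*CAPSID_R):
        if rng.random() < 0.55:
            cap[i] = "KR"[int(rng.integers(2))]
    for i in range(*CAPSID_GLY):
        if rng.random() < 0.75:
            cap[i] = "G"
    cap[0] = "M"
    _scrub(cap, rng, [r"D.D..D"], set())
    # rep: random scaffold with all seven motifs planted
    rep = _random_protein(rng, REP_LEN)
    protected = {0}
    for off, motif in REP_MOTIFS.values():
        for k, aa in enumerate(motif):
            rep[off + k] = aa
        protected.update(range(off, off + len(motif)))
    rep[0] = "M"
    _scrub(rep, rng, _rep_scrub_patterns(), protected)
    _ancestors_cache = ("".join(cap), "".join(rep))
    return _ancestors_cache


def generate_reference_library(
    n_capsid: int = 4, n_rep: int = 4, seed: int = 2020
) -> dict[str, dict[str, str]]:
    """Deterministic capsid/Rep reference proteins (mutated ancestors)."""
    rng = np.random.default_rng(seed)
    cap_anc, rep_anc = ancestral_proteins()
    refs: dict[str, dict[str, str]] = {"capsid": {}, "rep": {}}
    for i in range(n_capsid):
        refs["capsid"][f"capsid_ref_{i}"] = "".join(
            _mutate(list(cap_anc), rng, _capsid_protected(False)))
    for i in range(n_rep):
        rep = _mutate(list(rep_anc), rng, _rep_protected(), rate=REP_MUTATION_RATE)
        _scrub(rep, rng, _rep_scrub_patterns(), _rep_protected())
        refs["rep"][f"rep_ref_{i}"] = "".join(rep)
    return refs


def _capsid_protected(include_ca: bool) -> set[int]:
    protected = {0}
    protected.update(range(*CAPSID_GLY))
    if include_ca:
        protected.update(range(CAPSID_CA_OFFSET, CAPSID_CA_OFFSET + len(CA_MOTIF_SEQ)))
    return protected


def _rep_protected() -> set[int]:
    protected = {0}
    for off, motif in REP_MOTIFS.values():
        protected.update(range(off, off + len(motif)))
    return protected


def _mutate(seq: list[str], rng: np.random.Generator, protected: set[int],
            rate: float = CAPSID_MUTATION_RATE) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if i not in protected and rng.random() < rate:
            out[i] = _rand_aa(rng)
    return out


# ---------------------------------------------------------------------------
# DNA-level construction
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    g = gc / 100.0
    return np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A C G T


def _encode(protein: str, rng: np.random.Generator, gc: float,
            taa_q_index: Optional[int] = None, stop_codon: str = "TAA") -> str:
    """Reverse-translate with GC-weighted codon choice; append a stop.

    ``taa_q_index`` encodes that glutamine as TAA (readable only under the
    ciliate code), used to emulate alternative-genetic-code genomes; such
    genomes terminate their CDSs with TGA, the only ciliate stop.
    """
    p = _base_probs(gc)
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    codons = []
    for i, aa in enumerate(protein):
        if taa_q_index is not None and i == taa_q_index:
            if aa != "Q":
                raise ValueError("taa_q_index must point at a glutamine")
            codons.append("TAA")
            continue
        options = CODONS_BY_AA[aa]
        weights = np.array([np.prod([p[order[b]] for b in c]) for c in options])
        codons.append(options[int(rng.choice(len(options), p=weights / weights.sum()))])
    return "".join(codons) + stop_codon


def _build_hairpin(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[str, int]:
    """Hairpin insert (stem + loop + revcomp stem) with the nonanucleotide
    at the loop apex; returns (sequence, motif offset within the insert)."""
    s, l = spec.stem_len, spec.loop_len
    total = 2 * s + l
    p = _base_probs(max(45.0, spec.gc))
    arr = [("ACGT")[int(rng.choice(4, p=p))] for _ in range(total)]
    m_off = s + (l - 9) // 2 if l >= 9 else s + l - 9
    if m_off < 0:
        raise ValueError("hairpin too small to hold the nonanucleotide")
    for k, b in enumerate(spec.nonanucleotide):
        arr[m_off + k] = b
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for i in range(s):  # right stem mirrors the (possibly motif-bearing) left stem
        arr[total - 1 - i] = comp[arr[i]]
    return "".join(arr), m_off


def _build_intron(spec: SyntheticSpec, rng: np.random.Generator) -> str:
    """GT..AG intron with an in-frame TAA stop, free of competing splice sites.

    Constructed with restricted alphabets: no G between the stop and the
    acceptor (so no competing AG) and no T adjacent to a G before the
    stop (so no competing GT), guaranteeing the planted intron is the
    unique minimal canonical excision that removes the stop.
    """
    ilen = spec.intron_length
    if ilen < 30:
        raise ValueError("intron_length must be >= 30")
    stop_at = 12

    def pick(alphabet: str) -> str:
        return alphabet[int(rng.integers(len(alphabet)))]

    arr = ["G", "T"]
    arr += [pick("ACG") for _ in range(2, stop_at - 1)]
    arr.append(pick("AC"))  # base right before the stop: no G before the T
    arr += ["T", "A", "A"]
    arr += [pick("ACT") for _ in range(stop_at + 3, ilen - 2)]
    arr += ["A", "G"]
    return "".join(arr)


def _place(seq: list[str], insert: str, pos: int) -> None:
    seq[pos:pos + len(insert)] = list(insert)


def _scrub_hairpin_neighborhood(
    seq: list[str],
    h0: int,
    hp_len: int,
    stem_len: int,
    motif_span: tuple[int, int],
    ori_strand: str,
    rng: np.random.Generator,
    reach: int = 29,
) -> None:
    """Make the planted nonanucleotide the unique pattern match near the
    hairpin.

    Degenerate patterns are loose enough that shifted or reverse-strand
    windows over the hairpin frequently also match; such hits fold onto
    the same physical hairpin and would compete with the planted
    annotation in the same-first-base exclusion.  Breakable offenders
    (those with a constrained pattern position falling on a free base)
    are resampled until gone, respecting stem complementarity.  A few
    mirror windows are intrinsically unbreakable — every constrained
    position sits inside the planted motif itself; those are left in
    place and lose to the planted annotation on the detector's
    apex-proximity tie-break, because their motif necessarily sits
    closer to a hairpin end than the apex-planted one.
    """
    from crucivir.stemloop_finder import IUPAC

    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    a0 = max(0, h0 - reach)
    a1 = min(len(seq), h0 + hp_len + reach)
    partner = {}
    for i in range(stem_len):
        partner[h0 + i] = h0 + hp_len - 1 - i
        partner[h0 + hp_len - 1 - i] = h0 + i
    fixed = set(range(*motif_span))
    fixed |= {partner[p] for p in range(*motif_span) if p in partner}
    compiled = [(pat, iupac_regex(pat)) for pat in DEFAULT_PATTERNS]

    def breakable_position(span: tuple[int, int], strand: str, pat: str):
        """A free forward position whose pattern character is constrained."""
        for p in range(*span):
            if p in fixed:
                continue
            idx = p - span[0] if strand == "+" else span[1] - 1 - p
            if len(IUPAC[pat[idx]]) < 4:
                return p, idx
        return None

    for _ in range(500):
        region = "".join(seq[a0:a1])
        rc_region = revcomp(region)
        targets = []
        for pat, rx in compiled:
            for m in rx.finditer(region):
                span = (a0 + m.start(), a0 + m.start() + 9)
                if ori_strand == "+" and span == motif_span:
                    continue
                got = breakable_position(span, "+", pat)
                if got:
                    targets.append((got[0], got[1], "+", pat))
            for m in rx.finditer(rc_region):
                span = (a1 - m.start() - 9, a1 - m.start())
                if ori_strand == "-" and span == motif_span:
                    continue
                got = breakable_position(span, "-", pat)
                if got:
                    targets.append((got[0], got[1], "-", pat))
        if not targets:
            return
        # picking the offender at random avoids deterministic cycles in
        # which two complementarity-coupled windows keep re-creating
        # each other
        p, idx, strand, pat = targets[int(rng.integers(len(targets)))]
        allowed = IUPAC[pat[idx]]
        if strand == "+":
            choices = [b for b in "ACGT" if b not in allowed]
        else:
            choices = [b for b in "ACGT" if comp[b] not in allowed]
        seq[p] = choices[int(rng.integers(len(choices)))]
        if p in partner:
            seq[partner[p]] = comp[seq[p]]
    # best effort: windows still standing at this point sit off-apex on
    # the hairpin and lose the detector's apex-proximity tie-break


def _span_on_forward(c_lo: int, c_hi: int, pos: int, cassette_len: int, strand: str) -> tuple[int, int]:
    """Map a cassette-local [c_lo, c_hi) span to forward coordinates."""
    if strand == "+":
        return pos + c_lo, pos + c_hi
    return pos + cassette_len - c_hi, pos + cassette_len - c_lo


def generate_genome(spec: SyntheticSpec, genome_id: str = "synthetic") -> tuple[CircularGenome, TruthRecord]:
    """Build one genome and its truth record; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    cap_anc, rep_anc = ancestral_proteins()

    # --- proteins ---------------------------------------------------------
    cap = _mutate(list(cap_anc), rng, _capsid_protected(spec.include_ca_motif))
    if spec.include_ca_motif:
        for k, aa in enumerate(CA_MOTIF_SEQ):
            cap[CAPSID_CA_OFFSET + k] = aa
        protected = _capsid_protected(True)
    else:
        protected = _capsid_protected(False)
    _scrub(cap, rng, [r"D.D..D"], protected)
    capsid_protein = "".join(cap)

    rep_protein = ""
    if spec.include_rep:
        rep = _mutate(list(rep_anc), rng, _rep_protected(), rate=REP_MUTATION_RATE)
        protected = {0}
        planted = dict(REP_MOTIFS)
        if spec.motif2_class == "absent":
            del planted["motif_II"]
            off = REP_MOTIFS["motif_II"][0]
            for k in range(3):
                rep[off + k] = _rand_aa(rng)
        else:
            planted["motif_II"] = (REP_MOTIFS["motif_II"][0], MOTIF2_INSTANCE[spec.motif2_class])
        if not spec.include_walker:
            for name in ("walker_A", "walker_B", "motif_C", "arg_finger"):
                off, motif = planted.pop(name)
                for k in range(len(motif)):
                    rep[off + k] = _rand_aa(rng)
        for off, motif in planted.values():
            for k, aa in enumerate(motif):
                rep[off + k] = aa
            protected.update(range(off, off + len(motif)))
        if "arg_finger" in planted:
            # the Arg-finger pattern is a bare R searched downstream of
            # motif C; clear competing arginines from that window so the
            # planted one is the first (and only) match
            from crucivir.protein_motifs import ARG_FINGER_WINDOW

            mc_end = planted["motif_C"][0] + len(planted["motif_C"][1])
            finger_at = planted["arg_finger"][0]
            for i in range(mc_end + ARG_FINGER_WINDOW[0],
                           min(len(rep), mc_end + ARG_FINGER_WINDOW[1])):
                if i != finger_at and rep[i] == "R":
                    rep[i] = _rand_aa(rng)
                    while rep[i] == "R":
                        rep[i] = _rand_aa(rng)
        _scrub(rep, rng, _rep_scrub_patterns(), protected)
        rep_protein = "".join(rep)

    # --- coding cassettes -------------------------------------------------
    ciliate_q: Optional[int] = None
    if spec.use_ciliate_q:
        # the TAA-encoded Q sits near the protein midpoint so that the
        # standard-code reading is genuinely truncated on both sides and
        # only the ciliate code renders a complete capsid
        mid = len(capsid_protein) // 2
        qs = [i for i in range(*CAPSID_S) if capsid_protein[i] == "Q"]
        if qs:
            ciliate_q = min(qs, key=lambda i: abs(i - mid))
        else:
            cap[mid] = "Q"
            capsid_protein = "".join(cap)
            ciliate_q = mid
    stop = "TGA" if spec.use_ciliate_q else "TAA"  # TGA is the only ciliate stop
    cap_cds = _encode(capsid_protein, rng, spec.gc, taa_q_index=ciliate_q, stop_codon=stop)
    cap_cassette = stop + cap_cds  # leading in-frame stop pins ORF maximality

    rep_cassette = ""
    intron_local: Optional[tuple[int, int]] = None
    if spec.include_rep:
        rep_cds = _encode(rep_protein, rng, spec.gc, stop_codon=stop)
        if spec.include_intron:
            at = 3 * REP_INTRON_CODON
            intron = _build_intron(spec, rng)
            rep_cds = rep_cds[:at] + intron + rep_cds[at:]
            intron_local = (3 + at, 3 + at + len(intron))  # cassette-local
        rep_cassette = stop + rep_cds

    hairpin, m_off = _build_hairpin(spec, rng)

    # --- layout -----------------------------------------------------------
    h0 = 60
    c0 = h0 + len(hairpin) + 60
    r0 = c0 + len(cap_cassette) + 60
    end = (r0 + len(rep_cassette) if spec.include_rep else c0 + len(cap_cassette)) + 60
    if end > spec.length:
        raise ValueError(f"planted elements ({end} nt) exceed genome length {spec.length}")

    # --- background with genome-level GC compensation ----------------------
    planted_seq = hairpin + cap_cassette + rep_cassette
    planted_gc = planted_seq.count("G") + planted_seq.count("C")
    n_bg = spec.length - len(planted_seq)
    target_gc_bases = spec.gc / 100.0 * spec.length
    p_bg = float(np.clip((target_gc_bases - planted_gc) / n_bg, 0.05, 0.95))
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - p_bg) / 2, p_bg / 2, p_bg / 2, (1 - p_bg) / 2])
    seq = list(bases[rng.choice(4, size=spec.length, p=probs)])

    # --- plant everything --------------------------------------------------
    hp_insert = hairpin if spec.ori_strand == "+" else revcomp(hairpin)
    _place(seq, hp_insert, h0)

    cap_strand = "+"
    _place(seq, cap_cassette, c0)
    cap_lo, cap_hi = _span_on_forward(3, len(cap_cassette), c0, len(cap_cassette), "+")
    capsid_segments = [(cap_lo, cap_hi, cap_strand)]

    rep_segments: list[tuple[int, int, str]] = []
    intron_fwd: Optional[tuple[int, int]] = None
    if spec.include_rep:
        rep_strand = "+" if spec.orientation == "unisense" else "-"
        insert = rep_cassette if rep_strand == "+" else revcomp(rep_cassette)
        _place(seq, insert, r0)
        Lc = len(rep_cassette)
        if intron_local is None:
            lo, hi = _span_on_forward(3, Lc, r0, Lc, rep_strand)
            rep_segments = [(lo, hi, rep_strand)]
        else:
            e1 = _span_on_forward(3, intron_local[0], r0, Lc, rep_strand)
            e2 = _span_on_forward(intron_local[1], Lc, r0, Lc, rep_strand)
            rep_segments = [(e1[0], e1[1], rep_strand), (e2[0], e2[1], rep_strand)]
            intron_fwd = _span_on_forward(intron_local[0], intron_local[1], r0, Lc, rep_strand)

    if spec.ori_strand == "+":
        ori_start = h0 + m_off
        ori_position = ori_start
    else:
        ori_start = h0 + len(hairpin) - 9 - m_off
        ori_position = ori_start + 8
    _scrub_hairpin_neighborhood(
        seq, h0, len(hairpin), spec.stem_len, (ori_start, ori_start + 9),
        spec.ori_strand, rng,
    )

    genome = CircularGenome(id=genome_id, seq="".join(seq), source="assembled_contig")
    truth = TruthRecord(
        genome_id=genome_id,
        ori_position=ori_position,
        ori_start=ori_start,
        ori_strand=spec.ori_strand,
        stem_len=spec.stem_len,
        loop_len=spec.loop_len,
        nonanucleotide=spec.nonanucleotide,
        capsid_segments=capsid_segments,
        rep_segments=rep_segments,
        orientation=(spec.orientation if spec.include_rep else "not_applicable"),
        motif2_class=spec.motif2_class if spec.include_rep else "absent",
        motif2_position=REP_MOTIFS["motif_II"][0] if spec.include_rep and spec.motif2_class != "absent" else None,
        intron=intron_fwd,
        genetic_code="ciliate" if spec.use_ciliate_q else "standard",
        capsid_protein=capsid_protein,
        rep_protein=rep_protein,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

def default_sampler(rng: np.random.Generator, index: int) -> SyntheticSpec:
    """Study-condition sampler: genome sizes 2474-7947, GC ~ 43 +/- 5,
    orientation 40/58 unisense/ambisense with ~2% Rep-less elements,
    motif-II class mix dominated by HUQ, occasional introns and
    alternative-code genomes."""
    include_rep = rng.random() < 0.978
    return SyntheticSpec(
        length=int(rng.integers(2474, 7948)),
        gc=float(np.clip(rng.normal(43.0, 4.9), 30.0, 60.0)),
        nonanucleotide=NONANUCLEOTIDE_POOL[int(rng.choice(5, p=[0.35, 0.2, 0.1, 0.15, 0.2]))],
        stem_len=int(rng.integers(5, 15)),
        loop_len=int(rng.integers(7, 16)),
        ori_strand="+" if rng.random() < 0.8 else "-",
        orientation="unisense" if rng.random() < 0.41 else "ambisense",
        motif2_class=["HUQ", "HYQ", "HUH", "other_alt", "absent"][
            int(rng.choice(5, p=[0.70, 0.12, 0.05, 0.08, 0.05]))],
        include_walker=rng.random() < 0.95,
        include_intron=rng.random() < 0.08,
        include_ca_motif=rng.random() < 0.15,
        include_rep=include_rep,
        use_ciliate_q=rng.random() < 0.01,
        seed=0,  # overwritten by generate_dataset
    )


def generate_dataset(
    n: int,
    spec_sampler: Optional[Callable[[np.random.Generator, int], SyntheticSpec]] = None,
    seed: int = 0,
) -> tuple[SequenceCollection, list[TruthRecord]]:
    """Generate ``n`` genomes with independent per-genome seeds derived
    from the master seed; fully reproducible."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = spec_sampler or default_sampler
    master = np.random.default_rng(seed)
    child_seeds = master.integers(0, 2**31 - 1, size=n)
    records, truths = [], []
    for i in range(n):
        spec = sampler(master, i)
        spec.seed = int(child_seeds[i])
        gid = f"synth_{i:04d}"
        genome, truth = generate_genome(spec, genome_id=gid)
        records.append(genome)
        truths.append(truth)
    return SequenceCollection(records=records, format_origin="fasta"), truths


def truth_table(truths: list[TruthRecord]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append({
            "genome_id": t.genome_id,
            "ori_position": t.ori_position,
            "ori_start": t.ori_start,
            "ori_strand": t.ori_strand,
            "stem_len": t.stem_len,
            "loop_len": t.loop_len,
            "nonanucleotide": t.nonanucleotide,
            "capsid_segments": ";".join(f"{s}-{e}{st}" for s, e, st in t.capsid_segments),
            "rep_segments": ";".join(f"{s}-{e}{st}" for s, e, st in t.rep_segments),
            "orientation": t.orientation,
            "motif2_class": t.motif2_class,
            "intron": f"{t.intron[0]}-{t.intron[1]}" if t.intron else "",
            "genetic_code": t.genetic_code,
        })
    return pd.DataFrame(rows)


def linearize_with_redundancy(genome: CircularGenome, start: int, k: int) -> str:
    """Rotation of the genome starting at ``start`` with its first ``k``
    bases re-appended — the inverse of terminal-redundancy trimming."""
    L = genome.length
    if not 0 <= start < L:
        raise ValueError("start out of range")
    if not 10 <= k < L / 2:
        raise ValueError("k must satisfy 10 <= k < length/2")
    rotated = genome.seq[start:] + genome.seq[:start]
    return rotated + rotated[:k]
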
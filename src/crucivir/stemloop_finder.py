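"""Detection and scoring of the rolling-circle replication origin stem-loop.

CRESS-DNA viruses initiate rolling-circle replication at a DNA hairpin
whose loop presents a conserved nonanucleotide (canonically TAGTATTAC in
circoviruses) that the Rep protein nicks.  The detector:

1. scans both strands of the circular genome for degenerate IUPAC
   nonanucleotide patterns (wrapping across the origin),
2. folds a window of ``flank`` bases either side of each motif hit with a
   pluggable secondary-structure backend (default: a deterministic
   exhaustive search for the maximum-pairing hairpin),
3. scores each hairpin by its deviation from the ideal geometry of an
   11-bp stem and an 11-base loop (one point per base of deviation),
4. accepts candidates with score <= 15 that satisfy geometry and
   positional exclusion rules.

All candidates — accepted or rejected — are reported with their rejection
reason, so detection behaviour is fully auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from crucivir.genome_io import CircularGenome

#: Conserved CRESS-DNA nonanucleotide patterns scanned by default.
DEFAULT_PATTERNS = ("NANTANTAN", "NAKWRTTAC", "TAWWDHWAN", "TRAKATTRC")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Watson-Crick pairs plus G·T wobble, as unordered base pairs.
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

_MIN_LOOP = 3  # minimum unpaired span enclosed by a pair


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate pattern into a lookahead regex
    (lookahead so that overlapping matches are all reported)."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in pattern {pattern!r}")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile(f"(?=({''.join(parts)}))")


def matches_iupac(seq: str, pattern: str) -> bool:
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for b, p in zip(seq.upper(), pattern.upper()))


@dataclass(frozen=True)
class MotifHit:
    """A nonanucleotide match on the circular genome.

    ``position`` is the forward-strand coordinate of the motif's 5' base:
    for a plus-strand hit this is the leftmost base of the match, for a
    minus-strand hit the rightmost.  ``start`` always gives the leftmost
    forward-strand coordinate of the matched region.
    """

    pattern: str
    position: int
    strand: str  # '+' or '-'
    matched_seq: str

    @property
    def start(self) -> int:
        return self.position if self.strand == "+" else self.position - len(self.matched_seq) + 1

    def shifted(self, delta: int, length: int) -> "MotifHit":
        return replace(self, position=(self.position + delta) % length)


@dataclass(frozen=True)
class Hairpin:
    """A hairpin extracted from a folded window.

    ``stem_len`` counts the contiguous stacked pairs of the helix closing
    the loop (an internal bulge terminates the counted stem); ``loop_len``
    is the span enclosed by the helix's innermost pair.  ``start``/``end``
    delimit the outermost pair's span on the forward strand, half-open,
    with ``end < start`` meaning wrap-around.
    """

    stem_len: int
    loop_len: int
    start: int
    end: int
    pairs: tuple[tuple[int, int], ...]  # stem pairs, window-local, 5'->3' on the hit strand
    backend: str = "max_pairing_hairpin"


@dataclass
class StemLoopAnnotation:
    """A candidate origin of replication: motif + hairpin + score."""

    motif: MotifHit
    hairpin: Optional[Hairpin]
    score: int
    accepted: bool = False
    rejection_reason: str = "none"

    def shifted(self, delta: int, length: int) -> "StemLoopAnnotation":
        hp = self.hairpin
        if hp is not None:
            hp = replace(hp, start=(hp.start + delta) % length, end=(hp.end + delta) % length)
        return StemLoopAnnotation(
            motif=self.motif.shifted(delta, length),
            hairpin=hp,
            score=self.score,
            accepted=self.accepted,
            rejection_reason=self.rejection_reason,
        )


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def scan_nonanucleotides(
    genome: CircularGenome, patterns=DEFAULT_PATTERNS
) -> list[MotifHit]:
    """All degenerate-pattern matches on both strands, wrapping the origin.

    Hits are returned in deterministic order (leftmost coordinate, strand,
    pattern); duplicate placements matched by several patterns are all
    reported.
    """
    L = genome.length
    hits = []
    for pattern in patterns:
        k = len(pattern)
        rx = iupac_regex(pattern)
        wrap = k - 1 if genome.circular else 0
        fwd = genome.seq + genome.seq[:wrap]
        for m in rx.finditer(fwd):
            p = m.start()
            if p >= L:
                continue
            hits.append(MotifHit(pattern=pattern, position=p, strand="+", matched_seq=m.group(1)))
        rc = revcomp(genome.seq)
        rc_ext = rc + rc[:wrap]
        for m in rx.finditer(rc_ext):
            p = m.start()
            if p >= L:
                continue
            # rc position p <-> forward coordinate of the motif's 5' base
            hits.append(
                MotifHit(pattern=pattern, position=(L - 1 - p) % L, strand="-", matched_seq=m.group(1))
            )
    hits.sort(key=lambda h: (h.start % L, h.strand, h.pattern))
    return hits


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------

def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def hairpin_scan(window: str) -> list[tuple[int, int, int, int]]:
    """All hairpin-shaped nested pairings of a window.

    A hairpin is an outer pair (a, b), a contiguous stem of ``stem``
    stacked pairs, and the enclosed loop of ``b - a + 1 - 2*stem``
    unpaired bases (>= 3).  Watson-Crick pairs plus G·T wobble.  Every
    (a, b, stem, loop) candidate is returned, including sub-maximal stem
    depths of each anchor, so that callers can pick the deepest stem
    compatible with geometry constraints.
    """
    n = len(window)
    out = []
    for a in range(n - 4):
        for b in range(a + 4, n):
            if not _can_pair(window[a], window[b]):
                continue
            s = 1
            while (b - s) - (a + s) - 1 >= _MIN_LOOP and _can_pair(window[a + s], window[b - s]):
                s += 1
            for k in range(1, s + 1):
                out.append((a, b, k, b - a + 1 - 2 * k))
    return out


def nussinov_pairs(window: str) -> list[tuple[int, int]]:
    """Maximum-pairing nested folding (Nussinov-style dynamic program).

    Watson-Crick pairs plus G·T wobble; minimum loop 3.  The traceback is
    deterministic and prefers stacking the outermost pair, which keeps
    helices contiguous.
    """
    n = len(window)
    if n == 0:
        return []
    N = np.zeros((n, n), dtype=np.int32)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                if _can_pair(window[k], window[j]):
                    cand = (N[i][k - 1] if k > i else 0) + 1 + N[k + 1][j - 1]
                    if cand > best:
                        best = cand
            N[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= _MIN_LOOP:
            continue
        if _can_pair(window[i], window[j]) and N[i + 1][j - 1] + 1 == N[i][j]:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
        elif N[i][j] == N[i][j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j - _MIN_LOOP):
                if _can_pair(window[k], window[j]):
                    if N[i][k - 1] + 1 + N[k + 1][j - 1] == N[i][j]:
                        pairs.append((k, j))
                        stack.append((i, k - 1))
                        stack.append((k + 1, j - 1))
                        break
    pairs.sort()
    return pairs


def nussinov_candidates(window: str) -> list[tuple[int, int, int, int]]:
    """Hairpin candidates read off a maximum-pairing Nussinov structure:
    each helix (maximal stacked run) contributes its stacking depths,
    with the loop measured as the span enclosed by the innermost pair."""
    pairs = nussinov_pairs(window)
    pair_set = set(pairs)
    out = []
    for (a, b) in pairs:
        if (a - 1, b + 1) in pair_set:
            continue  # not the outermost pair of its helix
        stem = 1
        while (a + stem, b - stem) in pair_set:
            stem += 1
        for k in range(1, stem + 1):
            out.append((a, b, k, b - a + 1 - 2 * k))
    return out


#: Registry of folding backends: name -> callable(window) -> candidate
#: hairpins as (outer_i, outer_j, stem_len, loop_len) tuples.
FOLDING_BACKENDS: dict[str, Callable[[str], list[tuple[int, int, int, int]]]] = {
    "max_pairing_hairpin": hairpin_scan,
    "nussinov_dna": nussinov_candidates,
}


def _select_candidate(
    candidates: list[tuple[int, int, int, int]],
    window_len: int,
    motif_span: tuple[int, int],
    min_stem: Optional[int] = None,
    min_loop: Optional[int] = None,
    proximity: Optional[int] = None,
) -> Optional[tuple[int, int, int, int]]:
    """Best hairpin candidate for a motif hit.

    Loops overlapping the motif are always preferred (the annotation is
    motif-anchored).  Without geometry constraints the maximum-pairing
    hairpin wins (longest stem, then the most centered loop).  With
    ``min_stem``/``min_loop`` given, candidates meeting them are
    preferred and ranked by closeness to the ideal 11-bp stem / 11-base
    loop geometry — the detector annotates the most ori-like hairpin
    presenting the motif — before stem length and centering; candidates
    that additionally keep the motif at least ``proximity`` bases inside
    both hairpin ends are preferred over those that would fail the
    edge-proximity exclusion.  If nothing meets the constraints the best
    overall is returned so the caller can report a rejection."""
    if not candidates:
        return None

    def motif_inside(c) -> bool:
        a, b, _, _ = c
        return a + proximity <= motif_span[0] and motif_span[1] - 1 + proximity <= b

    pool = [c for c in candidates
            if (min_stem is None or c[2] >= min_stem) and (min_loop is None or c[3] >= min_loop)]
    constrained = bool(pool)
    if pool and proximity is not None:
        inside = [c for c in pool if motif_inside(c)]
        pool = inside or pool
    use = pool or candidates

    def key(c):
        a, b, stem, loop = c
        loop_lo, loop_hi = a + stem, b - stem + 1  # half-open loop span
        overlaps = loop_lo < motif_span[1] and motif_span[0] < loop_hi
        center_dist = abs((loop_lo + loop_hi - 1) / 2 - (window_len - 1) / 2)
        if constrained:
            ideal_dev = abs(stem - 11) + abs(loop - 11)
            return (not overlaps, ideal_dev, -stem, center_dist, a, b)
        return (not overlaps, -stem, center_dist, a, b)

    return min(use, key=key)


def fold_window(
    genome: CircularGenome,
    hit: MotifHit,
    flank: int = 20,
    backend: str = "max_pairing_hairpin",
    min_stem: Optional[int] = None,
    min_loop: Optional[int] = None,
    proximity: Optional[int] = None,
) -> Optional[Hairpin]:
    """Fold motif +/- ``flank`` bases on the hit's strand; return the hairpin.

    The window is always folded on the forward strand: a cruciform
    extruded from double-stranded DNA presents the same hairpin on both
    strands, and strand-canonical folding guarantees that plus- and
    minus-strand motif hits over one physical hairpin are measured with
    identical geometry (per-strand folding would differ through the
    non-palindromic G·T wobble).  Returns None when the window folds
    into no pair at all; raises when the window would run past the end
    of a linear record.  Optional ``min_stem``/``min_loop`` steer the
    choice toward geometry-compliant hairpins (used by
    :func:`find_stemloops`); without them the single best hairpin is
    returned.
    """
    if not 15 <= flank <= 20:
        raise ValueError("flank must be in [15, 20]")
    fold = FOLDING_BACKENDS[backend]
    L = genome.length
    k = len(hit.matched_seq)
    left = hit.start % L
    if not genome.circular and (left - flank < 0 or left + k + flank > L):
        raise ValueError(f"window around position {hit.position} exceeds linear record {genome.id!r}")
    window = genome.fragment((left - flank) % L, (left + k + flank) % L)
    got = _select_candidate(fold(window), len(window), (flank, flank + k),
                            min_stem, min_loop, proximity)
    if got is None:
        return None
    wi, wj, stem, loop_len = got
    start = (left - flank + wi) % L
    end = (left - flank + wj + 1) % L
    stem_pairs = tuple((wi + t, wj - t) for t in range(stem))
    return Hairpin(
        stem_len=stem, loop_len=loop_len, start=start, end=end,
        pairs=stem_pairs, backend=backend,
    )


# ---------------------------------------------------------------------------
# Scoring and filtering
# ---------------------------------------------------------------------------

def score_stemloop(stem_len: int, loop_len: int) -> int:
    """One point per base of deviation from the ideal 11-bp stem / 11-base loop."""
    if stem_len < 0 or loop_len < 0:
        raise ValueError("stem and loop lengths must be non-negative")
    return abs(stem_len - 11) + abs(loop_len - 11)


@dataclass
class StemLoopConfig:
    patterns: tuple = DEFAULT_PATTERNS
    flank: int = 20
    max_score: int = 15
    min_stem: int = 5  # "stem longer than 4 bp"
    min_loop: int = 7  # "loop including seven or more bases"
    proximity: int = 4
    backend: str = "max_pairing_hairpin"


def find_stemloops(
    genome: CircularGenome, config: StemLoopConfig | None = None
) -> list[StemLoopAnnotation]:
    """Run the full ori-detection cascade on one genome.

    For every motif hit the window is folded and scored; candidates pass
    when the hairpin geometry meets the minimum stem/loop sizes and the
    score is at or below ``max_score``.  Two exclusion rules then apply:
    among candidates whose hairpins share the same first base only the
    lowest-scoring one is kept, and candidates whose nonanucleotide lies
    within ``proximity`` bases of the hairpin's first or last nucleotide
    are rejected.  All candidates are returned with their status.
    """
    config = config or StemLoopConfig()
    annotations = []
    for hit in scan_nonanucleotides(genome, config.patterns):
        hp = fold_window(genome, hit, flank=config.flank, backend=config.backend,
                         min_stem=config.min_stem, min_loop=config.min_loop,
                         proximity=config.proximity)
        if hp is None:
            annotations.append(
                StemLoopAnnotation(motif=hit, hairpin=None, score=10**6,
                                   accepted=False, rejection_reason="geometry")
            )
            continue
        score = score_stemloop(hp.stem_len, hp.loop_len)
        ann = StemLoopAnnotation(motif=hit, hairpin=hp, score=score)
        if hp.stem_len < config.min_stem or hp.loop_len < config.min_loop:
            ann.rejection_reason = "geometry"
        elif score > config.max_score:
            ann.rejection_reason = "score_gt_threshold"
        else:
            ann.accepted = True
        annotations.append(ann)

    # exclusion (i): nonanucleotide within `proximity` bases of either
    # hairpin end (measured along the hit strand; both ends checked).
    # Applied before de-duplication so that an edge-hugging candidate
    # cannot evict a centered one from the same hairpin.
    for ann in annotations:
        if not ann.accepted:
            continue
        d5, d3 = _motif_edge_distances(ann, genome.length)
        if d5 < config.proximity or d3 < config.proximity:
            ann.accepted = False
            ann.rejection_reason = "motif_too_close_to_stem_end"

    # exclusion (ii): same hairpin first base -> keep the lowest score.
    # Ties go to the loop closest to ideal, then to the motif farthest
    # from the hairpin ends (the nonanucleotide sits at the loop apex,
    # which disambiguates mirror-strand matches over the same physical
    # hairpin), then to the motif matching more of the conserved
    # patterns (the more canonical nonanucleotide), then to the
    # downstream motif, then to the plus strand.
    def canonicalness(ann: StemLoopAnnotation) -> int:
        return sum(1 for p in config.patterns if matches_iupac(ann.motif.matched_seq, p))

    by_first_base: dict[int, list[StemLoopAnnotation]] = {}
    for ann in annotations:
        if ann.accepted:
            by_first_base.setdefault(ann.hairpin.start, []).append(ann)
    for group in by_first_base.values():
        if len(group) > 1:
            group.sort(
                key=lambda a: (a.score, abs(a.hairpin.loop_len - 11),
                               -min(_motif_edge_distances(a, genome.length)),
                               -canonicalness(a),
                               -(a.motif.start % genome.length),
                               a.motif.strand != "+")
            )
            for ann in group[1:]:
                ann.accepted = False
                ann.rejection_reason = "duplicate_first_base"

    annotations.sort(key=lambda a: (a.motif.start % genome.length, a.motif.strand))
    return annotations


def _motif_edge_distances(ann: StemLoopAnnotation, L: int) -> tuple[int, int]:
    """Distances from the motif's ends to the hairpin's first/last base,
    measured 5'->3' on the hit strand (negative if the motif pokes out)."""
    hp = ann.hairpin
    m = ann.motif
    k = len(m.matched_seq)
    hp_len = (hp.end - hp.start) % L or L
    m_lo = (m.start - hp.start) % L  # forward offset of motif within hairpin
    m_hi = m_lo + k - 1
    if m_lo > hp_len:  # motif entirely outside
        return -1, -1
    if m.strand == "+":
        return m_lo, (hp_len - 1) - m_hi
    return (hp_len - 1) - m_hi, m_lo


def nonanucleotide_frequencies(annotations: list[StemLoopAnnotation]) -> pd.DataFrame:
    """Per-position base frequencies over accepted annotations' motifs.

    Returns a 9x4 DataFrame (rows = motif positions 1..9, columns A,C,G,T);
    each row sums to 1.
    """
    seqs = [a.motif.matched_seq for a in annotations if a.accepted]
    if not seqs:
        raise ValueError("no accepted stem-loop annotations")
    k = len(seqs[0])
    counts = np.zeros((k, 4))
    order = {"A": 0, "C": 1, "G": 2, "T": 3}
    for s in seqs:
        for i, b in enumerate(s):
            counts[i, order[b]] += 1
    freq = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(freq, index=range(1, k + 1), columns=["A", "C", "G", "T"])
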
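"""Conserved-motif profiling of Rep and domain partitioning of the capsid.

The Rep of CRESS-DNA viruses carries an N-terminal HUH endonuclease domain
(motifs I, II, III) and a C-terminal superfamily-3 helicase domain
(Walker A, Walker B, motif C, Arg finger).  Motif II is the metal-binding
His-hydrophobic-His ("HUH") triad; cruciviruses frequently replace the
second His with Gln (HUQ) or additionally replace the hydrophobic residue
(e.g. HYQ).  A genome whose Rep lacks all seven motifs — or that has no
Rep CDS at all — is called a crucivirus-like circular genetic element
(CruCGE) rather than a crucivirus (CruV).

Motif patterns are data, not code: they ship as a TSV of regexes with an
expected region per motif and can be replaced wholesale.

The capsid protein is partitioned into the tombusvirus-like R (RNA
binding), S (shell, single jelly-roll) and P (protruding) domains by
locating the S-domain with a gapless position-specific scoring profile
built from reference capsids; R is the prefix, P the suffix.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

HYDROPHOBIC = set("AVLIMFWC")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

ENDONUCLEASE_MOTIFS = ("motif_I", "motif_II", "motif_III")
HELICASE_MOTIFS = ("walker_A", "walker_B", "motif_C", "arg_finger")
ALL_MOTIFS = ENDONUCLEASE_MOTIFS + HELICASE_MOTIFS

#: residues downstream of motif C searched for the Arg finger
ARG_FINGER_WINDOW = (3, 40)


@dataclass(frozen=True)
class MotifDef:
    name: str
    regex: str
    region: str  # nterm | cterm | after_motif_C


def load_motif_defs(path=None) -> dict[str, MotifDef]:
    """Load motif definitions from a TSV (default: the bundled pattern file)."""
    if path is None:
        src = resources.files("crucivir").joinpath("data/motif_patterns.tsv")
        text = src.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    defs = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, regex, region = line.split("\t")[:3]
        defs[name] = MotifDef(name=name, regex=regex, region=region)
    return defs


@dataclass(frozen=True)
class MotifRecord:
    present: bool
    position: Optional[int] = None
    matched: Optional[str] = None


@dataclass
class RepMotifProfile:
    motifs: dict[str, MotifRecord] = field(default_factory=dict)
    motif2_trigram: Optional[str] = None
    motif2_class: str = "absent"
    grs_present: bool = False

    @property
    def n_present(self) -> int:
        return sum(1 for name in ALL_MOTIFS if self.motifs.get(name, MotifRecord(False)).present)

    @property
    def helicase_motifs_all_absent(self) -> bool:
        return not any(
            self.motifs.get(name, MotifRecord(False)).present for name in HELICASE_MOTIFS
        )


def find_rep_motifs(
    rep: str, motif_defs: Optional[dict[str, MotifDef]] = None, include_grs: bool = False
) -> RepMotifProfile:
    """Locate the seven conserved Rep motifs within their expected regions.

    Endonuclease motifs are searched in the N-terminal half, helicase
    motifs C-terminal of motif III (falling back to the C-terminal half),
    and the Arg finger in a fixed window downstream of motif C.  The first
    match within a region wins; absence is data, not an error.
    """
    if len(rep) < 50:
        raise ValueError("Rep protein shorter than 50 residues")
    defs = motif_defs or load_motif_defs()
    profile = RepMotifProfile()
    half = len(rep) // 2

    def search(name: str, lo: int, hi: int) -> MotifRecord:
        d = defs[name]
        m = re.search(d.regex, rep[lo:hi])
        if m is None:
            return MotifRecord(False)
        return MotifRecord(True, position=lo + m.start(), matched=m.group(0))

    for name in ENDONUCLEASE_MOTIFS:
        profile.motifs[name] = search(name, 0, half)

    m3 = profile.motifs["motif_III"]
    helicase_lo = (m3.position + len(m3.matched)) if m3.present else half
    for name in ("walker_A", "walker_B", "motif_C"):
        profile.motifs[name] = search(name, helicase_lo, len(rep))

    mc = profile.motifs["motif_C"]
    if mc.present:
        lo = mc.position + len(mc.matched) + ARG_FINGER_WINDOW[0]
        hi = min(len(rep), mc.position + len(mc.matched) + ARG_FINGER_WINDOW[1])
        profile.motifs["arg_finger"] = search("arg_finger", lo, hi)
    else:
        profile.motifs["arg_finger"] = MotifRecord(False)

    m2 = profile.motifs["motif_II"]
    if m2.present:
        profile.motif2_trigram = m2.matched
        profile.motif2_class = classify_motif2(m2.matched)
    if include_grs and "grs" in defs:
        profile.grs_present = search("grs", 0, half).present
    return profile


def classify_motif2(trigram: Optional[str], hydrophobic: set[str] = HYDROPHOBIC) -> str:
    """Classify a motif-II triad: HUH, HUQ, HYQ, other_alt, or absent.

    U denotes any hydrophobic residue ({A,V,L,I,M,F,W,C} by default); HYQ
    is the specific His-Tyr-Gln arrangement.
    """
    if not trigram or len(trigram) != 3 or trigram[0] != "H":
        return "absent"
    mid, last = trigram[1], trigram[2]
    if last == "H" and mid in hydrophobic:
        return "HUH"
    if last == "Q":
        if mid == "Y":
            return "HYQ"
        if mid in hydrophobic:
            return "HUQ"
    return "other_alt"


def call_cruv_or_crucge(profile: Optional[RepMotifProfile], has_rep_cds: bool) -> str:
    """CruCGE iff there is no Rep CDS, or the Rep shows none of the seven
    conserved motifs; CruV otherwise."""
    if not has_rep_cds or profile is None:
        return "CruCGE"
    return "CruV" if profile.n_present > 0 else "CruCGE"


# ---------------------------------------------------------------------------
# Capsid domain partition
# ---------------------------------------------------------------------------

@dataclass
class SDomainProfile:
    """Gapless position-specific log-odds profile of the S-domain."""

    matrix: np.ndarray  # (width, 20) log-odds vs uniform background
    width: int

    def score_window(self, window: str) -> float:
        total = 0.0
        for i, aa in enumerate(window):
            j = _AA_INDEX.get(aa)
            if j is not None:
                total += self.matrix[i, j]
        return total


def build_s_profile(s_domains: Sequence[str], pseudocount: float = 1.0) -> SDomainProfile:
    """Build a log-odds profile from equal-length reference S-domains."""
    widths = {len(s) for s in s_domains}
    if len(widths) != 1:
        raise ValueError("reference S-domains must have equal length (gapless profile)")
    width = widths.pop()
    counts = np.full((width, 20), pseudocount)
    for s in s_domains:
        for i, aa in enumerate(s):
            j = _AA_INDEX.get(aa)
            if j is not None:
                counts[i, j] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return SDomainProfile(matrix=np.log2(freqs / 0.05), width=width)


@dataclass
class CapsidDomains:
    r_domain: tuple[int, int]
    s_domain: tuple[int, int]
    p_domain: tuple[int, int]
    gly_tract: Optional[tuple[int, int]]
    ca_motif_positions: list[int]
    basic_fraction_r: float
    s_score: float = 0.0
    warning: Optional[str] = None


def partition_capsid(
    capsid: str, s_profile: SDomainProfile, score_floor: float = 0.0
) -> CapsidDomains:
    """Partition a capsid protein into contiguous R, S and P domains.

    The S-domain is the best-scoring gapless window against the profile;
    R is everything N-terminal of it (possibly empty for truncated
    capsids), P everything C-terminal.  Within R the Gly-rich tract is the
    longest window of >= 8 residues that is >= 50% glycine.
    """
    if len(capsid) < 60:
        raise ValueError("capsid protein shorter than 60 residues")
    w = s_profile.width
    best_pos, best_score = 0, -math.inf
    for pos in range(0, max(1, len(capsid) - w + 1)):
        sc = s_profile.score_window(capsid[pos:pos + w])
        if sc > best_score:
            best_pos, best_score = pos, sc
    warning = None
    if best_score < score_floor or len(capsid) < w:
        s_lo = s_hi = 0
        warning = "no S-domain window above score floor"
    else:
        s_lo, s_hi = best_pos, min(len(capsid), best_pos + w)
    r = capsid[:s_lo]
    basic = sum(1 for aa in r if aa in "KRH") / len(r) if r else 0.0
    return CapsidDomains(
        r_domain=(0, s_lo),
        s_domain=(s_lo, s_hi),
        p_domain=(s_hi, len(capsid)),
        gly_tract=_gly_tract(r),
        ca_motif_positions=[s_lo + p for p in find_ca_motif(capsid[s_lo:s_hi])],
        basic_fraction_r=basic,
        s_score=best_score,
        warning=warning,
    )


def _gly_tract(r_domain: str, min_len: int = 8, min_frac: float = 0.5) -> Optional[tuple[int, int]]:
    best = None
    n = len(r_domain)
    for i in range(n):
        g = 0
        for j in range(i + 1, n + 1):
            if r_domain[j - 1] == "G":
                g += 1
            length = j - i
            if length >= min_len and g / length >= min_frac:
                if best is None or length > best[1] - best[0]:
                    best = (i, j)
    return best


def find_ca_motif(segment: str) -> list[int]:
    """All (overlapping) start positions of the Ca-binding motif DxDxxD."""
    return [m.start() for m in re.finditer(r"(?=(D.D..D))", segment)]


# ---------------------------------------------------------------------------
# Isoelectric point profile
# ---------------------------------------------------------------------------

#: EMBOSS pKa values.
PKA_POSITIVE = {"nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


def net_charge(peptide: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge of a peptide (termini included)."""
    charge = 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in peptide:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if net_charge(peptide, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def isoelectric_profile(protein: str, window: int = 21) -> np.ndarray:
    """Sliding-window pI along the protein (truncated windows at the edges)."""
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    half = window // 2
    out = np.empty(len(protein))
    for i in range(len(protein)):
        lo, hi = max(0, i - half), min(len(protein), i + half + 1)
        out[i] = isoelectric_point(protein[lo:hi])
    return out
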
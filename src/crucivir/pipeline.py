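"""End-to-end discovery pipeline and summary statistics.

Stage order mirrors the discovery workflow: circularize contigs (terminal
redundancy) -> capsid screen (bit score >= 50) -> gene annotation under
the standard code, with splice-site and ciliate-code rescue for genomes
whose capsid or Rep cannot be read in one frame -> stem-loop/ori
annotation -> Rep and capsid motif profiling -> CruV/CruCGE call ->
sequential naming beginning with the smallest genome -> summary.  Every
stage logs its in/out counts to the logger; the run is fully
deterministic for a given configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from crucivir.diversity import matrix_stats, pairwise_identity_matrix
from crucivir.genome_io import CircularGenome, SequenceCollection, detect_terminal_redundancy, gc_content
from crucivir.orf_and_genes import (
    GeneAnnotation,
    classify_orfs,
    classify_orientation,
    detect_splice_candidates,
    find_orfs,
    mark_putative_orfs,
    screen_capsid_candidates,
    sixframe_segments,
    smith_waterman,
)
from crucivir.protein_motifs import RepMotifProfile, call_cruv_or_crucge, find_rep_motifs
from crucivir.stemloop_finder import StemLoopConfig, find_stemloops

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_overlap: int = 10
    bit_threshold: float = 50.0
    min_orf: int = 300
    complete_coverage: float = 0.8  # ref fraction covered for a "complete" CDS
    rescue_homology_bits: float = 25.0
    stemloop: StemLoopConfig = field(default_factory=StemLoopConfig)
    naming_start: int = 81
    compute_pi: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stemloop"]["patterns"] = list(d["stemloop"]["patterns"])
        return d


@dataclass
class SummaryReport:
    n_genomes: int = 0
    gc_mean: Optional[float] = None
    gc_sd: Optional[float] = None
    length_min: int = 0
    length_max: int = 0
    n_with_rep: int = 0
    n_crucge: int = 0
    orientation_fractions: dict = field(default_factory=dict)
    n_stemloop_annotated: int = 0
    nonanucleotide_pattern_counts: dict = field(default_factory=dict)
    nonanucleotide_counts: dict = field(default_factory=dict)
    motif2_counts: dict = field(default_factory=dict)
    pi_stats: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), sort_keys=True, **kwargs)


def _coverage(hit, refs: dict[str, dict[str, str]]) -> float:
    for lib in refs.values():
        if hit.reference_id in lib:
            return (hit.ref_span[1] - hit.ref_span[0]) / len(lib[hit.reference_id])
    return 0.0


def _ref_len(hit, refs: dict[str, dict[str, str]]) -> int:
    for lib in refs.values():
        if hit.reference_id in lib:
            return len(lib[hit.reference_id])
    return 1


def annotate_genome(genome: CircularGenome, refs: dict[str, dict[str, str]],
                    config: PipelineConfig) -> dict:
    """Annotate genes, stem-loops and motifs on one genome (in place).

    Returns a per-genome property dict (Table-of-properties row).
    """
    orfs = find_orfs(genome, min_len=config.min_orf, code="standard")
    classify_orfs(orfs, refs)

    def best_of(cls: str, pool: list[GeneAnnotation]) -> Optional[GeneAnnotation]:
        hits = [o for o in pool if o.product_class == cls]
        if not hits:
            return None
        return max(hits, key=lambda o: o.best_hit.raw_score if o.best_hit else 0.0)

    capsid = best_of("capsid", orfs)
    rep = best_of("rep", orfs)

    def complete(ann: Optional[GeneAnnotation]) -> bool:
        return ann is not None and ann.best_hit is not None and \
            _coverage(ann.best_hit, refs) >= config.complete_coverage

    # splice rescue for an absent or truncated Rep
    if not complete(rep):
        spl = _splice_rescue(genome, refs, config)
        if spl is not None and (rep is None or _coverage(spl.best_hit, refs) > _coverage(rep.best_hit, refs)):
            if rep in orfs:
                orfs.remove(rep)
            orfs.append(spl)
            rep = spl

    # ciliate-code rescue, only when the standard code failed to render a
    # complete capsid or Rep
    if not complete(capsid) or (not complete(rep)):
        orfs6 = find_orfs(genome, min_len=config.min_orf, code="ciliate")
        classify_orfs(orfs6, refs)
        for cls, current in (("capsid", capsid), ("rep", rep)):
            if complete(current):
                continue
            cand = best_of(cls, orfs6)
            # a complete ciliate-code ORF is reference-sized; one much
            # longer is a stop-codon read-through, not a rescue
            if cand is not None and cand.best_hit is not None and \
                    len(cand.protein) > 1.5 * _ref_len(cand.best_hit, refs):
                cand = None
            if cand is not None and _coverage(cand.best_hit, refs) >= config.complete_coverage:
                if current in orfs:
                    orfs.remove(current)
                orfs.append(cand)
                if cls == "capsid":
                    capsid = cand
                else:
                    rep = cand

    mark_putative_orfs(orfs, genome.length, min_len=config.min_orf)
    annotated = [o for o in orfs if o.product_class != "unknown"]
    genome.features.extend(annotated)

    stemloops = find_stemloops(genome, config.stemloop)
    accepted = [a for a in stemloops if a.accepted]
    genome.features.extend(accepted)
    best_sl = min(accepted, key=lambda a: (a.score, a.motif.start % genome.length), default=None)

    profile: Optional[RepMotifProfile] = None
    if rep is not None and len(rep.protein) >= 50:
        profile = find_rep_motifs(rep.protein)
    virus_class = call_cruv_or_crucge(profile, has_rep_cds=rep is not None)
    orientation = classify_orientation(capsid, rep)

    return {
        "input_id": genome.id,
        "length": genome.length,
        "gc": round(gc_content(genome), 4),
        "has_capsid": capsid is not None,
        "has_rep": rep is not None,
        "rep_spliced": bool(rep.spliced) if rep is not None else False,
        "genetic_code": (capsid.genetic_code if capsid is not None else "standard"),
        "orientation": orientation,
        "n_stemloops": len(accepted),
        "nonanucleotide": best_sl.motif.matched_seq if best_sl else "",
        "nonanucleotide_pattern": best_sl.motif.pattern if best_sl else "",
        "stemloop_score": best_sl.score if best_sl else None,
        "motif2_class": profile.motif2_class if profile is not None else "absent",
        "n_rep_motifs": profile.n_present if profile is not None else 0,
        "class": virus_class,
        "capsid_protein": capsid.protein if capsid is not None else "",
        "rep_protein": rep.protein if rep is not None else "",
        "n_putative_orfs": sum(1 for o in annotated if o.product_class == "putative_orf"),
    }


def _splice_rescue(genome: CircularGenome, refs: dict[str, dict[str, str]],
                   config: PipelineConfig) -> Optional[GeneAnnotation]:
    spl = _splice_rescue_linear(genome, refs, config)
    if spl is None and genome.circular:
        # the Rep region may straddle the origin of the resolved circle;
        # retry with the origin moved half a genome away and map back
        from crucivir.genome_io import rotate

        half = genome.length // 2
        rotated = rotate(
            CircularGenome(id=genome.id, seq=genome.seq, circular=True), half)
        spl = _splice_rescue_linear(rotated, refs, config)
        if spl is not None:
            spl = spl.shifted(half, genome.length)
    return spl


def _splice_rescue_linear(genome: CircularGenome, refs: dict[str, dict[str, str]],
                          config: PipelineConfig) -> Optional[GeneAnnotation]:
    regions_by_strand: dict[str, list[tuple[int, int, float]]] = {"+": [], "-": []}
    for strand, _f, nt_a, nt_b, prot in sixframe_segments(genome.seq):
        for ref_id, ref_seq in refs.get("rep", {}).items():
            hit = smith_waterman(prot, ref_seq, query_id=genome.id, ref_id=ref_id)
            if hit.bits < config.rescue_homology_bits:
                continue
            q0, q1 = hit.query_span
            if strand == "+":
                regions_by_strand["+"].append((nt_a + 3 * q0, nt_a + 3 * q1, hit.bits))
            else:
                regions_by_strand["-"].append((nt_b - 3 * q1, nt_b - 3 * q0, hit.bits))
    best_strand = max("+-", key=lambda s: sum(b for _, _, b in regions_by_strand[s]))
    scored = regions_by_strand[best_strand]
    if not scored:
        return None
    # weak stray hits far below the best would poison the anchor set
    top = max(b for _, _, b in scored)
    regions = [(a, b, best_strand) for a, b, bits in scored if bits >= 0.25 * top]
    spl = detect_splice_candidates(genome, regions)
    if spl is None:
        return None
    best = None
    for ref_id, ref_seq in refs.get("rep", {}).items():
        hit = smith_waterman(spl.protein, ref_seq, query_id=spl.id, ref_id=ref_id)
        if best is None or hit.raw_score > best.raw_score:
            best = hit
    spl.best_hit = best
    return spl


def run_discovery(
    contigs: SequenceCollection,
    refs: dict[str, dict[str, str]],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, SummaryReport, dict]:
    """Run the full discovery pipeline on assembled contigs.

    Returns (per-genome table, summary report, run manifest).  Input
    records flagged non-circular are first resolved through terminal
    redundancy; finished circular records pass straight through.
    """
    config = config or PipelineConfig()
    if not refs.get("capsid"):
        raise ValueError("reference library must contain at least one capsid protein")

    genomes: list[CircularGenome] = []
    for rec in contigs:
        if rec.circular:
            genomes.append(rec)
            continue
        _, genome = detect_terminal_redundancy(rec.seq, config.min_overlap, contig_id=rec.id)
        if genome is not None:
            genomes.append(genome)
    logger.info("circularize: %d contigs in, %d circular genomes out", len(contigs), len(genomes))

    retained_ids = {cid for cid, _ in
                    screen_capsid_candidates(genomes, refs["capsid"], config.bit_threshold)}
    genomes = [g for g in genomes if g.id in retained_ids]
    logger.info("capsid screen (bits >= %.0f): %d genomes retained", config.bit_threshold, len(genomes))

    rows = []
    for genome in genomes:
        rows.append(annotate_genome(genome, refs, config))

    # sequential naming beginning with the smallest genome
    order = sorted(range(len(genomes)), key=lambda i: (genomes[i].length, genomes[i].id))
    names = {}
    for rank, i in enumerate(order):
        prefix = "CruV" if rows[i]["class"] == "CruV" else "CruCGE"
        names[i] = f"{prefix}-{config.naming_start + rank}"
    for i, row in enumerate(rows):
        row["name"] = names[i]
        genomes[i].id = names[i]

    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("length", kind="mergesort").reset_index(drop=True)
        cols = ["name"] + [c for c in table.columns if c != "name"]
        table = table[cols]
    report = summarize(table, compute_pi=config.compute_pi)
    manifest = {
        "config": config.to_dict(),
        "n_input_contigs": len(contigs),
        "n_genomes": len(genomes),
        "names": [names[i] for i in order],
    }
    return table, report, manifest


def summarize(table: pd.DataFrame, compute_pi: bool = True) -> SummaryReport:
    """Summary statistics over a per-genome property table."""
    if len(table) == 0:
        return SummaryReport()
    n = len(table)
    orient = table["orientation"].value_counts().to_dict()
    fractions = {
        "unisense": orient.get("unisense", 0) / n,
        "ambisense": orient.get("ambisense", 0) / n,
        "not_applicable": orient.get("not_applicable", 0) / n,
    }
    with_sl = table[table["n_stemloops"] > 0]
    nona_counts = with_sl["nonanucleotide"].value_counts().to_dict()
    pattern_counts = with_sl["nonanucleotide_pattern"].value_counts().to_dict()
    motif2 = table.loc[table["motif2_class"] != "absent", "motif2_class"].value_counts().to_dict()

    pi_stats = {}
    if compute_pi:
        for cls, col in (("capsid", "capsid_protein"), ("rep", "rep_protein")):
            seqs = [(row["name"] if "name" in row else str(i), row[col])
                    for i, row in table.iterrows() if row[col]]
            if len(seqs) >= 2:
                mean, sd = matrix_stats(pairwise_identity_matrix(seqs))
                pi_stats[cls] = {"mean": round(mean, 4), "sd": round(sd, 4), "n": len(seqs)}

    return SummaryReport(
        n_genomes=n,
        gc_mean=round(float(table["gc"].mean()), 4),
        gc_sd=round(float(table["gc"].std(ddof=1)), 4) if n > 1 else 0.0,
        length_min=int(table["length"].min()),
        length_max=int(table["length"].max()),
        n_with_rep=int(table["has_rep"].sum()),
        n_crucge=int((table["class"] == "CruCGE").sum()),
        orientation_fractions={k: round(v, 4) for k, v in fractions.items()},
        n_stemloop_annotated=int((table["n_stemloops"] > 0).sum()),
        nonanucleotide_pattern_counts=pattern_counts,
        nonanucleotide_counts=nona_counts,
        motif2_counts=motif2,
        pi_stats=pi_stats,
    )
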
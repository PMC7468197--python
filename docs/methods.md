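# Methods

This note documents the models and procedures implemented in
`crucivir`, the parameters that matter, the numerical choices made
where the design was genuinely open, and what the synthetic-data
validation does and does not establish.

## Circular-genome resolution

Assemblers walking a circular template re-emit the first bases of a
contig at its end. `detect_terminal_redundancy` tests exact
suffix == prefix overlaps from ⌊n/2⌋ down to `min_overlap` (default 10
nt) and trims the longest hit. Only exact repeats are considered:
assemblers emit exact terminal duplications, and resolving mismatched
overlaps is a different (error-correction) problem. Contigs shorter
than twice the minimum overlap are declared unresolvable.

Coordinates are 0-based, half-open, anchored on the forward strand
throughout; a feature with `end < start` wraps the origin. Conversion
to 1-based inclusive coordinates happens only at GenBank/GFF3
serialization, where wrap-around features become `join()` locations
across the origin (and are merged back into a single wrap segment on
reading).

## Capsid screen and homology classification

All protein alignments use affine-gap BLOSUM62 alignments (local:
open 11, extend 1 in the "first gap character carries the opening
cost" convention; global: open 10, extend 1). Raw scores are converted
to bit scores and E-values with fixed Karlin–Altschul constants for
gapped BLOSUM62 (λ = 0.267, K = 0.041), so thresholds expressed in bits
or E-values are reproducible without an external search engine.

The capsid screen translates all six frames of a contig, splits at
stops, and aligns every stop-free segment (≥ 20 aa) against the capsid
reference library; the contig is retained at ≥ 50 bits. ORFs are
classified as capsid or Rep when their best hit reaches ≥ 25% identity
over ≥ 50% of the reference length; the identity threshold is the
annotation-transfer threshold re-expressed at protein level, where the
homology actually lives. Unclassified ORFs longer than 300 nt (stop
codon included) that do not overlap a capsid/Rep call are "putative
ORFs". A capsid or Rep call is *complete* when its hit covers ≥ 80% of
the reference; several ORFs per genome may receive the same class
(dual-capsid genomes exist).

## Splice-site and ciliate-code rescue

When no complete Rep is readable in a single frame (internal stop, or
endonuclease and helicase homology in different frames), the pipeline
searches donor/acceptor pairs — canonical GT..AG by default, with a
context bonus for an AG|GT donor and AG|G acceptor; the consensus is a
configurable parameter — whose excision yields a stop-free ORF covering
all Rep-homology anchor regions. Candidates are ranked by intron
length (minimal first), then context. Homology regions more than
four-fold weaker (in bits) than the strongest hit are excluded from the
anchor set, and if the Rep region straddles the origin of the resolved
circle the search is repeated with the origin rotated half a genome
away.

If splicing fails, annotation is retried under the ciliate genetic code
(translation table 6: TAA/TAG encode Gln, TGA terminates) and adopted
only if it renders a complete, reference-sized ORF — a candidate longer
than 1.5× its reference is a stop-codon read-through, not a rescue.

## Stem-loop origin detection

The detector scans both strands of the circle (wrapping the origin)
for degenerate nonanucleotide patterns — defaults NANTANTAN, NAKWRTTAC,
TAWWDHWAN, TRAKATTRC — and folds a window of the motif ± `flank` bases
(default 20, configurable within 15–20). Each hairpin is scored as
`|stem − 11| + |loop − 11|`; candidates pass with score ≤ 15, stem ≥ 5
bp and loop ≥ 7 nt.

**Folding backend.** The default backend (`max_pairing_hairpin`)
enumerates every hairpin-shaped nested pairing of the window — an outer
pair, a contiguous stem of stacked Watson–Crick or G·T wobble pairs,
and an enclosed loop of ≥ 3 bases — and is verified in the test suite
against an independent brute-force placement enumeration. A global
maximum-pairing Nussinov backend (`nussinov_dna`) is also provided and
oracle-checked, but it is not the default: measured on planted
hairpins, globally count-optimal structures frequently trade the
contiguous biological stem for scattered flank pairs, which is a poor
model of a cruciform and sharply reduces recovery of true origins.
Free-energy folding in kcal/mol is out of scope; the backend registry
accepts external folders.

**Candidate choice.** Folding is *strand-canonical*: the window is
always folded on the forward strand, because the cruciform extruded
from double-stranded DNA is one physical structure, and per-strand
folding would measure mirror-strand motif hits over the same hairpin
differently through the non-palindromic G·T wobble. Among a hit's
hairpin candidates, loops overlapping the motif are preferred (the
annotation is motif-anchored); among geometry-compliant candidates the
one closest to the ideal 11 bp/11 nt ori geometry wins, preferring
candidates that keep the motif at least `proximity` (default 4) bases
inside both hairpin ends; without geometry constraints the longest stem
wins, then the most centered loop.

**Exclusions.** Candidates whose nonanucleotide lies within four bases
of the hairpin's first or last nucleotide (both ends checked, strict
`< 4`) are rejected first; then, among accepted candidates sharing the
same hairpin first base, only the best is kept. That ordering means an
edge-hugging candidate cannot evict a centered one from the same
hairpin. Ties in the same-first-base rule are broken by: loop closest
to 11, motif farthest from the hairpin ends (the nonanucleotide sits at
the loop apex), motif matching more of the conserved pattern set (the
degenerate patterns intrinsically match shifted and mirror-strand
windows over one physical hairpin; the true apex nonanucleotide is the
more canonical match), downstream motif, plus strand. Several accepted
annotations at different loci are all reported, and every candidate —
accepted or not — carries its rejection reason.

## Rep motifs and capsid domains

Motif patterns are data (a TSV of regexes with an expected region per
motif), not code. Defaults: motif I `FT[LI]NN`, motif II `H[A-Z][HQ]`,
motif III `Y[A-Z]{2,3}K` (all searched in the N-terminal half);
Walker A `G[A-Z]{4}GK[TS]`, Walker B `[ILMFV]{2}D[DE]`, motif C
`[ILMFV][A-Z]TSN` (searched C-terminal of motif III); the Arg finger is
any Arg 3–40 residues downstream of motif C. Only the motif-II triad
classes are anchored in the underlying biology (HUH = His-hydrophobic-
His with hydrophobic = {A,V,L,I,M,F,W,C}; HUQ replaces the second His
with Gln; HYQ is the specific His-Tyr-Gln arrangement); the other
regexes are editable consensus approximations. A geminivirus Rep
sequence (GRS) pattern ships disabled-by-default and marked
low-confidence. A genome is called CruCGE when it has no Rep CDS or a
Rep with zero of the seven motifs.

Capsid partitioning locates the S-domain with a gapless
position-specific log-odds profile (pseudocount 1, uniform background)
built from reference capsids, slid over the query; R is the prefix
(possibly empty for truncated capsids), P the suffix, so the three
domains always tile the protein. The Gly-rich tract is the longest
window of ≥ 8 residues with ≥ 50% Gly within R. Gapped profile
alignment is deliberately avoided for determinism. The isoelectric
profile uses bisection on the Henderson–Hasselbalch net-charge function
with the EMBOSS pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
D 3.9, E 4.1, C 8.5, Y 10.1), window 21 by default, truncated at the
edges, each window treated as a peptide with its own termini.

## Diversity

PI is computed SDT-style from a global alignment: identical columns
over the alignment length, where internal gap columns count and
terminal overhangs do not (recorded in the matrix's `pi_definition`).
One deterministic alignment engine serves capsid and Rep alike.
Summaries use sample SD (n − 1). Threshold clustering draws an edge for
`min_pi < PI < max_pi` (strict), collapses 100%-identical pairs to one
representative first, and reports connected components — single
linkage, the weakest sensible contract for clusters identified visually
from an ordered matrix — with a clique mode available
(`mode="clique"`). Similarity networks connect proteins whose
local-alignment E-value (E = K·m·n·e^(−λS)) falls below a per-dataset
cutoff; isolated nodes are retained, and edge sets nest monotonically
in the cutoff.

## Synthetic data: what it emulates, and what it does not

The generator emulates the study conditions of the crucivirus survey:
genome lengths drawn uniformly on 2,474–7,947 nt; GC ~ N(43, 4.9)%;
ori nonanucleotides drawn from concrete instances of the four conserved
patterns with the canonical TAGTATTAC most common; stems 5–14 bp and
loops 7–15 nt; ~41/59 unisense/ambisense orientation with ~2% Rep-less
elements; motif-II classes dominated by HUQ (70%) over HYQ, HUH and
other variants, with ~5% motif-II-free Reps and ~5% helicase-motif-free
Reps; ~8% intron-bearing Reps; and ~1% alternative-genetic-code
genomes. Capsid and Rep CDSs are mutated copies of fixed ancestral
proteins (capsid 10%, Rep 22% per-residue substitution — the Rep is the
faster-evolving protein in this group, and the differentiated rates
reproduce that contrast in the PI statistics); the bundled reference
library derives from the same ancestors, which is what makes
homology-based classification meaningful.

Constructional guarantees, and their limits:

- Coding regions use GC-weighted codon choice and the non-coding
  background probability is solved so the *genome-level* GC hits the
  target (within ~2 points for genomes ≥ 3 kb).
- Protein background is random except at motif positions; spurious
  matches of the default motif patterns are resampled away (and
  arginines competing with the planted Arg finger cleared from its
  search window), so detector truth is unambiguous.
- The hairpin neighbourhood is resampled until the planted
  nonanucleotide is the only breakable pattern match nearby; a few
  mirror windows are intrinsically unbreakable (every constrained
  pattern position falls inside the planted motif itself) and are
  instead resolved by the detector's apex/canonicalness tie-breaks.
  The pool of planted nonanucleotides was screened exhaustively so that
  no reverse complement or unbreakable shifted window matches any
  default pattern.
- Planted introns carry an in-frame stop and are built with restricted
  alphabets so the planted GT..AG pair is the unique minimal canonical
  excision; alternative-code genomes terminate CDSs with TGA (the only
  ciliate stop) and encode one mid-protein Gln as TAA.

Passing the planted-truth tests therefore shows that the detectors
recover what the model of a crucivirus genome says they should —
including across strand, rotation, linearization, splicing and
genetic-code variation — not that they reproduce any particular real
dataset. Real genomes have codon bias, repeat structure, and
thermodynamically (not combinatorially) folded origins; the
combinatorial backend is more permissive than a thermodynamic folder,
so per-genome stem-loop annotation counts run higher than a
ViennaRNA-style backend would give. One known, accepted miss: a
planted stem-5/loop-7 hairpin places its nonanucleotide three bases
from the hairpin start, which the four-base proximity rule excludes by
design (~1% of the stem/loop grid).

## Degenerate inputs and determinism

Empty FASTA files, duplicate ids, all-N sequences, sub-60-residue
capsids, sub-50-residue Reps, empty reference libraries, and
zero-variance ANOVA groups all raise or return documented conventions
(ANOVA on identical constant groups returns F = 0, p = 1). Every
stochastic component takes an explicit seed; per-genome generator
streams derive from (master seed, index), so datasets are reproducible
under any generation order, and a full pipeline rerun is byte-identical.

## Problem sizes used in validation

The test suite and the acceptance script validate on: 500 random
windows (≤ 30 nt) against the folding oracle; 200 random protein pairs
(≤ 50 aa) against the textbook local-alignment DP; 200 planted-ori
genomes (3 kb) for recall and strand accuracy; a 60-genome full
pipeline run for classification accuracy, summary statistics, PI means
and the capsid-vs-Rep ANOVA; and 5 planted protein families of 5
members for cluster recovery. These sizes give stable statistics while
keeping a full validation run in the minutes range on one CPU.
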
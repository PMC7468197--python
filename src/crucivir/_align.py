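"""Shared protein-alignment machinery.

Local and global affine-gap alignments are delegated to Biopython's
PairwiseAligner; raw scores are converted to bit scores and E-values with
the Karlin-Altschul statistics for gapped BLOSUM62 searches
(lambda = 0.267, K = 0.041), so that thresholds expressed in bits or
E-values are reproducible without an external search engine.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: Karlin-Altschul parameters for gapped BLOSUM62 (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=8)
def get_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    try:
        sub = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def bit_score(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def e_value(raw: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw)


def align_rows(aligner: Align.PairwiseAligner, a: str, b: str):
    """Best alignment as (score, row_a, row_b) gapped strings.

    For local mode the rows cover only the aligned region; for global mode
    they cover both sequences end to end.  The first optimal alignment is
    taken, which makes results deterministic.
    """
    aln = aligner.align(a, b)[0]
    return aln.score, aln[0], aln[1]
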
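"""Pairwise-identity diversity analysis, clustering, and similarity networks.

Percent pairwise identity (PI) follows the species-demarcation-tool
convention: identical columns over the pairwise global alignment length,
where internal gap columns count toward the length and terminal overhangs
do not.  Threshold clustering treats the identity matrix as a graph
(edge iff min_pi < PI < max_pi) and reports connected components —
single-linkage, the weakest sensible contract for clusters identified
visually from an ordered matrix — with an optional clique mode.
Similarity networks connect proteins whose local-alignment E-value falls
below a per-dataset cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from crucivir import _align
from crucivir.orf_and_genes import smith_waterman

PI_DEFINITION = "identical columns / alignment length (internal gaps counted, terminal overhangs excluded)"


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, percent, diagonal 100
    aligner: str = "needleman-wunsch BLOSUM62 open=-10 extend=-1"
    pi_definition: str = PI_DEFINITION

    def pi(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t", float_format="%.4f")


def pairwise_percent_identity(
    a: str, b: str, matrix: str = "BLOSUM62", gap_open: float = 10, gap_extend: float = 1
) -> float:
    """SDT-style PI of one pair via global alignment."""
    aligner = _align.get_aligner("global", matrix, gap_open, gap_extend)
    _, row_a, row_b = _align.align_rows(aligner, a, b)
    lo = 0
    hi = len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    ident = sum(1 for x, y in zip(row_a[lo:hi], row_b[lo:hi]) if x == y and x != "-")
    return 100.0 * ident / (hi - lo)


def pairwise_identity_matrix(
    proteins: Sequence[tuple[str, str]] | dict[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = 10,
    gap_extend: float = 1,
) -> IdentityMatrix:
    """Symmetric percent-identity matrix over all unordered pairs."""
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    for pid, seq in items:
        if not seq:
            raise ValueError(f"empty sequence for id {pid!r}")
    ids = [pid for pid, _ in items]
    n = len(ids)
    values = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        pi = pairwise_percent_identity(items[i][1], items[j][1], matrix, gap_open, gap_extend)
        values[i, j] = values[j, i] = pi
    return IdentityMatrix(
        ids=ids,
        values=values,
        aligner=f"needleman-wunsch {matrix} open=-{abs(gap_open)} extend=-{abs(gap_extend)}",
    )


def matrix_stats(m: IdentityMatrix, ddof: int = 1) -> tuple[float, float]:
    """(mean, SD) over the off-diagonal upper triangle (sample SD default)."""
    iu = np.triu_indices(len(m.ids), k=1)
    vals = m.values[iu]
    sd = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
    return float(np.mean(vals)), sd


@dataclass
class ClusterSet:
    clusters: list[list[str]]
    min_pi: float
    max_pi: float
    min_size: int
    linkage: str = "single (connected components)"
    representatives: dict[str, list[str]] = field(default_factory=dict)


def cluster_by_threshold(
    m: IdentityMatrix,
    min_pi: float,
    max_pi: float = 100.0,
    min_size: int = 1,
    mode: str = "component",
) -> ClusterSet:
    """Threshold clustering of an identity matrix.

    Edges connect pairs with ``min_pi < PI < max_pi`` (strict).  Pairs at
    100% identity are first collapsed to a single representative (the
    lexicographically smallest id), enforcing the "nonidentical sequences"
    rule.  Clusters are connected components (``mode="component"``) or
    greedily chosen maximal cliques (``mode="clique"``); components with
    fewer than ``min_size`` members are dropped.  Output ordering is
    deterministic: by size descending, then by first id.
    """
    if not 0 <= min_pi < max_pi <= 100:
        raise ValueError("require 0 <= min_pi < max_pi <= 100")
    n = len(m.ids)
    # collapse 100%-identical sequences
    ident_graph = nx.Graph()
    ident_graph.add_nodes_from(range(n))
    for i, j in combinations(range(n), 2):
        if m.values[i, j] >= 100.0:
            ident_graph.add_edge(i, j)
    reps: dict[int, list[int]] = {}
    for comp in nx.connected_components(ident_graph):
        members = sorted(comp, key=lambda i: m.ids[i])
        reps[members[0]] = members

    g = nx.Graph()
    g.add_nodes_from(reps)
    for i, j in combinations(sorted(reps), 2):
        if min_pi < m.values[i, j] < max_pi:
            g.add_edge(i, j)

    if mode == "component":
        raw = [sorted(c) for c in nx.connected_components(g)]
    elif mode == "clique":
        cliques = sorted(
            (sorted(c) for c in nx.find_cliques(g)),
            key=lambda c: (-len(c), [m.ids[i] for i in c]),
        )
        raw, used = [], set()
        for c in cliques:
            if not used & set(c):
                raw.append(c)
                used |= set(c)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    clusters = [sorted(m.ids[i] for i in c) for c in raw if len(c) >= min_size]
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ClusterSet(
        clusters=clusters,
        min_pi=min_pi,
        max_pi=max_pi,
        min_size=min_size,
        linkage="single (connected components)" if mode == "component" else "clique",
        representatives={m.ids[k]: [m.ids[i] for i in v] for k, v in reps.items() if len(v) > 1},
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across groups.

    Degenerate inputs (zero variance everywhere with equal means) return
    F = 0, p = 1 by convention.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of size >= 2")
    means = [float(np.mean(g)) for g in groups]
    if all(float(np.var(g)) == 0.0 for g in groups):
        if len(set(means)) == 1:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


@dataclass
class SimilarityGraph:
    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def connected_components(self) -> list[set[str]]:
        return sorted(nx.connected_components(self.graph), key=lambda c: (-len(c), min(c)))

    def isolated_nodes(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.degree[n] == 0)

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id1\tid2\tevalue\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['evalue']:.3e}\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def build_similarity_network(
    proteins: Sequence[tuple[str, str]] | dict[str, str],
    groups: Optional[dict[str, str]] = None,
    cutoff: float = 1e-20,
) -> SimilarityGraph:
    """All-vs-all local-alignment network with an E-value cutoff.

    E = K * m * n * exp(-lambda * S) with the gapped BLOSUM62 constants;
    an edge is drawn iff E < cutoff.  Isolated nodes are retained.
    """
    items = list(proteins.items()) if isinstance(proteins, dict) else list(proteins)
    if len(items) < 2:
        raise ValueError("need at least two proteins")
    g = nx.Graph()
    for pid, _ in items:
        g.add_node(pid, group=(groups or {}).get(pid, ""))
    for (id_a, seq_a), (id_b, seq_b) in combinations(items, 2):
        hit = smith_waterman(seq_a, seq_b, query_id=id_a, ref_id=id_b)
        if hit.evalue < cutoff:
            g.add_edge(id_a, id_b, evalue=hit.evalue, bits=hit.bits)
    return SimilarityGraph(graph=g, cutoff=cutoff)


def plot_identity_heatmap(m: IdentityMatrix, path) -> None:
    """Optional heatmap rendering of an identity matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(m.values, vmin=0, vmax=100, cmap="viridis")
    fig.colorbar(im, ax=ax, label="% pairwise identity")
    ax.set_xticks(range(len(m.ids)))
    ax.set_yticks(range(len(m.ids)))
    ax.set_xticklabels(m.ids, rotation=90, fontsize=5)
    ax.set_yticklabels(m.ids, fontsize=5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
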
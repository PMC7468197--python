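"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through the most naive route
available — exhaustive enumeration or textbook dynamic programs — and
stay independent of the package implementations they check.
"""

from functools import lru_cache

from Bio.Align import substitution_matrices

WOBBLE_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_hairpins(window: str, min_loop: int = 3) -> set[tuple[int, int, int, int]]:
    """Every (outer_i, outer_j, stem, loop) hairpin placement, found by
    sliding all (start, stem, loop) geometries over the window and
    validating each base pair explicitly."""
    n = len(window)
    out = set()
    for start in range(n):
        for stem in range(1, n):
            for loop in range(min_loop, n):
                end = start + 2 * stem + loop  # exclusive
                if end > n:
                    break
                ok = all(
                    (window[start + i], window[end - 1 - i]) in WOBBLE_PAIRS
                    for i in range(stem)
                )
                if ok:
                    out.add((start, end - 1, stem, loop))
    return out


def max_nested_pairs(window: str, min_loop: int = 3) -> int:
    """Maximum number of nested pairs via plain interval recursion."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        score = best(i, j - 1)
        for k in range(i, j - min_loop):
            if (window[k], window[j]) in WOBBLE_PAIRS:
                left = best(i, k - 1) if k > i else 0
                score = max(score, left + 1 + best(k + 1, j - 1))
        return score

    return best(0, len(window) - 1)


def gotoh_local_score(a: str, b: str, gap_open: float = 11, gap_extend: float = 1) -> float:
    """Textbook affine-gap local alignment (Gotoh), BLOSUM62.

    Gap convention: a gap of length L costs open + (L-1)*extend (the
    first gap character carries the opening cost).
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def anova_f_closed_form(groups):
    """One-way ANOVA F statistic from the between/within mean squares."""
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    return (ss_between / (k - 1)) / (ss_within / (n_total - k))
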
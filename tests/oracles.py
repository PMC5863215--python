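"""Independent brute-force oracles used by the test suite.

Each oracle is a direct, exhaustive (or closed-form) computation kept
deliberately separate from the package's implementation path.
"""

from __future__ import annotations

import itertools
import math

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Full O(mn) Smith-Waterman with affine gaps (BLAST convention:
    a gap of length k costs open + k*extend), plain nested loops."""
    m, n = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in b
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in a
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _BLOSUM[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend,
                X[i - 1][j] - gap_extend,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend,
                Y[i][j - 1] - gap_extend,
            )
            best = max(best, M[i][j])
    return best


def best_partner_by_sw(seqs: dict[str, str]) -> dict[str, str]:
    """For each id, the other id with the highest Smith-Waterman score
    (ties to the lexicographically smallest partner)."""
    out = {}
    for q in seqs:
        scored = sorted(
            ((-sw_score(seqs[q], seqs[s]), s) for s in seqs if s != q),
        )
        out[q] = scored[0][1]
    return out


def rbh_pairs_bruteforce(hits) -> set[tuple[str, str]]:
    """Reciprocal best pairs by a double loop over a hit table.

    *hits* is an iterable of objects with qseqid, sseqid, evalue,
    bitscore.  Best partner = lowest evalue, ties by higher bitscore,
    then lexicographic sseqid.
    """
    queries = {h.qseqid for h in hits if h.qseqid != h.sseqid}
    best: dict[str, str] = {}
    for q in queries:
        candidates = [h for h in hits if h.qseqid == q and h.sseqid != q]
        candidates.sort(key=lambda h: (h.evalue, -h.bitscore, h.sseqid))
        if candidates:
            best[q] = candidates[0].sseqid
    pairs = set()
    for q, s in best.items():
        if best.get(s) == q:
            pairs.add((min(q, s), max(q, s)))
    return pairs


def enumerate_greedy_clusterings(
    weights: dict[tuple[str, str], int],
    nodes: set[str],
    min_density: float,
    max_size: int,
) -> list[frozenset[frozenset[str]]]:
    """All final partitions reachable by greedy merge sequences.

    At every step the permissible merges (cross-edge density and size
    constraints satisfied) with the *maximum average cross-weight* are
    candidates; the enumeration branches over every tie, so the result
    is the set of outcomes under any tie-breaking policy.  Exponential;
    keep inputs <= 8 nodes.
    """

    def cross(x: frozenset[str], y: frozenset[str]) -> tuple[float, int]:
        total = count = 0
        for u in x:
            for v in y:
                w = weights.get((min(u, v), max(u, v)))
                if w is not None:
                    total += w
                    count += 1
        return total / (len(x) * len(y)), count

    results: set[frozenset[frozenset[str]]] = set()

    def step(partition: frozenset[frozenset[str]]) -> None:
        merges = []
        parts = sorted(partition, key=sorted)
        for x, y in itertools.combinations(parts, 2):
            if len(x) + len(y) > max_size:
                continue
            avg, count = cross(x, y)
            if count == 0:
                continue
            if count / (len(x) * len(y)) < min_density:
                continue
            merges.append((avg, x, y))
        if not merges:
            results.add(partition)
            return
        best = max(avg for avg, _, _ in merges)
        for avg, x, y in merges:
            if avg == best:
                step((partition - {x, y}) | {x | y})

    step(frozenset(frozenset([n]) for n in nodes))
    return sorted(results, key=lambda p: sorted(map(sorted, p)))


def ls_best_quartet_topology(d: dict[tuple[str, str], float], taxa: list[str]) -> frozenset:
    """Least-squares best quartet topology over the three possible splits.

    Returns the winning split as frozenset({frozenset(pair1), frozenset(pair2)}).
    Fits the 5-branch quartet tree to the 6 pairwise distances by
    ordinary least squares (closed form via numpy lstsq).
    """
    import numpy as np

    def dist(x, y):
        return d[(x, y)] if (x, y) in d else d[(y, x)]

    a, b, c, e = taxa
    splits = [((a, b), (c, e)), ((a, c), (b, e)), ((a, e), (b, c))]
    best = None
    for (p, q), (r, s) in splits:
        # branches: p, q, r, s external; one internal
        rows, rhs = [], []
        order = [p, q, r, s]
        for x, y in itertools.combinations(order, 2):
            row = [0.0] * 5
            row[order.index(x)] = 1.0
            row[order.index(y)] = 1.0
            same_side = {x, y} in ({p, q}, {r, s})
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            rhs.append(dist(x, y))
        A = np.array(rows)
        y_ = np.array(rhs)
        sol, *_ = np.linalg.lstsq(A, y_, rcond=None)
        rss = float(((A @ sol - y_) ** 2).sum())
        key = (rss, sorted((sorted((p, q)), sorted((r, s)))))
        if best is None or key < best[0]:
            best = (key, frozenset({frozenset((p, q)), frozenset((r, s))}))
    return best[1]


def enumerate_two_row_alignments(a: str, b: str):
    """Yield every gapped 2-row alignment of a and b (no gap-gap columns)."""

    def rec(i: int, j: int, rows: tuple[str, str]):
        if i == len(a) and j == len(b):
            yield rows
            return
        if i < len(a) and j < len(b):
            yield from rec(i + 1, j + 1, (rows[0] + a[i], rows[1] + b[j]))
        if i < len(a):
            yield from rec(i + 1, j, (rows[0] + a[i], rows[1] + "-"))
        if j < len(b):
            yield from rec(i, j + 1, (rows[0] + "-", rows[1] + b[j]))

    yield from rec(0, 0, ("", ""))


def pair_alignment_score(
    row_a: str, row_b: str, gap_open: float = -10.0, gap_extend: float = -0.5
) -> float:
    """Affine-gap sum score of one aligned row pair (gap run costs
    open + (k-1)*extend), substitution scores from BLOSUM62."""
    total = 0.0
    in_gap = False
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            in_gap = False
            continue
        if x == "-" or y == "-":
            total += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            total += _BLOSUM[x, y]
            in_gap = False
    return total


def evalue_closed_form(raw_score: float, m: int, n: int,
                       lam: float = 0.267, K: float = 0.041) -> float:
    bits = (lam * raw_score - math.log(K)) / math.log(2)
    return m * n * 2.0 ** (-bits)
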
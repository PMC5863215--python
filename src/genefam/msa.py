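"""Per-family protein multiple sequence alignment and aligned-FASTA io.

The aligner is a native progressive MSA: pairwise distance estimates feed
a UPGMA guide tree, and profiles are merged bottom-up with an affine-gap
(Gotoh) profile-profile dynamic program under sum-of-pairs BLOSUM62
scoring.  It is deterministic for a fixed input order: DP traceback
prefers diagonal, then up, then left, and guide-tree ties break
lexicographically.  Externally produced aligned FASTA (``fasta_aln``,
``-`` gaps) is accepted verbatim through :func:`read_fasta_aln`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .preparation import SequenceRecord


class AlignmentError(ValueError):
    pass


def _check_rows(rows: dict[str, str], unit: int = 1) -> int:
    if not rows:
        raise AlignmentError("alignment has no rows")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise AlignmentError(f"ragged alignment rows: lengths {sorted(lengths)}")
    (length,) = lengths
    if length == 0 or length % unit:
        raise AlignmentError(f"bad alignment length {length}")
    for sid, row in rows.items():
        if not row.replace("-", ""):
            raise AlignmentError(f"row {sid!r} is all gaps")
    for col in range(length):
        if all(row[col] == "-" for row in rows.values()):
            raise AlignmentError(f"all-gap column at index {col}")
    return length


@dataclass(frozen=True)
class ProteinAlignment:
    """Equal-length gapped amino-acid rows keyed by sequence id."""

    rows: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", _check_rows(self.rows))

    def degapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")

    @property
    def ids(self) -> list[str]:
        return list(self.rows)


@dataclass(frozen=True)
class CodonAlignment:
    """Equal-length gapped nucleotide rows; length is a multiple of 3."""

    rows: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "length", _check_rows(self.rows, unit=3))

    def degapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")

    @property
    def ids(self) -> list[str]:
        return list(self.rows)


def read_fasta_aln(path: str | Path, moltype: str = "aa") -> ProteinAlignment | CodonAlignment:
    rows: dict[str, str] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in rows:
                    raise AlignmentError(f"duplicate id {current!r} in {path}")
                rows[current] = ""
            elif current is None:
                raise AlignmentError(f"sequence data before header in {path}")
            else:
                rows[current] += line.upper()
    cls = ProteinAlignment if moltype == "aa" else CodonAlignment
    return cls(rows)


def write_fasta_aln(aln: ProteinAlignment | CodonAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, row in aln.rows.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# --- scoring -----------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHABET = list(_BLOSUM.alphabet) + ["-"]
_INDEX = {c: i for i, c in enumerate(_ALPHABET)}
_GAP = _INDEX["-"]

_S = np.zeros((len(_ALPHABET), len(_ALPHABET)))
for _i, _a in enumerate(_BLOSUM.alphabet):
    for _j, _b in enumerate(_BLOSUM.alphabet):
        _S[_i, _j] = _BLOSUM[_a, _b]
# residue-vs-gap and gap-vs-gap pairs score 0 in match columns; gap costs
# are carried by the affine DP states instead.

DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -0.5


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Per-column symbol counts, shape (columns, alphabet)."""
    length = len(rows[0])
    counts = np.zeros((length, len(_ALPHABET)))
    for row in rows:
        for i, c in enumerate(row):
            counts[i, _INDEX.get(c, _INDEX["X"])] += 1
    return counts


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float,
    gap_extend: float,
) -> tuple[list[str], list[str]]:
    """Gotoh affine-gap global alignment of two profiles.

    Returns the input rows re-gapped to a common length.  Traceback
    tie-break: diagonal, then up (gap in B), then left (gap in A).
    """
    ca, cb = _profile_counts(rows_a), _profile_counts(rows_b)
    la, lb = ca.shape[0], cb.shape[0]
    match = (ca[:, : _GAP] @ _S[: _GAP, : _GAP] @ cb[:, : _GAP].T) / (len(rows_a) * len(rows_b))

    neg = -np.inf
    # state 0 = M (diagonal), 1 = X (gap in B, consume A), 2 = Y (gap in A)
    score = np.full((3, la + 1, lb + 1), neg)
    ptr = np.zeros((3, la + 1, lb + 1), dtype=np.int8)  # previous state
    score[0, 0, 0] = 0.0
    for i in range(1, la + 1):
        score[1, i, 0] = gap_open + gap_extend * (i - 1)
        ptr[1, i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        score[2, 0, j] = gap_open + gap_extend * (j - 1)
        ptr[2, 0, j] = 0 if j == 1 else 2

    def _best(cands: list[tuple[float, int]]) -> tuple[float, int]:
        # exact ties resolve in listed (preference) order
        best = cands[0]
        for c in cands[1:]:
            if c[0] > best[0]:
                best = c
        return best

    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            v, p = _best([(score[s, i - 1, j - 1], s) for s in (0, 1, 2)])
            score[0, i, j] = v + match[i - 1, j - 1]
            ptr[0, i, j] = p
            v, p = _best(
                [
                    (score[0, i - 1, j] + gap_open, 0),
                    (score[1, i - 1, j] + gap_extend, 1),
                    (score[2, i - 1, j] + gap_open, 2),
                ]
            )
            score[1, i, j] = v
            ptr[1, i, j] = p
            v, p = _best(
                [
                    (score[0, i, j - 1] + gap_open, 0),
                    (score[1, i, j - 1] + gap_open, 1),
                    (score[2, i, j - 1] + gap_extend, 2),
                ]
            )
            score[2, i, j] = v
            ptr[2, i, j] = p

    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = la, lb
    _, state = _best([(score[s, i, j], s) for s in (0, 1, 2)])
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == 0:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i - 1])
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            for k, row in enumerate(rows_a):
                out_a[k].append(row[i - 1])
            for k in range(len(rows_b)):
                out_b[k].append("-")
            i -= 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append("-")
            for k, row in enumerate(rows_b):
                out_b[k].append(row[j - 1])
            j -= 1
        state = prev
    return ["".join(reversed(r)) for r in out_a], ["".join(reversed(r)) for r in out_b]


def _strip_all_gap_columns(rows: dict[str, str]) -> dict[str, str]:
    length = len(next(iter(rows.values())))
    keep = [c for c in range(length) if any(r[c] != "-" for r in rows.values())]
    return {sid: "".join(row[c] for c in keep) for sid, row in rows.items()}


def pairwise_distance(a: str, b: str) -> float:
    """p-distance from a global pairwise alignment (gap columns excluded)."""
    aligner = PairwiseAligner(
        mode="global",
        substitution_matrix=_BLOSUM,
        open_gap_score=DEFAULT_GAP_OPEN,
        extend_gap_score=DEFAULT_GAP_EXTEND,
    )
    aln = aligner.align(a.replace("*", "X"), b.replace("*", "X"))[0]
    sa, sb = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(sa, sb) if x != "-" and y != "-"]
    if not pairs:
        return 1.0
    return sum(1 for x, y in pairs if x != y) / len(pairs)


def align_family(
    proteins: list[SequenceRecord],
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> ProteinAlignment:
    """Progressively align the proteins of one gene family.

    Requires at least two sequences.  Output row order follows input
    order; every row degaps to its input sequence.
    """
    if len(proteins) < 2:
        raise AlignmentError("alignment needs at least 2 sequences")
    ids = [r.id for r in proteins]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids")
    seqs = {r.id: r.seq for r in proteins}
    for sid, s in seqs.items():
        if not s:
            raise AlignmentError(f"empty sequence {sid!r}")

    order = sorted(ids)  # lexicographic leaf order for deterministic ties
    n = len(order)
    if n == 2:
        groups: dict[int, list[str]] = {0: [order[0]], 1: [order[1]]}
        merges = [(0, 1)]
    else:
        dm = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dm[i, j] = dm[j, i] = pairwise_distance(seqs[order[i]], seqs[order[j]])
        Z = linkage(squareform(dm, checks=False), method="average")
        groups = {i: [order[i]] for i in range(n)}
        merges = [(int(a), int(b)) for a, b, *_ in Z]

    profiles: dict[int, dict[str, str]] = {
        k: {sid: seqs[sid] for sid in members} for k, members in groups.items()
    }
    next_id = len(groups)
    for a, b in merges:
        pa, pb = profiles.pop(a), profiles.pop(b)
        if min(pa) > min(pb):  # deterministic orientation
            pa, pb = pb, pa
        new_a, new_b = _align_profiles(list(pa.values()), list(pb.values()), gap_open, gap_extend)
        merged = dict(zip(pa.keys(), new_a)) | dict(zip(pb.keys(), new_b))
        profiles[next_id] = merged
        next_id += 1
    (final,) = profiles.values()
    final = _strip_all_gap_columns(final)
    return ProteinAlignment({sid: final[sid] for sid in ids})


def sum_of_pairs_score(
    aln: ProteinAlignment,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Sum-of-pairs score of an alignment (affine gap runs per row pair)."""
    total = 0.0
    rows = list(aln.rows.values())
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            in_gap = False
            for x, y in zip(a, b):
                if x == "-" and y == "-":
                    in_gap = False
                    continue
                if x == "-" or y == "-":
                    total += gap_extend if in_gap else gap_open
                    in_gap = True
                else:
                    total += _S[_INDEX.get(x, _INDEX["X"]), _INDEX.get(y, _INDEX["X"])]
                    in_gap = False
    return total
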
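"""All-vs-all protein similarity search with 12-column tabular output.

For every ordered (query, subject) pair the single best local alignment
is computed exactly (Smith-Waterman via Bio.Align, BLOSUM62, affine gaps
in the BLAST convention: a gap of length k costs open + k*extend with
open=11, extend=1).  Scores are converted to bit scores and e-values with
pinned Karlin-Altschul parameters (lambda=0.267, K=0.041, gapped BLOSUM62
defaults), so e-values are reproducible but not bit-identical to any
particular BLAST build.  Externally produced 12-column files are accepted
verbatim through :func:`read_tabular12`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Align import PairwiseAligner, substitution_matrices

from .preparation import SequenceRecord

KA_LAMBDA = 0.267
KA_K = 0.041
GAP_OPEN = 11
GAP_EXTEND = 1

_BLOSUM = substitution_matrices.load("BLOSUM62")


class SearchError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityHit:
    """One row of 12-column tabular pairwise-similarity output."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend or self.sstart > self.send:
            raise SearchError(f"hit {self.qseqid}->{self.sseqid}: inverted coordinates")
        if self.evalue < 0:
            raise SearchError(f"hit {self.qseqid}->{self.sseqid}: negative evalue")


@dataclass(frozen=True)
class SearchParams:
    """Search configuration mirroring the BLASTP-facing knobs of the pipeline."""

    evalue_cutoff: float = 1e-10
    qcov_cutoff: float = 0.0  # percentage of query length an HSP must cover
    max_hsps: int = 1
    word_size: int = 3  # retained for interface parity; exact search ignores it

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise SearchError("evalue_cutoff must be > 0")
        if not 0 <= self.qcov_cutoff <= 100:
            raise SearchError("qcov_cutoff must be in [0, 100]")


def bitscore_from_raw(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def evalue_from_bitscore(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def _make_aligner() -> PairwiseAligner:
    return PairwiseAligner(
        mode="local",
        substitution_matrix=_BLOSUM,
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
    )


def _hit_from_alignment(aln, qid: str, sid: str, m: int, db_residues: int) -> SimilarityHit:
    qa, sa = str(aln[0]), str(aln[1])
    matches = mismatches = gapopens = 0
    prev_gap = False
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            if not prev_gap:
                gapopens += 1
            prev_gap = True
        else:
            prev_gap = False
            if x == y and x != "X":
                matches += 1
            else:
                mismatches += 1
    length = len(qa)
    bits = bitscore_from_raw(aln.score)
    ev = evalue_from_bitscore(bits, m, db_residues)
    (qblocks, sblocks) = aln.aligned
    return SimilarityHit(
        qseqid=qid,
        sseqid=sid,
        pident=round(100.0 * matches / length, 2),
        length=length,
        mismatch=mismatches,
        gapopen=gapopens,
        qstart=int(qblocks[0][0]) + 1,
        qend=int(qblocks[-1][1]),
        sstart=int(sblocks[0][0]) + 1,
        send=int(sblocks[-1][1]),
        evalue=ev,
        bitscore=round(bits, 1),
    )


def all_vs_all(proteins: list[SequenceRecord], params: SearchParams | None = None) -> list[SimilarityHit]:
    """Search every sequence against the database of all input sequences.

    Self-pairs are emitted (downstream edge construction removes them).
    Hits failing the e-value or query-coverage cutoff are discarded.
    Output is sorted by (qseqid, evalue, sseqid).
    """
    params = params or SearchParams()
    if len(proteins) < 2:
        raise SearchError("all-vs-all search needs at least 2 sequences")
    ids = [r.id for r in proteins]
    if len(set(ids)) != len(ids):
        raise SearchError("duplicate sequence ids in search input")
    seqs = {r.id: r.seq.replace("*", "X") for r in proteins}
    db_residues = sum(len(s) for s in seqs.values())
    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    for qid in ids:
        q = seqs[qid]
        for sid in ids:
            s = seqs[sid]
            alns = aligner.align(q, s)
            if len(alns) == 0 or alns.score <= 0:
                continue
            hit = _hit_from_alignment(alns[0], qid, sid, len(q), db_residues)
            if hit.evalue > params.evalue_cutoff:
                continue
            qcov = 100.0 * (hit.qend - hit.qstart + 1) / len(q)
            if qcov < params.qcov_cutoff:
                continue
            hits.append(hit)
    hits.sort(key=lambda h: (h.qseqid, h.evalue, h.sseqid))
    return hits


_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def write_tabular12(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.qseqid,
                        h.sseqid,
                        f"{h.pident:.2f}",
                        str(h.length),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.6e}" if h.evalue else "0.0",
                        f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def read_tabular12(path: str | Path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise SearchError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            hits.append(
                SimilarityHit(
                    qseqid=cols[0],
                    sseqid=cols[1],
                    pident=float(cols[2]),
                    length=int(cols[3]),
                    mismatch=int(cols[4]),
                    gapopen=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
    return hits
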
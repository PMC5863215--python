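"""Similarity hits to weighted graph edges.

The edge weight is -log10(evalue)/2 capped at 100 and rounded half-up to
an integer; an underflowed e-value of exactly 0 maps to the cap.  Self
matches are removed here, and the reciprocal-best-hit (RBH) filter can
restrict edges to mutually best partners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .simsearch import SimilarityHit


class EdgeError(ValueError):
    pass


@dataclass(frozen=True)
class WeightedEdge:
    """Undirected similarity-graph edge with integer weight 0-100."""

    a: str
    b: str
    weight: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise EdgeError(f"self-loop on {self.a!r}")
        if not 0 <= self.weight <= 100:
            raise EdgeError(f"edge weight {self.weight} outside [0, 100]")


def compute_weight(evalue: float) -> int:
    """Edge weight for an e-value: min(-log10(e)/2, 100), rounded half-up.

    An e-value of 0 (similarity-search underflow) maps to 100, the limit
    of the formula.
    """
    if evalue < 0:
        raise EdgeError(f"negative evalue {evalue}")
    if evalue == 0:
        return 100
    w = -math.log10(evalue) / 2.0
    w = min(w, 100.0)
    w = math.floor(w + 0.5)  # round half-up
    return max(w, 0)


def _better(h1: SimilarityHit, h2: SimilarityHit) -> SimilarityHit:
    """The better of two hits: lower evalue, then higher bitscore, then sseqid."""
    k1 = (h1.evalue, -h1.bitscore, h1.sseqid)
    k2 = (h2.evalue, -h2.bitscore, h2.sseqid)
    return h1 if k1 <= k2 else h2


def parse_hits(hits: Iterable[SimilarityHit], rbh_only: bool = False) -> list[WeightedEdge]:
    """Build undirected weighted edges from directional similarity hits.

    Self-pairs are dropped; duplicate ordered pairs keep the minimum
    e-value.  With *rbh_only*, an unordered pair survives only when each
    sequence is the other's best partner.  Each surviving pair is emitted
    once, weighted by the better of its two directional e-values, sorted
    by (a, b) with a < b.
    """
    directional: dict[tuple[str, str], float] = {}
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.qseqid == h.sseqid:
            continue
        key = (h.qseqid, h.sseqid)
        if key not in directional or h.evalue < directional[key]:
            directional[key] = h.evalue
        if h.qseqid not in best:
            best[h.qseqid] = h
        else:
            best[h.qseqid] = _better(best[h.qseqid], h)

    pairs: dict[tuple[str, str], float] = {}
    for (q, s), ev in directional.items():
        key = (min(q, s), max(q, s))
        if key not in pairs or ev < pairs[key]:
            pairs[key] = ev

    if rbh_only:
        kept = {}
        for (a, b), ev in pairs.items():
            if (
                a in best
                and b in best
                and best[a].sseqid == b
                and best[b].sseqid == a
            ):
                kept[(a, b)] = ev
        pairs = kept

    return [WeightedEdge(a, b, compute_weight(ev)) for (a, b), ev in sorted(pairs.items())]


def write_edges(edges: Iterable[WeightedEdge], path: str | Path) -> None:
    """3-column tab-separated edge list (id_a, id_b, weight)."""
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.weight}\n")


def read_edges(path: str | Path) -> list[WeightedEdge]:
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise EdgeError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            edges.append(WeightedEdge(cols[0], cols[1], int(cols[2])))
    return edges
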
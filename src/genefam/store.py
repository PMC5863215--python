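"""Family aggregation: CIGAR-encoded alignments, SQLite store, orphan genes.

The final deliverable of the pipeline is a single-file relational store
holding gene features, per-family NHX gene trees and per-member protein
alignment rows encoded as CIGAR strings (run-length encoding, M =
residue, D = gap, count 1 omitted — the Ensembl Compara cigar_line
convention).  A ``transcript_species`` view joins transcripts to their
gene's species.  Orphan genes are the sequences that never made it into
a family: absent from the similarity graph or discarded by the cluster
size filter.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .edge_weights import WeightedEdge
from .preparation import FeatureStore, SequenceRecord, demangle_id
from .sparse_cluster import subset_fasta

SCHEMA_VERSION = "1"


class StoreError(ValueError):
    pass


_CIGAR_RE = re.compile(r"(\d*)([MD])")


def msa_to_cigar(gapped_row: str) -> str:
    """Run-length encode an aligned row: residues to M, gaps to D."""
    if not gapped_row:
        raise StoreError("empty alignment row")
    if set(gapped_row) == {"-"}:
        raise StoreError("all-gap alignment row has no CIGAR")
    out = []
    run_char = gapped_row[0]
    run_len = 0
    for c in gapped_row + "\0":
        symbol = "D" if c == "-" else "M"
        prev = "D" if run_char == "-" else "M"
        if c != "\0" and symbol == prev:
            run_len += 1
        else:
            out.append(f"{run_len if run_len > 1 else ''}{prev}")
            run_char = c
            run_len = 1
    return "".join(out)


def cigar_to_row(cigar: str, ungapped: str) -> str:
    """Expand a CIGAR back to a gapped row over its ungapped sequence."""
    consumed = 0
    pieces = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise StoreError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        count = int(m.group(1) or 1)
        if m.group(2) == "M":
            pieces.append(ungapped[consumed : consumed + count])
            consumed += count
        else:
            pieces.append("-" * count)
    if pos != len(cigar):
        raise StoreError(f"malformed CIGAR {cigar!r}")
    if consumed != len(ungapped):
        raise StoreError(
            f"CIGAR consumes {consumed} residues but sequence has {len(ungapped)}"
        )
    return "".join(pieces)


@dataclass(frozen=True)
class FamilyRecord:
    """One gene family: NHX tree text plus (member id, CIGAR) pairs."""

    family_id: int
    newick: str
    members: list[tuple[str, str]]


_SCHEMA = f"""
PRAGMA foreign_keys = ON;
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE gene (
    gene_id TEXT PRIMARY KEY,
    symbol TEXT,
    species TEXT NOT NULL,
    chrom TEXT NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    strand TEXT NOT NULL CHECK (strand IN ('+', '-'))
);
CREATE TABLE transcript (
    transcript_id TEXT PRIMARY KEY,
    gene_id TEXT NOT NULL REFERENCES gene(gene_id),
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
CREATE TABLE exon (
    exon_id TEXT PRIMARY KEY,
    transcript_id TEXT NOT NULL REFERENCES transcript(transcript_id),
    rank INTEGER NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL
);
CREATE TABLE cds_segment (
    transcript_id TEXT NOT NULL REFERENCES transcript(transcript_id),
    rank INTEGER NOT NULL,
    start INTEGER NOT NULL,
    end INTEGER NOT NULL,
    PRIMARY KEY (transcript_id, rank)
);
CREATE TABLE gene_family (
    family_id INTEGER PRIMARY KEY,
    newick TEXT NOT NULL
);
CREATE TABLE family_member (
    family_id INTEGER NOT NULL REFERENCES gene_family(family_id),
    transcript_id TEXT NOT NULL REFERENCES transcript(transcript_id),
    cigar TEXT NOT NULL,
    PRIMARY KEY (family_id, transcript_id)
);
CREATE VIEW transcript_species AS
    SELECT transcript.transcript_id AS transcript_id, gene.species AS species
    FROM transcript JOIN gene ON transcript.gene_id = gene.gene_id;
"""


def aggregate(
    families: list[FamilyRecord],
    store_in: FeatureStore,
    path: str | Path,
    species_labels: Iterable[str] = (),
) -> None:
    """Write the single-file relational store for a pipeline run.

    Family member ids may be mangled ``<transcript>_<species>``; they are
    demangled against *species_labels* before transcript lookup.
    """
    labels = list(species_labels)

    def transcript_of(member_id: str) -> str:
        tid = member_id
        if labels:
            try:
                tid, _ = demangle_id(member_id, labels)
            except Exception:
                tid = member_id
        if tid not in store_in.by_id or store_in.by_id[tid].ftype != "transcript":
            raise StoreError(f"family member {member_id!r}: no transcript {tid!r} in store")
        return tid

    seen_fids = set()
    for fam in families:
        if fam.family_id in seen_fids:
            raise StoreError(f"duplicate family_id {fam.family_id}")
        seen_fids.add(fam.family_id)

    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        con.executescript(_SCHEMA)
        con.execute("INSERT INTO meta VALUES ('schema_version', ?)", (SCHEMA_VERSION,))
        for gene in store_in.genes():
            con.execute(
                "INSERT INTO gene VALUES (?,?,?,?,?,?,?)",
                (
                    gene.feature_id,
                    gene.feature_id,
                    gene.species,
                    gene.chrom,
                    gene.start,
                    gene.end,
                    gene.strand,
                ),
            )
            for tr in store_in.transcripts_of(gene.feature_id):
                con.execute(
                    "INSERT INTO transcript VALUES (?,?,?,?)",
                    (tr.feature_id, gene.feature_id, tr.start, tr.end),
                )
                for ex in store_in.exons_of(tr.feature_id):
                    con.execute(
                        "INSERT INTO exon VALUES (?,?,?,?,?)",
                        (ex.feature_id, tr.feature_id, ex.rank, ex.start, ex.end),
                    )
                for seg in store_in.cds_segments_of(tr.feature_id):
                    con.execute(
                        "INSERT INTO cds_segment VALUES (?,?,?,?)",
                        (tr.feature_id, seg.rank, seg.start, seg.end),
                    )
        for fam in families:
            con.execute(
                "INSERT INTO gene_family VALUES (?,?)", (fam.family_id, fam.newick)
            )
            for member_id, cigar in fam.members:
                con.execute(
                    "INSERT INTO family_member VALUES (?,?,?)",
                    (fam.family_id, transcript_of(member_id), cigar),
                )
        con.commit()
    finally:
        con.close()


def find_orphans(
    all_cds_ids: list[str],
    edges: list[WeightedEdge],
    discarded_ids: list[str],
    cds: list[SequenceRecord],
) -> list[SequenceRecord]:
    """Sequences outside every family: graph-absent plus size-filtered ids.

    Orphans are ids from the input CDS that appear in neither column of
    the edge list, united with the ids discarded by the cluster size
    filter; duplicates collapse, output sorted by id.
    """
    in_graph = {e.a for e in edges} | {e.b for e in edges}
    orphan_ids = sorted((set(all_cds_ids) - in_graph) | set(discarded_ids))
    return subset_fasta(cds, orphan_ids, strict=False)
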
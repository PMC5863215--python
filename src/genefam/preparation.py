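"""Input preparation: FASTA/GFF3 ingest, header mangling, longest-CDS selection.

Coding sequences arrive as one FASTA per species and one GFF3 of gene
features per species.  Before any cross-species comparison, transcript
identifiers are made globally unique by appending a sanitized species
label, and each gene is reduced to its single longest CDS so that one
sequence represents one gene throughout the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


class PreparationError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class SequenceRecord:
    """One nucleotide or peptide sequence with identifier and species label."""

    id: str
    seq: str
    species: str = ""
    moltype: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise PreparationError(f"invalid sequence id: {self.id!r}")
        if not self.seq:
            raise PreparationError(f"empty sequence for id {self.id!r}")
        alphabet = NT_ALPHABET if self.moltype == "nt" else AA_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise PreparationError(
                f"illegal {self.moltype} characters {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FeatureRecord:
    """One gene/transcript/exon/CDS-segment feature, 1-based inclusive coords."""

    feature_id: str
    ftype: str  # gene | transcript | exon | cds_segment
    species: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_id: str = ""
    rank: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise PreparationError(
                f"feature {self.feature_id!r}: end {self.end} < start {self.start}"
            )
        if self.strand not in "+-":
            raise PreparationError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")


class FeatureStore:
    """Indexed gene/transcript/exon/CDS features with referential closure.

    CDS segments are stored keyed by transcript; their ``rank`` runs 1..k
    in 5'-to-3' order along the transcript.
    """

    def __init__(self, features: Iterable[FeatureRecord] = ()) -> None:
        self.by_id: dict[str, FeatureRecord] = {}
        self.children: dict[str, list[FeatureRecord]] = {}
        for f in features:
            self.add(f)

    def add(self, f: FeatureRecord) -> None:
        if f.ftype in ("gene", "transcript"):
            if f.feature_id in self.by_id:
                raise PreparationError(f"duplicate feature id {f.feature_id!r}")
            self.by_id[f.feature_id] = f
        if f.parent_id:
            if f.parent_id not in self.by_id:
                raise PreparationError(
                    f"feature {f.feature_id!r} has unresolvable Parent {f.parent_id!r}"
                )
            self.children.setdefault(f.parent_id, []).append(f)

    def genes(self) -> list[FeatureRecord]:
        return sorted(
            (f for f in self.by_id.values() if f.ftype == "gene"),
            key=lambda f: f.feature_id,
        )

    def transcripts_of(self, gene_id: str) -> list[FeatureRecord]:
        return sorted(
            (f for f in self.children.get(gene_id, []) if f.ftype == "transcript"),
            key=lambda f: f.feature_id,
        )

    def cds_segments_of(self, transcript_id: str) -> list[FeatureRecord]:
        segs = [f for f in self.children.get(transcript_id, []) if f.ftype == "cds_segment"]
        return sorted(segs, key=lambda f: f.rank)

    def exons_of(self, transcript_id: str) -> list[FeatureRecord]:
        exs = [f for f in self.children.get(transcript_id, []) if f.ftype == "exon"]
        return sorted(exs, key=lambda f: f.rank)

    def gene_of_transcript(self, transcript_id: str) -> FeatureRecord:
        t = self.by_id.get(transcript_id)
        if t is None or t.ftype != "transcript":
            raise PreparationError(f"no transcript {transcript_id!r} in feature store")
        return self.by_id[t.parent_id]

    def validate(self) -> None:
        """Check referential closure and consecutive CDS ranks per transcript."""
        for fid, f in self.by_id.items():
            if f.parent_id and f.parent_id not in self.by_id:
                raise PreparationError(f"feature {fid!r}: dangling parent {f.parent_id!r}")
        for f in self.by_id.values():
            if f.ftype != "transcript":
                continue
            ranks = [s.rank for s in self.cds_segments_of(f.feature_id)]
            if ranks and ranks != list(range(1, len(ranks) + 1)):
                raise PreparationError(
                    f"transcript {f.feature_id!r}: CDS ranks {ranks} not consecutive from 1"
                )


def read_fasta(path: str | Path, moltype: str = "nt", species: str = "") -> list[SequenceRecord]:
    """Read a FASTA file; ids are the first whitespace-delimited header token.

    Sequences are uppercased on ingest.  Duplicate ids and characters
    outside the IUPAC alphabet for *moltype* are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise PreparationError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, seq=str(rec.seq).upper(), species=species, moltype=moltype)
        )
    if not records:
        raise PreparationError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


_GFF3_TYPE_MAP = {"gene": "gene", "mRNA": "transcript", "exon": "exon", "CDS": "cds_segment"}


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, val = item.partition("=")
        attrs[key.strip()] = val.strip()
    return attrs


def read_gff3(path: str | Path, species: str) -> list[FeatureRecord]:
    """Parse gene/mRNA/exon/CDS lines of a GFF3 file into FeatureRecords.

    Only the ID, Parent and Name attributes are interpreted.  CDS and exon
    ranks are assigned 1..k in 5'-to-3' transcript order (ascending start
    on '+', descending start on '-').  Coordinates stay 1-based inclusive.
    """
    raw: list[tuple[str, str, str, str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise PreparationError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _, ftype, start, end, _, strand, _, col9 = cols
            if ftype not in _GFF3_TYPE_MAP:
                continue
            attrs = _parse_attributes(col9)
            fid = attrs.get("ID", "")
            parent = attrs.get("Parent", "")
            if not fid:
                fid = f"{ftype.lower()}:{parent}:{start}"
            raw.append((fid, _GFF3_TYPE_MAP[ftype], parent, chrom, int(start), int(end), strand))

    declared = {fid for fid, ftype, *_ in raw if ftype in ("gene", "transcript")}
    features: list[FeatureRecord] = []
    sub_by_parent: dict[tuple[str, str], list[tuple]] = {}
    for fid, ftype, parent, chrom, start, end, strand in raw:
        if ftype in ("gene", "transcript"):
            if ftype == "transcript" and parent not in declared:
                raise PreparationError(f"transcript {fid!r}: unresolvable Parent {parent!r}")
            features.append(
                FeatureRecord(fid, ftype, species, chrom, start, end, strand, parent_id=parent)
            )
        else:
            if parent not in declared:
                raise PreparationError(f"{ftype} feature: unresolvable Parent {parent!r}")
            sub_by_parent.setdefault((parent, ftype), []).append(
                (fid, chrom, start, end, strand)
            )
    for (parent, ftype), segs in sorted(sub_by_parent.items()):
        minus = segs[0][4] == "-"
        segs.sort(key=lambda s: s[2], reverse=minus)
        for rank, (fid, chrom, start, end, strand) in enumerate(segs, 1):
            features.append(
                FeatureRecord(
                    f"{fid}.{rank}" if ftype == "cds_segment" else fid,
                    ftype, species, chrom, start, end, strand,
                    parent_id=parent, rank=rank,
                )
            )
    return features


def sanitize_species(label: str) -> str:
    """Lowercase, spaces to underscores, other non-alphanumerics dropped."""
    out = re.sub(r"[^a-z0-9_ ]", "", label.lower()).replace(" ", "_")
    return re.sub(r"_+", "_", out).strip("_")


def mangle_headers(records: list[SequenceRecord], species: str) -> list[SequenceRecord]:
    """Append the sanitized species label to every sequence id.

    ``ENST0001`` + ``homo_sapiens`` becomes ``ENST0001_homo_sapiens``; the
    original id is recoverable with :func:`demangle_id`.
    """
    label = sanitize_species(species)
    if not label:
        raise PreparationError(f"empty species label after sanitization: {species!r}")
    out = []
    seen: set[str] = set()
    for r in records:
        new_id = f"{r.id}_{label}"
        if new_id in seen:
            raise PreparationError(f"header mangling collision on {new_id!r}")
        seen.add(new_id)
        out.append(replace(r, id=new_id, species=label))
    return out


def demangle_id(mangled: str, species_labels: Iterable[str]) -> tuple[str, str]:
    """Split a mangled id back into (original id, species label).

    Species labels may themselves contain underscores, so the longest
    matching label suffix wins.
    """
    best = ""
    for label in species_labels:
        if mangled.endswith("_" + label) and len(label) > len(best):
            best = label
    if not best:
        raise PreparationError(f"id {mangled!r} matches no declared species label")
    return mangled[: -(len(best) + 1)], best


def select_longest_cds(
    cds: list[SequenceRecord],
    store: FeatureStore,
    species_labels: Iterable[str] | None = None,
) -> list[SequenceRecord]:
    """Keep exactly one CDS per gene: the longest, ties to the smallest id.

    Record ids may be mangled (``<transcript>_<species>``); they are
    demangled against *species_labels* before lookup in the store.
    """
    labels = list(species_labels or [])
    by_gene: dict[str, list[SequenceRecord]] = {}
    for r in cds:
        tid = r.id
        if labels:
            try:
                tid, _ = demangle_id(r.id, labels)
            except PreparationError:
                pass
        gene = store.gene_of_transcript(tid)
        by_gene.setdefault(gene.feature_id, []).append(r)
    kept = []
    for gene_id in sorted(by_gene):
        candidates = by_gene[gene_id]
        candidates.sort(key=lambda r: (-len(r.seq), r.id))
        kept.append(candidates[0])
    return kept
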
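"""CDS translation and codon-aware back-translation.

Translation uses the standard nuclear genetic code only (the pipeline's
validation species are vertebrates).  Back-translation expands a gapped
protein alignment row to codons so that downstream distance and tree
computations can run in nucleotide space.
"""

from __future__ import annotations

from dataclasses import replace

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .preparation import SequenceRecord

STOP_CODONS = frozenset(CodonTable.unambiguous_dna_by_id[1].stop_codons)


class TranslationError(ValueError):
    pass


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def _translate_codon(codon: str) -> str:
    # N-containing codons translate to X unless the ambiguity is resolvable.
    if codon in STOP_CODONS:
        return "*"
    try:
        aa = str(Seq(codon).translate(table=1))
    except Exception:
        return "X"
    return aa


def translate_cds(rec: SequenceRecord, frame: int = 1) -> SequenceRecord:
    """Translate one of the six reading frames of a nucleotide record.

    Frames 1-3 are forward-strand offsets 0-2; frames 4-6 the same offsets
    on the reverse complement.  A trailing partial codon is dropped and a
    single terminal stop is stripped; internal stops are kept as ``*``.
    """
    if rec.moltype != "nt":
        raise TranslationError(f"record {rec.id!r} is not nucleotide")
    if frame not in range(1, 7):
        raise TranslationError(f"frame must be 1..6, got {frame}")
    seq = rec.seq if frame <= 3 else str(Seq(rec.seq).reverse_complement())
    seq = seq[(frame - 1) % 3 :]
    codons = _codons(seq)
    if not codons:
        raise TranslationError(f"record {rec.id!r}: no complete codon in frame {frame}")
    aa = "".join(_translate_codon(c) for c in codons)
    if aa.endswith("*"):
        aa = aa[:-1]
    if not aa:
        raise TranslationError(f"record {rec.id!r}: translation empty in frame {frame}")
    return replace(rec, seq=aa, moltype="aa")


def has_internal_stop(rec: SequenceRecord) -> bool:
    """True if frame-1 translation contains a stop before the final codon."""
    codons = _codons(rec.seq)
    return any(c in STOP_CODONS for c in codons[:-1])


def six_frame(rec: SequenceRecord) -> list[SequenceRecord]:
    """All six frame translations, ids suffixed ``_1`` .. ``_6``."""
    out = []
    for frame in range(1, 7):
        t = translate_cds(rec, frame)
        out.append(replace(t, id=f"{rec.id}_{frame}"))
    return out


def back_translate_alignment(prot_aln, cds: list[SequenceRecord]):
    """Expand a protein alignment to a codon alignment using the source CDS.

    Each residue column becomes its source codon, each gap becomes ``---``.
    A terminal stop codon on the CDS is dropped (it has no aligned residue).
    The frame-1 translation of each CDS must match its degapped protein row.
    """
    from .msa import CodonAlignment  # local import to avoid a cycle

    cds_by_id = {r.id: r for r in cds}
    rows: dict[str, str] = {}
    for sid, prow in prot_aln.rows.items():
        rec = cds_by_id.get(sid)
        if rec is None:
            raise TranslationError(f"no CDS provided for aligned id {sid!r}")
        if has_internal_stop(rec):
            raise TranslationError(f"CDS {sid!r} contains an internal stop codon")
        codons = _codons(rec.seq)
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        residues = prow.replace("-", "")
        if len(codons) != len(residues):
            raise TranslationError(
                f"CDS {sid!r}: {len(codons)} codons vs {len(residues)} aligned residues"
            )
        for i, (codon, res) in enumerate(zip(codons, residues)):
            if _translate_codon(codon) != res:
                raise TranslationError(
                    f"CDS {sid!r}: translation mismatch at residue index {i} "
                    f"(codon {codon} vs residue {res})"
                )
        it = iter(codons)
        rows[sid] = "".join("---" if c == "-" else next(it) for c in prow)
    return CodonAlignment(rows)
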
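"""Synthetic gene families for end-to-end testing without downloads.

The generator emulates the pipeline's validation setting: a handful of
mutually dissimilar gene families evolved over a known species tree.
Families start from independent random root CDS (uniform sense codons),
so between-family similarity is at chance level while within-family
similarity stays high at the default divergence.  Evolution down the
tree applies per-site nucleotide substitutions (resampled whenever they
would create an internal stop), codon-length indels, and optional whole
-gene duplications and losses per branch.  Output is exactly what the
pipeline consumes — per-species CDS FASTA and GFF3 plus a Newick species
tree — along with a tab-separated truth table of family memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetree import Node, SpeciesTree
from .preparation import SequenceRecord
from .translate import STOP_CODONS

_BASES = "ACGT"
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions; defaults mirror the desk-scale validation run."""

    n_species: int = 6
    n_families: int = 3
    root_cds_length: int = 300  # nucleotides, multiple of 3 (100 codons)
    subs_per_site: float = 0.05  # expected substitutions per site per unit branch
    indel_rate: float = 0.01  # codon indel events per codon per unit branch
    dup_prob: float = 0.0  # whole-gene duplication probability per branch
    loss_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_cds_length % 3:
            raise SimulationError("root_cds_length must be a multiple of 3")
        for p in (self.dup_prob, self.loss_prob):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class TruthRow:
    seq_id: str  # mangled id as it flows through the pipeline
    transcript_id: str
    species: str
    family: int
    duplications: int  # duplication events on this gene's lineage


@dataclass
class SimulatedData:
    species_tree: SpeciesTree
    cds_by_species: dict[str, list[SequenceRecord]]
    gff3_by_species: dict[str, str]
    truth: list[TruthRow] = field(default_factory=list)

    def truth_families(self) -> dict[str, int]:
        return {row.seq_id: row.family for row in self.truth}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA/GFF3 per species, the species tree, and the truth table."""
        from .preparation import write_fasta

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for sp, records in self.cds_by_species.items():
            fasta = outdir / f"{sp}.cds.fasta"
            write_fasta(records, fasta)
            gff = outdir / f"{sp}.gff3"
            gff.write_text(self.gff3_by_species[sp])
            paths[f"fasta:{sp}"] = fasta
            paths[f"gff3:{sp}"] = gff
        tree_path = outdir / "species_tree.nwk"
        tree_path.write_text(self.species_tree.to_newick() + "\n")
        paths["species_tree"] = tree_path
        truth_path = outdir / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("seq_id\ttranscript_id\tspecies\tfamily\tduplications\n")
            for row in self.truth:
                fh.write(
                    f"{row.seq_id}\t{row.transcript_id}\t{row.species}\t"
                    f"{row.family}\t{row.duplications}\n"
                )
        paths["truth"] = truth_path
        return paths


def simulate_species_tree(n_species: int, seed: int = 0) -> SpeciesTree:
    """Yule (pure-birth) tree with unit-normalized height; leaves sp1..spN."""
    if n_species < 2:
        raise SimulationError("need at least 2 species")
    rng = np.random.default_rng(seed)
    # grow by splitting a uniformly chosen leaf; branch spans grow with
    # exponential waiting times, then depths are normalized to height 1
    root = Node(name="")
    root_birth = 0.0
    leaves: list[tuple[Node, float]] = [(root, root_birth)]
    t = 0.0
    while len(leaves) < n_species:
        t += float(rng.exponential(1.0 / len(leaves)))
        idx = int(rng.integers(len(leaves)))
        node, birth = leaves.pop(idx)
        node.length = t - birth if node is not root else None
        left, right = Node(), Node()
        node.children = [left, right]
        leaves.append((left, t))
        leaves.append((right, t))
    t += float(rng.exponential(1.0 / len(leaves)))
    height = t if t > 0 else 1.0
    for leaf, birth in leaves:
        leaf.length = t - birth
    # name leaves deterministically left-to-right
    for i, leaf in enumerate(root.leaves(), 1):
        leaf.name = f"sp{i}"
    for node in root.postorder():
        if node.length is not None:
            node.length = node.length / height
    return SpeciesTree(root)


def _random_root_cds(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = length_nt // 3
    idx = rng.integers(len(_SENSE_CODONS), size=n_codons)
    codons = [_SENSE_CODONS[i] for i in idx]
    codons[0] = "ATG"
    return "".join(codons)


def _mutate(seq: str, branch: float, params: SimParams, rng: np.random.Generator) -> str:
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    # substitutions: per-site Bernoulli, resampled if a stop would arise
    p = min(params.subs_per_site * branch, 1.0)
    if p > 0:
        for ci in range(len(codons)):
            codon = list(codons[ci])
            changed = False
            for k in range(3):
                if rng.random() < p:
                    codon[k] = _BASES[int(rng.integers(4))]
                    changed = True
            if changed:
                new = "".join(codon)
                if new in STOP_CODONS:
                    new = _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))]
                codons[ci] = new
    # codon-preserving indels
    n_events = rng.poisson(params.indel_rate * branch * len(codons))
    for _ in range(int(n_events)):
        size = int(rng.integers(1, 4))  # 1-3 codons
        if rng.random() < 0.5 and len(codons) > size + 2:
            start = int(rng.integers(1, len(codons) - size))
            del codons[start : start + size]
        else:
            insert = [
                _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))] for _ in range(size)
            ]
            at = int(rng.integers(1, len(codons)))
            codons[at:at] = insert
    return "".join(codons)


@dataclass
class _Lineage:
    seq: str
    copy_index: int
    duplications: int


def simulate_families(sp: SpeciesTree, params: SimParams) -> SimulatedData:
    """Evolve ``n_families`` independent families down the species tree.

    Each surviving lineage at a leaf becomes one gene with a single
    transcript and a single-exon CDS; coordinates in the emitted GFF3
    are synthetic but self-consistent.  The truth table records the
    family and the number of duplication events per gene.
    """
    rng = np.random.default_rng(params.seed + 1)
    genes_by_species: dict[str, list[tuple[int, _Lineage]]] = {
        leaf: [] for leaf in sp.root.leaf_names()
    }

    for fam in range(1, params.n_families + 1):
        root_seq = _random_root_cds(rng, params.root_cds_length)
        counter = [0]

        def evolve(node: Node, lineages: list[_Lineage]) -> None:
            branch = node.length or 0.0
            survivors: list[_Lineage] = []
            for lin in lineages:
                if node is not sp.root and params.loss_prob and rng.random() < params.loss_prob:
                    continue
                seq = _mutate(lin.seq, branch, params, rng)
                copies = [_Lineage(seq, lin.copy_index, lin.duplications)]
                if node is not sp.root and params.dup_prob and rng.random() < params.dup_prob:
                    counter[0] += 1
                    copies.append(_Lineage(seq, counter[0], lin.duplications + 1))
                    copies[0] = _Lineage(seq, lin.copy_index, lin.duplications + 1)
                survivors.extend(copies)
            if node.is_leaf():
                for lin in survivors:
                    genes_by_species[node.name].append((fam, lin))
            else:
                for child in node.children:
                    evolve(child, [ _Lineage(l.seq, l.copy_index, l.duplications) for l in survivors])

        evolve(sp.root, [_Lineage(root_seq, 0, 0)])

    cds_by_species: dict[str, list[SequenceRecord]] = {}
    gff3_by_species: dict[str, str] = {}
    truth: list[TruthRow] = []
    for species in sorted(genes_by_species):
        records = []
        gff_lines = ["##gff-version 3"]
        offset = 1000
        for fam, lin in genes_by_species[species]:
            # ids are globally unique across species, like real accessions
            suffix = f"c{lin.copy_index}" if lin.copy_index else "0"
            gene_id = f"{species}f{fam}g{suffix}"
            tid = f"{species}f{fam}t{suffix}"
            seq = lin.seq
            start, end = offset, offset + len(seq) - 1
            offset = end + 1000
            gff_lines.append(
                f"chr1\tsim\tgene\t{start}\t{end}\t.\t+\t.\tID={gene_id}"
            )
            gff_lines.append(
                f"chr1\tsim\tmRNA\t{start}\t{end}\t.\t+\t.\tID={tid};Parent={gene_id}"
            )
            gff_lines.append(
                f"chr1\tsim\texon\t{start}\t{end}\t.\t+\t.\tID={tid}.e1;Parent={tid}"
            )
            gff_lines.append(
                f"chr1\tsim\tCDS\t{start}\t{end}\t.\t+\t.\tID={tid}.cds;Parent={tid}"
            )
            records.append(SequenceRecord(id=tid, seq=seq, species=species, moltype="nt"))
            truth.append(
                TruthRow(
                    seq_id=f"{tid}_{species}",
                    transcript_id=tid,
                    species=species,
                    family=fam,
                    duplications=lin.duplications,
                )
            )
        cds_by_species[species] = records
        gff3_by_species[species] = "\n".join(gff_lines) + "\n"
    return SimulatedData(sp, cds_by_species, gff3_by_species, truth)
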
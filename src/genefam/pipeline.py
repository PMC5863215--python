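"""End-to-end orchestration: prepare → translate → search → cluster →
align → back-translate → trees → aggregate → orphans.

Every intermediate is persisted in its standard text format inside the
run directory, and a JSON manifest records the configuration, the seed
and per-stage record counts, so a rerun with the same inputs and seed
reproduces byte-identical text outputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import __version__
from .edge_weights import parse_hits, read_edges, write_edges
from .genetree import (
    SpeciesTree,
    build_candidate_trees,
    leaf_species_map,
    select_and_root,
    write_nhx,
)
from .msa import align_family, write_fasta_aln
from .preparation import (
    FeatureStore,
    SequenceRecord,
    mangle_headers,
    read_fasta,
    read_gff3,
    sanitize_species,
    select_longest_cds,
)
from .simsearch import SearchParams, all_vs_all, write_tabular12
from .sparse_cluster import (
    Cluster,
    ClusterParams,
    hcluster,
    split_and_filter,
    subset_fasta,
)
from .store import FamilyRecord, aggregate, find_orphans, msa_to_cigar
from .translate import back_translate_alignment, translate_cds


class PipelineError(RuntimeError):
    pass


#: Parameter presets A-F: (evalue cutoff, query coverage, min edge weight,
#: min edge density).  All presets share max_hsps=1, no single-link
#: clustering, and max cluster size 500.  Preset D is the default.
PRESETS: dict[str, tuple[float, float, int, float]] = {
    "A": (1e-03, 0.0, 0, 0.34),
    "B": (1e-03, 0.0, 20, 0.50),
    "C": (1e-03, 90.0, 0, 0.34),
    "D": (1e-10, 0.0, 0, 0.34),
    "E": (1e-10, 0.0, 20, 0.50),
    "F": (1e-10, 90.0, 20, 0.50),
}


@dataclass(frozen=True)
class PipelineConfig:
    """One pipeline run: inputs, output directory and all stage knobs."""

    fasta_by_species: dict[str, str]
    gff3_by_species: dict[str, str]
    species_tree: str
    outdir: str
    preset: str = "D"
    search: SearchParams | None = None
    cluster: ClusterParams | None = None
    rbh_only: bool = False
    longest_cds_only: bool = True
    seed: int = 0

    def resolved(self) -> tuple[SearchParams, ClusterParams]:
        if self.preset not in PRESETS:
            raise PipelineError(f"unknown preset {self.preset!r}; choose one of A-F")
        ev, qcov, minw, dens = PRESETS[self.preset]
        search = self.search or SearchParams(evalue_cutoff=ev, qcov_cutoff=qcov, max_hsps=1)
        cluster = self.cluster or ClusterParams(
            min_edge_weight=minw, min_density=dens, max_size=500, single_link=False
        )
        return search, cluster


def expand_preset(name: str) -> tuple[SearchParams, ClusterParams]:
    """SearchParams and ClusterParams for one of the presets A-F."""
    if name not in PRESETS:
        raise PipelineError(f"unknown preset {name!r}; choose one of A-F")
    ev, qcov, minw, dens = PRESETS[name]
    return (
        SearchParams(evalue_cutoff=ev, qcov_cutoff=qcov, max_hsps=1),
        ClusterParams(min_edge_weight=minw, min_density=dens, max_size=500, single_link=False),
    )


def _log(msg: str) -> None:
    print(f"[genefam] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory.

    Raises :class:`PipelineError` naming the failing stage and record.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    search_params, cluster_params = config.resolved()
    counts: dict[str, int] = {}

    def stage(name):
        _log(f"stage: {name}")

    try:
        stage("prepare")
        sp_tree = SpeciesTree.from_file(config.species_tree)
        features = FeatureStore()
        cds: list[SequenceRecord] = []
        labels = []
        for species in sorted(config.fasta_by_species):
            label = sanitize_species(species)
            labels.append(label)
            for f in read_gff3(config.gff3_by_species[species], label):
                features.add(f)
            recs = read_fasta(config.fasta_by_species[species], moltype="nt")
            cds.extend(mangle_headers(recs, label))
        features.validate()
        if config.longest_cds_only:
            cds = select_longest_cds(cds, features, labels)
        if not cds:
            raise PipelineError("prepare: no CDS records")
        from .preparation import write_fasta

        write_fasta(cds, outdir / "cds.fasta")
        counts["cds"] = len(cds)

        stage("translate")
        proteins = [translate_cds(r, frame=1) for r in cds]
        write_fasta(proteins, outdir / "proteins.fasta")

        stage("search")
        hits = all_vs_all(proteins, search_params)
        write_tabular12(hits, outdir / "hits.tsv")
        counts["hits"] = len(hits)

        stage("parse-hits")
        edges = parse_hits(hits, rbh_only=config.rbh_only)
        write_edges(edges, outdir / "edges.tsv")
        counts["edges"] = len(edges)

        stage("cluster")
        clusters = hcluster(edges, cluster_params)
        kept, discarded_ids = split_and_filter(clusters, cluster_params)
        with open(outdir / "clusters.tsv", "w") as fh:
            for members in kept:
                fh.write("\t".join(members) + "\n")
        (outdir / "discarded_ids.txt").write_text(
            "".join(i + "\n" for i in discarded_ids)
        )
        counts["families"] = len(kept)
        counts["discarded_ids"] = len(discarded_ids)

        species_of = leaf_species_map([r.id for r in cds], labels)
        families: list[FamilyRecord] = []
        famdir = outdir / "families"
        famdir.mkdir(exist_ok=True)
        for fam_idx, members in enumerate(kept, 1):
            stage(f"family {fam_idx} ({len(members)} members)")
            fam_prot = subset_fasta(proteins, members)
            fam_cds = subset_fasta(cds, members)
            prot_aln = align_family(fam_prot)
            write_fasta_aln(prot_aln, famdir / f"family{fam_idx}.prot.fasta_aln")
            codon_aln = back_translate_alignment(prot_aln, fam_cds)
            write_fasta_aln(codon_aln, famdir / f"family{fam_idx}.codon.fasta_aln")
            candidates = build_candidate_trees(codon_aln, prot_aln)
            tree = select_and_root(candidates, sp_tree, species_of)
            write_nhx(tree, famdir / f"family{fam_idx}.nhx")
            families.append(
                FamilyRecord(
                    family_id=fam_idx,
                    newick=tree.to_newick(nhx=True),
                    members=[(m, msa_to_cigar(prot_aln.rows[m])) for m in members],
                )
            )

        stage("aggregate")
        aggregate(families, features, outdir / "families.sqlite", labels)

        stage("orphans")
        orphans = find_orphans([r.id for r in cds], edges, discarded_ids, cds)
        write_fasta(orphans, outdir / "orphans.fasta")
        counts["orphans"] = len(orphans)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{exc}") from exc

    manifest = {
        "version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "search": asdict(search_params),
        "cluster": asdict(cluster_params),
        "rbh_only": config.rbh_only,
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def family_stats(clusters: list[list[str]]) -> dict[str, float]:
    """Summary numbers for a clustering: counts by size class and means."""
    sizes = [len(c) for c in clusters]
    return {
        "families": len(sizes),
        "larger_than_200": sum(1 for s in sizes if s > 200),
        "smaller_than_3": sum(1 for s in sizes if s < 3),
        "largest": max(sizes) if sizes else 0,
        "mean_size": round(sum(sizes) / len(sizes), 2) if sizes else 0.0,
    }
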
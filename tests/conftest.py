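from __future__ import annotations

import pytest

from genefam.preparation import (
    FeatureRecord,
    FeatureStore,
    SequenceRecord,
)
from genefam.simulate import SimParams, simulate_families, simulate_species_tree


@pytest.fixture
def tiny_store() -> FeatureStore:
    """Two genes, three transcripts, with exons and CDS segments."""
    store = FeatureStore()
    feats = [
        FeatureRecord("g1", "gene", "spx", "chr1", 100, 2000, "+"),
        FeatureRecord("t1a", "transcript", "spx", "chr1", 100, 1500, "+", parent_id="g1"),
        FeatureRecord("t1b", "transcript", "spx", "chr1", 100, 2000, "+", parent_id="g1"),
        FeatureRecord("g2", "gene", "spx", "chr1", 5000, 6000, "-"),
        FeatureRecord("t2", "transcript", "spx", "chr1", 5000, 6000, "-", parent_id="g2"),
        FeatureRecord("t1a.e1", "exon", "spx", "chr1", 100, 400, "+", parent_id="t1a", rank=1),
        FeatureRecord("t1a.c1", "cds_segment", "spx", "chr1", 100, 400, "+", parent_id="t1a", rank=1),
        FeatureRecord("t1b.c1", "cds_segment", "spx", "chr1", 100, 700, "+", parent_id="t1b", rank=1),
        FeatureRecord("t2.c1", "cds_segment", "spx", "chr1", 5500, 6000, "-", parent_id="t2", rank=1),
        FeatureRecord("t2.c2", "cds_segment", "spx", "chr1", 5000, 5400, "-", parent_id="t2", rank=2),
    ]
    for f in feats:
        store.add(f)
    return store


@pytest.fixture(scope="session")
def sim_default():
    """The default simulated dataset: 3 families, 6 species, no dup/loss."""
    sp = simulate_species_tree(6, seed=11)
    return simulate_families(sp, SimParams(seed=11))


@pytest.fixture(scope="session")
def sim_run_dir(sim_default, tmp_path_factory):
    d = tmp_path_factory.mktemp("simdata")
    sim_default.write(d)
    return d


@pytest.fixture(scope="session")
def pipeline_run(sim_default, sim_run_dir, tmp_path_factory):
    """One full preset-D pipeline run over the default simulated dataset."""
    from genefam.pipeline import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("pipeline") / "run"
    species = sorted(sim_default.cds_by_species)
    config = PipelineConfig(
        fasta_by_species={s: str(sim_run_dir / f"{s}.cds.fasta") for s in species},
        gff3_by_species={s: str(sim_run_dir / f"{s}.gff3") for s in species},
        species_tree=str(sim_run_dir / "species_tree.nwk"),
        outdir=str(outdir),
        preset="D",
        seed=11,
    )
    return run_pipeline(config)


def nt_record(id: str, seq: str, species: str = "") -> SequenceRecord:
    return SequenceRecord(id=id, seq=seq, species=species, moltype="nt")


def aa_record(id: str, seq: str, species: str = "") -> SequenceRecord:
    return SequenceRecord(id=id, seq=seq, species=species, moltype="aa")
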
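# genefam

Desk-scale gene-family discovery from coding sequences, in the style of
the Ensembl Compara GeneTrees workflow: starting from per-species CDS
FASTA and GFF3 annotation plus a species tree, `genefam` derives
clustered gene families, per-family protein and codon alignments,
species-tree-reconciled gene trees with speciation/duplication
annotations, and a single-file relational store of families,
CIGAR-encoded alignments and gene features — along with the orphan
genes left outside every family.

It is a library plus a thin CLI, written for comparative genomicists
who want the whole chain runnable, auditable and testable on a laptop,
with every intermediate persisted in a standard text format (12-column
similarity tables, 3-column edge lists, aligned FASTA, NHX Newick,
SQLite).

## The method

1. **Prepare** — transcript ids are made globally unique by appending a
   sanitized species label (`ENST0001` → `ENST0001_homo_sapiens`), and
   each gene is reduced to its longest CDS.
2. **Translate** — frame-1 translation under the standard genetic code
   (six-frame translation is available); terminal stops are stripped.
3. **Search** — all-vs-all exact Smith–Waterman local alignment
   (BLOSUM62, affine gaps 11/1), with bit scores
   S' = (λS − ln K)/ln 2 and e-values E = mn·2^(−S') under pinned
   Karlin–Altschul constants (λ = 0.267, K = 0.041), emitting the
   familiar 12-column tabular format. Externally produced 12-column
   files are accepted verbatim.
4. **Edge weights** — each surviving pair becomes an undirected edge of
   weight w = min(−log₁₀ E / 2, 100), rounded to an integer; self-matches
   are removed and an optional reciprocal-best-hit filter applies.
5. **Cluster** — greedy agglomeration on the sparse graph: repeatedly
   merge the cluster pair with the highest average cross-edge weight,
   subject to a minimum cross-edge density and a maximum cluster size
   (500); families with fewer than 3 genes are discarded (a gene tree
   needs at least 3 leaves). Six parameter presets A–F pair search
   cutoffs (e-value 1e-3/1e-10, query coverage 0/90) with clustering
   thresholds (min edge weight 0/20, min density 0.34/0.50); preset D
   (1e-10, 0, 0, 0.34) is the default.
6. **Align** — per-family progressive protein MSA (UPGMA guide tree,
   affine-gap profile–profile alignment, sum-of-pairs BLOSUM62), then
   codon-aware back-translation so each residue column becomes its
   source codon and each gap becomes `---`.
7. **Trees** — five candidate neighbor-joining trees per family
   (protein p-distance and Poisson-corrected distance; nucleotide
   p-distance and Jukes–Cantor distance; third-codon-position
   p-distance), each rooted on every edge and reconciled against the
   species tree by LCA mapping; the rooting minimizing (duplications,
   losses) wins. Internal nodes are labelled S (speciation) or D
   (duplication); D nodes carry DCS, the Jaccard overlap of the species
   sets under their two children. Trees serialize as NHX.
8. **Aggregate** — gene features, NHX trees and alignment rows encoded
   as CIGAR strings (`MK-R` → `2MDM`) go into one SQLite file with a
   `transcript_species` view; orphan genes (absent from the similarity
   graph, or in discarded clusters) are exported as FASTA.

A simulator (`genefam simulate`) generates gene families evolved over a
Yule species tree with per-branch substitutions, codon-preserving
indels and optional duplications/losses, emitting exactly the formats
the pipeline consumes plus a ground-truth table — so the whole chain is
testable without any downloads.

## Worked example

Simulate three mutually dissimilar families across six species, then
run the pipeline with preset D:

```sh
genefam simulate --n-species 6 --n-families 3 --seed 1 -o demo/sim
genefam run \
  $(for i in 1 2 3 4 5 6; do \
      echo --fasta sp$i=demo/sim/sp$i.cds.fasta --gff3 sp$i=demo/sim/sp$i.gff3; \
    done) \
  --species-tree demo/sim/species_tree.nwk --preset D --seed 1 -o demo/run
genefam stats demo/run/clusters.tsv
```

which prints

```
18 CDS simulated
{"cds": 18, "discarded_ids": 0, "edges": 45, "families": 3, "hits": 108, "orphans": 0}
families        3
larger_than_200 0
smaller_than_3  0
largest 6
mean_size       6.0
```

18 CDS (3 families × 6 species) produce 108 significant similarity
hits, 45 undirected edges, and exactly the 3 simulated families — none
discarded, no orphans. The reconciled gene tree for family 1,
`demo/run/families/family1.nhx`, mirrors the species tree with every
internal node a speciation (`D=N`):

```
(sp1f1t0_sp1:0.015[&&NHX:S=sp1],((sp2f1t0_sp2:0.01[&&NHX:S=sp2],(sp3f1t0_sp3:0[&&NHX:S=sp3],
sp4f1t0_sp4:0[&&NHX:S=sp4]):0[&&NHX:D=N:S=sp3.2]):0.003333[&&NHX:D=N:S=sp2.3],...
```

The aggregated store is `demo/run/families.sqlite` (tables `gene`,
`transcript`, `exon`, `cds_segment`, `gene_family`, `family_member`;
view `transcript_species`).

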
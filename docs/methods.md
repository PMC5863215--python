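# Methods

This note documents the models, algorithms and numerical conventions
behind `genefam`, the choices made where the design was genuinely open,
and what the synthetic benchmark does and does not demonstrate.

## Problem setting

Given coding sequences (one FASTA and one GFF3 per species) and a
rooted species tree, the pipeline infers gene families — sets of genes
descending from a single ancestral gene — and, per family, a protein
and codon alignment and a gene tree reconciled against the species
tree, so that every internal node is labelled as a speciation or a
duplication. The chain is: translate → all-vs-all similarity search →
similarity graph → sparse-graph clustering → per-family MSA →
back-translation → candidate trees → reconciliation-guided rooting and
selection → aggregation into a relational store.

## Identifier discipline

Transcript ids are made globally unique by appending a sanitized
species label (lowercase; spaces to underscores; other
non-alphanumerics dropped). The sanitization guarantees the mangled id
survives Newick/NHX and tab-separated formats unquoted. Because species
labels may themselves contain underscores, demangling matches the
*longest* declared label suffix; this is exact as long as no declared
label is a proper suffix of another declared label combined with an
id that ends in an underscore-joined fragment — in practice, as long
as declared labels are distinct full binomials. Coordinates stay
1-based inclusive (the GFF3 convention) from parsing to the SQLite
store; no half-open conversion happens anywhere.

## Similarity search

The search is an exact all-vs-all Smith–Waterman local alignment
(Bio.Align), BLOSUM62, affine gaps in the BLAST convention (a gap of
length k costs 11 + k). One best local alignment is kept per ordered
pair (the max_hsps = 1 setting). Raw scores S become bit scores
S' = (λS − ln K)/ln 2 with λ = 0.267, K = 0.041 (gapped BLOSUM62
defaults, pinned), and e-values E = m·n·2^(−S') with m the query length
and n the total database residue count. These constants are fixed for
reproducibility; absolute e-values will differ from any particular
BLAST build (no low-complexity masking, no composition-based
statistics, exact rather than seeded search). Stop codons in protein
sequences are mapped to X before scoring. Hits failing the e-value
cutoff or the per-HSP query-coverage cutoff are dropped. The 12-column
tabular format is read and written losslessly, so externally produced
similarity tables can be substituted for the native search.

## Edge weights and clustering

Edge weight: w = −log₁₀(E)/2, capped at 100, rounded half-up to an
integer, floored at 0; E = 0 (underflow) maps to 100, the limit of the
formula. Directional hits merge into one undirected edge using the
better of the two e-values; self-matches are removed; an optional
reciprocal-best-hit filter keeps a pair only when each member is the
other's best partner (lowest e-value, ties by higher bit score, then
lexicographic id).

Clustering is greedy agglomeration on the sparse graph. Starting from
singletons, the pair of clusters (X, Y) maximizing the average
cross-edge weight — the sum of surviving cross-edge weights divided by
|X|·|Y|, absent edges counting 0 — is merged, subject to (a) cross-edge
count / (|X|·|Y|) ≥ the minimum density and (b) |X| + |Y| ≤ the maximum
size (500). Ties break on higher cross-edge count, then on the
lexicographically smallest member-id pair, making the result
deterministic. The merge log is exposed so every accepted merge can be
audited against the constraints. A single-link mode takes connected
components of the thresholded graph instead, splitting oversized
components by repeatedly deleting the globally lightest edge. The
agglomeration objective and tie-breaks are this package's own
reconstruction of a sparse-graph hierarchical clusterer; it is
parameter-compatible with the classic tool but not guaranteed
output-identical. Clusters below 3 members are discarded (a gene tree
needs at least 3 leaves) and their ids feed the orphan set.

## Alignment

The per-family protein MSA is progressive: pairwise p-distances from
global pairwise alignments feed a UPGMA guide tree (scipy average
linkage over lexicographically ordered leaves), and profiles are merged
bottom-up with a Gotoh three-state profile–profile dynamic program
(gap open −10, extend −0.5; match columns scored as the mean BLOSUM62
sum over residue pairs, residue-vs-gap pairs scoring 0 inside match
columns). DP traceback prefers diagonal, then up, then left, so the
alignment is deterministic. This is a documented substitution for
consistency-based aligners: the contract preserved is "a protein MSA in
aligned-FASTA format per family", and externally produced alignments
are accepted verbatim. Back-translation expands each residue column to
its source codon and each gap to `---`; a terminal stop codon is
dropped (it has no aligned residue), and rows whose CDS contains an
internal stop are rejected rather than guessed at.

## Trees

Five candidate trees per family are built by neighbor joining
(scikit-bio) on five distance estimators: protein p-distance, Poisson
correction −ln(1−p), nucleotide p-distance, Jukes–Cantor
−(3/4)·ln(1−4p/3), and a synonymous proxy (p-distance restricted to
third codon positions). Gapped or ambiguous sites are deleted pairwise;
undefined corrections are clamped to a ceiling of 10 substitutions per
site; negative NJ branch lengths are clamped to 0. These five
estimators stand in for a mixed DNA/protein method portfolio at desk
scale: the DNA-based estimators dominate for closely related
sequences, the protein-based ones for distant ones, and the selection
step below arbitrates.

Each candidate is rooted on every edge (edge lengths split in half) and
reconciled against the species tree via the standard LCA mapping: node
v maps to the species-tree LCA of its leaf species; v is a duplication
iff it maps to the same species node as one of its children. Losses
use the path-depth count (speciation child: depth difference − 1;
duplication child: full depth difference). The (candidate, rooting)
pair minimizing (duplications, losses, total branch length, serialized
tree text) is selected — a deterministic minimum-reconciliation-cost
selection standing in for consensus merging, preserving the stated
objective of minimizing duplications and losses relative to the species
tree. Duplication nodes carry DCS = |species(left) ∩ species(right)| /
|species(left) ∪ species(right)|, the duplication consistency score in
its intersection-over-union form; DCS = 1 means both child clades span
identical species sets.

Species trees load from Newick or from an offline (label, parent)
taxonomy table; multifurcations are resolved deterministically
(children ordered by smallest leaf, folded left with zero-length
branches), unary taxonomy nodes collapse, and unnamed internal nodes
get the stable label `<smallest leaf>.<leaf count>` so every NHX
`S=` tag on internal nodes is defined. Gene trees serialize as NHX:
leaves `[&&NHX:S=<species>]`, internal nodes `[&&NHX:D=Y|N:S=<mapped
taxon>]` plus `:DCS=<float>` on duplications; floats print with up to
six decimals, and read∘write is the identity on structure, labels,
events and DCS.

## Aggregation and orphans

Alignment rows are stored as CIGAR strings: run-length encoding with
M for residues and D for gaps, count 1 omitted on write (both forms
accepted on read). Protein-space CIGARs are stored, since the consumer
is the protein MSA. The store is a single SQLite file — tables `gene`,
`transcript`, `exon`, `cds_segment`, `gene_family` (NHX text),
`family_member` (family, transcript, CIGAR), a `transcript_species`
view joining transcript → gene → species, foreign keys enforced, and a
schema-version row. Orphans are the input CDS ids absent from both
columns of the edge list, united with the ids discarded by the cluster
size filter, deduplicated and exported as FASTA.

## Synthetic data

The simulator emulates the desk-scale validation setting: a Yule
(pure-birth) species tree normalized to unit height, and independent
families seeded with random sense-codon root CDS (default 100 codons,
ATG-initiated). Defaults — 6 species, 3 families, 0.05 substitutions
per site per unit branch length, 0.01 codon-indel events per codon per
unit branch, no duplication or loss — give 18 genes in 3 families of 6,
the no-duplication analog of a published validation set of 23 genes in
3 families across 6 mammals (whose extra members are within-family
duplicates). Substitutions are per-site uniform with stop-codon
rejection; indels insert or delete 1–3 whole codons, so frame and
sense are preserved by construction. Duplications copy a whole lineage
with probability `dup_prob` per branch; losses drop it.

Because family roots are mutually random, between-family similarity is
at chance level and the clustering problem is easy by design: perfect
recovery (adjusted Rand index 1.0) on these fixtures demonstrates that
the plumbing — translation, search statistics, weighting, clustering,
per-family processing — is correct, *not* that the pipeline resolves
hard real-world cases (recent paralogs, domain shuffling, low-complexity
sequence, fragmented annotations). The simulator has no rate
heterogeneity, no empirical codon model and no synteny.

For the parameter-sensitivity check, a more divergent input (4
families, 0.5 substitutions per site, 0.05 indels per codon) is used so
the presets actually separate: the strict preset F (e-value 1e-10,
coverage 90, min weight 20, density 0.50) yields at least as many
families as the relaxed preset A (1e-3, 0, 0, 0.34), with smaller mean
size — the expected direction, since every preset F constraint is a
refinement of preset A's.

## Problem sizes and determinism

All shipped analyses run on simulated inputs of 18–24 sequences of
~100 codons; the full test suite completes in seconds and the
acceptance script in well under a minute on one CPU. Every stage is
deterministic for a fixed seed and input: sorted iteration orders,
explicit tie-breaks in clustering, DP traceback and tree selection, and
a single `numpy` generator seeded from the run seed. Reruns with the
same inputs and seed produce byte-identical text outputs (the manifest
records configuration, seed and per-stage counts).

## Known limitations

- E-values are internally consistent but not calibrated against any
  BLAST release; preset cutoffs therefore select slightly different
  hit sets than the original tools would.
- The clusterer and the tree-selection step are documented
  reconstructions, not behavioral clones, of the classic
  sparse-graph clusterer and consensus tree builder.
- Only the standard nuclear genetic code is supported; selenocysteine
  and alternative codes are out of scope.
- The aligner optimizes sum-of-pairs greedily along the guide tree;
  it has no consistency objective or iterative refinement.
- Reconciliation assumes every gene-tree leaf's species appears in the
  species tree and that the gene tree is binary (guaranteed by
  construction here).
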
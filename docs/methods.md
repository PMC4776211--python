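# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data layer does and does not
emulate, and the numerical choices made where the design was open.

## Composition binning

**Feature space.** Each contig is represented by its tetranucleotide
frequency (TNF) vector: counts over every 4-bp window, windows containing
an N skipped, each tetramer collapsed to the lexicographic minimum of
itself and its reverse complement. The canonical set has 136 members
(16 palindromic tetramers plus 120 collapsed pairs); rows are normalized
to sum to 1. Collapsing makes the representation strand-agnostic, which
is the right invariance for assembly contigs whose strand is arbitrary;
`tnf(seq) == tnf(revcomp(seq))` is enforced by a property test. Vectors
are computed whole-contig (not windowed): contigs here are short enough
(1–10 kbp in the synthetic data) that windowing adds variance without
adding signal. Training uses contigs ≥ 3000 bp (default `min_len`);
contigs of 1000–2999 bp carry too little 4-mer signal to train on but
project well onto a trained map.

**ESOM.** `TetranucleotideESOM` is a scikit-learn-style estimator
(`fit`/`predict`/`get_params`) implementing a toroidal self-organizing
map trained online: for each input vector the best-matching unit (BMU,
Euclidean; ties to the lowest neuron index for determinism) is found and
all codebook vectors are pulled toward the input with weight
`lr · exp(−d²/2σ²)`, d the toroidal grid distance to the BMU. Defaults:
grid 50×82 (the "emergent" convention wants ≥ 5 neurons per training
vector — a smaller grid warns rather than fails), 20 epochs, learning
rate decaying linearly 0.5 → 0.1, radius max(rows, cols)/2 → 1. The
per-epoch mean quantization error is logged; the final value not
exceeding the first is asserted as an invariant (online SOM training is
not strictly monotone step-by-step, but is over whole epochs at these
schedules). Codebooks are initialized uniformly within the per-dimension
data range from the seeded generator, so runs are reproducible bit for
bit.

**Bin extraction.** The U-matrix assigns each neuron the mean codebook
distance to its 8 toroidal neighbors; cluster cores are its valleys.
Automated extraction thresholds the U-matrix at a percentile (default
30), takes toroidal 8-connected components of the sub-threshold neurons
as basin seeds, and then assigns every remaining neuron to its nearest
seed component by toroidal grid distance (watershed-style). The
expansion step matters: thresholding alone can label at most ~30% of
neurons at the default percentile, while BMUs spread across whole
basins; without expansion most contigs stay unbinned even on cleanly
separated data. Expanding to the nearest basin is the automated analog
of selecting a whole visible cluster by polygon, which is how such maps
are used interactively. A manual path remains: an explicit neuron→bin
mask overrides the automated extraction entirely. Components that
captured no BMU produce no bin.

## Bin refinement

The candidate set for reassembly is the union of (1) the selected
composition bin, (2) contigs within ≤ 2 undirected edges in the assembly
graph (GFA or edge-list input; orientation dropped, self-loops ignored),
and (3) contigs with a best protein hit in the target clade at
e ≤ 1e-10, with per-contig provenance flags. Candidates whose best
contig-level hit (lowest e-value, ties by bit score) is a known
contaminant taxon are removed and reported. Reads mapping to kept
contigs are recruited together with their mates (mate identity from the
`/1`,`/2` read-id suffix), whatever the mate's own placement — the
recruited read list feeds an external reassembly, which this package
deliberately does not perform.

**Misassembly splitting.** "Zero paired-read support" is operationalized
as zero spanning proper-pair *fragments*: per-position coverage is the
interval union of fragment (outer) spans. Maximal zero-coverage runs
strictly inside `[margin, L − margin]` are treated as breakpoints; the
contig is cut at each run's midpoint (a zero-width cut — without
base-level evidence the midpoint is the unbiased choice, and sequence is
conserved exactly). The margin defaults to `insert_mean + 3·insert_sd`
because positions closer to a contig end than about one insert length
cannot be spanned by any fragment; a margin ≥ L/2 skips the contig with
a warning. Pieces shorter than `min_piece` are discarded from the output
FASTA.

## Completeness

Families come from Markov clustering of a protein-similarity graph: the
column-stochastic matrix is alternately squared (expansion) and raised
elementwise to the inflation power with column renormalization
(inflation default 2.0, tolerance 1e-6, values < 1e-8 pruned for
stability), and clusters are the connected attractor systems of the
steady state. Self-loops get weight equal to the node's maximum incident
weight, a standard regularization the source formulation leaves open.
Single-copy marker families are those with exactly one member in every
reference genome; completeness of a target gene set is the fraction of
markers represented (≥ 1 gene) and, among represented markers, the
fraction with exactly one gene. The homology search that assigns target
genes to families is upstream of this package; the accounting consumes a
gene→family table.

## Proteomics

Each run is filtered individually: spectra collapse to peptides by best
score, the threshold sweeps downward, and FDR(t) = decoys/targets among
peptides scoring ≥ t (the concatenated-decoy convention; not
2D/(T+D)). The loosest threshold with FDR ≤ 1% is chosen and all
spectra of passing peptides retained — including passing decoys, which
downstream estimate the protein-level decoy rate. Parsimony inference
merges proteins with identical peptide sets, removes proper-subset
groups, removes subsumable groups (peptide set covered by the union of
≥ 2 other retained groups and no unique peptide), and requires ≥ 2
peptides with ≥ 1 unique; uniqueness is recomputed after every removal
round and the rules iterate to a fixpoint, which makes the outcome
order-independent. Balanced spectral counts give each group its unique
spectra plus a share of each shared spectrum proportional to the
groups' unique-spectrum counts in that sample (equal split when all
weights are zero; an `equal` policy is available) — the split rule is a
documented policy choice, as the splitting fraction is usually left
unspecified in descriptions of this procedure. Totals are conserved
exactly: summed balanced counts equal the number of assigned spectra.

## Expression

**Normalization.** Community level: each sample scaled to exactly 10⁶
(idempotent; zero-total samples are an error naming the sample).
Organism level: within one organism's rows, samples are rescaled so the
organism's totals equal the mean of the input totals, leaving other rows
untouched — this removes organism-abundance differences before
within-organism expression comparisons. States advance raw → community →
organism only. "Quantified" means count > 0; complete-case filtering
(feature positive in every sample) precedes ratio-based testing, so no
pseudocounts enter the ratios. The 1e-6 pseudocount exists only in the
clustering transform.

**Rank Product.** All K = nA·nB cross-condition ratio columns are
formed; features are ranked per column by descending ratio (average tie
ranks, for determinism), RP_up is the geometric mean of the ranks and
RP_down its ascending counterpart. The null is built by permuting the
feature labels within each *sample* column and recomputing ratios and
ranks per permutation (200 permutations by default); p = E(null RP ≤
observed)/G, floored at 1/(n_perm·G) so p stays in (0, 1]. Permuting
sample columns rather than the derived rank columns preserves the
dependence between ratio columns that share a sample; the independent
per-column rank shuffle, which the Rank Product literature also uses,
measured a type-I error of 6–12% at nominal 1% in this unpaired 3-vs-2
design, while the sample-column null measures ~1% (the acceptance suite
asserts [0.4%, 2%]). For K = 1 the constructions coincide, and when
G! ≤ 10⁶ the null is enumerated exhaustively. Significance follows the
joint rule: A:B mean ratio > 2 or < 0.5, and min(p_up, p_down) ≤ 0.01;
Benjamini–Hochberg columns are emitted for transparency but do not
enter the rule. A numerical detail: geometric means computed as
exp(mean(log r)) land a few ulps under their exact value, so null
comparisons use a 1e-9 relative nudge to count exact ties as ≤.

**GSEA.** Features are ranked by log₂(mean_A/mean_B), descending.
Classic (unweighted) running sum: +1/|S| on set members, −1/(N−|S|)
otherwise; ES is the maximum-magnitude deviation, signed. The null is
gene-set permutation: random same-size sets (shared across sets of equal
size), NES = ES / mean(|null ES| of matching sign), nominal p one-sided
on that sign (floored at 1/(n_perm+1)). FDR q compares each |NES| to the
pooled sign-normalized null over all sets, divided by the observed
exceedance fraction, clipped to 1, then made monotone non-increasing in
|NES| by a running maximum down the |NES| order (only ever raising q —
conservative). Sets smaller than 2 after intersection with the matrix,
or covering the whole ranking, are skipped with a warning; the raw
`enrichment_score` function accepts any proper subset including
singletons.

**Clustering.** Feature rows are converted to percentages (sum 100),
1e-6 is added to every value, and samples are clustered by average
linkage on the uncentered Pearson distance
d(x,y) = 1 − Σxᵢyᵢ/√(Σxᵢ²Σyᵢ²) ∈ [0, 2] (no mean-centering: the zero
point is meaningful for abundance profiles). Samples are processed in
lexicographic order so leaf layout is deterministic; the scipy linkage
is cross-checked against a naive agglomeration oracle in the tests, and
output is Newick plus a cophenetic correlation.

**Community structure.** Per-sample fractions of organismal groups are
computed from community-normalized values; fractions sum to 1 and
unmapped features are an error.

## Synthetic data

The generators emulate exactly the statistical structure the analysis
assumes, and nothing more:

- Genomes are order-3 Markov chains over nucleotides, so
  tetranucleotide composition is precisely the signal that separates
  them. `divergence` linearly mixes a shared base transition table with
  per-genome Dirichlet jitter: 0 gives identical genomes, 1 fully
  independent tables. The study conditions use divergence 0.8 — clearly
  separated genomes, as in a low-diversity community with one dominant
  eukaryote among distant prokaryotes.
- Contig lengths default to log-uniform 1–10 kbp, populating both the
  ≥ 3 kbp training class and the 1–3 kbp projection class. Chimeras join
  exactly two genomes at one uniformly placed interior junction
  (30–70% of the length); multi-junction chimeras are out of scope.
- Read-pair fragments (insert 200 ± 20 bp, 50 bp reads, fragment depth
  20 in the study conditions) are sampled only within single-genome
  segments, so junctions have zero spanning support by construction —
  the signal the splitter detects. Segments shorter than
  insert_mean + 4·insert_sd are skipped with a warning.
- Count matrices are negative-binomial (dispersion 0.1) around
  lognormal per-feature means (median 50, σ = 1), in the study's 3-vs-2
  replicate design, with 5% of features given a fold change of 4 (half
  up, half down) and lognormal library-size factors (σ = 0.4) that make
  the per-million normalization consequential.
- PSM tables draw target scores from N(13, 1) and decoy scores from
  N(10, 1) — targets stochastically dominate — with a decoy database the
  same size as the target one, 20% decoy spectra, and 10–20% of peptides
  shared between two proteins.
- The assembly graph connects contigs mostly within genomes (mean
  intra-genome degree 2); the hit table gives 60% of contigs one
  best-hit protein, target-genome contigs hitting the target clade and
  the rest hitting contaminant taxa, with e-values log-uniform in
  [1e-40, 1e-11].

What the generators do **not** model: sequencing errors, indels, quality
variation, GC/coverage biases, strain-level variation within a genome,
peptide detectability differences, or retention-time structure. Passing
tests therefore demonstrate that the algorithms recover the structure
they are designed for at realistic noise levels — not that they are
robust to every artifact of real libraries. All generators are
byte-deterministic under a fixed seed and emit 0-based half-open
coordinates throughout.

## Benchmark problem sizes

The benchmark layer (`esomics.benchmarks`) runs each measurement at the
study-condition sizes: 3 genomes × 300 contigs for bin recovery; 270
clean + 30 chimeric contigs at fragment depth 20 for splitting; 2000
features, 3-vs-2, 200 permutations for Rank Product calibration and
power; 3000 spectra over 40 target proteins for the proteomics chain;
200 families over 10 reference genomes for completeness; and the full
demo pipeline twice for determinism. These sizes keep a complete
benchmark run around two minutes on one CPU while leaving every
statistical check comfortably powered.

## Known limitations

- The ESOM is trained online on one CPU; no batch or GPU path. Grids
  much above ~10⁴ neurons become slow.
- MCL is dense (O(n³) per iteration); intended for the hundreds-of-nodes
  family graphs used here, not proteome-scale graphs.
- The Rank Product's exhaustive mode exists only for K = 1; for K > 1
  the Monte-Carlo null is the only option.
- GSEA implements gene-set permutation only (the design here has too few
  samples for phenotype permutation).
- Reassembly of recruited reads is delegated to an external assembler by
  design; the pipeline emits the read list and accepts a new assembly.
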
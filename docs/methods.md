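# Methods

This package reconstructs, at desk scale, the analysis chain used to study
the expression evolution of ancestral X/Y gametologs in placental mammals:
recovery of Y-linked transcripts by male/female subtraction, expression
quantification and cross-species harmonization, inference of ancestral
(proto-sex-chromosome) expression from outgroup autosomal orthologs,
current/ancestral ratio statistics, tissue-specificity evolution,
presence/absence conservation with Dollo loss counting, retrogene parent
assignment by synonymous divergence, and female/male dosage accounting.
Every stage is exercised against a synthetic gametolog system with known
ground truth; no external downloads or third-party aligners are required.

## The synthetic gametolog system

`simulate.simulate_system` generates one system per seed:

* **Species and tree.** `n_species` ingroup species (default 6) on a random
  ultrametric tree (~90 My root), plus `n_outgroups` (default 3) outgroup
  species that carry the autosomal one-to-one orthologs of the gametolog
  families. A packaged 25-species time tree with literature-scale divergence
  dates is shipped separately for conservation and deep-ancestor analyses.
* **Families and sequences.** 16 gametolog families with random protein-coding
  ancestral CDSs (900 nt). Per species, the X copy diverges ~2% from the
  ancestral CDS and the Y copy is mutated to a target X–Y nucleotide identity
  drawn uniformly from [0.92, 0.95] — the identity band where subtraction
  approaches are reliable. Substitutions are i.i.d., indel-free, and never
  create internal stop codons (the copies remain protein-coding).
* **Expression model.** Each family has a log-normal per-allele ancestral
  level *a* (log-mean log 30, sigma 1) with mild log-normal tissue modifiers.
  Outgroup orthologs express 2*a* (two autosomal alleles). Male X = *a*;
  female X = *a*(1 + escape gain) with a default escape gain of 0.25,
  representing XCI-escape over-expression. Y expression = *a*/decay.
* **Y decay and testis specificity.** Per-family somatic decay folds are
  log2-normal with dispersion 0.5 (the within-family dispersion is not
  constrained by any published value; 0.5 gives a realistic 1.5–8x spread and
  is a documented free choice). A `testis_specific_fraction` (default 0.25)
  of families lose expression only in somatic tissues, and at an accelerated
  rate (x5 by default): testis specificity in this system is the *result* of
  accelerated somatic decay, not an independent switch. The base scale is
  calibrated numerically so the across-family median of realized somatic decay
  equals `y_decay_median_fold` (default 3) despite the accelerated
  subpopulation; a 200-seed pilot gives a mean per-seed median of 3.02
  (per-seed range 2.3–4.4).
* **Losses.** Y copies are lost on random tree edges (per-edge probability
  0.04) under a strict Dollo regime — no regain below a loss edge, and the
  seven universally conserved families never lose their Y. The emitted
  presence matrix is therefore explainable by exactly the recorded loss
  events.
* **Retrogenes.** `n_retrogenes` intronless retrocopies (default 4) are
  planted on autosomal scaffolds, 95% of them from the four retro-prone
  families. The retro CDS derives from its parent gametolog by mostly
  synonymous (third-position) changes, so the parent remains the nearest
  sequence by dS. Retro expression is low (log-normal, median ~2 TPM) and
  sex-shared (autosomal insertion).
* **Genomes and reads.** Per species, genomic scaffolds carry each X gene
  with one annotated intron, the Y gene as contiguous (intronless) sequence
  on male-only scaffolds, background genes and retrocopies. RNA-seq reads are
  100 nt, drawn proportionally to expression x length with uniform starts.
  The default read error rate is 0 (the emulated libraries are
  quality-filtered, >93% of bases above Q35; the exact-overlap assembler
  stand-in presumes clean reads) — nonzero error rates are exercised
  explicitly in tests. Observed expression tables add log-normal measurement
  noise (sigma 0.2) per individual (2 individuals per species x sex).
* **One-to-one orthologs.** 40 background genes share IDs across all species
  and outgroups and act as the one-to-one ortholog set for scaling
  normalization and the PCA batch check. This is a desk-scale stand-in for a
  real ortholog call; gene-ID sharing across species is a simulation
  convenience, not a claim about real annotations.

What a green test does *not* establish: robustness to isoform structure,
paired-end or errorful reads, spliced transcripts, assembly of ampliconic
multicopy arrays (multicopy Y genes are modelled as exact duplicates),
realistic intron/exon structure on the Y, or ortholog-mapping errors.

## Subtraction

The recovery chain removes reads with ambiguous bases; subtracts male reads
mapping end-to-end to female references (exact 21-mer anchoring + ungapped
extension, <= 5 mismatches per 100 nt); builds the female 35-mer signature
(frequency >= 10, k-mers canonicalized min(forward, reverse complement) —
strandedness of the counting is not specified anywhere authoritative, so
canonicalization is the default and `stranded=True` disables it); removes male
reads containing any indexed 35-mer exactly; and assembles survivors with a
greedy overlap-layout assembler (all suffix-prefix overlaps >= 31 computed
once, merged longest-first, lexicographic tie-break, containment collapsed —
deterministic, and equivalent to iterative re-merging on error-free tiling
reads). Contigs are Y-linked when exact genomic matches cover >= 90% of the
contig in the male set and no female hit exists; "no significant female
alignment" is operationalized as *no* local match at >= 98% identity over
>= 90% of contig length, anchoring the known ~98% identity sensitivity limit
of subtraction methods. Recovery degrades sharply above 98% X–Y identity and
the suite asserts this expected failure.

## Quantification and harmonization

Reads are assigned by shared 21-mer counts (unique best transcript wins,
exact ties split equally — an EM rescue adds nothing at 92–95% divergence,
where the cross-mapping control shows < 5% ambiguous assignment); TPM is
(c/l) normalized to one million. Scaling normalization selects the 300
lowest-variance (log2) orthologs with TPM > 1 in every sample (all available,
with a warning, when fewer exist — the expression floor is an explicit
operationalization), computes per-sample median ratios to the gene-wise
geometric mean, and rescales factors to geometric mean 1, which makes the
procedure exactly idempotent. Aggregation takes medians across individuals,
combines brain and cerebellum into one brain value, sums multicopy and
retro copies, drops SRY (developmental expression) and drops X values for
species whose Y copy is lost. The PCA batch check compares silhouette widths
of tissue vs experiment groupings on PC1–PC2 of log2(TPM+1).

## Ancestral levels and statistics

Ancestral per-allele expression per family = median over outgroup species of
the ortholog value, divided by 2; testis and soma strata are computed
separately where needed. Ratios are log2((current + 0.1) / (ancestral + 0.1));
the 0.1 TPM pseudocount handles zeros (no authoritative choice exists; it is
config-exposed). Panels test each cell against fixed medians 0 and -1 with a
one-sample Wilcoxon signed-rank (exact null for n <= 25, normal approximation
with continuity correction above) — a one-sample location test is the
well-defined reading of "tested against a distribution with a fixed median".
BH correction at 0.05 is applied within one panel (the correction family is
config-level; per-panel is the default). Continuous ancestral state
reconstruction solves the tree Laplacian (ML Brownian motion == branch-length
weighted squared-change parsimony; verified against a numeric minimizer).
PGLS uses the Brownian covariance C_ij = shared path length, with a t-test on
the GLS slope (df = n - 2); on star trees it reduces exactly to OLS and its
simulated type-I error at alpha = 0.05 is 0.05 +- 0.02.

## Tissue specificity and conservation

TSI = max tissue value / sum over tissues on the aggregated per-tissue
values; genes above 0.6 (strict) are tissue-specific; the male gonad is
testis. The specificity-gain analysis splits Y gametologs at testis-TSI 0.6,
compares somatic vs testis current/ancestral ratios (ancestral levels for
testis and soma computed separately), excludes HSFY, and runs between-group
Mann-Whitney U plus fixed-median tests under one BH family. Conservation
counts genes present (pseudogene-with-expression counts as present, unclear
is missing data) in every assessed species. Dollo loss counts equal the
number of maximal subtrees whose assessed tips are all absent — verified
against exhaustive edge-labeling enumeration on 6-tip trees.

## Retrogenes

The translated search six-frame-translates genomic scaffolds, seeds on exact
4-aa words, extends ungapped under BLOSUM62 with an X-drop, and merges
same-strand matches within 1 kb (the merge radius has no authoritative value;
it is config-exposed). Each query residue counts once toward the merged
similarity, attributed to the best sub-match covering it, so frame-shifted
shadow hits cannot dilute a real copy. Matches are kept at similarity > 0.5
over > 80% query coverage and no annotated intron in the span; matches at
known gametolog loci are excluded before retro calling. Pairwise dS is
Nei–Gojobori (1986) — average synonymous sites of the two sequences,
pathway-averaged synonymous differences, Jukes–Cantor correction,
saturation (pS >= 3/4) flagged as infinite — on a codon-aware alignment
(amino-acid Needleman–Wunsch back-mapped to codons, gap columns dropped).
NG86 stands in for codeml's ML estimator; it is closed-form, dependency-free
and adequate at the low divergences in scope (users running the original
tool would use runmode -2, CodonFreq 2). The parent gametolog is the argmin
of dS (ties flagged ambiguous and excluded from parent-specific tallies);
retrogenes are retained when dS < 1 and cumulative TPM > 1, both strict.

## Dosage

Dosage ratios are computed per family x species x somatic tissue (gonads are
excluded: ovary and testis are not comparable): log2(Xf/Xm) and
log2(Xf/(Xm+Y)), with retrogene-inclusive variants adding cumulative retro
expression to the designated side; retro expression is sex-shared unless a
Y-linked insertion is marked. HSFXY is excluded from between-group tests
only. The escape gain estimate is the median of (Xf/Xm - 1) x 100 over
family x species x somatic-tissue cells.

## Packaged fixtures

`data/placental_tree.nwk` is a 25-species time tree assembled from standard
literature divergence dates. `data/presence_matrix.tsv` is a *synthetic*
presence/absence matrix (see its header): the per-cell states were chosen to
be exactly consistent with the published summary statistics of ancestral-Y
conservation — seven universally present genes and Dollo loss counts
1/2/2/2/2/3/4/5/5 for the nine non-conserved genes — because cell-level
presence data are not available for redistribution here. Counting
operations on it reproduce those summary numbers
by construction of the fixture, which is what the conservation acceptance
check verifies. `data/life_history_traits.tsv` holds synthetic
order-of-magnitude life-history values for the PGLS interface.

## Numerical and degenerate-input conventions

Intervals are 0-based half-open internally. Assembly and identity
tie-breaks are lexicographic. Zero-length branches get an epsilon (1e-8) in
ASR. All-zero TPM columns quantify to all-zero (no division by zero).
All-zero tissue vectors have undefined TSI and are skipped with a warning.
A gene absent in every assessed species contradicts ancestral presence and
is an error in Dollo counting. Per-stage seeds derive from one master seed
by fixed affine hashing; every simulation is byte-identical under a fixed
seed.
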
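# Methods

`orthoselect` implements a comparative-genomics workflow for a species with
plentiful cDNA sequence but sparse annotation: reduce raw reads to a
non-redundant high-quality set, assign each sequence its dog/human/mouse
orthologs, estimate per-gene selection pressure (ω = dN/dS) for each
species pair, transfer annotations through the orthology, and ask which
annotation classes evolve fast or slow. This note records the models, the
parameter choices, and what the synthetic benchmark does and does not
establish.

## Sequence quality control

Reads are translated in all six frames under the standard genetic code
(codons containing N give X) and the longest ATG-initiated product —
stop-terminated or running to the frame end — is taken as the read's
protein. Requiring an initiator is deliberate: a read with no ATG in any
frame has no defensible coding assignment and is flagged out rather than
silently kept.

Redundancy is removed in both spaces. Identity between two sequences is
the number of matched positions in the best local alignment divided by the
length of the shorter sequence, so a clean truncation of a longer read
scores 1.0 against its source and clustering at the 0.95 stringency merges
them. Clustering is single linkage — the transitive closure of the
pairwise ≥ 0.95 relation — because any threshold-based merge rule must
decide what to do with A~B~C chains, and single linkage is the
reproducible formalisation of "these reads describe the same transcript".
The cluster representative is the longest member (ties broken by smallest
identifier, for determinism). The non-redundant set is the intersection of
nucleotide-space and protein-space representatives; records still carrying
ambiguity letters (N, X) are then removed.

Local and global alignments use an affine-gap aligner (blastn-like
nucleotide scoring +2/−3, gap open −5 extend −2; BLOSUM62 with −11/−1 for
proteins). An exact k-mer prescreen (11-mers for DNA, 5-mers for protein,
≥ 3 resp. ≥ 2 shared) limits the quadratic dynamic programming to pairs
that could plausibly clear the identity threshold; at ≥ 95% identity a
large fraction of k-mers is necessarily preserved, so the prescreen cannot
lose true redundancy, while unrelated sequences almost never share enough
k-mers to be aligned at all.

## Ortholog assignment

Reference sets for a newly surveyed species are incomplete, so
reciprocal-best-hit orthology is unavailable (the reciprocal direction can
fail merely because the gene is missing from the species' own reference).
Assignment instead filters local-alignment hits through eight
progressively relaxed criteria on four statistics: the match-length ratio
(aligned columns over the shorter of query and subject), the mismatch
count, the gap-opening count, and percent identity —

| step | ratio | mismatches | gaps | identity |
|------|-------|-----------|------|----------|
| 1 | aligned length = shorter sequence | 0 | 0 | ≥ 99% |
| 2 | ≥ 0.99 | 0 | 0 | ≥ 99% |
| 3 | ≥ 0.87 | ≤ 4 | 0 | ≥ 99% |
| 4 | ≥ 0.725 | ≤ 5 | 0 | ≥ 99% |
| 5 | ≥ 0.69 | ≤ 4 | ≤ 1 | ≥ 99% |
| 6 | ≥ 0.625 | ≤ 8 | ≤ 1 | ≥ 98% |
| 7 | ≥ 0.575 | ≤ 13 | ≤ 2 | ≥ 97% |
| 8 | ≥ 0.52 | ≤ 12 | ≤ 2 | ≥ 97% |

Steps run in order; a query assigned at a stricter step is never
revisited, so adding laxer steps only adds assignments (tested as a
monotonicity property). The steps are not uniformly nested — the mismatch
cap tightens again at steps 5 and 8 even as the ratio bound relaxes — and
the implementation preserves the table as printed rather than
"correcting" it. Within a step, competing qualifying hits are resolved by
bit score, then e-value, then lexicographic subject id; the tie rule is a
design choice made for determinism, since any best-hit scheme needs one.

A query is *known* if the same filter links it to any sequence in the
public reference set of its own species, *novel* otherwise. Every accepted
assignment is then re-checked by global (Needleman–Wunsch) alignment and
dropped when global identity falls below 0.80: a strong local hit embedded
in otherwise unrelated sequence is homology of a domain, not orthology of
a gene. The 0.80 default replaces manual alignment inspection and is
configurable. Queries with verified orthologs in all three target species
form four-species ortholog groups; transcript-level subjects are collapsed
to their gene identifier.

The internal homology searcher exists so the pipeline runs end to end on
desk-scale data; BLAST tabular (outfmt-6) files produced externally are
accepted through the same filter, with sequence lengths supplied from
FASTA. The searcher's e-value is the score-ordering-preserving quantity
m·n·2^(−score), not a calibrated Karlin–Altschul statistic; the filter
never thresholds on it, using it only inside the tie-break.

## dN/dS estimation

Rates are estimated by the Nei–Gojobori (1986) counting method on
protein-guided codon alignments. A pairwise protein alignment is
back-translated onto the coding sequences (each residue column maps to its
source codon, protein gaps become `---`, and any residue/codon
disagreement is a hard error), which keeps the nucleotide alignment in
frame by construction. Gapped codon columns are excluded pairwise.

Per codon, each of the nine single-nucleotide neighbours is classified
synonymous or nonsynonymous under the standard code (changes creating
stops count as nonsynonymous), giving fractional site counts with
n + s = 3 exactly. Differences at two or three codon positions are
averaged over all minimal mutational pathways, excluding pathways through
stop codons unless every pathway is blocked. Proportions pN = Nd/N and
pS = Sd/S receive the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 is flagged as saturated. Both 61×61 difference counts and the 61
site decompositions are precomputed, making estimation O(1) per codon
pair.

ω carries an explicit status rather than a sentinel value: `finite`
(dN, dS > 0), `zero` (dN = 0 with synonymous divergence — a fixed
amino-acid sequence, biologically meaningful and distinct from "no
information"), `infinite` (dS = 0, dN > 0), `undefined` (identical
sequences), `saturated`. Grouped means and stratification use only
`finite` and `zero` estimates; the exclusion is conservative and the
excluded counts are reported.

A counting estimator was chosen over maximum-likelihood codon models
because the pairwise single-ω setting is exactly where counting is
adequate, and because every intermediate quantity (sites, pathway-averaged
differences, corrections) can be verified against an independent
brute-force enumeration — which the test suite does to 1e-9 on random
codon pairs.

## Annotation transfer and stratified selection analysis

Each cat gene inherits the complete term set of its human (or mouse)
ortholog in every namespace — GO process/function/location, anatomy, cell
type, pathology, developmental stage, pathway, phenotype, disease — as a
plain relational join; no term is ever invented, and genes without the
relevant ortholog inherit nothing. Coverage summaries report per-term gene
counts and percentages of the ortholog-set size at four decimals (the
denominator is always the declared ortholog-set total).

Genes sharing a term are grouped and their ω averaged per species pair
(unweighted arithmetic mean; terms with fewer than `min_genes = 2` usable
genes are dropped). For a global view, genes are ranked by ω under one key
species pair and split 25/50/25 into conserved, middle, and divergent
groups; tail sizes are round-half-up(0.25·n), which makes a 711-gene set
split 178/355/178, with ranking ties broken by gene id so sizes are exact.
Term enrichment of any group against a universe uses the exact
hypergeometric upper tail P(X ≥ k), with Benjamini–Hochberg q-values
reported alongside (never replacing) the raw p-values. The network/gene
ratio — 100 × distinct terms hit / genes, half-up to one decimal —
summarises how widely a group spreads over a pathway vocabulary.

## The synthetic benchmark

The generator is the estimator's generative inverse. Each gene family
starts from a random stop-free ATG-initiated coding sequence and evolves
independently down the four branches of a star phylogeny: candidate point
mutations are proposed uniformly over sites and alternative bases at an
expected `branch_subs` attempts per site per branch; mutations creating
internal stops are rejected; synonymous changes fix with probability 1,
nonsynonymous with probability ω (for ω > 1 the synonymous acceptance is
scaled by 1/ω instead, preserving the ratio). Per-gene ω is assigned by
deterministic index blocks so configured group fractions are met exactly.
On top of the families the generator injects redundant copies (exact
duplicates or 5'/3' truncations keeping ≥ 95% of the source, so the
clustering stringency must merge them), N-contamination of copies, a
public cat reference withholding a configurable fraction of genes (the
"novel" genes), Ensembl-style FASTA dumps with gene|transcript|protein
headers, annotation TSVs per namespace in which the `pathway` namespace
tags most genes with a term named for their selection regime, and a JSON
truth table covering every derived quantity.

Defaults: 100 genes of 150–400 codons, `branch_subs = 0.01`,
ω groups 0.02/0.10/0.40 at fractions 0.25/0.50/0.25 (a purifying-dominated
regime typical of mammalian ortholog sets), duplicate rate 0.3,
contamination rate 0.5 of copies, novel fraction 0.25. The default
divergence is chosen inside the assignment filter's operating range: the
printed mismatch caps (≤ 13 regardless of length) demand roughly ≥ 99%
nucleotide identity for kilobase transcripts, so a benchmark meant to
exercise recovery needs pairwise divergence of about 1% or below. The
ω-recovery analyses use 500-codon genes at `branch_subs = 0.05`, where the
estimator has more substitutions to count.

What the benchmark does not emulate: indels (alignments are gap-free by
construction; gap handling is exercised by hand-built fixtures), paralogs
(recovery numbers say nothing about paralog confusion), transition/
transversion bias and codon-usage structure (the simulator is
assumption-matched to the counting estimator, which also ignores bias),
and real annotation sparsity. Passing recovery tests therefore
demonstrates internal consistency of the machinery under the stated model,
not field performance on real reads.

One subtlety found during testing: at ω = 0 every *accepted* change is
synonymous, yet pathway-averaged counting can still register fractional
nonsynonymous differences when the same codon is hit by synonymous
substitutions on two different branches (the direct minimal path between
the two descendants may pass through nonsynonymous intermediates even
though the path through the ancestor does not). dN = 0 therefore holds
exactly only when same-codon double hits are absent, which is the case at
the default divergence; the test asserts it there.

## Numerical and degenerate-input conventions

Length statistics use the sample (n−1) standard deviation, reporting 0
with a flag for n = 1. Percentages use decimal half-up rounding (never
banker's rounding) at the stated precision. All randomness flows from
explicit integer seeds through per-purpose `numpy` generators
(`default_rng([seed, stream])`), so identical configuration gives
byte-identical output files; stage wall-times are logged to stderr and
kept out of the JSON report for that reason. Empty inputs raise errors
where a statistic would be undefined (no records, all-gap alignments,
n < 4 stratification) and return empty results where that is meaningful
(no hits, no clusters).

## Problem sizes used in the checks

The bundled verification suite runs entirely on generated data: ortholog
recovery on 30-gene benchmarks with duplicates and contamination,
ω recovery on 300 genes (100 per ω level, 500 codons), estimator-oracle
equivalence on 500 random 10-codon pairs, enrichment exactness over the
full N ≤ 20, n ≤ 10 grid, and determinism on a 100-gene end-to-end run.
These sizes give stable pass/fail behaviour at interactive runtimes; all
scale linearly (quadratically in the number of sequences for clustering)
if larger studies are needed.
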
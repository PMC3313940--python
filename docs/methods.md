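# Methods

This note documents the models, estimators and design choices behind
`mirword`, module by module, including what the synthetic-data generator
does and does not emulate.

## Sequence handling

UTRs are DNA, sense strand, mRNA orientation; no reverse-strand scanning.
Input FASTA is sanitized by uppercasing, mapping U→T, and dropping any
character outside {A,C,G,T} with a logged warning (Ns and IUPAC ambiguity
codes carry no usable information for exact word counting and would
otherwise poison the k-mer encoder). Word occurrences are counted **with
overlaps**: every start position at which the word matches contributes one
count; this is the sliding-window definition and the one the brute-force
oracle implements.

K-mer counting encodes bases as 0–3 and bins base-4 word codes
(lexicographic order A < C < G < T, matching `enumerate_words`), one
bincount pass per batch of sequences.

### Dinucleotide-preserving shuffle

The null model for sequence composition is the Altschul–Erikson
construction: the sequence is an Eulerian walk on the graph whose edges are
its overlapping dinucleotides; a random last-edge set forming a tree into
the terminal base is drawn (rejection sampling — with a 4-letter alphabet
the acceptance rate is high), remaining out-edges are permuted uniformly,
and the walk is replayed. This samples uniformly from all sequences with
exactly the input's dinucleotide multiset, hence identical length,
mononucleotide counts and end bases. Sequences shorter than 2 nt or with a
single distinct base are their own (unique) arrangement and are returned
unchanged.

### Seed sites

Canonical site types are defined from the miRNA seed (bases 2–8, 1-based
from the 5′ end): 6mer = reverse complement of bases 2–7; 7mer-m8 = reverse
complement of 2–8; 7mer-A1 = 6mer + A; 8mer = 7mer-m8 + A (the A1 adenosine
is a sequence identity, not a pairing). Each seed-match locus is reported
once at its **maximal** type; across loci, overlapping candidates resolve
longest-first, then leftmost, so reported sites never overlap. This
maximality convention is what yields exactly two sites (one 7mer-A1, one
7mer-m8) on the bundled 99-nt PDGFRA reporter segment.

Word–miRNA alignment (used to annotate and render enrichment reports)
matches the word or any contiguous sub-word of length ≥ 5 against the
reverse complement of every miRNA stretch, preferring the largest overlap
with the seed region, then the longest match, then 5′-most coordinates.
Letters whose matched miRNA base lies in 2–8 render uppercase; unaligned
words render fully lowercase.

## Differential expression

Normalization is per-sample median centering (all column medians → 0). The
heavier variance-stabilizing transforms used in microarray practice are
deliberately out of scope: the downstream word analysis consumes only the
gene *ranking*, which is insensitive to the normalizer at the scales this
package generates; a `skip` flag accepts pre-normalized matrices untouched.

The moderated t follows the standard empirical-Bayes hierarchy: s²_g | σ²_g
~ σ²_g·χ²_{d_g}/d_g and 1/σ²_g ~ (1/(d₀s₀²))·χ²_{d₀}/d₀. Writing
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the model implies E[e] = log s₀² +
ψ(d₀/2) − log(d₀/2) and Var[e] = ψ′(d_g/2) + ψ′(d₀/2). The sample moments
of {e_g} (genes with s²_g = 0 excluded — they carry no spread information
on the log scale) give d₀ via Newton inversion of the trigamma function
(limma's initialization, tolerance 1e-8) and then s₀². If the observed
spread does not exceed the sampling term, d₀ = ∞ with full pooling to
exp(mean e) and a logged warning; this is the correct fit when all genes
share one true variance. A test cross-checks the full fit (t̃, d₀, s₀²)
against limma's `eBayes` as an independent oracle.

Gene ranking defaults to the moderated t (a fold-change option exists —
whether "expression change" means t or LFC is genuinely open, so both are
exposed); ties break lexicographically on gene id everywhere a sort occurs,
and genes with undefined statistics (zero variance with d₀ = 0) rank last
with a warning.

## Word enrichment

The running-sum maximum statistic was chosen as the concrete rank-based
word statistic because it is directly testable against a few lines of
brute-force arithmetic and is sensitive to concentration at the top of the
list. Options: binary presence instead of counts, and counts per kilobase
of UTR; defaults are raw counts, no length normalization (defaults
declared, not inferred).

Null model, per word: B rank permutations (fixed counts, re-permuted gene
order) plus S dinucleotide-shuffle replicates (original order, re-counted
words), pooled into one null sample of size B+S; defaults B = 500, S = 5.
Z standardizes the observed score by its own null mean/sd. The FDR at
threshold z is the empirical exceedance ratio — expected null words ≥ z
(total null-Z exceedances divided by B+S) over observed words ≥ z — capped
at 1 and monotonized by a running maximum down the Z-ranked list.
Calibration is stratified by word length (5/6/7-mers separately), because
word frequency, and with it score variance, scales with length. Words with
constant count vectors, or degenerate nulls, are reported unscorable and
excluded from ranking; ranks are a permutation of 1..n_scored, ties in Z
broken lexicographically.

The analysis is one-sided toward down-regulation; the `--up` flag reverses
the ranked list for the opposite tail.

Randomness: one master seed; child streams derive from numpy
`SeedSequence` spawn keys per (kind, word-length, replicate), so results
are independent of evaluation order and safe to parallelize.

The scoring kernel streams gene rows in permuted order, carrying per-word
running sums and maxima (numba-compiled with a numpy fallback), in float64
throughout so the brute-force oracle equality holds to 1e-12.

## Cohort integration

Spearman rho is the Pearson correlation of average-ranked values. Its
p-value uses the large-sample t approximation for n ≥ 10 and exact
permutation below (all n! orderings for n ≤ 7, else 10,000 seeded
Monte-Carlo draws): cohort-scale n makes the approximation standard, tiny
inputs need exactness.

The subclass contrast is a one-tailed Wilcoxon rank-sum (target subclass
lower than the pooled rest), exact when min(n₁, n₂) ≤ 8 and tie-free,
normal approximation with tie correction otherwise; p53-stratified runs
exclude samples with unknown status (unstratified runs include them).

Candidate targets come from the strict intersection of two external
prediction lists (score < threshold in both; genes missing from either
list are excluded). The combined ranking — rank(t̃ ascending) +
rank(ρ ascending), ties lexicographic — is this package's own rule,
isolated in one function so alternatives (e.g. rank products) can be
swapped; it formalizes "most negative on both axes" without asserting how
the original analyses weighted the two.

## Synthetic data

`generate_utrs` draws i.i.d.-composition sequences (default uniform;
lengths uniform on 200–1200 nt, bracketing typical mammalian 3′UTR
lengths) and splices 1–2 copies of the planted word (default `CACTGCC`,
the miR-34a-5p 7mer-m8 match) into a fraction f = 0.2 of genes.
`generate_overexpression` models triplicate log-expression with Gaussian
noise (σ = 1 by default) and a planted δ = 1 down-shift for carriers in
the treated arm. A GC-skew option exists because shuffle-null calibration
is only informative off-uniform; the FDR-calibration experiments use 60%
GC.

`generate_cohort` uses the four glioblastoma transcriptional subclasses at
55/28/52/56 samples (191 total), shifts the miRNA down by Δ = 1 log-unit
in the proneural subclass, and builds one target mRNA from the *realized*
standardized miRNA profile with loading a = 2·sin(π·ρ_s/6) (the Gaussian
rank-correlation inverse), so the population Spearman correlation is
≈ −ρ_target (default 0.6). Decoy mRNAs are independent; p53 status is
i.i.d. Bernoulli (35% mutant), independent of subclass.

The cohort-recovery benchmark (`experiments.cohort_recovery_experiment`)
gives its planted target a 1.5-log-unit overexpression response over
0.5-log-unit replicate noise — the strong-direct-target regime the
integration analysis is designed to surface; with the weaker word-analysis
settings a single gene's response is not reliably separable among ~100
candidates at n = 3, which is a property of the design, not of the code.

What the generators do **not** emulate: probe-level array artifacts,
batch or background structure, UTR isoform heterogeneity, correlated
co-regulation among decoys, miRNA family redundancy, and copy-number
effects on expression. Passing recovery tests therefore demonstrate that
the machinery is correct and calibrated under its assumptions, not that
real-cohort effect sizes will match.

## Problem sizes and numerical choices

The standard experiments run at G = 2000 UTRs with the 7-mer universe
(16,384 words), B = 500 permutations and S = 5 shuffle replicates — large
enough for the planted word to dominate and for the empirical FDR to be
meaningful, small enough to iterate on a laptop. Recovery and calibration
claims are made over 10 master seeds; the null rejection-rate calibration
uses 200. Tolerances: exact combinatorial quantities are asserted exactly;
oracle equalities at 1e-10–1e-12; stochastic calibrations at the width a
binomial at the stated replication supports (e.g. 0.05 ± 0.03 over 200
seeds). Degenerate inputs (constant vectors, zero variances, empty strata,
missing genes) are either errors naming the offender or logged exclusions,
never silent.

## Known limitations

* The word statistic is evaluated for one miRNA at a time; joint
  deconvolution of co-transfected or family miRNAs is out of scope.
* No thermodynamic or conservation scoring of sites; external predictor
  scores are consumed, never recomputed.
* The empirical FDR is a pooled exceedance ratio, not a per-word adjusted
  p-value; overlapping words are correlated and the stratified pooling
  accounts for length only.
* Exactly two experimental arms; no multi-factor designs.
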
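# Methods

This note documents the statistical machinery, the conventions chosen where
several were defensible, and what the synthetic-data validation does and
does not establish.

## ORF validation and filtering

A candidate coding sequence is accepted when, in this order: its length is
a positive multiple of 3; it begins with ATG; it ends with TAA, TAG or TGA;
it contains no in-frame internal stop codon (out-of-frame stop
trinucleotides are irrelevant and allowed); it contains only A/C/G/T; its
length is strictly greater than `min_len_bp` (default 300, so a 300 bp
sequence is excluded); and, when a homolog reference length is supplied for
its id, length/reference lies in [0.95, 1.05] inclusive. The first failing
rule is the recorded rejection reason, which makes reports deterministic.
The length threshold counts the full CDS including start and stop codons.
Filtering is idempotent: re-filtering the kept set rejects nothing.

## Single-codon indices

Raw counts, per-mille frequencies and the GC partition include the start
ATG and the stop codon (the ORF is the counting unit). RSCU is defined for
the 59 sense codons in degenerate families — Met and Trp have no synonymous
competition — and, separately, for the three stop codons treated as their
own family; within each observed family the RSCU values average to exactly
1. SCUO uses log base 2 (the index is a ratio of entropies, so the base
cancels); families with zero count are omitted, and 0·log 0 is taken as 0.
A gene containing no degenerate amino acid has no defined SCUO and raises
`UndefinedStatisticError` rather than returning a sentinel.

High-frequency codons are those with RSCU > 1.5 *or* within-family share
> 60%; both cutoffs are strict inequalities. Abundant/rare sets are the
top/bottom 15 sense codons by per-mille frequency, stop codons excluded,
with frequency ties broken lexicographically so the sets are reproducible.

## Codon pairs and bias calling

Pairs are ordered sense-codon pairs taken within the interior of each gene
(start and stop codons excluded; pairs never span genes) at junction
distance d = 0..5 intervening codons. The expected frequency of a pair is
the product of the two single-codon frequencies estimated from the same
interior codons — an analytic independence expectation rather than one
realisation of a shuffle, which keeps the test deterministic. RSCPU
normalises each pair by its amino-acid-pair family: expected count =
family count / (S_a · S_b); the four Met/Trp-only pairs are excluded from
RSCPU (3717 synonymous pairs of the 3721) but retained in the bias table.

Significance uses the Audic–Claverie posterior predictive
p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^{x+y+1}), which is the
negative-binomial pmf NB(r = x+1, p = N1/(N1+N2)); tails are therefore
computed through scipy's nbinom, which is exact and overflow-safe. The
two-sided p-value doubles the smaller tail, capped at 1; reported p-values
are floored at 1e-10. A pair (or codon) is called preferred/avoided only
when p < 0.01 *and* |log₂(obs/exp)| ≥ 1.5 (≈ 3-fold, since 2^1.5 ≈ 2.83).
Expected counts are rounded to the nearest integer for the test; the log₂
ratio applies a +0.5-count continuity correction only when either count is
zero. The p-value itself always uses the raw integers.

## Positional bias

Each gene long enough is cut into ten 10-codon bins: bin_1..bin_5 are
codons 2–51 (1-based, start codon excluded), bin_−5..bin_−1 the 50 codons
before the stop. Only ORFs with ≥ 102 codons enter, guaranteeing the 5′
and 3′ bins are disjoint; shorter genes are counted and skipped.

KLD(k) sums, over degenerate families present in bin k, the natural-log
divergence of the bin's within-family shares p_{i,j}(k) from the
corpus-wide shares q_{i,j}. Codons with p = 0 contribute 0 (the x·ln x
limit); q > 0 wherever p > 0 because q is estimated from a superset of the
binned codons. Finite bins bias KLD upward even under the null, so the
reported profile subtracts the mean KLD of SSC-shuffled replicates
(default 100, seeded) rebinned identically; the replicate SD gives the
noise scale. The SSC shuffle permutes codons among all corpus positions
encoding the same amino acid — every protein sequence and the corpus codon
counts (hence q) are preserved exactly, so it isolates positional signal.

Post-start-codon bias compares the codons observed immediately after the
start ATG (or after internal ATGs whose successor is not the stop) with
corpus-wide interior frequencies, using the same test and cutoffs as the
pair analysis, and aggregates obs/exp over the 12 positional-nucleotide
masks (Ann … nnT). Context logos take 18-nt windows (9 nt upstream flank +
anchor codon + 6 nt downstream) and report per-position information
R = max(0, 2 − H − e_n) bits with the small-sample correction
e_n = 3/(2·ln2·n); the anchor positions are dropped from the output.

## Composition

k-mer frequencies use overlapping windows that never span sequence
boundaries, on the coding strand only (no reverse-complement
symmetrisation — these are mRNA coding sequences). ρ_CG = f_CG/(f_C f_G);
ρ_CWG = f_CWG f_C f_W f_G / (f_CW f_WG f_CNG) with W ∈ {A,T} and f_CNG
summed over all middle nucleotides — the formula is applied exactly as
stated, without re-derivation. ρ_CG is returned even when the ρ_CWG
denominator vanishes; accessing an undefined ρ_CWG raises.

GC₃ terciles sort genes by (GC₃, id) and give the middle stratum any
remainder (646 → 215/216/215; 10 → 3/4/3). Group contrasts use a
gene-level percentile bootstrap (default 1000 resamples, seeded) because
genes, not nucleotides, are the exchangeable unit. The SCUO–GC₃ relation
is summarised by a least-squares quadratic (coefficients ascending, R²,
and the interior minimum when the curvature is positive).

## Cross-species comparison

Species profiles carry the 59-long RSCU vector in fixed codon order and
the 61 × 61 adjusted-residual matrix of neighbouring pairs
(r_ij = (o_ij − e_ij)/√(e_ij(1 − row_i/N)(1 − col_j/N)), approximately
N(0,1) under independence; cells with a zero marginal get 0). RSCU
clustering z-scores each codon column across species first — codons with
large absolute usage would otherwise dominate the metric — then applies
average linkage on Euclidean distances (a Spearman rank-correlation
distance is also available). Codon-context trees use
1 − Pearson correlation of the flattened residual matrices. PCA is
centered, with the sign of each component fixed so its largest-magnitude
loading is positive, making scores reproducible across input orders.
Dendrograms are emitted as Newick with linkage heights as node depths and
sanitised leaf names.

## Synthetic corpora

The generator draws gene lengths from a lognormal law with mean ≈ 214
codons, floored at 102 codons (so every gene is eligible for positional
binning) — a corpus of the default 646 genes then holds ~138k codons,
typical of a transcriptome-scale ORF set. Amino acids are uniform over the
20 by default; within-family codon weights, stop-codon weights and
flanking profiles default to uniform, so the default corpus is an
everything-null corpus and all structure is injected explicitly:

* **codon_weights** set within-family probabilities; the implied RSCU
  target is S_i·w.
* **pair_coupling** reweights a first-order Markov chain over the 61
  interior codons: P(c_t | c_{t−1}) ∝ P0(c_t)·coupling(c_{t−1}, c_t). A
  weight w on (a,b) enriches the neighbouring pair by slightly less than
  w-fold (the row normalisation absorbs P0(b), and the single-codon
  marginal shifts), which is why recovery is asserted to 15% rather than
  exactly. Spaced pairs stay near independence, mirroring the observation
  that neighbour coupling does not propagate to d ≥ 1.
* **positional_overrides** replace family weights for codons falling in a
  named bin, moving within-family shares (hence KLD) only there.
* **upstream/downstream profiles** and **post_start_first_nt** inject
  flanking-nucleotide motifs; the post-start bias acts on the whole codon
  choice at position 2 (first-letter reweighting across families), since a
  within-family reweighting could not move the first nucleotide.

The SC shuffle permutes all interior codons across the corpus; start/stop
codons stay in place, so gene lengths are preserved and shuffled records
remain valid ORFs by construction (interior codons of validated ORFs are
never stops).

What passing on synthetic data shows — and does not. The generator
produces i.i.d.-per-position (or first-order Markov) codons with clean
flanks; real transcriptomes add expression-weighted sampling, assembly
artefacts, isoform redundancy, amino-acid composition structure and
long-range correlations. The validation therefore establishes
correctness of the statistics and calibration of the tests under their
own null, not robustness to annotation error in real data; the filtering
stage is the only guard against the latter.

## Problem sizes and numerical choices

Test and acceptance runs use corpora of 500–2000 genes (~10⁵–4×10⁵
codons), 20 null replicates for type-I-error checks, 100 SSC replicates
for the KLD baseline and 1000 bootstrap resamples — sizes at which the
asserted tolerances (RSCU ± 0.05, RSCPU ± 10%, ρ_CG ± 0.02 at 10⁶ nt,
call rate ≤ 1%) hold with large margin under the generating model. All
randomness flows through numpy `default_rng` seeds recorded in the run
manifest; reruns with the same configuration and seed are reproducible.
Normalisation identities (RSCU/RSCPU family means, per-mille sums, PCA
variance ratios) are asserted to 1e-9.

## Known limitations

* The Audic–Claverie test treats the rounded expected count as an observed
  library count; for very small expectations the rounding discretisation
  dominates, which is why the fold-change gate matters at small N.
* RSCPU is undefined for amino-acid-pair families never observed; they are
  simply absent from the map.
* The comparative module's "adjusted RSCU" (per-codon z-scores) is one of
  several reasonable standardisations; the rank-correlation metric is
  provided as an alternative.
* No mRNA secondary-structure or folding-energy computation, no CAI/ENC,
  no GO annotation: these are outside the package's scope.
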
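# Methods

This note records the models implemented in `umiamp`, the defaults that
matter, and the design choices made where the procedure was genuinely open.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Read model and barcode extraction

A barcoded amplicon read is `tag5 | UMI | primer | insert`: a universal tag
(~21 nt), a random UMI of 6–12 nt (default 10), the target-specific sequence
of the barcoded primer, then the insert. Only one primer of each pair carries
the UMI; mates inherit the assignment of the barcoded side.

Trimming removes the best 5′ occurrence of the tag and the best 3′ occurrence
of its reverse complement, scored by error rate over the matched length.
Defaults: error tolerance 0.1 of the matched length (mismatches and indels,
via edlib infix alignment) and minimum partial end overlap 3 nt. These mirror
common adapter-trimming semantics; they are declared defaults, not values
with an external source, and are exposed as parameters.

Primer matching allows substitutions only (≤1 by default) at offsets within
±2 of the expected UMI length. An indel inside the primer would shift the
barcode boundary unreliably, so such reads fall to off-target rather than
acquire a wrong barcode. The unique best hit (fewest mismatches, then
smallest offset) wins; a tie between amplicons is off-target. Barcodes whose
length differs from the expected UMI length (within the ±2 search window)
are retained on an off-length stream and flagged for the clustering stage.
The four read categories — tagged, off-length, off-target, untrimmed — are
mutually exclusive and sum to the input count; untrimmed takes precedence
since without the tag the layout anchor is gone.

Extraction can alternatively use an external alignment (`pysam` records): the
amplicon whose primer-start coordinate matches the alignment start within a
slack of 2 is assigned and the query bases before the inferred primer start
(the aligner's soft clip) form the barcode. On clean reads the two routes are
tested to agree exactly.

## Barcode clustering

PCR or sequencing errors inside the UMI create "mutant" barcodes. Because an
error-free barcode should appear in substantially more reads than any single
erroneous version, barcodes within edit distance 1 (Levenshtein; indels are
in scope because length-changing errors demonstrably occur) are merged when
the putative ancestor has ≥ 6× the candidate's reads (6.0× exactly
qualifies). Exceptions allow more aggressive clustering where the evidence
for independence is weakest: single-read barcodes join any cluster within
distance 1 with the ratio waived, and off-length barcodes join within
distance 2 with the ratio waived. The exception thresholds are declared
defaults exposed as parameters (`max_dist`, `offlen_dist`, `ratio`).

The scan is a deterministic greedy pass: barcodes ordered by read count
descending (ties broken lexicographically) each join the qualifying cluster
with the largest canonical read count, comparing only against cluster
*canonicals* — this bounds chain merging (A→B→C absorption through
intermediate variants) and matches the ancestor-with-most-reads assumption.
The ordering and tie-breaks make the output a pure function of the input
multiset; a literal reimplementation of the rule serves as the equivalence
oracle in the tests.

Barcode collisions (two molecules drawing the same UMI) are approximated by
the birthday bound `P ≈ 1 − exp(−n(n−1)/(2·4^L))`; at n = 500 and L = 10 this
is ≈ 0.11 for *any* collision among all pairs, i.e. ≈ 1.2×10⁻⁴ per pair —
negligible against clustering error. The approximation underestimates
noticeably only in tiny barcode spaces (exact enumeration at L = 1 gives 0.25
vs 0.22), which is outside the valid length range and covered by a dedicated
test.

## Consensus reads

Reads within an amplicon share a fixed, primer-anchored layout, so columns
are aligned by offset rather than realigned per read (indel-aware multiple
alignment is out of scope; consensus FASTQ output is suitable for external
realignment and calling). Per column with observations (bᵢ, qᵢ):

- score(b) = Σ qᵢ over reads showing b; consensus base = argmax;
- consensus quality = min(60, score(winner) − Σ score(others)), floored at 2;
- a score tie, or a winner supported by ≤ half the covering reads, emits `N`
  at quality 2 — deliberately conservative, because thin clusters otherwise
  inflate false calls;
- a deletion observation competes like a base and, if it wins, the column is
  omitted;
- single-read clusters pass through unchanged (their qualities are the only
  evidence available).

This sum-of-phred rule with subtractive quality and a cap of 60 is this
package's concrete formulation of abundance-plus-quality consensus; the cap
and majority floor are parameters, and alternative column rules can be
plugged in at `consensus_from_pileups`.

## Molecule counting and technical noise

Quantification counts barcode clusters (molecules) and raw reads per amplicon
and replicate. For cross-run comparison, counts restricted to amplicons
observed in all replicates are scaled to a mean of 10,000 and
log2-transformed (the restriction guarantees positivity, so no pseudocount).
For noise estimation, replicates are first downsampled to equal read totals
(seeded uniform sampling without replacement, removing sequencer-loading
variability), then CV = sample SD / mean is computed on raw counts. The
sample (n−1) SD is the default — unstated in comparable protocols and
material at n = 3 replicates — and is exposed as `ddof`. The Poisson
sampling limit 1/√mean is attached per amplicon.

Note an estimation artifact that the tests account for: with 3 replicates the
sample SD is biased low (E[SD] ≈ 0.886 σ at n = 3), so even exactly
Poisson-distributed counts show mean CV/limit ratios around 0.85–0.9. The
noise-suppression checks therefore use the mean ratio over ≥ 200 amplicons
with a ±25 % band rather than per-amplicon equality.

## Sampling statistics and the naive caller

The number of variant molecules among n sampled molecules at allele fraction
f is Binomial(n, f); the power of a caller requiring ≥ k variant molecules is
the exact binomial tail P(X ≥ k). The inverse (smallest n reaching a target
power) is found by bisection on the monotone tail. The equivalent
negative-binomial formulation — molecules sampled until the k-th variant —
gives the same required-n answer; the binomial tail is primary here because
the experiment fixes n, not k. DNA input converts via ≈ 3,300 haploid genome
copies per 10 ng of human genomic DNA and a capture efficiency (fraction of
input molecules that end up as barcoded consensus reads).

Accuracy metrics are set-algebraic: sensitivity = |called ∩ truth| / |truth|,
FPR = |called \ truth| / bases of evaluated region, reported to one decimal
in percent.

The molecule-level allele counter is plumbing for closed-loop tests, not a
production caller: per site it counts consensus molecules per non-reference
base (`N` excluded from numerator and denominator) and calls when the count
reaches `min_variant_molecules` (default 2) and the fraction reaches
`min_fraction` (default 0.005, half the 1 % target fraction). One boundary
deserves note: at n = 400 molecules a true 2-copy site sits exactly at
2/400 = 0.005, so any cluster-count inflation (401 recovered molecules makes
the fraction 0.4988 %) silently fails the fraction test. The closed-loop
power comparisons therefore run the counter with a non-binding fraction
threshold (0.004), so that the quantity measured is the ≥ k-molecule rule the
binomial model describes; the default is kept for standalone use.

## The synthetic data generator

The simulator emulates the molecular process with known truth:

- **Molecules.** Per amplicon, n molecules (fixed, or Poisson-resampled per
  replicate). Each independently carries each configured variant: a
  homozygous variant of an admixed genome at the mixture fraction (default
  0.02), a heterozygous one at half of it (0.01), or an explicit per-variant
  fraction. Each molecule draws a uniform random UMI; collisions are allowed
  and visible in the truth table, so the birthday approximation is testable.
- **Amplification.** Reads per molecule ~ Poisson(μ · Lᵢ) with μ =
  `mean_reads_per_molecule` (default 10) and Lᵢ ~ lognormal(0, σ) per
  molecule. The default σ = 2.0 reflects the multiplicative compounding of
  per-cycle efficiency differences over the ~25 cycles of universal PCR this
  library design uses: it produces read-count CVs severalfold above the
  Poisson limit while barcode counts stay at it, the regime in which molecule
  counting pays off. σ is per-molecule; run-to-run efficiency shifts of a
  whole amplicon are not separately modelled.
- **Errors.** Each read accumulates PCR substitutions over a simplified
  binary duplication lineage of depth ⌈log₂(reads)⌉ at `pcr_error_rate`
  (default 10⁻⁴ per base per generation) — enough to create the
  correlated-within-cluster errors that stress clustering and consensus
  without simulating a full branching tree — then sequencing substitutions at
  `seq_error_rate` (default 10⁻³). Qualities are Gaussian (mean 33, SD 3)
  truncated to [2, 41]. Error rates are stated assumptions of the generator,
  not measured values.
- **Determinism.** All draws flow from one seed; identical configuration and
  seed give byte-identical FASTQ. A `deterministic` switch fixes
  reads/molecule for exact-count tests.

What the generator does **not** model: size-selection losses, primer-dimer
molecules, barcode resampling (one template acquiring several UMIs), FFPE
deamination, strand-specific or motif-dependent sequencer error profiles, and
indel sequencing errors. Passing tests therefore demonstrate the pipeline's
correctness under the stated stochastic model, not robustness to every
artifact of real libraries.

## Problem sizes used in tests and the acceptance script

End-to-end recovery runs 2 amplicons × 500 molecules at ~15 reads/molecule
(≈15,000 reads) with amplification dispersion 0 — the recovery criterion
fixes reads/molecule at 10–20, and with heavy-tailed amplification a material
fraction of molecules emits no reads and is unrecoverable by any method, so
recovery is measured against molecules with ≥ 1 read. Noise suppression uses
200 amplicons × ~100 molecules × 3 replicates at the counts level (the CV
property concerns count distributions, not base calls). The closed loop runs
50 variant sites across 10 amplicons at 400 molecules each (≈50,000 reads).
These sizes keep every check comfortably reproducible on a single CPU while
leaving the statistical assertions well-powered.

## Known limitations

- Columns are never realigned, so insertions within the insert shift all
  downstream columns of that molecule's reads; indel variants are out of
  scope for the naive caller.
- Mate (read 2) sequences are carried but not folded into consensus; the
  barcoded side carries all molecule information used.
- Clustering compares candidates to canonicals only; pathological barcode
  sets with long mutation chains would over-split rather than over-merge.
- The CV machinery assumes replicates are exchangeable; no batch covariates.
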
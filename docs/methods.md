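# Methods

## Model and assumptions

`asepipe` measures allele-specific expression (ASE) in F1 individuals bred
from two inbred, (near-)homozygous parental lines — e.g. isofemale fly
lines — where every informative site is a **fixed SNP**: each parent
monomorphic, alleles different. Three assumptions follow:

- Parents differ from each other and from the reference by substitutions
  only; the two parent-specific genomes share the reference coordinate
  system. Genomes differing by indels are rejected on input.
- An F1 read pair belongs to exactly one parental haplotype, observable
  only where the pair covers a fixed SNP. Pairs covering none, or showing
  conflicting diagnostic alleles, are ambiguous; there is no majority vote,
  because a single conflicting site already falsifies "unambiguous".
- Mapping bias is a property of the (sequence, mapper) combination, so the
  bias measured on simulated reads pushed through the same mapper applies
  to the real reads.

## Pipeline

1. **Fixed-SNP inference.** Parental reads are mapped and piled up
   CIGAR-aware (insertions consume query, deletions reference, soft clips
   neither; mate-overlapping bases of a pair count once; N and deletion
   observations are excluded). A site is called iff both parents have
   depth ≥ `min_depth` (default 10) and a major allele with purity ≥
   `min_purity` (default 0.9), and the major alleles differ. The paper-level
   concept of "fixed" fixes no thresholds, so both are configuration knobs;
   the defaults tolerate sporadic sequencing errors while demanding
   near-monomorphic parents. The map → call → substitute → remap loop runs
   until the SNP set is unchanged or `max_iters` (default 2) is reached;
   convergence is set-equality of (chrom, pos, alleles) tuples, so cycling
   is impossible to miss.
2. **Diploid construction.** Alleles are substituted into copies of the
   reference; with two provided genomes the SNP map is derived by pairwise
   comparison instead (N positions are not diagnostic) and stage 1 is
   skipped. Features (genes and exons from GTF) are *projected*: each
   carries its ordered contained SNPs. Zero-SNP features are reported as
   not assessable rather than given a vacuous 50/50 result.
3. **Grid simulation.** For each SNP of each feature, fragment starts are
   the absolute multiples of `grid_step` whose fragment (2·read_length +
   insert_size) overlaps the SNP and fits the spliced transcript; each
   start emits one error-free pair per parental genome. Counts from the two
   genomes are equal by construction, so an unbiased mapper must return a
   ratio of one. Templates are spliced transcripts because that is what
   RNA-seq fragments are drawn from; grid reads carry no sequencing errors
   so the estimate isolates mapping artifacts. Default geometry is
   2 × 100 bp with a 78 bp insert; `grid_step = 1` is the default density
   (tests and the acceptance script use 3–4 to keep desk-scale runs brisk).
   A pair may overlap its SNP only within the unsequenced insert gap; it is
   then counted ambiguous, identically for both genomes, and does not move
   the ratio.
4. **Counting.** A mapped pair is assigned p1/p2/ambiguous by the rule
   above and added once to every feature containing a diagnostic SNP it
   covered (gene and exon rows in one pass); pairs overlapping a feature
   without covering its SNPs increment that feature's ambiguous column as
   QC. Applied to the mapped grid this yields per-feature bias factors
   `b = sim_p1/sim_p2`; `100·|b−1| > 5` marks a feature as more than weakly
   biased, and `sim_p2 = 0` marks it untestable.
5. **Statistics.** See README for the G-test, ANOVA, TMM and BH-FDR forms.
   Within one library the allele ratio cancels library size, so TMM and
   library-size adjustment enter only at the replicate level (ANOVA);
   pooling for the G-test is unweighted. The 0.5 pseudocount keeps
   log-ratios finite; features with fewer than `min_total` (default 10)
   pooled pairs are tested but flagged low-coverage. Gene and exon families
   get separate FDR corrections.

## The bundled aligner

A deterministic exact-k-mer (k = 20) seed-and-extend, ungapped, paired-end
aligner scores every candidate locus on *both* haplotypes and keeps the
better score (≤ 5 mismatches per read; insert within nominal ± 20). A best
score achieved at two different loci is a multi-mapping tie and the pair is
discarded; equal scores at the same coordinate on the two haplotypes are
kept — that is allelic ambiguity, which the assignment stage handles. This
separation (mapping ambiguity = noise, allelic ambiguity = data) is the
contract any external mapper must honour; bring-your-own-SAM inputs bypass
the bundled aligner entirely. Being ungapped, it is not splice-aware:
self-contained runs use genomic parental reads and single-exon fixtures,
while spliced data requires an external mapper.

## Synthetic data: what it emulates and what it does not

`generate_fixture` builds a random single-chromosome transcriptome
(default 20 genes × 1 kb exonic sequence, 5 planted fixed SNPs per gene,
parent 1 carrying the reference allele), evenly tiled parental genomic
libraries at ~20× (deterministic coverage, so SNP recovery measures the
caller rather than coverage luck), and F1 replicates of 200 pairs per gene
with allele-1 fraction r/(1+r), optional substitution errors, optional
random mate orientation, and optional allele-1 dropout — each allele-1 pair
silently removed with probability `dropout_p1`, mimicking allele-specific
mapping loss. Everything derives from one seed; identical seeds give
byte-identical files. Not emulated: splice junctions in read space,
base-quality structure, PCR duplicates, coverage heterogeneity, indel or
structural variation, non-fixed (segregating) SNPs within parents. Passing
tests therefore demonstrate correctness of the machinery under the model's
assumptions, not robustness to every artifact of real libraries.

`simulate_count_tables` draws the same per-gene quantities directly as
binomials (F1 allele-1 count ~ Binomial(depth, r/(1+r)) thinned by the
dropout; grid counts with the parent-1 side thinned at the same rate, i.e.
the grid runs through the same lossy mapper). Statistical calibration
studies — type-I error on 2,000 null genes at depth 200, bias-correction
efficacy under 10% allele-1 dropout, parameter recovery at depth 2,000 —
use this count-level path: the quantities tested are exactly the ones the
read-level pipeline produces, and the read-level path is itself verified
end-to-end on the 20-gene fixtures (grid ratio of one, ≥ 99.99% correct
parental assignment, exact planted-SNP recovery, pipeline determinism).

## Numerical choices

- `bias_pct` is computed as `100·|p1−p2|/p2`, exact on integer counts, so
  the 5% boundary classification is not floating-point dependent.
- `G` is clamped at 0 (rounding can produce −1e-16 for perfect fits);
  `0·ln 0 = 0`.
- ANOVA with identical responses across replicates is degenerate: p = 1
  with a flag when the mean is also zero, p = 0 with a flag otherwise.
  Identity is detected by zero range, not by the computed variance, to be
  robust to summation rounding.
- TMM: reference library is the one whose upper-quartile scaled count is
  closest to the mean; all-zero-overlap or fully trimmed comparisons fall
  back to a factor of 1; factors are rescaled to unit geometric mean.
- Ordering of every output table is fully specified (feature id within
  q-value within level), making runs byte-reproducible.

## Known limitations

- No splice-aware or gapped alignment in the bundled mapper.
- Indel and structural differences between parents are out of scope.
- Overlapping genes sharing a diagnostic SNP are both incremented; no
  disambiguation is attempted (the overlap is visible in the counts).
- The G-test treats pooled counts as one binomial draw; overdispersion
  across replicates is the ANOVA's job, and unreplicated designs inherit
  the G-test's anti-conservativeness under extra-binomial noise.
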
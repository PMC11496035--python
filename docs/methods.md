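# Methods

## Problem and model

A-to-I RNA editing is observed as A>G mismatches between stranded RNA-seq
reads and the genome (inosine base-pairs like guanosine).  Calling
editing sites therefore reduces to a filter cascade over per-position
base counts that separates editing from genomic variation and noise:

1. **Evidence.**  Each surviving aligned base contributes one count at
   its genomic position, keyed by the read's *transcript* strand.  Reads
   are dropped for: unmapped / secondary / supplementary / duplicate
   flags, mapping quality < 20.  Bases are dropped for: base quality
   < 25, or falling in the first 6 (last 0) *sequenced* positions of the
   read — the classic read-end artifact trim.  Under the default dUTP
   protocol ("second read matches the transcript strand") a single-end
   read is antisense to its transcript; `first_read` and `unstranded`
   protocols are provided.
2. **Per-sample call.**  At each position the strand carrying the
   majority of coverage is used.  A site is called iff coverage ≥ 10;
   exactly one alternative base has ≥ 2 reads (two alternatives ≥ 2
   reject the position — editing is a single deterministic
   substitution); level = alt/(ref+alt) ∈ [0.01, 0.95]; and, when DNA
   evidence exists at the position, DNA coverage ≥ 5 with 0 DNA variant
   reads.  Positions without DNA coverage are retained but flagged
   `no_dna_support`.  Ref/alt are reported in transcript orientation.
3. **Masking and aggregation.**  Sites at positions listed in any
   VCF/BED SNP source are removed (position-based, allele-agnostic —
   interval-intersection semantics).  Site keys are unioned across
   samples; a key supported by < 3 calling samples is dropped
   ("supported" = called, not merely covered).  Conflicting substitution
   types at one position resolve to the type with most supporting
   samples, then most alt reads, then the lexicographically smallest
   code.  Matrix cells distinguish level (called), 0.0 (coverage ≥ 10
   but not called) and missing (insufficient coverage).

### Annotation

Region precedence is CDS > 5'UTR > 3'UTR > exon_noncoding > intron >
upstream/downstream > intergenic, with a 5,000 bp up/downstream flank
(SnpEff's default window; configurable).  Among overlapping genes, a gene
on the site's strand wins, then the higher-precedence region, then the
lexicographically smallest gene id — so results are independent of GTF
record order.  Multi-transcript genes are annotated against the
transcript yielding the highest-precedence region.  For CDS sites the
spliced codon is extracted (reverse-complemented for minus-strand genes),
the edited base substituted, and both codons translated with the standard
genetic code.  Stop-gain is kept as its own class even though A>G cannot
produce a stop from a sense codon — asserting its emptiness is a free
correctness check.  Editing of a stop codon that yields a sense codon is
folded into `missense`.

### Sequence context

The ±10 bp window around each A-to-I site (21 positions), reverse
complemented for minus-strand sites so position 0 is always the edited A
in transcript orientation.  Context is genomic (pre-mRNA), not spliced —
ADAR acts co-transcriptionally on intron-containing duplexes.  Windows
truncated by contig ends are dropped, not padded (padding distorts
frequencies).  Enrichment is log2(observed/background) per position and
base against the genome-wide composition; zero counts are replaced by a
0.5 pseudocount so exact agreement with the background gives exactly 0.

### miRNA target rewiring

miRanda-style behaviour is approximated with a documented surrogate
scheme (exact reproduction of miRanda v3.3 output is a non-goal): local
affine-gap alignment of the reversed miRNA against the target with
Watson-Crick +5, G:U wobble +2, mismatch −3, gap open/extend −8/−2;
miRNA seed positions 2–8 weighted ×4; no match credit at position 1 or
beyond 19.  Surrogate energy −0.5·(3·GC + 2·AU + 1·GU) over the aligned
pairs.  Hits must reach score ≥ 140 and energy ≤ −10 (the conventional
miRanda thresholds).  The published ×2 seed weighting was replaced by
miRanda's own ×4 scale factor: with ×2 the maximum attainable score for
any miRNA ≤ 26 nt is 11·5 + 7·10 = 125, i.e. the score threshold of 140
would be unreachable by construction, so ×4 is the smallest standard
choice that makes the stated thresholds meaningful (a perfect 22-mer
duplex scores 11·5 + 7·20 = 195).  For the gain/loss decision, scanning
is restricted by default to the 21-bp window centred on the edited base
(full-UTR scanning is a flag); only hits overlapping the edited position
count.  A miRNA is *lost* if it has a passing overlapping hit before but
not after the A→G substitution, *gained* in the symmetric case.

### Stage statistics

"Variance analysis" is read as one-way fixed-effects ANOVA on editing
levels per site (3 stages × 3 replicates); a Kruskal–Wallis option
exists because levels are proportions.  A site is tested when ≥ 2 stages
have ≥ 2 usable values; all-equal inputs are reported as F = 0, p = 1
rather than NaN.  Undetected-but-covered cells enter as level 0
(absence of editing at adequate coverage is evidence of level ≈ 0);
uncovered cells are excluded.  The significance call is uncorrected
p < 0.05 to match common practice in this literature; a BH-adjusted
column is always emitted alongside.  Stage-specific sites are those
called in ≥ 1 sample (configurable) of exactly one stage and 0 samples
of every other stage.  Enrichment is the one-sided Fisher exact test
(equivalently the hypergeometric tail) over user-supplied GMT sets with
BH adjustment; GO/KEGG retrieval and ID mapping are out of scope.  Hub
genes are a degree ranking on the undirected simple graph of a supplied
edge list (duplicates collapse, self-loops drop).

## The simulator's stated world

Defaults: 2 chromosomes × 100 kb; 12 genes (alternating strands, every
sixth a lincRNA), each with two exons, a CDS of 120–200 codons starting
ATG and ending in a stop with no internal stops, 80–160 bp 5' UTR,
280–420 bp 3' UTR, 500–900 bp intron; ≥ 30 % of the genome stays
intergenic.  300 editing sites are planted on transcript-strand A's with
≥ 25 bp spacing: 30 % differential (levels 0.1/0.5/0.9 across GM/DM1/DM5
— a large, unambiguous effect), 30 % stage-specific (0.4 in one stage, 0
elsewhere), the rest constitutive (0.3 everywhere); 60 CDS sites are
split between predetermined synonymous (third-position A, non-ATA) and
missense (first/second-position A) outcomes, and 8+8 3' UTR sites are
engineered so that a dedicated 22-nt miRNA's seed match is created
(gain) or destroyed (loss) by the substitution.  100 SNP confounders
(DNA-heterozygous A>G positions, RNA level 0.5) are planted and listed
in the emitted VCF — exactly one VCF record per confounder.  Because no
reported depth exists for the emulated design, coverage defaults are
chosen for testability: RNA coverage ~ Poisson(100) per position within
gene bodies, DNA ~ Poisson(30); alt counts ~ Binomial(coverage, level);
a symmetric error floor (default 0.001) elsewhere.  An optional context
bias resamples the −1/+1 neighbours of planted sites (e.g. 10 % G
upstream, 40 % G downstream) to emulate the ADAR motif.

Engineered miRNA sites are *validated at generation time*: each
candidate (site, miRNA) pair, and its cross-talk against every other
engineered miRNA and window, is checked with the package's own scanner
under default parameters, and conflicting random draws are rejected.
This guarantees the planted gain/loss truth holds exactly for the
default scan configuration; under non-default scan parameters the truth
table is not guaranteed.  Independence of the tests is preserved by
separate oracles: duplex scores are checked against a brute-force
dynamic-programming oracle, and gain/loss symmetry against the inverse
substitution.

What the simulator does **not** emulate — and hence what a green test
does not establish: realistic error profiles (errors are uniform and
strand-symmetric), indels and splicing-aware reads, coverage biases
(RNA coverage is uniform across gene bodies including introns),
overlapping genes, hyper-editing clusters, and any property of the real
deposited datasets.  Recovery results on this world are statements about
the pipeline's correctness, not about biological replication.

## Numerical choices

* Seeding: every generator draw derives from `default_rng([seed, k])`
  with a distinct stream id `k` per operation, so each step is
  independently reproducible and outputs are byte-identical under a
  fixed seed.
* Strand ties at site calling go to '+'; argmax ties among alternative
  bases resolve alphabetically (only reachable in rejected multi-allelic
  cases).
* ANOVA on constant input returns (0, 1) explicitly; infinite F (zero
  within-group variance, distinct means) maps to p = 0.
* Spearman on constant vectors reports rho = NaN with an explanatory
  note instead of raising.
* The duplex aligner resolves score ties toward the leftmost, shortest
  alignment; non-overlapping hits are found by best-hit masking and
  recursion into the flanking segments.
* Coordinates are 1-based inclusive in every interface; BED input is
  converted from 0-based half-open at the boundary.

## Known limitations

* The DNA pileup is consumed as given (no genotype-likelihood model);
  GATK-style variant calling and BQSR are out of scope.
* `pileup_from_tsv` trusts upstream quality filtering, as documented in
  the dialect.
* The miRNA scorer is a surrogate: thresholds carry over from miRanda
  conventions but scores are not comparable to miRanda's.
* Chromosome-level Spearman correlations need ≥ 3 chromosomes; the
  default demo world has 2 and reports the correlation as undefined.
* Hyper-editing cluster detection and editing-vs-expression causal
  analysis are not implemented.
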
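# Methods

## The cASE statistic

A transcribed variant at which an individual is heterozygous acts as a
*reporter*: RNA-seq reads covering it can be assigned to the reference
or alternative allele, and an imbalance between the two read counts
reveals unequal expression of the two gene copies. casekit aggregates
this evidence across individuals into a single *combined
allele-specific expression* (cASE) measure per reporter.

Per sample *i* with reference count *r<sub>i</sub>* and alternative
count *a<sub>i</sub>* (coverage *n<sub>i</sub> = r<sub>i</sub> +
a<sub>i</sub>*), the exact two-sided binomial p-value against a
balanced expectation is

  p<sub>i</sub> = P(|X − n<sub>i</sub>/2| ≥ |r<sub>i</sub> − n<sub>i</sub>/2|),  X ~ Binomial(n<sub>i</sub>, ½),

computed from the symmetric pmf (2·CDF at min(r,a), capped at 1).  The
exact test is preferred over a normal approximation because reporter
coverage is frequently low.  Each p-value is mapped to a signed
deviate z<sub>i</sub> = sign(r<sub>i</sub> − a<sub>i</sub>) ·
Φ⁻¹(1 − p<sub>i</sub>/2), positive for reference-allele excess, and
capped at |38| (the probit of the smallest positive double) so extreme
counts never produce infinities.

Deviates are combined with a coverage-weighted Stouffer rule,

  Z = Σ w<sub>i</sub> z<sub>i</sub> / √(Σ w<sub>i</sub>²),  w<sub>i</sub> = n<sub>i</sub>,

which is the standard unit-variance construction for weighted
combination of standard-normal deviates; unit variance under the null
is what makes the calibration and subgroup comparisons below
well-defined.  Duplicating a sample is deliberately *not* equivalent
to doubling its weight (the denominator is √Σw², not Σw); a dedicated
test guards this against regression.

### Permutation null and two p-values

The null distribution is built from the same read counts with the
allele labels of each sample independently swapped with probability ½
(1000 draws by default).  Reassigning intact (ref, alt) pairs across
individuals would leave Z literally unchanged — every z<sub>i</sub>
would keep its own weight — so label flipping is the only shuffle of
the observed counts that produces a usable null.  Because the
two-sided binomial p is symmetric under the swap, a flip is exactly a
sign change of z<sub>i</sub>, and the null is computed that way.  The
random stream is keyed to (seed, CRC32 of the reporter id) with
samples in sorted order, so results are independent of row order and
reproducible across processes.

Two p-values are reported:

* **p_perm** — the add-one empirical estimate
  (1 + #{|Z<sub>k</sub>| ≥ |Z|}) / (1 + N), floored at 1/(N+1);
* **p_tail** — a Gaussian tail 2·(1 − Φ(|Z − μ̂|/σ̂)) with μ̂, σ̂
  fitted to the null draws, which resolves significance far below the
  permutation floor.

Note the conditional null preserves the observed count magnitudes, so
under a genuine strong effect the null is wide (each |z<sub>i</sub>| is
large) and p_tail is a conservative statement of how surprising the
observed *coherence of directions* is — it is not the tail of a
standard normal at Z.  Reporters whose samples are all perfectly
balanced have a degenerate (point-mass) null; they are reported with
p = 1 rather than an error.

Across reporters, Benjamini–Hochberg FDR is applied to p_tail
(column `q_value`).  Samples under `min_cov` reads (default 10) are
dropped; a reporter with no surviving sample is emitted flagged
`low_coverage` with direction "none" and p = 1 instead of silently
disappearing.

## Candidate mediation within TADs

Regulatory variants act mostly within their topologically associating
domain, so for each reporter the candidate set is every other variant
sharing at least one TAD with it (union over overlapping TADs;
membership uses the explicit convention that a 1-based variant
position p lies in a BED interval (s, e] iff s < p ≤ e).

Reporter-heterozygous samples are split by candidate genotype:
heterozygous (dosage 1) versus homozygous (0 and 2 pooled); missing
calls are dropped, never imputed.  With R.Z the all-sample reporter Z
and C.Z the Z of the candidate-het subgroup, the candidate is proposed
as a putative mediator when

1. |C.Z| > |R.Z| strictly — the signal concentrates in the samples
   that can transmit a cis effect;
2. the homozygous subgroup is non-significant — its Z, unit-variance
   under the null, has standard-normal tail p ≥ α (default 0.05);
3. both subgroups have at least `min_subgroup` = 3 samples (a
   one-sample Z is degenerate for the comparison).

Both comparisons are made on the combined Z scale, which is
unit-variance by construction; the homozygous subgroup uses the
analytic normal tail rather than its own permutation null because the
same scale argument applies and it keeps the candidate scan cheap.
The reporter can never nominate itself (its hom subgroup is empty and
|C.Z| = |R.Z| fails the strict inequality).  The rule is a heuristic
Z comparison, not a formal mediation model; collider or dilution
effects from candidates correlated with unobserved drivers are out of
scope.

LD between candidate and reporter is annotated as the squared Pearson
correlation of unphased dosage vectors over pairwise-complete samples
(composite r²).  Monomorphic pairs give an undefined r² reported as
missing — never 0, which would wrongly claim evidence of equilibrium.

## Synthetic data

The generator emulates the minimal structure the analysis relies on:

* **Genotypes.** Two haplotypes per sample, independent, summed to a
  genotype — Hardy–Weinberg by construction.  LD within a block comes
  from first-order copying: the first variant is Bernoulli(MAF), each
  subsequent variant copies the previous variant's allele with
  probability c, else is redrawn.  For equal MAFs the haplotype
  correlation between adjacent variants is exactly c (and products of
  c along the chain for distant pairs), so target r² values are set
  directly: the packaged tag scenario uses c = 0.9798 for r² ≈ 0.96
  and chain placement for two r² ≈ 0.05 candidates; the mediation
  scenario uses c = 0.7 for r² ≈ 0.49.
* **Coverage.** Gamma–Poisson (negative-binomial) depth with mean μ
  (default 50) and variance μ + dμ² (dispersion d = 0.3), floored at
  one read.  RNA-seq depth is overdispersed; the defaults are package
  choices for a realistic islet-like depth profile, not estimates from
  any dataset.
* **Allelic skew.** A designated causal variant carries a risk allele
  (its reference allele by default, configurable).  A
  reporter-heterozygous sample's expected reference-read fraction is
  θ when the reporter's reference allele shares a haplotype with the
  risk allele, 1 − θ when anti-phased, and exactly ½ when the sample
  is homozygous at the causal variant — cis-regulation acts only
  through the carrying haplotype.  Reference counts are binomial
  around that fraction.

Everything is deterministic given the config seed (two SeedSequence
streams: haplotypes and counts), and only reporter-heterozygous
samples emit records.

What the generator does **not** model: read-mapping bias toward the
reference allele, within-sample overdispersion of the allelic fraction
(beta-binomial noise), multi-gene expression structure, genotyping
error, and coalescent LD patterns.  Passing tests therefore
demonstrate the statistical machinery is correct under its stated
assumptions, not that real RNA-seq counts satisfy those assumptions —
in particular, real data would need an upstream mapping-bias
correction before the binomial model is trustworthy.

### Default study conditions used in validation

Calibration uses 2,000 independent null reporters (θ = 0.5, 20
samples, mean coverage 30, 200 permutations each) and checks the
empirical rejection rate at α = 0.05.  Power uses 100 replicates per
θ at 30 samples and coverage 50.  Mediation recovery uses 100
replicates of the default causal scenario (θ = 0.75, 60 samples,
coverage 50, candidate r² ≈ 0.5).  These sizes make the whole
validation run in well under a minute of CPU while keeping Monte-Carlo
error small relative to the acceptance bands.

## Assay quantifications

Closed forms, each returning its defined identity value exactly:

* CRISPR deletion efficiency from wild-type-allele qPCR with a
  copy-number reference gene: (1 − 2^−ΔΔCt) × 100 with
  ΔΔCt = ΔCt_edited − ΔCt_wt.  The sign is fixed so that a *later*
  target Ct in edited cells (fewer intact alleles) yields positive
  efficiency — the only direction consistent with deletion.  Negative
  efficiencies are reported unclamped with a warning.
* Relative expression 2^−ΔΔCt; shift-invariant in all four Ct values.
* GSIS: secreted insulin as % of content; stimulation as fold over
  the low-glucose basal percentage.
* Dual luciferase: firefly/Renilla, relative to the empty-vector
  control ratio.
* Growth curves: optical density normalized to day 0.

Technical duplicates are averaged before the formulas are applied
(`average_replicates`); no amplification-efficiency correction
(Pfaffl-type) is attempted.

## Motif scoring

JASPAR-format position frequency matrices (bracketed or plain
dialect) are turned into log-odds against a uniform background after
mixing a pseudocount of 0.8 into the *column frequencies*:
p = (f + 0.8·¼)/(1 + 0.8).  Working on frequencies rather than raw
counts makes the score invariant to rescaling the matrix — two motifs
built from different numbers of sites but identical base composition
score identically.  The relative profile score of a window is
(raw − min)/(max − min) over the column-wise worst/best log-odds sums,
so the consensus scores exactly 1 and the anti-consensus exactly 0.

A variant is scanned by scoring, on both strands, every matrix-length
window overlapping the variant position in the reference and the
alternative sequence; each allele's best score is thresholded (0.80
default) to call differential binding (`both`, `ref_only`,
`alt_only`, `neither`).  Ambiguity codes are rejected rather than
averaged.  No genome-wide scanning and no pinned matrix-database
release: the operator is validated on toy matrices with hand-computed
oracles.

## Numerical and degenerate-input choices

* Exact binomial p computed as 2·CDF(min(r, a)); p = 1 at perfect
  balance; z capped at ±38.
* Zero-coverage records are skipped in batch processing; the scalar
  API raises.
* Permutation p uses the add-one estimator, so it can never be 0.
* Gaussian-tail fit uses the sample standard deviation (ddof = 1) and
  raises on σ̂ = 0 (the pipeline substitutes the empirical p there).
* Multi-allelic VCF sites are rejected by default; an explicit option
  decomposes them into biallelic pseudo-variants.
* BED and count-table parsers report the offending line/row number;
  coordinates are converted between 0-based BED and 1-based variant
  conventions in exactly one place.
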
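# Methods

## The model

`tepop` simulates a fragment of a large vertebrate genome forward in time in a
Wright–Fisher population, tracking two kinds of variants jointly:

* **point mutations**, entering at rate *μ* per bp per generation, assigned a
  fitness class by genomic context (coding vs non-coding) from a configurable
  selection-class table, the remainder neutral;
* **TE insertions**, entering at a genome-wide rate *P* per diploid per
  generation from a fixed pool of progenitor elements assumed to live outside
  the simulated fragment (inserted copies are dead ends: they neither
  transpose nor excise).  The fragment receives the share
  *P* · fragment/genome of the genome-wide rate.

The fragment (default 4 Mb of a 1.78 Gb genome) is tiled 1:2:1 into
high / low / high recombination regions (defaults 2·10⁻¹⁰ and 2·10⁻¹¹
crossovers/bp/generation before rescaling).  High-recombination regions carry
twice the coding density (20,000 vs 10,000 coding bp per Mb), built from
160 bp exons placed uniformly at random without overlap until the per-region
target is reached; the final exon may overshoot the target by less than one
exon length.

Each new TE is **short** (probability `p_long = 0.5`) or **long**.  Fitness
effects are fixed at insertion time from the landing position:

| context | 2Ns |
| --- | --- |
| any TE inside an exon | −2000 |
| long TE, high-recombination region | −10 |
| long TE, low-recombination region | −1 |
| short TE, anywhere non-coding | −0.1 |

The long-TE penalty rising with local crossover rate encodes selection
against ectopic recombination between dispersed homologous copies.
**Insertion bias** *Q* is the probability that a new insertion lands in the
high-recombination region class (position uniform within the class);
*Q* = 0.5 reproduces per-bp uniformity because both classes total the same
length.  **Bursts**: in burst mode transposition occurs only inside a window
opening 1,000,000 years before the present and lasting 100,000 years, at 100
times the constant-mode rate; outside the window the rate is zero.
Generation time is one year, so years convert 1:1 to generations before
rescaling.

Fitness is multiplicative across loci — heterozygote factor (1 + *hs*),
homozygote (1 + *s*), dominance *h* = 0.5 throughout, each factor floored at
zero — and parents are sampled with probability proportional to fitness
(fecundity selection, constant N).  Gametes are formed with per-region
Poisson crossover counts, positions uniform within the region, haplotypes
alternating at sorted crossover points from a fair-coin start.

## Rescaling

A population of 10⁶ diploids is too large to iterate, so all parameters are
rescaled by a factor λ: *μ*, recombination rates and *P* are multiplied by λ;
N and all generation counts (including the burst window) are divided by λ;
per-class selection coefficients are set so that 2·N_scaled·s equals the
declared 2Ns.  θ = 4Nμ, the population map length and every 2Ns product are
invariant; the reference configuration uses λ = 1000 (N = 1000, 20,000
generations).  The mean-field quantities are preserved exactly, but rescaling
compresses timescales, so rare-event regimes (very strong selection,
s approaching −1 after scaling) become more discrete; the validation suite
quantifies what survives at the scales it uses.

## Implementation

Segregating variants live in a position-sorted registry of parallel metadata
arrays.  Haplotypes are sparse, sorted lists of registry indices, so each
generation costs O(total derived alleles carried) rather than O(2N·S);
selected variants are additionally mirrored in per-haplotype sublists so that
fitness evaluation only walks selected alleles.  The inner meiosis, fitness
and registry-rebuild loops are numba kernels.  A dense presence-matrix
backend implements the same generation step from the identical random-draw
sequence; the test suite asserts bit-for-bit agreement between backends,
which pins the sparse kernels to a transparently simple reference.

Numerical/bookkeeping choices:

* finite sites with collision re-draw: a new point mutation landing on a
  currently segregating position is re-drawn (an error is raised if the
  fragment saturates); multiple TE insertions may share a position;
* variants reaching population count 2N move to a substitution log (with
  position and length class, since fixed-TE densities are a target statistic)
  and are dropped from haplotypes — relative fitness is unchanged because a
  fixed multiplicative factor is shared by all individuals;
* a conservation counter verifies created = segregating + lost + fixed;
* neutral point mutations can be tracked at a configurable fraction
  (`tracked_neutral_fraction`).  Neutral sites do not influence the dynamics,
  so thinning only subsamples the SNP measurement channel; frequencies and
  frequency spectra of the tracked subset are unbiased.  Batteries that
  measure absolute diversity (the neutral oracles) always track everything.

## Summary statistics and the sign pattern

Eight diploids are sampled without replacement.  Per region class and TE
length class the suite computes the three statistics used throughout:
mean frequency of polymorphic insertions (sample count strictly between 0 and
2n), polymorphic density per Mb, and fixed density per Mb (sample count
exactly 2n, pooling population substitutions with sample-fixed segregating
variants — what resequencing data shows).  Mean frequencies are NaN (never
silently 0) when no polymorphic variant exists.

The high-vs-low contrast of each statistic across replicates is reduced to a
sign: a two-sided paired Wilcoxon signed-rank test at α = 0.05 (exposed as a
parameter) decides significance, and the direction is taken from the signed
rank mass itself rather than the median difference — with small per-replicate
TE counts the paired differences are heavily tied and a zero median can
coexist with clearly one-sided evidence.  The TE frequency *level* (above or
below the mean derived-SNP frequency) disambiguates burst scenarios; it
compares the replicate-median TE mean frequency pooled over both regions with
the same quantity for derived SNPs.  The sign triplet plus level maps to a
dominant-process label through an exact decision table
(`Linked Sel.`, `Pur. Selec. Ect. Rec.`, burst and preferential-insertion
combinations, else `unclassified`).

## Windowed empirical-style analyses

The windowed toolkit consumes MELT-style TE calls (VCF dialect with clade,
length, divergence, call rate), SNP VCFs with two outgroup columns, BED
window tables carrying an externally estimated ρ = 4N_e·r, and per-locus
differentiation scores, and implements the published filtering rules
verbatim: duplicate calls (< 2000 bp apart, same clade) resolved to the
lowest divergence then highest call rate; loci with any missing genotype
dropped; windowed mean TE frequency undefined below 3 polymorphic insertions;
zero-TE windows flagged excluded; LINE stratification at < 20% (short) and
> 30% (long) of the clade maximum length; candidate loci in the top 1% of
both X^T X and eBPis with an absolute frequency shift ≥ 0.5 between the
northern and Floridian pools, annotated with interval overlap against three
candidate-window tracks.

Statistics: θπ is the unbiased per-site heterozygosity sum 2p(1−p)·n/(n−1)
per bp; dXY = mean between-population difference p₁(1−p₂)+p₂(1−p₁) per bp;
FST is Hudson's estimator combined across SNPs as a ratio of sums (the
estimator is a package choice, switchable in principle, since the upstream
publication did not name one); r/μ = ρ/θπ cancels N_e.  Correlations are
Spearman rank tests with pairwise deletion; the correlogram returns the rho
and P matrices plus a P > 0.05 mask.  Polarization keeps loci where both
outgroup individuals are genotyped, homozygous and agree; the derived allele
is the one they lack.  Sharing categories per individual follow the
precedence outgroup > other cluster > within cluster > private.  Window
coordinates are half-open 0-based; variant positions 1-based; conversion is
centralized in the IO layer.

## Synthetic data

The generators produce self-contained fixtures with exact truth tables:

* per-window TE counts coupled to a log-uniform AR(1) recombination map
  through a Gaussian copula whose latent correlation is enforced exactly in
  sample, so the realized Spearman tracks the target closely (the
  Spearman→Pearson conversion 2·sin(πρ/6) maps the target onto the latent
  scale);
* per-cluster genotype frequencies from Beta models: a singleton-skewed
  shape for large stable clusters and a flatter shape for recently
  bottlenecked ones;
* planted duplicates (same-clade twin < 1500 bp away with strictly higher
  divergence; all other same-clade calls are kept ≥ 4000 bp apart so no
  accidental chain forms), planted missing genotypes, and planted candidate
  loci with deterministic genotypes guaranteeing the frequency shift;
* score backgrounds constructed so that no non-planted locus falls in the
  joint top-1% tail of both statistics (the top background X^T X loci receive
  the bottom background eBPis values), making the planted candidate set the
  exact ground truth of the filter.

What the generators do **not** emulate: read-level evidence and genotyping
error, linkage between loci, shared ancestry of allele frequencies across
clusters (per-cluster frequencies are independent, which understates private
variation), and real TE sequence features.  Passing the planted-recovery
tests therefore demonstrates the correctness of the filtering and windowing
logic, not robustness to MELT-specific artefacts.

## Validation batteries and problem sizes

The suite validates the simulator against independent oracles at reduced
scale (sizes chosen once, stated here as the package's configuration):

* **neutral oracles** — N = 100, 1 Mb, 2,000 generations, 50 replicates, all
  selection off: mean π within 15% of 4Nμ; the sample SFS against the
  neutral 1/i expectation using across-replicate variance (linked sites
  share genealogies, so pooled site counts are not independent draws);
  fixation probabilities of a single semidominant variant over 20,000 trials
  per coefficient at 2Ns ∈ {0, 1, 10} against the diffusion approximation
  (1−e^(−2hs))/(1−e^(−4Nhs));
* **insertion bias** — the preferential-insertion scenario at N = 100, 1 Mb,
  2,000 generations, 10 replicates: the realized draw-time fraction of
  insertions in high-recombination regions against the configured 70% within
  the pooled binomial 99% CI;
* **scenario sign rows** — constant, burst and preferential-insertion
  scenarios at N = 200, 1.5 Mb, 4,000 generations, 50 replicates each
  (λ = 5000 relative to the full-size population, all 2Ns preserved).

At this scale each replicate carries only a handful of polymorphic TE
insertions per region class (the per-Mb TE input is scale-invariant, but the
region classes are a quarter the full-size length), so the statistical power
of the per-replicate frequency contrasts is limited: the density-based signs
are recovered reliably, while mean-frequency contrasts — a few hundredths in
absolute frequency against a per-replicate noise of ~0.15 — sit near the
detection threshold of a 50-replicate signed-rank test.  This is a power
property of the reduced scale, not of the estimator; the same pipeline on
larger fragments tightens all contrasts.

## Known limitations

* No migration or population structure, no non-Wright-Fisher dynamics, no
  gene conversion, no solo-LTR formation, no TE excision; inserted elements
  are transpositionally inert.
* TE "length" is a two-class label; the simulator does not model sequence or
  truncation (the truncation summary applies to empirical call sets only).
* The burst is a single rectangular pulse; real transposition histories are
  smoother.
* Burst-mode runs have zero transposition outside the burst window (the
  constant/burst switch is binary); a baseline-plus-burst mixture can be
  composed by the caller but is not a preset.
* Beneficial fractions in the positive-selection presets are drawn from the
  neutral remainder of the class table, not subtracted from deleterious mass.
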
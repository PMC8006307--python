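# Methods

This note documents the models, estimators, numerical conventions, and
deliberate simplifications behind `coldmap`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The experimental design being modeled

A biparental cross between a tolerant (T) and a sensitive (S) parent is
advanced to F2; each F2 plant is selfed to give an F2:3 family that is
phenotyped (seed survival rate SR after cold treatment, and a 0–7 damage
score SD), while the F2 plant itself supplies DNA. The SR extremes — by
default the top and bottom 30 of 460 lines — form two DNA pools that are
sequenced; per-site allele depths in the two pools are the data for the
genome scan. A significant consensus interval is then refined by
genotyping the whole population at markers inside it and running a
QTL scan.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions
under which every downstream claim is validated.

**Founders.** SNP sites are placed per chromosome with Poisson counts at
`snp_density` (default 100/Mb) and uniform positions; parental bases
differ at every site.

**Meiosis.** Each gamete receives Poisson-many crossovers with mean equal
to the chromosome's genetic length (default 4 cM/Mb, a rice-typical
scale), uniform breakpoint placement, and no interference. An F2
individual is two independent gametes; genotypes are queried from the
breakpoint mosaics, so genotype frequencies converge to 1:2:1.

**Phenotype.** SR_i = clip(baseline + Σ_q (a_q·x_i + d_q·z_i) + ε_i, 0, 100)
with x ∈ {+1, 0, −1} for {TT, TS, SS}, z the heterozygosity indicator,
and ε ~ N(0, noise_sd²); defaults baseline 50%, noise_sd 10. Clipping is
applied after noise because SR is a percentage by definition. SD is
derived as 7·(1 − SR/100) plus small noise (sd 0.2): the two indices are
near-duplicate measures in real assays (strongly negative correlation),
and downstream mapping uses SR only, so SD is not modeled independently.

**Pooled reads.** Per site and pool, the true tolerant-allele frequency
is the pooled allele count over 2·bulk_size chromosomes; depth is
Poisson(mean_depth = 100) and tolerant-allele reads are
Binomial(depth, f(1−e) + (1−f)e) with per-base error e = 0.001. The
counts table is VCF-oriented with ALT = tolerant-parent allele, so the
alt-index is the tolerant SNP-index and a planted QTL produces positive Δ.

**Simplifications.** F2 genotypes serve both the pooled DNA and the
F2:3 family phenotype: the extra within-family segregation of real F2:3
phenotyping is not simulated, which makes phenotype–genotype coupling
slightly cleaner than in a real study. No read-level simulation, indels,
or multi-allelic sites. Consequently, passing recovery tests demonstrate
the correctness and calibration of the inference chain under the stated
noise model — not the sequencing-scale idiosyncrasies (mapping bias,
depth heterogeneity, segregation distortion) of real data.

## Association statistics

All four statistics are computed from the per-site 2×2 allele-by-bulk
table (a, b; c, d) = (T-pool ref/alt, S-pool ref/alt):

* **Δ(SNP-index)**: alt/(ref+alt) difference between pools, in [−1, 1].
* **G**: 2 Σ nᵢ ln(nᵢ/n̂ᵢ) with expectations under row/column
  independence; natural logs; zero cells contribute zero. G equals
  2n × mutual information (nats), which the tests exploit as an
  independent oracle.
* **ED**: Euclidean distance between four-base frequency vectors (the
  biallelic embedding uses two nonzero entries). Raw ED ∈ [0, √2];
  the classical fourth-power variant is available via `k`.
* **Fisher**: two-tailed exact p summing hypergeometric probabilities of
  all same-margin tables with probability ≤ observed, with a 1e-12
  relative tie tolerance. Implemented with log-gamma arithmetic over the
  full support; validated against exhaustive enumeration for every table
  with margins ≤ 30.

Sites with total depth < 10 in either pool are set missing: every
statistic is unstable at negligible depth, and no per-site depth rule
sharper than this is defensible from the design alone.

## Genome scan

Windows of 1 Mb every 20 kb (both configurable; the 20-kb step matches
the granularity of reported interval endpoints, the window size is a
package choice). Δ and ED use unweighted window means; G′ is the
tricube-weighted mean of G with weights (1 − (d/h)³)³; the Fisher track
is the window mean of −log₁₀ p (back-transformed in reports). Windows
with fewer than 5 SNPs are missing.

Thresholds at 95/99% are genome-wide empirical nearest-rank quantiles of
each method's windowed statistic (upper tail; |Δ| for the SNP-index
difference). For Δ a depth-aware Monte-Carlo null band is used by
default for region calling: per replicate each pool's frequency is drawn
from 2·bulk_size fair allele draws and reads from Binomial(depth, f),
and the band is the two-sided quantile of |Δ|, tabulated over a depth
grid with linear interpolation. Because this band reflects raw per-site
noise, the (much smoother) windowed Δ track crosses it essentially only
under true signal, which keeps the four-method consensus rare under the
null; the empirical-quantile route remains available for comparability
across methods.

Significant windows are merged into regions tolerating a one-window gap
(prevents single-window dropouts from splitting a QTL); regions narrower
than 100 kb are dropped; each region carries its method's peak. The
consensus is the per-chromosome interval intersection across all four
methods (closed 1-based arithmetic: [max starts, min ends]); containment
of the consensus in every supporting region is asserted on every call.
When several consensus regions exist, the one with the highest G′ peak
ranks first.

## Linkage stage

Recombination fractions between codominant F2 markers are estimated by
EM over the ambiguous double-heterozygote class (each line contributes
two meioses; all other classes have known recombinant counts); distances
use Kosambi's d = 25 ln((1+2r)/(1−2r)) by default (Haldane available).

The scan is Haley–Knott regression on a 0.5-cM grid: the phenotype is
regressed on the expected additive and dominance predictors given the
flanking markers, computed from the F2 transition matrices; missing
marker calls are marginalized against the 1:2:1 prior. LOD =
(n/2) log₁₀(RSS₀/RSS₁); PVE = 100(1 − RSS₁/RSS₀); the additive effect
is the fitted coefficient with the tolerant-parent allele positive.
Haley–Knott was chosen over a full EM mixture likelihood because it is
orders of magnitude faster and near-identical in LOD at the effect sizes
of interest; with no cofactors the scan at a fully genotyped marker is
algebraically identical to single-marker ANOVA (asserted to 1e-6 in the
tests). An ICIM-style option pre-adjusts the phenotype by stepwise
selected background markers (entry/exit p = 0.001/0.002) excluding
markers within 10 cM of the tested interval; it is off by default since
the studies here plant a single QTL.

The significance rule is max(permutation threshold, LOD 3.0): the
permutation threshold is the nearest-rank (1−α) quantile of the max-LOD
distribution over seeded phenotype permutations (default 1000 at
α = 0.01, vectorized via per-position orthonormal bases), and the fixed
floor reconciles the conventional LOD ≥ 3 declaration rule with it by
taking the stricter of the two. Support intervals are the 1-LOD drop
around the peak (a standard construction; the peak is always contained
by construction and this is asserted).

## Variant effects

Classification priority is CDS > UTR > intron > intergenic, with the
first overlapping transcript winning (the annotation tools used in such
studies do not publish their tie rule; first-transcript-wins is
deterministic and documented). UTRs are exonic non-CDS intervals, 5′ and
3′ merged into one category; splice-site classes are not modeled. Coding
SNPs rebuild the affected codon in transcript orientation
(reverse-complement on the minus strand, including junction-spanning
codons) and translate with the standard code; a strand-mirroring
property test asserts that reverse-complementing the whole fixture
preserves every call. Transcripts whose CDS length is not a multiple of
three are skipped with a warning. The reference base is checked against
the FASTA and a mismatch is an error naming the position.

## Haplotype and expression utilities

Lines are keyed by their concatenated allele string over the candidate
SNPs; unphased heterozygous calls form their own class (F2:3 haplotyping
treats lines as allele-string categories, and probabilistic splitting
would manufacture phase information that is not in the data). Group
contrasts use Welch's unequal-variance t-test — the safer default when
class sizes and variances differ. Relative expression is 2^−ΔΔCt
against a housekeeping reference and calibrator sample, assuming 100%
amplification efficiency; efficiency correction is out of scope.

## Numerical conventions and degenerate inputs

* Nearest-rank quantiles everywhere a quantile convention matters.
* Coordinates are 1-based closed internally (as in VCF); BED output is
  0-based half-open.
* Bulk selection ranks once by SR descending, then SD ascending, then
  line id — deterministic and order-invariant; ties crossing the
  boundary are resolved by that ranking.
* Zero-depth sites, empty panels, all-zero tables, monomorphic markers,
  and r ≥ 0.5 are rejected with explicit errors rather than silently
  propagated.
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; per-stage child streams make each stage
  reproducible in isolation, and identical configurations give
  bit-identical outputs.

## Replicated validation studies

The null-calibration and recovery studies run 20 replicates each at the
design scale of the study being emulated: four 25-Mb chromosomes at
100 SNPs/Mb (≈10,000 sites), 460 lines, 30+30 bulks, 100× pooled depth,
additive effect +15 SR %-points (recovery) or none (null), noise sd 10.
This scale keeps a full 20+20-replicate run under a minute on one CPU
while preserving the statistical structure (window counts, depth regime,
bulk sizes) that the thresholds and consensus logic depend on.

Two statistical points discovered during development are worth recording.
First, a sign test of Δ symmetry across the sites of a *single* null
genome is invalid: linked sites share bulk-composition noise, so sign
counts are block-correlated; the symmetry test therefore pools many
independent replicate experiments and uses a conservative block-variance
bound. Second, a nearest-rank 99% permutation quantile at B = 2000 has a
Monte-Carlo sd of ≈0.12 LOD, so seed-to-seed agreement is asserted at a
3-sigma tolerance rather than a tighter nominal one.

## Known limitations

* Single-QTL inference: no multi-QTL model selection or epistasis.
* The simulator's single-generation simplification (above) slightly
  understates phenotype–genotype noise relative to true F2:3 designs.
* Indels and multi-allelic sites are parsed past, not analyzed.
* The plotting surface is intentionally minimal and untested.
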
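# Methods

## Estimators

Allele frequencies are computed per parental population as exact allele-copy
ratios: the sum of alt-allele counts over non-missing genotypes divided by
twice the number of non-missing genotypes. A site's informativeness is
δ = |p̂_P1 − p̂_P2|, undefined when either population contributes fewer than
`min_alleles` (default 2, i.e. one genotyped individual) non-missing allele
copies. AIM selection keeps sites with δ ≥ threshold, compared with a 1e-12
tolerance so that true fixed differences are never lost to rounding; the
comparison is inclusive, so `threshold = 1` retains exactly the
fixed-difference sites and AIM sets are nested across thresholds. Each AIM
is polarized by the allele with the strictly higher P2 frequency, which is
well defined whenever δ > 0.

Hybrid index is the individual's mean P2-allele dosage over non-missing
AIMs divided by two; interclass heterozygosity is its fraction of
heterozygous non-missing AIMs. Both are undefined (NA in output) only when
every AIM genotype is missing. The orientation (P2 → 1) is arbitrary but
fixed, and logged with every run. No minimum-site filter is applied by
default; `--min-sites` can blank estimates built on very few sites, which
are legal but noisy.

Missing-data policy: a half-called diploid genotype (`./1`) is treated as
fully missing. Partial genotypes have no defined dosage, and counting
single allele copies would give individuals with systematic half-calls a
different denominator for HI (alleles) than for het (sites). Multiallelic
records are dropped rather than split: the δ/polarization machinery is
defined on exactly two alleles.

## HWE geometry

For a cross between genomes with P2-allele frequencies h_A and h_B, with
m = (h_A + h_B)/2 and σ² = ((h_A − h_B)/2)², expected offspring genotype
frequencies are p11 = m² − σ², p12 = 2m(1−m) + 2σ², p22 = (1−m)² − σ².
σ² ≤ m(1−m) on the unit square, so the frequencies are a proper
distribution; σ² = 0 recovers the single-population HWE formula. Offspring
hybrid index is m regardless of σ², which is why depth and crossing never
bias HI, and p12 exceeds the HWE curve by 2σ², which is why no cross can
fall below it.

`enumerate_space(G)` starts from the two parental states (allele
frequencies 0 and 1) and, at each generation, crosses every unordered pair
of allele frequencies seen in any earlier generation — parentals included.
The inclusive mating rule is a deliberate choice: without it no backcross
ever arises, and restricting mates to the immediately preceding generation
would exclude crosses (e.g. F1 × parental after generation 2) that are
biologically routine. Offspring heterozygosity depends only on the parents'
allele frequencies, so states are deduplicated on allele frequency; points
are deduplicated after rounding to 12 decimals (all coordinates are dyadic
rationals k/2^G, exactly representable, so the rounding is a formality).
The cap of 8 generations bounds the quadratic growth in pair count; the
default of 6 generations yields 561 distinct points.

`classify_point` uses a 1e-9 tolerance band around the boundary; points
below the curve indicate HWE violation (e.g. assortative mating), points
above the lines exceed what any single cross can produce.

## Simulator

`simulate_parental_pools` draws two populations at `n_sites` unlinked
sites: `n_fixed_diff` sites are true fixed differences (alt frequency 0 in
P1, 1 in P2) and the rest draw independent per-population alt frequencies
from a configurable spectrum, by default Beta(0.5, 0.5) — a U-shaped site
frequency spectrum in which most segregating sites are near fixation in one
population, the realistic regime for SNP panels; `("uniform",)` gives a
flatter, harder regime. Genotypes are two binomial allele copies at the
population frequency. The site table records the true frequencies so
validation code can compare sample δ with truth.

`cross` draws one allele from each parent per site (a parent of dosage d
transmits alt with probability d/2), independently across sites; offspring
are missing wherever either parent is. `make_hybrid_classes` builds, per
class, `n_per_class` F1s (one parent from each pool, without replacement
while the pools last), F2s (each F1 × another F1, a cyclic pairing so mates
are distinct whenever n ≥ 2), and first-generation backcrosses (each F1 × a
random parental from the respective pool).

`downsample_depth` emulates low-coverage genotype calling with no
sequencing error: per genotype, `depth` alleles are drawn with replacement
from the individual's two copies, and the site is recoded heterozygous only
if both alleles appear. Homozygotes are unaffected; a true heterozygote
survives with probability 1 − 2^(1−depth), giving the closed-form
attenuation E[het_obs] = het_true·(1 − 2^(1−depth)) while leaving E[HI]
unchanged (a miscalled heterozygote goes to either homozygote with equal
probability). `individuals=` restricts downsampling, e.g. to hybrids while
the parental reference sample stays at full depth.

`subsample_parentals` produces replicate popmaps with n random individuals
kept per parental label; the rest are relabeled `<label>_excluded` so they
drop out of frequency estimation but remain in the results table.

Because sites are unlinked, class expectations are exact and Monte-Carlo
standard errors scale as 1/sqrt(sites × individuals). Real
reduced-representation data has linkage, shared drift, and genotyping
error, so real-data uncertainty is larger than these fixtures suggest:
passing recovery tests here validates the estimators and the depth model,
not the hardness of any particular empirical dataset.

## Error metrics

Accuracy = 1 − |mean(observed) − expected| / expected. It is deliberately
unclamped (gross errors go negative rather than saturating at 0) and
refuses expected = 0; parental classes are summarized by MAE instead.
Precision is the mean distance of estimates from their own centroid —
mean absolute deviation for one axis, mean Euclidean distance for (HI, het)
points, the natural units of the triangle plot. For misassignment analyses,
hybrid indices are first folded (h > 0.5 → 1 − h) so both parental extremes
map to 0, then compared as log((a + ε)/(b + ε)) with natural log and
ε = 1e-6 by default; the base only rescales and ε is exposed as a
parameter. Negative values mean the estimate moved toward the nearest
parental extreme.

## Problem sizes and numerical choices

The validation suite and the acceptance script use desk-scale simulations
chosen so that Monte-Carlo error is far below the effects being measured:
20 individuals per parental pool and per hybrid class (the standard design
throughout), 150–500 fixed-difference sites for recovery and depth
experiments (class-mean SE ≤ 0.005), 4000 segregating sites × 20 replicate
subsamples for the false-fixed-difference distribution, and 10^5 unlinked
sites for the pedigree Monte-Carlo oracle (3 SE ≈ 0.005). Depth-model
accuracy is replicated over 5 seeds (10 for the 2X hybrid-index average).
All stochastic operations take explicit seeds or numpy Generators; the CLI
logs an auto-generated seed when none is given, and the simulate
subcommand is byte-deterministic under a fixed seed.

Genotypes are stored as int8 with −1 as the missing sentinel; frequencies
are computed as integer-count ratios in double precision (one division per
site), so δ for fixed differences is exactly 1.0 and the 1e-12 threshold
tolerance is a guard, not a correction.

## Limitations

- Diploid, biallelic SNPs only; no genotype likelihoods, imputation, or
  ploidy ≠ 2.
- The HWE engine is strictly neutral: no selection, drift, mutation, or
  linkage.
- The depth model has no sequencing error or allelic bias; it isolates the
  allele-sampling component of heterozygote miscalling.
- Frequency-based point estimates carry no per-individual uncertainty;
  users needing credible intervals should pair this tool with a Bayesian
  ancestry model.
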
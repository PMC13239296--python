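# Methods

This note records the models behind each stage, the parameter choices that
matter, what the synthetic data do and do not emulate, and the numerical
decisions a maintainer would want to know. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genotype model and filtering

Genotypes are alternate-allele dosages {0, 1, 2} with a distinct MISSING
sentinel (−1); all statistics treat missing calls pairwise-complete (a
missing call drops that individual from that locus) except the RDA, which
needs a complete matrix and imputes per-locus mean dosage — imputation is
confined to the ordination and never leaks into diversity estimates.

The sequential filter runs depth window → reproducibility → one SNP per
fragment (seeded random choice, so runs are reproducible although the
protocol says only "at random") → MAF → locus missingness → individual
missingness → monomorphic removal. Two wordings in the source protocol are
implemented literally but exposed as configuration because they are
unusual: loci are kept when *less than 90%* missing and individuals when
*less than 80%* missing (a 50% cap is more common), and the MAF cut is
inclusive ("≤ 1% excluded") over all individuals pooled. Filtering is
idempotent on clean data; a matrix whose MAF profile was shaped *after*
individual removal can in principle lose further loci on a second pass.

## Diversity panel

* He is 2p(1−p) from sample frequencies; uHe applies Nei's 2n/(2n−1). Both
  are reported; the displayed default is He since the reference tables use
  it.
* F_IS uses the ratio-of-means (hierfstat/Nei) convention
  1 − mean(Ho_l)/mean(uHe_l) over polymorphic loci; CIs are percentile
  intervals from a bootstrap over loci (resampling unit = locus; default
  1000 replicates). Coverage of the generating value under selfing-induced
  inbreeding is verified by simulation in the test suite.
* Rarefied allelic richness uses the closed hypergeometric form
  Σ_a [1 − C(N−N_a, g)/C(N, g)] in log-gamma space; g defaults to the
  smallest valid gene-copy count over the compared (group, locus) cells
  and is configurable, since the source protocol does not state it. Loci
  with fewer than g copies in any group are dropped from AR.
* PL's denominator is loci with ≥ 1 valid call in the group; PA counts
  loci carrying ≥ 1 allele seen in no other group, as a percentage of
  subset loci. Both definitions are sample-size sensitive and are reported
  as-is, not corrected.

## Outlier detection

One binary predictor per scan (provenance; wild-vs-hatchery), dummy-coded,
genotype columns centred (optional standardisation). The constrained axis
comes from the SVD of the fitted-value matrix; with one predictor this is
rank one and locus loadings are proportional to per-locus regression
slopes (and, with standardisation, to point-biserial correlations — pinned
by a test). Outliers are |z| > 3 over the loading distribution, the
convention of the standard RDA genome-scan workflow; the threshold is
configurable and the partition reports achieved counts rather than
asserting any particular number. Under a fully null simulation the flag
rate matches 2Φ(−3) within binomial error (tested).

## Differentiation and ordination

Weir & Cockerham (1984) variance components a, b, c are computed per locus
from genotype counts for two groups; the multi-locus estimate is the ratio
of sums Σa/Σ(a+b+c); negative estimates are reported as computed. The
bootstrap resamples loci with replacement (999 replicates); the one-tailed
p is (1 + #{θ* ≤ 0})/(n_boot + 1) with the +1 guard against zero p;
Benjamini–Hochberg runs across all pairs of a call. An independent
literal-formula implementation agrees to 1e−10 on random toy data (tested).

Bitwise distance is the mean per-locus |dosage difference|/2 over
pairwise-complete loci. PCoA is classical scaling (double-centre −D²/2,
eigendecompose); negative eigenvalues are reported and their axes dropped;
coordinates are defined up to sign. It agrees with scikit-bio's PCoA and
with PCA of centred data on Euclidean input (tested).

## Effective population size

LD method: r² is the squared Pearson correlation of dosages over
individuals complete at both loci, multiplied by (S/(S−1))² — the
Burrows-composite scaling against which Waples' (2006) sampling
expectations were calibrated; without it, small-sample estimates diverge.
The overall r̂² is the pair-sample-size-weighted mean; E[r²|S] uses the
harmonic mean S over pairs (1/S + 3.19/S² for S ≥ 30; 0.0018 + 0.907/S +
4.44/S² below); Ne inverts r̂² − E with the bias-adjusted coefficients
(1/3, 2.76) or (0.308, 2.08). Non-positive drift signal gives Ne = +∞.
Confidence intervals: parametric (chi-square on an n_pairs df) is the
default per convention, but it is anti-conservative because locus pairs
share individuals; the jackknife here therefore deletes *individuals*
(not loci — delete-one-locus pseudo-values barely vary and structurally
under-cover), and the jackknife is what the validation uses. On
Wright–Fisher populations of true N = 50 (500 unlinked loci, exhaustive
sampling after an 8-generation burn-in) the median estimate is within 20%
and jackknife coverage ≥ 85% (acceptance suite, 100 replicates).

The default MAF cutoff is 0 (the panel is already MAF-filtered, matching
the dartR gl.LDNe default). On panels dominated by very rare alleles the
weighted r̂² picks up excess sampling correlation from low-copy loci that
the freq-independent E[r²|S] does not absorb, biasing large-Ne estimates;
wild-pool estimates on the synthetic panel are accordingly noisy and high
(hatchery-cohort estimates, with their strong drift signal, are robust).

The molecular-coancestry alternative computes pairwise allele-sharing
corrected by its expectation at reference allele frequencies and
Neb = 1/(2 f̄). Referencing frequencies to the cohort itself self-centres
mean coancestry near zero (exactly zero for clones), so an explicit
`reference` (e.g. the genotyped donor pool, the natural parental baseline)
should be supplied whenever available; the self-referenced default
measures only excess relatedness over the cohort average and is
conservative. LD is the default method throughout.

## Synthetic data

The generic wild-population generator is Balding–Nichols: ancestral
frequency uniform on [maf_lo, maf_hi] per locus, population frequency
Beta(p(1−F)/F, (1−p)(1−F)/F), Hardy–Weinberg genotypes, DArT-style depth
(mean 6.79, clipped to [5, 12]), reproducibility ≥ 0.96, and 18.3%
missingness. Realised multi-locus θ recovers the F target within ±0.02
(tested over 20 seeds). Optionally the pool is bred at constant size
`wild_ne` for a few generations before sampling so genotypes carry
background LD consistent with that effective size; without it wild LD-Ne
is +∞ by construction (independent loci).

The full-study scenario (`scenario_full_study`) emulates the analysed
panel: 100 donors per provenance, F1 cohorts of 62 (warm) and 36 (cool),
1600 loci, 27 provenance-divergent and 15 hatchery-selected planted loci.
Its frequency model is two-class: ~6% "common divergent" loci (ancestral
MAF 0.02–0.10, Balding–Nichols F = 0.16) that dominate the ratio-of-sums
θ, over a bulk of rare loci whose frequency is scale·((1−d)u + d·e_pop)
with shared and private standard-exponential components (scale 0.0013,
d = 0.35, warm scaled by 0.36). The panel is assembled by
SNP-discovery-style ascertainment: 8× candidate loci are generated through
the shared burn-in pedigree (so selection leaves LD intact) and the panel
keeps per-class quotas of loci observed polymorphic in the pooled wild
sample. A single-class model cannot meet the panel's joint conditions —
θ ≈ 0.08 requires relative frequency variance that forces widespread
in-sample monomorphism at these diversity levels — and an all-polymorphic
200-sample panel bounds mean He from below (a cool-singleton locus already
contributes 2pq ≈ 0.012), so the realised neutral He lands near
0.020/0.008 (ratio ≈ 2.6) rather than the reference panel's 0.017/0.006.

Hatchery cohorts draw each offspring's dam and sire with symmetric
Dirichlet-weighted donor probabilities (concentration 0.12 warm / 0.55
cool, calibrated once so LD-Ne on the cohorts reproduces the reported
scale of effective breeder numbers, ~21 and ~74 of 100 donors), selfing
rates 0.15/0.05, Mendelian transmission, and post-hoc resampling of the 15
selected loci from frequencies shifted by +0.30 (a detectable
domestication signal, not a fitness model). Parentage (dam/sire IDs) is
recorded so realised skew is directly testable.

What the generator does **not** emulate: wild-population inbreeding (wild
F_IS is ~0 here, whereas real kelp populations show significant positive
F_IS), linkage/recombination structure beyond drift LD at unlinked loci,
depth-dependent genotyping error, age-structured sampling effects, and
the deposited panel's exact MAF-profile quirks (its printed per-population
PL and He values are not jointly attainable under any two-population model
with an all-polymorphic wild panel; see the per-class He bound above).
Passing tests therefore demonstrate correctness of the estimators and the
direction and rough magnitude of hatchery effects, not a locus-for-locus
reconstruction of the real dataset.

## Breeding simulator

Closed populations, unlinked biallelic loci, no mutation/selection/
migration. Donor missing calls are imputed by binomial draws from pool
frequencies before transmission. Each generation reassigns sexes by a
seeded shuffle (odd counts put the extra individual among dams) and draws
each offspring's parents uniformly with replacement. RNG streams are
hierarchically split (sweep → donor count → bootstrap) so adding donor
counts leaves other cells unchanged.

Validation: `expected_he_decay` implements the textbook
He_0(1 − 1/(2Ne))^t with Ne = 4NdNs/(Nd+Ns). That closed form is exact for
constant-size *monoecious* lines (both gametes drawn from the whole pool),
which is how the drift validation runs; the sexed, no-selfing scheme loses
*less* heterozygosity at tiny N (a sib line decays at the golden-ratio
rate 0.809/generation, first generation exactly 5/6 — both pinned by
tests). With many more offspring than donors, realised-frequency He loses
only ~1/(2·N_offspring) per generation for any donor count: the donor
bottleneck acts through donor *sampling* (He_0), not later drift — also
pinned by a test. Decay comparisons aggregate as ratios of means
(mean-of-ratios is Jensen-biased for tiny donor pools).

## Problem sizes

The analysis scripts and acceptance script use scaled problem sizes chosen
to keep a full run in the minutes range while leaving Monte-Carlo error
well inside the effects measured: donor sweeps run 300 neutral loci, 200
offspring per generation and 20 bootstrap draws (the library accepts the
full 1559 × 500 × 100 protocol via `SimulationConfig`); scenario-level
Ne values are medians over 3 replicate datasets; drift validation uses 200
replicate lines; Ne recovery 40–100 Wright–Fisher replicates. Every
stochastic stage is seeded from a single root seed.
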
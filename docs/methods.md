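# Methods

`breedcomp` estimates **genomic breed composition** — the vector of
fractions of an animal's genome attributable to each of B reference breeds
— from biallelic SNP genotypes coded 0/1/2, and studies how well that
estimation survives reduction to low-density SNP panels.  Real multi-breed
cattle genotype databases are proprietary, so the package carries a
first-class simulator that reproduces the statistical structure such an
analysis relies on.  This note records the models, the defaults and why
they hold, the numerical choices, and what the synthetic data can and
cannot show.

## The two estimators

### SNP-BLUP regression

For each target breed, training purebreds of that breed receive a
dependent variable y = 1 and an equal number of animals, drawn as evenly
as possible from the other B−1 breeds, receive y = 0 (per-breed counts
differ by at most one; the breeds receiving the remainder are chosen at
random under the run's seed).  The model is

y = μ·1 + X g + e,  g ~ N(0, I σ²g/m),  e ~ N(0, I σ²e),

with X the raw allele-count matrix (no centering or standardisation of the
stored coefficients), μ an unpenalised intercept, and m SNPs.  With the
phenotypic variance of the 1/0 trait p·q (p the fraction of coded animals
of the target breed), heritability h² = 0.999, and the genetic variance
split equally over SNPs, the mixed-model equations reduce to ridge
regression with

λ = m (1 − h²) / h² ≈ 0.001·m,

independent of p·q, which cancels.  The system is solved after
eliminating μ, in the primal (m×m) form when m ≤ n and the dual/kernel
(n×n) form otherwise; the two agree to ~1e−8 relative and this is asserted
against an independently coded dense inversion of the full mixed-model
equations in the tests.  A `lambda_mode="total"` variant (λ = (1−h²)/h²,
the whole genetic variance on every SNP) is implemented for comparison;
it leaves the system nearly unregularised and is not the default.

**Scoring.**  Each animal's raw score per breed is the sum of its allele
counts times the estimated SNP effects.  Two variants are implemented:

* **intercept-free** (default): score = x'ĝ.  The score carries a
  model-specific additive offset (−μ̂ relative to the regression
  prediction), but for near-pure animals that offset pushes all off-target
  scores below zero, where clamping and the 0.05 threshold remove them and
  rescaling returns the target breed at ~1.0.  This is the
  assignment-robust choice and the literal "effects times allele counts"
  pipeline.
* **intercept-anchored** (`include_intercept=True`): score = μ̂ + x'ĝ, the
  regression prediction, centered at 1 for target purebreds and 0
  otherwise.  F1 crossbreds score 0.5 per parental breed to within ~0.01.
  This is the consistent estimator of breed *fractions*.

The trade-off is real at desk scale: the intercept-free offsets have
standard deviation ~0.05–0.1 across breed models when training has ~100
animals per breed, which biases admixed-fraction ratios; the anchored
scores instead carry a small positive leak (~+0.03) on off-target animals
that survives the 0.05 threshold and dilutes purebred assignment.  With
the study-scale 500 animals per breed the anchored variant estimates F1
fractions essentially unbiasedly.  Purebred assignment therefore uses the
default score and fraction estimation for admixed animals is best done
with the anchored score; both are exposed and tested.

**Post-processing** (applied identically after both estimators): negatives
clamped to 0 → values below 0.05 set to 0 → remaining values divided by
their sum.  An all-zero row is flagged unassignable rather than raising.
A purebred is *assigned* when one breed's processed proportion reaches
0.90 (boundary inclusive).

### Supervised admixture EM

Per-breed allele frequencies F are fixed from the labelled training
purebreds (observed frequencies, clamped to [1e−6, 1−1e−6]) and each
animal's ancestry vector q on the K-simplex maximises the binomial
likelihood Σ_j [g_j ln(q'F_j) + (2−g_j) ln(q'(1−F_j))].  The likelihood is
concave in q for fixed F, so the multiplicative EM update from the uniform
start converges to the global optimum; the log-likelihood is asserted
non-decreasing at every iteration.  Convergence is ΔLL < 1e−6 (default)
or 2,000 iterations, per animal, vectorised over animals with an active
set.  No acceleration is used.

This is a *projection* analysis: the animals being predicted never update
F.  Two consequences worth knowing:

* determinism and per-animal independence (an animal's estimate does not
  depend on who else is in the batch);
* with finite training (n per breed), F̂ ≠ F, and the per-animal optimum
  sits slightly off the simplex vertex even for true purebreds — with 200
  training animals per breed and 5,000 SNPs the median own-breed q̂ is
  ~0.99, not 1.0.  The 0.90 assignment threshold is insensitive to this.

### Robustness to mislabeled training animals

Replacing half of one breed's training purebreds with F1 crossbreds that
keep the purebred label degrades the two estimators very differently: the
contaminated frequency row F̂ remains the closest available component to
the true breed, so the EM still assigns true purebreds at ~1.0, while the
SNP-BLUP regression is pulled toward the contaminated class mean and its
0.90-threshold assignment rate collapses for that breed.  This direction
holds in 9–10 of 10 seeds at 13 breeds / 3,000 SNPs / 100 training per
breed.  At much smaller scale (few breeds, ~1,000 SNPs) with a
high-divergence crossing partner the sign can flip, because the
contaminated frequency row is then visibly displaced; the experiment
helper leaves the scale to the caller.

## The simulator

**Breed frequencies.**  Balding–Nichols: ancestral frequency p uniform on
[0.05, 0.95] per SNP; breed k draws Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k),
mean p, variance F_k·p(1−p).  Under the package's Fst convention (below),
two breeds with drifts F_a, F_b realize pairwise Fst ≈ S/(1−S) with
S=(F_a+F_b)/4 — roughly half the single-breed drift.  The default drift
is per-breed `linspace(0.075, 0.34, B)`, calibrated (against realized
frequencies only) so the pairwise Fst matrix spans ~0.040–0.143, the
envelope observed between European cattle breeds (≈0.039 for the closest
pair to ≈0.146 for the most diverged).  A scalar drift gives a single
pairwise value; 0.2 lands it at ~0.09, the middle of that envelope.

**Genotypes.**  Purebreds are Hardy–Weinberg draws Binomial(2, f_kj),
unrelated within breed.  Crossbreds are built from explicit parental
gametes: a purebred parent transmits its breed at every locus; an F1
parent transmits a mosaic of its two breeds generated by Haldane-model
recombination (Poisson crossovers on a linear 1 cM/Mb map over the
chromosome's bp length, random start phase).  Each transmitted locus
carries a breed of origin; alleles are drawn Bernoulli from the origin
breed's frequency.  Both the pedigree-expected fractions and the realized
per-genome fractions are recorded — for an F1 of two purebreds the
realized fraction is exactly ½ (the variance appears one generation
later, e.g. in three-way crosses, where the B/C fractions spread around
0.25).  A locus-independent origin mode exists for cheap tests.

**Study design defaults.**  13 breeds with the study's per-breed training
(500), purebred-validation (up to 250) and SNP-selection (up to 1,000)
counts, 29 autosomes totalling ~2.5 Gbp, 49,213 SNPs placed uniformly with
counts proportional to chromosome length, and ten two-/three-way cross
designs (Angus×Charolais F1 being the largest).  `SimulationConfig.scaled`
builds structure-preserving desk-scale versions; everything is
deterministic given the seed.

**What the simulator does not emulate.**  No linkage disequilibrium within
breeds (SNPs are exchangeable draws), no ascertainment-skewed
informativeness spectrum, no genotyping error or missingness, no
within-breed relatedness beyond the explicit cross pedigrees, no
mutation/selection.  The most consequential gap is the per-SNP
informativeness tail: real arrays contain near-diagnostic breed variants
(per-SNP Fst approaching 1) and LD that lets 2,000 well-chosen SNPs tag
far more ancestry information than 2,000 exchangeable Balding–Nichols
SNPs, whose per-SNP Fst tail is Beta-thin.  Consequently low-density
results transfer qualitatively (accuracy grows with density;
informativeness ranking helps at low density) but the density at which
SNP-BLUP assignment stabilises is higher here (between 2,000 and 5,000
exchangeable SNPs) than on real arrays (~2,000).  Passing tests on this
generator say the algorithms are correct and behave as the theory
predicts under the stated population model — not that a specific density
suffices on a specific real array.

## Divergence

Per-SNP Fst = s²/(p̄(1−p̄)) with s² the **population** (divide-by-B)
variance of allele frequency among breeds and p̄ the unweighted mean;
SNPs monomorphic across breeds get 0.  The divide-by-B convention makes a
fixed difference between two breeds give exactly 1 (the sample-variance
alternative would give 2 for B=2, inadmissible for a fixation index).
The genome-wide value is the mean of per-SNP ratios by default
(ratio-of-means available).  Pairwise Fst applies the same machinery to
breed pairs.  The breed tree is Saitou–Nei neighbor joining on the
pairwise matrix; negative branch lengths are clamped to zero with the
deficit moved to the sibling branch so path lengths through the joined
pair are conserved; ties in pair selection break to the first index pair.

## Population construction

* **LD pruning**: within sliding 50-SNP windows (step 10, per
  chromosome), the higher-index member of every pair with r² > 0.5 is
  removed.
* **GRM**: VanRaden method 1 with observed allele frequencies, monomorphic
  SNPs skipped; PCA is the eigendecomposition of the GRM, scores scaled by
  √eigenvalue, variance explained as eigenvalue over trace.  Recorded-breed
  outliers are flagged at a configurable multiple (default 4) of the
  within-breed RMS distance from the breed centroid in the leading PCs —
  the discard rule on real data was not quantified, so this stays a knob,
  not an asserted constant.
* **IBS training selection**: per breed, distance d = mean|g_i−g_j|/2
  (1 − half the mean shared alleles; a scaled Manhattan metric),
  average-linkage hierarchical clustering cut at k=500 clusters, one
  random animal per cluster.  The published pipeline used PLINK's
  clustering whose exact agglomeration heuristic is unspecified;
  average linkage is deterministic and serves the same purpose — spreading
  training picks across the breed's diversity.
* **Validation bands**: purebred-verified at ≥0.90 for any breed; two-way
  crosses when the top-two fractions fall in 45–55:45–55 or 70–80:20–30
  (either order) with every other breed <0.05; three-way when three breeds
  are ≥0.20 and any fourth is <0.025.

## Panel design

Per-chromosome SNP counts are proportional to chromosome length with
largest-remainder rounding (floors, then +1 to the largest fractional
remainders, ties to the earlier chromosome), so every strategy at a given
density uses the identical allocation.  Scores come only from the
SNP-selection population.  Methods: per-SNP Fst; PCA weights as the
eigenvalue-weighted sum of squared loadings over the leading B−1
components of the standardised-genotype covariance (components
configurable; B−1 is what separates B clusters); the SD across breeds of
per-breed SNP-BLUP effects; random-forest impurity importance (500 trees,
√m features per split, seeded); and one-vs-rest PLS regression on ±1
class codes (10 components), per-SNP weight the largest |coefficient|
across breeds.  Selection modes: highest-per-chromosome (ties to lower
bp), equal-count contiguous blocks with the remainder appended to the
last blocks (max score per block), max score per position cluster, the
position-cluster medoids themselves, and seeded random.  No LD threshold
or minimum spacing is imposed between selected SNPs, deliberately.

Position clustering is k-medoids on basepair positions.  Because the data
are one-dimensional, the optimal clusters are contiguous runs, and the
implementation solves that problem *exactly* by divide-and-conquer dynamic
programming over intervals (O(k·n log n)); each cluster's medoid is its
lower median, so ties resolve to the lower position.  A build-and-swap
local search would be slower and only locally optimal; the DP matches
exhaustive search on every small instance by construction.

## Quality control and I/O

PLINK 1 binary (SNP-major .bed with the 0x6c 0x1b 0x01 magic, two-bit
codes, A1-allele counting; .bim positions 1-based) is the interchange
format; the codec is tested against hand-packed bytes and property-based
round trips.  QC drops SNPs below a 0.90 call rate or off autosomes 1–29,
then samples below a 0.90 call rate; minor allele frequency is
deliberately never filtered.  Remaining sporadic missing genotypes are
imputed to the per-SNP mean rounded to the nearest count (ties round half
up) — a simple stand-in that is exact on complete synthetic data and is
not equivalent to family-based imputation on real data.

## Numerical and degenerate-input choices

* Constant-y SNP-BLUP systems return ĝ=0 with μ = mean(y) instead of
  failing; marker alignment mismatches raise.
* Frequency clamping at 1e−6 keeps the admixture likelihood finite;
  convergence is on ΔLL, not Δq; q is renormalised each EM step against
  floating-point drift.
* Two-taxon NJ collapses to a single split edge; three taxa use the
  closed-form star.
* Largest-remainder ties and score ties always break to the earlier
  index/lower position, making every panel reproducible byte-for-byte.
* All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning; identical config+seed reproduces
  bit-identical datasets.

## Problem sizes used in the shipped tests and acceptance runs

The shipped acceptance runs use 13 breeds with 5,000 SNPs on 5 chromosomes
(100 training / 50 validation per breed) for full-panel assignment, and
10,000 SNPs with a 200-per-breed SNP-selection population for 2,000-SNP
panel construction; the F1-recovery check uses 500 training per breed and
200 crossbreds; the mislabeling experiment uses 3,000 SNPs and ten seeds.
These sizes preserve the design's structure (ratios of populations, panel
density relative to map size) at desk scale.
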
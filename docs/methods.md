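# Methods

## The evaluation model

Every 210-day standardized lactation record of doe *q* is modelled as

y = μ + farm + parturition year + parturition month + season + birth type
    [+ CSN1S1 genotype class] + b₁·age + b₂·age² + aₚ + peᵩ + e

where aₚ is the additive genetic effect of the animal (one level per
pedigree animal, record-holding or not), peᵩ the permanent-environment
effect shared by a doe's repeated lactations, and e the residual.
Covariance assumptions: var(**a**) = **A**σ²ₐ with **A** the numerator
relationship matrix, var(**pe**) = **I**σ²ₚₑ, var(**e**) = **I**σ²ₑ,
mutually independent, all effects Gaussian. Traits are the 210-day milk,
fat, protein and dry-matter yields in kg. The genotype-inclusive and
-exclusive variants differ only in the fixed-effect list; comparing them
isolates what acknowledging the casein genotype does to the variance
partition and to animal ranking.

Assumptions worth stating explicitly: no genetic groups for unknown
parents (an unknown parent is a draw from the founder population); no
maternal effects; homogeneous residual variance across farms and years;
genotype classes act purely additively as class shifts.

## Pedigree machinery

* Inbreeding: Meuwissen & Luo recursion — for each animal, ancestor
  coefficients are accumulated youngest-first and
  F = Σⱼ L²ᵢⱼ dⱼ − 1, with dⱼ the Mendelian-sampling variance scalar
  (1 for founders, 0.75 − 0.25 F_p with one known parent,
  0.5 − 0.25(F_s + F_d) with two). O(ancestors) per animal, no dense
  matrix, so herdbook-scale pedigrees are fine.
* **A** on subsets: tabular method over the subset plus all its ancestors.
* **A**⁻¹: Henderson's rules with the same inbreeding-aware dⱼ, assembled
  directly as a sparse matrix. The identity log|A| = Σ log dⱼ supplies the
  likelihood's log-determinant term for free.
* The summary's relatedness range uses the full A below 2000 animals and a
  seeded 10⁵-pair sample above (full pairwise work is O(n²)).

## REML

Variance components are estimated by EM-REML on Henderson's mixed-model
equations. Per iteration the coefficient matrix C (order: fixed effects,
all pedigree animals, recorded does) is factorized densely (Cholesky),
and the EM updates use the exact conditional expectations:

σ²ₐ ← (ûᵀA⁻¹û + σ²ₑ·tr(A⁻¹C^{aa})) / q,
σ²ₚₑ ← (p̂ᵀp̂ + σ²ₑ·tr(C^{pp})) / n_pe,
σ²ₑ ← (êᵀê + σ²ₑ·tr(C⁻¹WᵀW)) / n.

EM was chosen over direct AI-REML maximisation because its monotone
restricted-likelihood ascent is itself a testable invariant; the recorded
trace is checked on every fitted model. The restricted log-likelihood is
evaluated from the MME factorization as
−2ℓ = (n−m)·log σ²ₑ + q·log σ²ₐ + n_pe·log σ²ₚₑ + log|A| + log|C| + yᵀPy,
which the test suite verifies equals the direct dense
log|V| + log|XᵀV⁻¹X| + yᵀPy formula to machine precision.

* Convergence: squared relative change of the component vector below the
  tolerance; the default 10⁻¹² follows the programme convention the
  package mirrors. EM crawls near boundaries, so fits report
  `converged_`/`n_iter_` honestly rather than pretending.
* Starting values σ²ₐ = σ²ₚₑ = σ²ₑ = var(y)/3; components are floored at
  10⁻⁸·var(y) when an update would cross zero (logged in the result).
* Identifiability: first-level reference constraints on every factor,
  age centred at the sample mean before squaring, and exactly collinear
  columns (e.g. a season fully determined by month) removed by an
  order-preserving greedy Gram–Schmidt pass — earlier factors win, the
  dropped column names are reported.
* Standard errors come from the inverse average-information matrix at the
  optimum (verified against a numerical Hessian of the restricted
  likelihood); the h² SE uses the delta method. Bivariate fits run the
  two-trait analogue with 2×2 G₀/P₀/R₀ blocks (EM updates are PSD by
  construction; an eigenvalue clip guards round-off) and report genetic
  and phenotypic correlations. Multi-trait strategy: univariate fits for
  variances and h², one bivariate fit per trait pair — not a single
  4-trait fit.
* Correlation SEs are a large-sample Fisher-z style approximation; they
  are reported but nothing downstream depends on them.

## BLUP, prediction error and reliability

At fixed components the MME are solved once; PEVᵢ = (C⁻¹)_{aa,ii}·σ²ₑ
comes from the exact inverse of the coefficient matrix (dense
factorization; this is the intended operating range of a few thousand
equations — beyond that the same block solves are simply slower).
SEP = √PEV, reliability R_AP = 1 − SEP²/σ²ₐ clipped to [0, 1], accuracy
RTi = √R_AP. Note the reliability identity is *not* squared: the squared
form sometimes quoted is inconsistent with the published worked values
(1 − 2.21²/16.87 = 0.71 is the printed reliability as-is), so the package
implements R_AP = RTi² = 1 − SEP²/σ²ₐ. Confidence ranges PBV ± k·SEP carry
exact normal coverages (68.3% at k = 1, 95.4% at k = 2); interpretation
bands for accuracy and reliability are lower-inclusive (a documented
tie rule — the sources are silent).

## Lactation standardization

Fleischmann test-interval accumulation: first interval back-extended to
day 0 at the first test's daily yield, interior intervals contribute the
mean of their endpoint yields times their length, and the last yield is
carried (or the accumulation truncated) to exactly day 210. Component
percentages are interval-milk-weighted means, so
fat_kg / milk_kg recovers the weighted mean percentage identically.
Which standardization the original recording scheme used is not public;
Fleischmann is the conventional choice and is isolated behind one
function. Season is derived from month by meteorological
Northern-hemisphere quarters (also a convention the sources leave open).
Default depuration windows are breed reference mean ± 4 SD per trait,
configurable.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *structure* the evaluation assumes: a
random-mating multi-generation pedigree with a configurable buck:doe
ratio; Hardy–Weinberg founders and Mendelian transmission at a single
5-allele casein locus (A, B strong; E medium; F weak; N null; class
labels written in the breed convention, BA not AB); true breeding values
drawn exactly from MVN(0, **A** ⊗ G₀) by recursive gene flow
(founder draw + Mendelian-sampling deviations, inbreeding-aware);
59 farms, kidding years 2005–2016, months May–December, four seasons,
birth types 1–5; 1–6 lactations per doe with ages advancing ~12 months
per parity inside the observed 14–130-month range; and the exact linear
model above for the phenotypes, jointly over the four trait channels.
Test days follow a Wood curve y(t) = a·t^b·e^(−ct) with default
(b, c) = (0.2, 0.004) — peak at 50 days in milk, the textbook dairy-goat
shape — scaled so the continuous 210-day integral equals the lactation
total; the 7-point Fleischmann round-trip then agrees within its ~1.7%
discretization bias.

Default variance components and trait means are the study conditions the
package targets (e.g. milk σ²ₐ = 11511.83, σ²ₚₑ = 1689.51,
σ²ₑ = 15578.23 kg²; mean 416 kg). Deliberately *not* emulated: the real
population's genotype-class frequencies (unpublished — defaults are
uniform allele frequencies, flagged as placeholders), per-class fixed
effects (scaled from the 3.6/1.6/0.6/0 g·L⁻¹ αS1-casein expression levels,
placeholders likewise), selection and non-random mating, heterogeneous
farm variances, seasonal calving waves, and any real-data messiness
(missing test days, recording errors). Passing tests therefore certify
the *machinery* — estimators recover the parameters of data generated
under the model's own assumptions — not that field data meet those
assumptions.

## Selection index and sampling

ICO = Σ w_t·z(PBV_t) over milk, fat and protein (dry matter excluded as an
indirect re-measurement of fat and protein). The programme's economic
weights are not public, so the default is equal weights on standardized
PBVs — a placeholder that real use must override. The genotyping sample
takes the bottom n_low ranks, the top n_high, and the n_mid consecutive
ranks centred on the median rank (ties broken by animal id, lower rank
first), which makes "around the median" deterministic and
order-invariant.

## Validation studies and problem sizes

The suite's simulation checks run at deliberately desk-scale sizes chosen
to keep Monte-Carlo error inside each check's tolerance: SEP coverage uses
ten ~600-animal replicates (coverage of PBV ± 2·SEP lands at ~95.4%, the
exact normal value, since PEV from the MME inverse is the true error
variance under the model); h² recovery runs at ~1900 records on a
~690-animal pedigree; bivariate r_G recovery uses ~350 recorded does with
a well-identified design (h² = 0.625, no nuisance effects) averaged over
two seeds; the bootstrap check of the AI standard errors regenerates data
at the fitted components and refits 25 times. The 12-record grid-search
oracle certifies that EM reaches the restricted-likelihood optimum found
by brute force.

## Known limitations

* EM convergence near a zero component is slow (sublinear); fits at tight
  tolerances may report `converged_ = False` with a perfectly usable
  estimate. An AI-accelerated second phase would fix the speed, at the
  cost of the monotonicity guarantee.
* PEV requires the (block) inverse of the coefficient matrix; the dense
  path is exact but O(m³), so evaluations beyond ~10⁴ equations need a
  selected-inversion backend this package does not ship.
* Single-locus genotypes only; no linkage, no genomic relationships,
  no single-step evaluation.
* The screening battery treats records as exchangeable across parities;
  a repeated-measures sphericity analysis of the wide layout is out of
  scope.
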
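# Methods

This note documents the statistical models implemented in `tempomon`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Diversity estimators

Unbiased gene diversity is h = n/(n−1)(1 − Σpᵢ²) on n sequences; the
diploid expected heterozygosity applies the same correction on the
gene-copy scale (2n copies). Observed heterozygosity is the proportion of
heterozygous individuals among non-missing calls. Rarefied richness is the
hypergeometric expectation Σᵢ[1 − C(n−nᵢ, g)/C(n, g)] of distinct alleles
in g copies, computed through log-gamma functions for stability; it equals
the observed count exactly at g = n. The rarefaction unit is gene copies
for diploid loci and sequences for the haploid locus; when several samples
are compared, g defaults to the smallest sample among them (the size
behind published haplotype-richness columns is generally not recoverable,
so richness at an arbitrary g is never treated as a reference value).

The resampling correction draws B subsamples of n\* individuals without
replacement (default B = 1000, mirroring standard practice in monitoring
studies); per-locus statistics are computed on the individuals non-missing
at that locus within the subsample, averaged across loci per subsample,
and summarized by the mean and empirical 2.5/97.5 percentiles. Samples
smaller than n\* are skipped with a warning rather than padded. A
half-missing diploid call is treated as fully missing — the simplest
consistent rule where no published convention exists.

F_IS uses the Weir–Cockerham within-sample variance components: per
allele, b = n/(n−1)[p(1−p) − (2n−1)/(4n)·h] (among individuals) and
c = h/2 (within individuals); the multi-locus coefficient is the ratio of
summed components Σb/Σ(b+c), the "weighted" convention, with monomorphic
loci excluded.

## F-statistics and AMOVA

Both estimators are moment solutions of a nested random-effects ANOVA on
allele indicator variables over gene copies. The engine computes, for any
nesting, the sums of squares and the expected-SS coefficient matrix
K(l,m) = Σ_{cells e of finer(l,m)} n_e²/n_{cell_l(e)} from cell sizes
alone, then solves the triangular moment equations. With levels
samples / individuals / copies this reproduces the Weir–Cockerham (1984)
estimator exactly (verified against an independent transcription of the
published formulas to 1e-10); adding a groups level gives the three-level
AMOVA while retaining the within-individual component, which is folded
into the reported within-sample variance.

Haploid (Φ) mode runs the squared-distance form of the same decomposition:
SSD within a cell is Σ_{i<j} d²ᵢⱼ/n, and the size-based coefficient matrix
is shared with the indicator ANOVA. The default distance is identity (all
distinct haplotypes equidistant); a user matrix of squared distances (e.g.
substitution counts) is accepted, since published Φ values typically rest
on an unprinted divergence matrix. Negative variance components are
reported as estimated, never truncated, and indices are formed from raw
components — published tables do print small negative Φ values.

Permutation schemes: F_CT permutes whole samples among groups, F_SC
permutes individuals among samples within groups, F_ST permutes
individuals among all samples; p = (1 + #{perm ≥ obs})/(n_perm + 1),
default 1000 permutations.

## Hardy–Weinberg and linkage QC

The HWE test is the conditional exact test: the probability of a genotype
array given allele counts is n!·Πaⱼ!·2^h / ((2n)!·Πfᵢⱼ!), and the p-value
is the total probability of arrays no more probable than the observed one
(ties inclusive). Biallelic loci up to n = 500 and small multi-allelic
tables are enumerated; otherwise a Monte Carlo version shuffles the 2n
gene copies into random pairs — an unbiased estimate of the same p. For
calibration diagnostics the randomized (tie-broken) p-value
P(T < t) + U·P(T = t) is available: it is exactly uniform under the null,
whereas the reported inclusive p is conservative, as for any discrete
exact test. The inter-locus test permutes one locus's genotypes across
individuals within each sample and sums the G statistic of the
genotype-by-genotype table across samples. Multiple testing uses Holm's
sequentially rejective procedure.

## Effective-size estimators

*Moments.* Fc = (1/K)Σᵢ(xᵢ−yᵢ)²/(zᵢ−xᵢyᵢ) per locus over the K alleles
present in either sample (alleles absent from both are dropped), loci
weighted by allele count. Sampling correction for Plan I (sampling before
reproduction with replacement into the breeding pool, census N):
Ne = t/(2[Fc − 1/(2S₀) − 1/(2Sₜ) + 1/N]); Plan II omits the 1/N term. A
non-positive bracket reports +infinity: the observed change is within
sampling noise. CI: chi-square on Fc with df = Σ(K_l − 1).

*Fs.* Numerators Σ(x−y)² and denominators Σz(1−z) are pooled across loci;
the bias correction is
Fs′ = [Fs(1 − 1/(4ñ)) − 1/ñ] / [(1 + Fs/4)(1 − 1/(2N))] with ñ the
harmonic mean sample size in individuals, and Ne = t/(2Fs′). The CI is a
delete-one-locus jackknife on the corrected-Fs scale, transformed to Ne;
a single locus yields a point estimate with an undefined CI.

*Pseudo-likelihood.* Each allele (vs rest) contributes
Σ_{p₀} Prior(p₀)·P(k₀|p₀)·Σ_{pₜ} WFᵗ(pₜ|p₀, Ne)·P(kₜ|pₜ) with a uniform
prior on a 128-bin frequency grid and binomial Wright–Fisher transitions
between bins (exact binomial CDF mass per bin, t-step by matrix power,
cached per (bins, 2Ne, t)). Under Plan I with known census the observation
model is hypergeometric — the correct likelihood for drawing distinct fish
from a finite pool. The MLE is the maximum over a log-spaced Ne grid
(default 120 points, 4–20000); a maximum at the top grid point reports
+infinity; the CI is the 2-unit support interval. This estimator's median
is right-skewed when the drift signal is well below the sampling noise
(the likelihood is nearly flat toward large Ne), an inherent property at
weak signal also visible in published comparisons where pseudo-likelihood
estimates exceed moments and Fs estimates; the recovery tests document it.

*LD.* Burrows composite disequilibrium from allele dosages X ∈ {0,1,2}:
Δ = cov(X_A, X_B)/2 with the n/(n−1) covariance,
r² = Δ²/(p_A(1−p_A)p_B(1−p_B)), screened at Pcrit (default 0.02) and
weighted by the per-pair usable n. The sampling expectation is
E[r²|S] = 1/S + 3.19/S² for S ≥ 30 (0.0018 + 0.907/S + 4.44/S² below),
and the random-mating inversion Ne = (1/3 + √(1/9 − 2.76r²′))/(2r²′)
(0.308, 2.08 below S = 30). r²′ ≤ 0 reports +infinity; a negative
discriminant is flagged "below estimable minimum". CI: delete-one
locus-pair jackknife. The method assumes drift–recombination steady state;
samples taken shortly after a linkage-equilibrium founding understate LD,
so benchmark scenarios include burn-in generations.

*Conventions.* The Nei–Tajima Fc (not the Pollak form) is primary. Years
between samples are equated with generations; consecutive-year estimates
can be rescaled by C/G for overlapping generations (G defaults to 1.27,
the species' mean parental age; C is configuration-supplied and the
correction is off by default, since no published value of C is
available). Temporal estimates are labeled by the first sample's year.
Broodstock effective size is 4NmNf/(Nm+Nf).

## The simulator

A dioecious Wright–Fisher population with 1:1 sex ratio, unlinked
multi-allelic loci (Dirichlet-initialized frequencies, no mutation — a
12-year horizon makes microsatellite mutation negligible), and a maternal
haploid locus. Family-size overdispersion implements the low Ne/Nc regime
of type III survivorship: each parent receives a gamma(α) breeding weight,
making offspring counts Dirichlet-multinomial; α is solved (Brent) so the
expected variance Ne of the transition — per-sex Crow–Denniston
Nₑₛ = (N_s k̄ − 1)/(k̄ − 1 + Vk/k̄) combined as 1/Ne = 1/(4Nₑ_f) + 1/(4Nₑ_m)
— hits the requested value; realized per-generation Ne is recorded from
realized family sizes. Measured drift matches the target within ~1–2%
(drift-law and heterozygosity-decay tests).

Supplementation replaces a fraction φ of a generation with offspring of
captive lots whose broodstocks are drawn without replacement from the
current adults; paired lots assign offspring uniformly at random to
male–female pairs, communal lots draw both parents at random. Plan I
sampling draws S distinct adults before reproduction; sampled fish remain
available as parents (the finite-pool correction this induces is the 1/N
term of the Plan I estimators).

Presets: `isolated_wf` (Ne = 100, Nc = 1000, 9 loci × 8 alleles, S = 50 at
generations 0 and 2) is the estimator-recovery benchmark; it uses a
moderately even allele spectrum (Dirichlet 5) so that recovery measures
implementation correctness rather than the documented rare-allele bias of
temporal moments. `wild_decline` is a census crash 10⁵ → 10³ with Ne ≈
Nc/10. `supplemented_sink` is a steep decline (Ne 2000 → 30) sampled
during the collapse with hatchery input ramping to φ = 0.5: the
single-sample LD estimate reflects the parental generation and residual
LD decays only by (1−c)² per generation, so it exceeds the temporal
estimate on average — the inbreeding-vs-variance effective size signature
of a declining, supplemented population.

What the generator does not emulate: mutation, age structure and
overlapping generations (the C/G correction is exercised analytically,
not against an age-structured truth), spatial reach structure with larval
drift (an exploratory stepping-stone exists but is off by default and not
acceptance-tested), genotyping error and null alleles. Passing recovery
tests therefore show the estimators are correct under their own model
assumptions at realistic monitoring scales — not that they are robust to
those real-data complications.

## Numerical and testing choices

Problem sizes in the test suite are chosen for desk-scale runs: 200
replicates for temporal-estimator recovery (medians asserted within the
stated tolerances), 100 for LD recovery and for the source–sink
direction, 1000 for test-calibration checks. Medians, not means, summarize
recovery because every Ne estimator is a reciprocal of a noisy
non-negative signal and is heavily right-skewed. Ties in exact tests count
inclusively toward p (the conservative convention); calibration checks use
the randomized p, the exactly-uniform quantity for discrete tests.
Infinite estimates are first-class values ("inf" in TSV output) and are
excluded, with counts reported, from any rank, mean, or regression.

Known limitations: the pseudo-likelihood median overshoots truth by
~25–35% in the weak-signal benchmark regime (see above); the inter-locus
G permutation test and LD estimator assume unlinked loci; the largest-
remainder count reconstruction cannot distinguish published frequency
rows whose rounding is inconsistent with the stated sample size (it warns
or raises instead of guessing).
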
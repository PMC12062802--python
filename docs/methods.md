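# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `hircus`, in the spirit of a model/methods appendix.

## Single-locus summaries

Genotype and allele frequencies are plain counts over the non-missing calls
at a locus; p is the reference-allele frequency and q = 1 − p is derived, so
p + q = 1 holds exactly. The diversity indices are the classical functions
of allele frequencies: Ho = p² + q² (expected homozygosity under random
mating), He = 1 − Ho, Ne = 1/Ho, and Botstein's PIC, implemented in its
general k-allele form

    PIC = 1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²

which reduces to He − 2p²q² for the biallelic loci this pipeline targets.
Note these are *expected* rates computed from allele frequencies; observed
heterozygosity is emitted as a separate diagnostic column and is not used in
any index.

### Hardy–Weinberg test

Expected genotype counts are (np², 2npq, nq²) at the observed allele
frequency and the statistic is the uncorrected Pearson chi-square over the
three genotype classes. Two degrees-of-freedom conventions coexist in the
applied literature:

- `standard` (df = 1): classes − 1 − estimated parameters, the textbook
  choice for a biallelic locus;
- `paper` (df = 2): classes − 1, widespread in livestock candidate-gene
  reports (the "χ²₀.₀₅ = 5.99" critical value quoted in such tables is the
  df = 2 quantile).

`df_mode="paper"` is the default so that published tables using that
convention reproduce verbatim; both modes share the same χ² value.
Monomorphic loci raise rather than return a degenerate test (the expected
heterozygote count is zero). Report tables round half-up to 2 decimals,
matching how such tables are conventionally printed; full precision is kept
internally.

## Haplotype EM

Let f be frequencies over the 2^L haplotypes of L biallelic loci. Assuming
random union of gametes, an unphased genotype g has likelihood
Σ (2 − δ_{h1 h2}) f(h1) f(h2) over the unordered haplotype pairs consistent
with g (a genotype with k heterozygous loci has 2^{k−1} such pairs, or one
if k = 0). EM alternates the usual expectation (distribute each individual
over its consistent pairs proportionally to pair probability) and
maximization (expected gamete counting) steps. Numerical choices:

- initialization: the deterministic linkage-equilibrium product of allele
  frequencies; optional seeded Dirichlet restarts (`restarts=`) guard
  against local maxima, with the best final likelihood kept;
- convergence: max |Δf| < 1e-8 or 1,000 iterations; non-convergence returns
  the current estimate flagged `converged=False`;
- the log-likelihood is asserted non-decreasing at every iteration;
- individuals with any missing call at the analysed loci are excluded from
  EM (complete-case, count logged) but still receive diplotype assignments;
- L is capped at 12 (2^L enumeration).

### LD

For two biallelic loci with ref-class marginals p_A, p_B and joint ref-ref
frequency f00: D = f00 − p_A p_B, D′ = |D| / D_max with
D_max = min(p_A(1−p_B), (1−p_A)p_B) for D > 0 and
min(p_A p_B, (1−p_A)(1−p_B)) otherwise, and
r² = D² / (p_A(1−p_A) p_B(1−p_B)). |D| below 1e-14 is snapped to zero so
exact independence reports D′ = r² = 0. LD at a monomorphic locus is an
error, not a zero. The reported matrix puts D′ above and r² below the
diagonal, and r² > 0.33 (strictly) flags a strong-LD pair. Each pair's
haplotype frequencies come from a dedicated two-locus EM rather than from
a single joint 4-locus fit, matching standard pairwise-LD reporting.

### Diplotypes and rare-haplotype exclusion

The posterior of an unordered pair is (2 − δ) f(h1) f(h2) normalized over
consistent pairs, marginalizing missing loci; the maximum-posterior pair is
reported with its probability. Exact ties prefer the pair containing the
more frequent haplotype, then lexicographic order — a determinism choice,
not a statistical one. Individuals inconsistent with every
positive-frequency pair (possible after rare-haplotype exclusion) are
assigned over the full haplotype space with a 1e-6 pseudo-frequency floor
and flagged low-confidence. `filter_rare` removes haplotypes below 5 % and
renormalizes the rest to sum to 1 — the interpretation under which a
published two-haplotype table summing to exactly 100 % is coherent — while
keeping the raw frequencies and the dropped mass in the output.

## Association

The genotype-by-sex model is fit as a Gaussian GLM (statsmodels) with
identity link by default; with that link the fit equals the least-squares
solution, which the tests verify against the normal-equations closed form.
A log link is available for traits better modelled multiplicatively. The
design dummy-codes genotype against the wild-type homozygote (G1 =
heterozygote, G2 = variant homozygote) and sex as S1 = 1 for males; with
interactions present, an empty genotype-by-sex cell makes the design
singular and the error names the cell.

**Stepwise reduction.** Forward–backward search over
{G1, G2, S1, G1S1, G2S1} with the hierarchy constraint (an interaction may
enter only after both parents, a parent may leave only after its
interactions). A term enters when its Wald p-value, Bonferroni-adjusted for
the size of the candidate family, clears `enter_alpha` (0.05); without the
adjustment the chance of a pure-noise trait acquiring at least one term
grows with the number of candidates tested, and the adjusted rule keeps
that family-wise rate at the nominal level — which is also the behaviour
the null-simulation tests pin down. A term is dropped when it is no longer
significant and its removal does not worsen the selection criterion (AIC
default, BIC by flag).

**Stratified comparisons.** Within each sex, one-way ANOVA across genotype
(or diplotype) levels, then all pairwise two-sample tests
Bonferroni-adjusted with m = number of pairs within that trait-by-stratum
family (3 for three genotypes; per-table families, not experiment-wide).
Letters come from the maximal cliques of the non-significance graph
(Bron–Kerbosch), which guarantees by construction that two groups share a
letter iff their adjusted difference is not significant — lowercase at
α = 0.05, uppercase at α = 0.01. Between sexes, Welch's unequal-variance
t-test is the default (pooled-variance by flag, appropriate when a Levene
check supports equal variances), starred \* for p < 0.05 and \*\* for
p < 0.01. Groups with fewer than two observations are excluded with a
warning rather than silently.

## Synthetic cohorts

The generator emulates the marginal structure of the goat study the
pipeline was built around:

- **Cohort**: 153 animals, 78 male / 75 female.
- **Genotypes**: each individual is a random union of two gametes drawn iid
  from a haplotype table; defaults CCCA = 0.5759 and TGTG = 0.4241 over
  the four loci g.15523T>C, g.15530G>C, g.18413T>C (exonic), g.19711G>A,
  with a `leak` (default 0.02) of mass spread uniformly over the 14
  recombinant haplotypes so that EM and LD code paths see strong but
  imperfect LD (D′ < 1 off-diagonals). Independent gamete draws make the
  cohort satisfy multi-locus HWE by construction; the df = 1 test rejects
  in ≈5 % of seeds, as the calibration test checks.
- **Traits**: thirty slaughter / meat-quality / organ-coefficient traits,
  each generated from the same genotype-by-sex GLM the package fits —
  intercept at the female mean, sex effect equal to the male–female
  difference, genotype effects zero by default (configurable per trait),
  Gaussian residuals. The published per-sex summaries used for calibration
  print standard errors of the mean (their magnitudes match the group SDs
  printed elsewhere for the same traits), so residual SDs are recovered as
  SE·√n per sex and averaged: e.g. live weight ≈ N(29.86, 4.9²) kg for
  females plus a +7.27 kg male effect. Values are clipped to physical
  bounds (percentages to [0, 100], weights to ≥ 0, pH to [0, 14]); with the
  default means and SDs clipping is a ≫3σ event, so Gaussianity is
  effectively intact. A residual SD of zero is allowed as the noiseless
  limit (useful for exactness tests).

What the generator deliberately does **not** emulate: trait–trait
correlations beyond those induced by sex and genotype (real slaughter
traits are strongly mutually correlated), pedigree/relatedness structure,
non-Gaussian tails, and any genotype–trait effect that was not put in by
configuration. Passing tests on synthetic cohorts therefore demonstrate
the *statistical machinery* — estimator correctness, calibration, error
control — not biological conclusions about real animals.

## Problem sizes in tests

The test suite runs the EM-recovery and LD-saturation checks at n = 5,000
individuals, Wald-coverage at 500 replicates of n = 2,000, null stepwise at
200 replicates of n = 153, and HWE calibration at 500 seeds — sizes chosen
so each property is measured with useful precision while the whole suite
stays fast on a laptop.

## File formats

Native genotype tables are TSV (`individual_id`, `sex`, one column per
locus, genotypes as unordered allele pairs, `NA`/`./.`/`--`/blank for
missing); locus columns whose header carries a `REF>ALT` suffix are
self-describing, otherwise loci must be declared by the caller (the format
does not carry region annotations — declare loci to preserve them). Trait
tables are CSV with units in parenthesised column suffixes; blank cells are
missing, anything non-numeric is an error naming the cell. A minimal VCF
path (biallelic SNPs, GT field) is provided via cyvcf2, with sex supplied
separately since VCF does not carry it. Positions are opaque labels —
nothing in the statistics uses genomic coordinates.
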
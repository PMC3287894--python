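# Methods

## Model and procedure

The association model is linear: a quantitative trait `Y` regressed on
genotype-derived predictors for `N` unrelated individuals. Genotypes are
carrier-coded (0/1, presence of at least one minor allele), after folding
dosages so the counted allele is the minor one. Only nonsynonymous
variants enter the analysis (synonymy is taken as given annotation, never
computed); variants are *rare* when 0 < MAF < `rare_threshold` (default
0.05, the conventional 5% cut) and *common* when MAF ≥ threshold.
Monomorphic columns are dropped up front — they carry no information and
break standardization.

One SORC repetition draws, independently per gene, a uniform subgroup size
`S_k ∈ {1, …, M_k}` and a uniform subset of that size; the subset and its
complement are each collapsed to a burden indicator (logical OR of carrier
columns). The sampling law is taken literally: `S_k = M_k` leaves the
second subgroup empty and the gene degenerates to a whole-gene burden that
repetition (no re-draw). Single-variant genes always contribute their own
carrier column. The penalized fit minimizes

    ||Y − Xβ − Uγ||² + λ(||β||₁ + ||γ||₁)

with an unpenalized intercept: `X` collapsed rare indicators, `U`
uncollapsed common carriers, both blocks penalized with equal weight (one
λ; no differential weighting). Selection is attributed *per variant*:
a selected `X` column marks every rare variant in its subgroup, a selected
`U` column its single common variant. Randomness of the partitions over
`R` repetitions is what discriminates subgroup members from one another;
common variants, whose columns never change, simply accumulate their
marginal selection frequency. Stability = selection count / R; it lives on
the lattice {0, 1/R, …, 1}.

Gene scores are the maximum member stability, with ties broken first by
the number of members with stability ≥ 0.5, then by gene id, making the
ranking deterministic. Across phenotype replicates, a gene is counted as
*identified* when it ranks in the top `T` (default 15).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `rare_threshold` | 0.05 | MAF cut between rare and common; field convention |
| `R` | 100 | random-collapsing repetitions; stability resolution is 1/R |
| `cv_folds` | 10 | K in K-fold CV for λ |
| λ grid | 100 geometric points, down to 10⁻³·λ_max | λ_max is the smallest λ with all coefficients zero; matches the common coordinate-descent path defaults |
| λ rule | minimum mean CV error | the least conservative standard rule; a 1-SE rule would select fewer variants and depress all stabilities uniformly |
| `zero_tol` | 1e-8 | nonzero-coefficient threshold on the standardized scale; coordinate descent returns exact zeros, the tolerance only guards alternative solvers |
| `top_T` | 15 | identification cut for gene counting |

Design columns are standardized (mean 0, unit variance) before the fit by
default; constant columns are excluded and reported. Covariates are not
modeled. The LASSO path and CV are computed by scikit-learn
(`Lasso`/`LassoCV`); λ here equals `2·N·alpha` in scikit-learn's
parameterization, and the tests verify the fit against the subgradient
(KKT) optimality conditions directly.

Two independent RNG streams are spawned from the run seed: one for the
partitions (consumed in sorted gene order), one for CV fold assignment.
The collapsing sequence is therefore invariant to `cv_folds`, and a run is
bit-reproducible given its seed; plans can be serialized (JSON lines) and
replayed.

## Baseline rankers

All baselines rank by −log₁₀(p) with no multiple-testing correction —
they are compared purely as rankers. The single-marker test is the simple
linear regression of `Y` on one carrier column (two-sided t, N−2 df). The
collapsing method tests the whole-gene burden indicator the same way. The
CMC method was originally formulated with case-control multivariate
statistics; for a Gaussian trait it is realized here as the overall F-test
of the per-gene multiple regression on MAF-binned rare burden indicators
(default: one whole-gene bin; optional second bin split at MAF 1%) plus
the gene's uncollapsed common carriers. Collinear design columns are
dropped greedily in input order at relative tolerance 1e-10 (rare-variant
designs are routinely rank-deficient); degrees of freedom reflect the kept
columns. Under Gaussian errors all three tests are exact, which the null
calibration test confirms empirically.

## Synthetic cohort generator

The simulator emulates a mini-exome quantitative-trait cohort: `K` genes
with 4–12 variants each, independent sites in Hardy–Weinberg equilibrium
(genotype ~ Binomial(2, MAF)), 87% of sites rare with MAF drawn from
`0.05·Beta(0.4, 2)` (mean ≈ 0.008, substantial mass below 0.01) and common
sites uniform on (0.05, 0.5). A few functional genes carry functional
*rare* variants (default 4 per gene, roughly half a typical gene's rare
complement) with per-allele effects uniform on [0.17, 1.2] trait units;
functional variants are drawn only from sites actually observed in the
cohort (realized minor-allele count ≥ 1), since an unobserved site cannot
be scored by any method. Phenotype replicates share the genotype matrix:
`Y = Σ effect·dosage + Normal(0, noise_sd²)`, fresh noise per replicate.

Effects act on dosage although the analysis recodes to carrier status —
a deliberate generative/analysis mismatch typical of additive trait
models meeting burden coding. What the generator does **not** emulate:
linkage disequilibrium (sites are independent; an exchangeable within-gene
correlation mode would be the natural extension), population structure,
relatedness, covariate effects, binary traits, and realistic coalescent
haplotype structure. Passing tests therefore demonstrate the machinery and
its statistical behavior under clean HWE sampling, not robustness to LD or
stratification.

The default evaluation profile — 50 genes, 3 functional, N = 700, unit
noise, 20 phenotype replicates, R = 50 — is sized so the full method
comparison runs in minutes on one CPU. At this scale a top-10 gene list
covers the easiest quintile of the genome, so all four methods recover
nearly all three functional genes and the separation *between* methods is
compressed relative to a genome-scale search space; the discriminating
readouts are the top-1 recovery rate and the functional/non-functional
stability contrast.

## Numerical and degenerate-input choices

* p-values are floored at 1e-300 so −log₁₀(p) stays finite at underflow
  (perfect separation).
* Carrier-coded input has no observable allele count; MAF is recovered by
  the Hardy–Weinberg inversion `1 − sqrt(1 − carrier fraction)`, an
  approximation, capped to [0, 0.5].
* Missing genotypes are an error, not imputed. Multiallelic and non-SNV
  VCF records are skipped with a warning.
* Individual alignment between genotype and phenotype files is by id with
  hard failure on mismatch — no silent reordering.
* A phenotype with fewer distinct values than CV folds raises rather than
  producing degenerate folds; a repetition that fails aborts the run (no
  silent skipping, which would bias stabilities).

## Known limitations

Stability is a ranking score without finite-sample error control; the
choice of how many top variants to report is unresolved here. The equal
penalty on rare and common blocks is one reading of the objective;
differential weighting is plausible and unexplored. The min-CV λ rule is
liberal — null genes regularly reach moderate stabilities, and on small
gene panels an occasional null common variant attains stability ≈ 1.
Subsampling-based stability selection (randomness over individuals rather
than over collapsing criteria) is intentionally out of scope.
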
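# Methods

## The panel model

`cogpanel` targets behavioral data from a replicated genetic reference
panel: S isogenic strains, each measured with a handful of replicate
animals at two ages (6 and 14 months) on bounded percentage traits. The
working model behind every stage is the classic variance-components
decomposition for inbred panels: an animal's value is

    y_ijk = g_i(age) + e_ijk,    g_i(6m) ~ baseline + QTL + polygenic,
    g_i(14m) = g_i(6m) + d_i,    e_ijk ~ N(0, Ve),

where `g_i` is the strain genetic value (between-strain variance Va at
baseline), `d_i` a strain-specific decline drawn from
N(decline_mean, decline_sd²), and `e` the replicate-level environmental
deviation. Genotypes take two states per locus (0 = B6/B6 homozygote,
1 = B6/D2 heterozygote), the structure of an F1 backcross panel; a
consequence carried through the whole package is that recessive effects of
the D2 allele are invisible, and QTL effects are additive on the 0/1 code.

## Heritability of strain means

For one trait × age, a one-way ANOVA by strain gives MS_between and
MS_within. With `n0 = (N − Σn_i²/N)/(S − 1)` the effective replicate count
(equal to the common n in balanced designs):

    Ve = MS_within
    Va = max(0, (MS_between − MS_within)/n0)      (negative estimates
                                                   truncated, flagged)
    h²_RIx̄ = Va / (Va + Ve/n̄),   n̄ = mean replicates per strain.

This is the heritability *of strain means* — it grows with replication
because averaging replicates shrinks the environmental share of a strain
mean. The ratio estimator carries a small negative bias at panel sizes
(mean estimate ≈ 0.57–0.58 at a truth of 0.6 with 27 strains × 4 reps),
which the parameter-recovery tests bound at ±0.05. Whether the denominator
should use `n0` or `n̄` is a genuine ambiguity of the field's verbal
definition ("normalized to the number of biological replicates per
strain"); this implementation uses `n̄` in the denominator and `n0` for
the Va moment estimator, and reports both quantities so either convention
can be reconstructed.

Degenerate inputs: all-identical values report h² = 0 with a flag rather
than 0/0; a panel where every strain has n = 1 leaves Ve inestimable and
raises; h² is clipped to [0, 1].

## Single-marker QTL scan

The scan regresses strain means on each marker's genotype code:

    LOD_m = (n/2) · log10(RSS0 / RSS1) = −(n/2) · log10(1 − r²_m),

with `r_m` the marker–phenotype correlation. This deliberately replaces a
kinship-corrected mixed-model scan (the LOCO-style approach used by
dedicated QTL packages): on strain-mean data of this size the simple scan
reproduces the same operational behavior, and its null calibration is
handled entirely by permutations — strain labels of the phenotype vector
are shuffled (1,000 times by default), the genome-wide maximum LOD is
collected, and the threshold at level α is the empirical (1 − α) quantile.
Measured type-I error at α = 0.05 over 200 null panels (27 strains, 500
markers) lands at 0.03–0.05. Monomorphic markers score LOD = 0 with a
flag; perfect fits (RSS1 = 0) are capped at a configurable ceiling
(default 30) with a flag. LOD is invariant to affine rescaling of the
phenotype. Kinship correction, interval mapping, multi-QTL models and
covariates are deliberately out of scope.

## Power and minimum detectable effect

For a locus explaining a proportion `pve` of strain-mean variance, the
regression F statistic has the exact conditional distribution
F(1, n−2; λ) with non-centrality λ = β²·Σ(g−ḡ)²/σ². Taking the
expectation of Σ(g−ḡ)² over genotype draws gives

    λ = (n − 1) · pve / (1 − pve),

and the LOD threshold converts exactly to an F critical value via
F_crit = (n−2)·(10^(2·LOD/n) − 1). Power is the non-central F tail beyond
F_crit. The more familiar asymptotic form — a 1-df non-central chi-square
on 2·ln10·LOD with λ ≈ n·pve/(1−pve) — overstates power badly at panel
sizes (0.88 versus a simulated 0.70 at n = 27, pve = 0.5, LOD 3.5); the
finite-sample F form agrees with simulation to well within 0.05, which is
why it is the one implemented. `min_detectable_pve` inverts the power
curve by root bracketing on pve ∈ (0, 1) and raises when the requested
power is unreachable at the given threshold.

## Module–trait screen

Module construction is an input: the package consumes a gene → module
assignment plus a strain-averaged expression matrix, mirroring the
division of labor in co-expression studies where the clustering comes
from a dedicated tool. Within that scope:

* **Filtering** keeps genes with ≥ 1 TPM (configurable) in ≥ 50% of
  samples, both bounds inclusive.
* **Eigengene** = first principal component (SVD) of the
  gene-standardized module submatrix, scaled to unit variance. PCA leaves
  the sign arbitrary, so it is fixed by requiring non-negative correlation
  with the mean standardized member expression.
* **Correlation screen**: Pearson r and two-sided p per module × trait,
  Benjamini–Hochberg adjustment with the family defined as *modules
  within one trait × age* (configurable; the alternative — one global
  family — is stricter when many traits are screened). Raw and adjusted
  p are both reported. Strains missing either value are dropped pairwise,
  with a floor of 3 shared strains.
* **Hub gene** = argmax of intramodular connectivity
  k_i = Σ_{j≠i} |cor(x_i, x_j)|^β with soft power β = 6 (the standard
  unsigned-network default); ties resolve to the lexicographically first
  gene id for determinism.

Measured discipline at the study scale (50 null modules + one module with
eigengene–trait r = 0.7, 40 strains): the true module is recovered in
≈ 100% of panels and false discoveries average ≈ 0 per panel at
FDR < 0.05 — comfortably inside the nominal 5% budget, reflecting BH's
conservatism under independence.

## Reserve / resilience classification

Per basis (one trait, or a composite formed by summing per-trait z-scores
of strain means within each age), thresholds are computed over included
strains (n ≥ 2 at both ages): quartiles Q1/median/Q3 of 6-month values,
the 14-month median, and the mean decline. Categories, in a fixed
precedence order:

1. `excluded` — n < 2 at either age;
2. reserve flag — baseline ≥ Q3(6m) AND later ≥ median(14m);
3. resilience flag — baseline ≥ median(6m) AND delta > mean(delta);
4. `reserve_and_resilience` / `reserve` / `resilience` by the flags,
   else `impaired` if baseline < Q1(6m), else `normal`.

Design choices where the operational definition leaves room:

* Quantiles use linear interpolation between order statistics; equality
  satisfies every "≥" comparison, and "below Q1" is strict.
* "Slower than average" is delta strictly greater than the unweighted
  mean delta of included strains; the 6→14-month interval is constant, so
  raw deltas order identically to annualized rates.
* The strict stringency replaces x ≥ T with x − SE ≥ T, x < T with
  x + SE < T, and the decline comparison with
  delta − SE(delta) > mean(delta), SE(delta) combining the two age SEs in
  quadrature. For the composite basis the SE is the quadrature sum of
  per-trait z-score SEs — an extension, since per-trait SE margins are
  the only ones the definition pins down.
* Thresholds are computed over included strains only, since excluded
  strains cannot be categorized against them.
* An earlier, discarded resilience criterion ("no significant 6→14-month
  difference") is not implemented as a category; it proved too permissive
  at panel replicate counts.

Classification is invariant to monotone affine transformation of any
trait and to input row order; strict flags are always a subset of
suggestive flags. An independent brute-force rule-applier in the test
suite agrees with the implementation call-for-call over thousands of
random panels.

## Baseline-versus-later correlations

Per trait, Pearson r (with two-sided p) of 6-month strain means against
14-month means, and against decline scores. The latter embeds a
regression-to-the-mean artifact — delta contains −baseline, so noise in
the baseline forces the correlation negative (≈ −1/√2 for independent
ages of equal variance) — and the output should be read with that
arithmetic in mind.

## The synthetic-data generator

What it emulates: ~27 strains with 1–8 replicates (default balanced, 4),
two ages, three percent traits with Va = 36 and Ve = 96 squared points
(true baseline strain-mean h² = 0.6 at 4 replicates — mid-band for
cognitive traits in such panels), strain declines from N(−6, 5²) (14-month
genetic variance 36 + 25 = 61, implied h² ≈ 0.72, keeping both ages in the
moderate-to-strong 0.5–0.75 band), genotypes as stationary two-state
Markov chains (start frequency 0.5, switch probability = adjacent-marker
recombination fraction, 19 chromosomes × 25 markers at 5 cM), an optional
planted QTL whose effect is scaled on the *empirical* marker variance so
it explains exactly the requested share of Va, and expression modules
whose latent eigengene is mixed from the standardized trait vector and
residualized noise so the *sample* correlation equals the requested r
exactly; member genes are loading × eigengene + noise with loadings
uniform in [0.6, 0.95] and noise variance 1 − loading², then shifted to a
non-negative TPM-like scale. The y-maze is longitudinal (same animals at
both ages); fear conditioning is cross-sectional (distinct cohorts), as
the terminal assay forces. Arm-entry sequences alternate with probability
p_alt and otherwise return to the arm two steps back, so the expected
alternation score is 100·p_alt.

What it does not emulate: sex effects (the field is carried but constant),
epistasis, genotype–environment interaction, linkage between the planted
QTL and the polygenic background, read-level RNA-seq noise or
between-cohort batch structure. Bounded traits are truncated to [0, 100]
(events counted and reported, not resampled); tests run in regimes where
truncation is rare, so passing them says little about heavily censored
data. One global seed feeds named child streams (genotypes, phenotypes,
expression, arm entries, permutations), making every component
bit-reproducible and insulating each stream from changes in the others.

## Problem sizes and numerical choices

The verification suite uses: 500 panels for heritability recovery
(tolerance ±0.05 on the mean), 200 null panels × 1,000 permutations × 500
markers for scan calibration (acceptance band 0.02–0.09 at α = 0.05),
1,000 simulated scans against the analytic power curve (±0.05), 200 panels
of 51 modules for FDR discipline, and 1,000 random panels for classifier
oracle equivalence — sizes chosen so the whole suite completes in a couple
of minutes on one CPU while leaving Monte-Carlo error well below each
tolerance. Quantile estimation everywhere uses linear interpolation;
sample SDs use the n−1 denominator; permutation thresholds and all
simulations are reproducible from explicit seeds.

## Known limitations

* No kinship correction: in panels with strong population structure the
  single-marker scan's permutation threshold calibrates the genome-wide
  null but does not remove polygenic confounding of individual peaks.
* h²_RIx̄ assumes the one-way random-effects model; shared-cage or batch
  effects would inflate Va.
* The power model treats the threshold as fixed; in practice the
  permutation threshold is itself estimated, adding (small) variance.
* The composite score weights traits equally after z-scaling; traits with
  higher measurement error are implicitly down-weighted only through
  their SEs in strict mode.
* Classifier categories depend on panel-relative thresholds, so adding or
  removing strains can change calls for unchanged strains — an inherent
  property of quantile-based operational definitions.
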
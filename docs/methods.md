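# Methods

This note documents the statistical procedures `nf1mod` implements, the
modeling assumptions they carry, the defaults and why they were chosen,
what the synthetic-data generator does and does not emulate, and the
numerical conventions used throughout.

## Trait and models

The quantitative trait is a nonnegative count (the number of café-au-lait
macules larger than 5 mm; "CALM count"). Every association stage supports
four model tags formed by crossing:

- trait scale: `unt` (raw count) or `log` (log10(x + 10); maps 0 to
  exactly 1 and is strictly increasing);
- genetic coding: `add` (minor-allele dosage 0/1/2), `dom` (carrier
  indicator), or `add_collapsed` (additive for common variants plus one
  collapsed column per tile for rare variants).

All fits are ordinary least squares with two-sided t-based p-values at the
model's complete-case residual degrees of freedom. OLS on a count trait is
a deliberate assumption inherited from the study design being emulated,
not a claim that counts are Gaussian; the null-calibration tests confirm
the resulting p-values are uniform to KS resolution at the cohort sizes
used, which is the property downstream FDR and meta-analysis rely on.

Missing data are handled complete-case per fitted model (decided once,
globally). Sex is coded female = 0, male = 1 in every design matrix.

## Expression screen

Raw intensities are background-subtracted, floored at zero,
quantile-normalized across samples (each sample's sorted values replaced by
the rank-wise mean profile; ties receive the average of the reference
values at the tied ranks), and transformed to log2(x + 1). Quantile
normalization leaves each sample's rank order unchanged.

The screen regresses the phenotype on each transcript's expression —
phenotype as response, matching the orientation of the original design —
and corrects the per-transcript p-values with the Benjamini–Hochberg
step-up. Candidates must satisfy FDR q < 0.3, mean log2 level ≥ 6 and
expression range (max − min) ≥ 2; transcripts on a user-supplied rescue
list bypass the level/range filters (flagged `rescued`) but never the FDR
condition. Zero-variance transcripts yield flagged (missing-p) results and
are excluded from the FDR correction rather than raising.

Verification mirrors qPCR practice: relative expression by the
double-delta-Ct rule (2^−ΔΔCt), re-regressed against the trait, retaining
candidates at nominal p < 0.05.

The screen's operating-point test computes recall and false-discovery
proportion at the q < 0.3 threshold, i.e. before the level/range filters.
Those filters encode measurement reliability (low or flat probes), not
discovery error control, so FDR calibration is the property to check; the
generator nevertheless places a fraction of null transcripts below each
filter so the filtering logic is exercised, while planted transcripts are
constructed to sit above both.

## Variant QC and coding

QC runs in a fixed order — the order changes the result, so it is part of
the contract:

1. calls with per-call quality score < 99 become missing;
2. samples with > 30% missing calls are removed;
3. variants with > 20% missing calls among remaining samples are removed;
4. monomorphic variants (including all-missing, with a distinct reason
   code) are removed.

Hardy–Weinberg equilibrium is tested with the exact conditional test
(summing the probabilities of all heterozygote counts no more probable than
the observed one, conditional on allele counts), computed on an unrelated
subset: samples sharing a parent link are clustered and the
lexicographically smallest id per cluster is kept, a deterministic stand-in
for pedigree-aware selection. Variants with exact p < 0.03 are flagged but
retained — in ascertained samples an HWE departure can mark a causative
variant — and the flags are carried as annotations only. The exact test
was chosen over a chi-square approximation because the cohorts are small;
it matches an exact-integer enumeration oracle on every table with up to
200 alleles.

Trio consistency uses the dosage truth table: a child call is inconsistent
iff no pair of transmissible parental alleles can produce it; any missing
member makes the trio untestable.

Rarity (MAF < 0.05) is computed on the post-QC analysis cohort, not
per-tile. Collapsing summarizes the rare variants of each tile as the
proportion of a sample's non-missing rare sites carrying at least one
minor allele ("presence" reading). The phrase "proportion of the minor
allele" also admits an allele-fraction reading (minor-allele count over
twice the non-missing sites); both are implemented, selectable by flag,
with presence as the default — on a tile with a single rare variant the
presence reading reduces exactly to the dominant coding, which makes the
collapsed column interpretable as a carrier burden. Tiles with no rare
variant produce no column; all-missing sample×tile cells stay missing.

## Tiles

Tiles are derived from recombination-hotspot intervals (BED, 0-based
half-open). Boundaries are placed at hotspot midpoints, so k hotspots on a
chromosome yield k + 1 tiles, every base (including bases inside a
hotspot) belongs to exactly one tile, and chromosome ends bound the outer
tiles (open-ended when no length is supplied). Midpoint placement is a
design choice: the alternative (tiles between hotspot edges) leaves
hotspot-interior variants unassigned. Hotspot coordinates are user input;
no genome build is assumed.

## Tiled regression

The trait is residualized on age and sex once, before selection
("pre-adjusting"); the single-variant analysis instead carries the
covariates inside each model, matching the different formulations of the
two stages. The procedure then runs:

1. **Tile screen.** Each tile's variants are fit jointly (overall F-test)
   and individually. The tile is retained iff the F-test p < 0.2 or any
   single-variant p < 0.05. If a tile has more variants than complete
   cases, the joint fit is skipped (logged) and the single-variant screen
   decides alone.
2. **Within-tile stepwise.** Forward entry of the best-p candidate while
   p < 0.05, with a backward look after each entry that repeatedly removes
   the least significant term with p ≥ 0.05.
3. **Chromosome and genome levels.** Survivors are pooled and the same
   stepwise rule is re-run from an empty model at each level.

Ties on entry p are broken toward the lower genomic coordinate
(determinism). Models are refit from scratch at every move. The final
model satisfies a fixed point: every retained term has p < 0.05, and
re-offering any removed variant does not achieve p < 0.05.

Entry at α = 0.05 is per-term, so under a global null the procedure still
returns a non-empty model at a rate governed by the screening and entry
alphas; the planted-signal recovery test therefore asserts that the causal
variant is contained in the selected set and monitors (without asserting)
the spurious-inclusion rate.

## Meta- and mega-analysis

Liptak's method combines per-cohort two-sided p-values with
z_i = Φ⁻¹(1 − p_i) and Z = Σ √n_i·z_i / √(Σ n_i), reporting
p = 1 − Φ(Z). The default is the *unsigned* convention — z is computed
from the p-value alone, ignoring the sign of the cohort effect — because
that is the convention under which the published combined values are
reproduced, including the case where cohort effect directions disagree. A
signed variant (z multiplied by sign(beta)) is available behind a flag.
With one cohort the combination is the identity; with equal sizes it
reduces to unweighted Stouffer. p-values of exactly 0 or 1 are domain
errors (infinite quantile).

The mega-analysis pools individual-level data and fits
trait ~ intercept + age + sex + cohort indicators + genotype, reporting
the genotype coefficient. A genotype collinear with the cohort structure
yields a flagged missing result rather than an unstable estimate.

## Synthetic-data generator

The generator's defaults are the emulated study conditions: cohorts of
89/29/62 (the post-ancestry-filter analysis sizes) with cohort-specific
age distributions (means 36.5/38.1/15.2 years, SDs 13.8/12.7/7.7, clipped
at 0) and male fractions (0.394/0.455/0.556); 118 SNVs — 58 common, 60
rare with mean MAF ≈ 0.017 — placed uniformly across a 120 kb chromosome
carrying four hotspots, hence five tiles; and a leading common pair with
target dosage correlation 0.9 at equal MAFs 0.191. Equal frequencies for
the pair are forced by the Fréchet bound: at MAFs 0.191/0.137 the maximum
attainable dosage correlation is ≈ 0.83, so a 0.9 target there is
infeasible and the generator raises an error explaining the bound.

Haplotypes are drawn from a Gaussian copula thresholded at Φ⁻¹(MAF), so
genotypes satisfy Hardy–Weinberg proportions by construction. The latent
correlation for each LD pair is calibrated by bisection on the bivariate
normal CDF so that the *realized* dosage correlation matches the target
(checked, not assumed; the indicator (phi) correlation of the two
thresholded haplotypes equals the dosage correlation because dosages are
sums of two independent haplotype indicators).

The trait is a rounded, zero-floored Gaussian latent:
intercept 14 + 0.05·age + 2·sex + Σ beta_v·code_v + N(0, 8), with the
default planting one additive effect of −5 per minor allele on a member of
the correlated pair (an effect size of the magnitude the analysis is meant
to detect at discovery scale). A rounded latent rather than a
Poisson/negative-binomial count matches the OLS analysis assumption; a
missing genotype at a planted variant contributes 0 (carrier status
unknown). Per-call quality scores place 2% of calls below the masking
threshold and 1% of calls are missing outright.

Expression (log2 scale, 1000 transcripts × 79 samples by default) plants
20 transcripts with slopes |b| ∈ [0.06, 0.12] on the centered trait and
residual SD 0.7 — per-transcript correlations ≈ 0.5–0.75, strong enough
that the screen's recall criterion is a test of the screen rather than of
power — baselines in [6.5, 9.5]; among nulls, 20% sit below the level
filter and 10% have residual SD 0.15 (range < 2), so both filters act.

Deliberately **not** emulated: realistic LD maps, population structure or
ancestry admixture, genotyping batch effects, expression batch/array
effects, age-dependence of the trait beyond a linear term, and
trio-structured cohorts at study scale (trio transmission is generated
only to exercise the Mendelian check). Passing tests therefore demonstrate
correctness of the procedures under the stated model, not robustness to
those real-data complications.

Determinism: all draws flow from one `numpy` generator seeded by the
config; identical config and seed give byte-identical output files.

## Numerical conventions

- OLS is solved by normal equations (the designs are tiny and
  well-conditioned); singular stepwise candidate sets are skipped; the
  per-fit t p-values are floored at the smallest positive double to keep
  them in (0, 1].
- BH FDR is the vectorized step-up with enforced monotonicity; missing
  p-values are excluded and returned missing; inputs outside (0, 1] are
  domain errors.
- The HWE exact test computes the heterozygote-count distribution in log
  space (gammaln) and includes terms with probability ≤ observed within a
  1e-9 relative tolerance, which absorbs float noise against the
  exact-integer definition.
- Genotype readers fold any column whose coded-allele frequency exceeds
  0.5 to the data-determined minor allele, making one read a normalization
  pass and subsequent write/read cycles byte-stable.
- Problem sizes in the test suite (e.g. 100 stepwise-recovery replicates
  at n = 500, 200 screen replicates, 2000 null replicates, exhaustive
  oracle sweeps to 200 alleles and 6-element p-lists) were chosen to give
  tight binomial/KS resolution while keeping the full suite around a
  minute of CPU.

## Known limitations

- The VCF subset is deliberately minimal: biallelic GT (+ optional GQ)
  only; phased separators are treated as unphased, and multi-allelic
  records are not supported.
- The pedigree model is trio links in the phenotype table; general
  pedigree likelihood checks are out of scope.
- Gender-stratified screens are supported only by subsetting samples
  upstream; no stratified inference procedure is defined.
- The tiled procedure's p-values are selection-conditioned (as in any
  stepwise method) and should be read as descriptive of the selected
  model, not as marginal tests.
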
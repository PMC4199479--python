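# nf1mod

Candidate-gene modifier analysis for quantitative phenotypes in
neurofibromatosis type 1 (NF1), built as a tested, reusable pipeline.

NF1 is a monogenic disorder with highly variable expressivity: individuals
carrying the same *NF1* mutation can differ widely in features such as the
number of café-au-lait macules (CALMs). One route to finding modifier genes
is "genetical genomics": screen transcript abundance (here, from
lymphoblastoid cell lines) for association with quantitative phenotype
severity, sequence the best candidate genes, and test their variants for
association with the trait across a discovery cohort and independent
replication cohorts.

`nf1mod` implements each stage of that design against plain-text inputs
(phenotype TSV, genotype TSV or minimal VCF, hotspot BED, expression TSV):

- **Expression screen** — per-transcript OLS of the trait on log2
  expression, Benjamini–Hochberg FDR (threshold 0.3), mean-level (≥ 6) and
  expression-range (≥ 2) filters with a biological rescue list, and
  qPCR-style verification (ΔΔCt, nominal p < 0.05).
- **Variant QC** — per-call quality masking (score < 99 → missing), sample
  (> 30%) and variant (> 20%) missingness filters, monomorphic drop, exact
  Hardy–Weinberg test on the unrelated subset (p < 0.03 flagged, never
  removed), and a trio Mendelian-consistency check.
- **Genotype coding** — additive (minor-allele count), dominant
  (carrier indicator), and additive-with-collapsing, where rare variants
  (MAF < 0.05) in each recombination-hotspot-delimited tile are summarized
  as the proportion of rare sites at which a sample carries a minor allele.
- **Tiled regression** — after pre-adjusting the trait for age and sex,
  each tile is screened (overall F-test at 0.2, or any single variant at
  0.05); retained tiles undergo forward stepwise selection with backward
  elimination (entry/stay α = 0.05), and survivors are re-selected at
  chromosome and genome level, yielding a joint model of independent
  variants.
- **Single-variant association, meta- and mega-analysis** — per-cohort OLS
  of the (optionally log10(x+10)-transformed) CALM count on
  intercept + age + sex + genotype; cohort p-values combined by Liptak's
  method, `Z = Σ √n_i z_i / √Σ n_i` with `z_i = Φ⁻¹(1 − p_i)`; and a pooled
  mega-analysis with cohort indicator covariates.
- **Synthetic data** — a seedable generator that emulates the study design
  (cohorts of 89/29/62 with realistic age/sex structure, 118 SNVs in five
  hotspot tiles including a correlated common pair targeted at dosage
  ρ = 0.9 via a calibrated Gaussian copula, a count trait with planted
  additive/dominant effects, and an expression matrix with a planted
  trait-tracking minority), so every stage is testable without any
  external download.

## Worked example

```bash
nf1mod simulate --seed 5 --out-dir sim
nf1mod qc --geno sim/genotypes.tsv --pheno sim/phenotype.tsv --out-dir qc
# -> retained 180 samples x 116 variants -> qc
nf1mod screen --expr sim/expression.tsv --pheno sim/phenotype.tsv --out screen.tsv
# -> 1000 transcripts screened, 28 candidates -> screen.tsv
nf1mod tiled --geno qc/genotypes_qc.tsv --pheno sim/phenotype.tsv \
             --tiles sim/hotspots.bed --transform unt --out tiled.tsv
nf1mod mega --geno qc/genotypes_qc.tsv --pheno sim/phenotype.tsv \
            --transform unt --model add --out mega.tsv
```

The simulated study plants an additive effect of −5 CALMs per minor allele
on variant `v001` (one member of the correlated common pair) and 20
trait-tracking transcripts among 1000. In the run above the QC stage
dropped two monomorphic variants; the 28 screen candidates contain all 20
planted transcripts; and the pooled mega-analysis recovers the planted
variant and its correlated twin as the leading common-variant signals:

```
target_id  model         beta      se        p         n
v001       unt_add_mega  -3.65352  1.23765   0.003618  171
v000       unt_add_mega  -3.19623  1.15407   0.006241  175
```

`v000` — the correlated, non-causal twin — tags the same signal, exactly
the behavior the tiled stepwise stage is designed to disentangle: in
`tiled.tsv` only one member of the pair (`v001`, beta −3.88, p 0.0016)
survives the joint model.

The same stages are available as a library (`nf1mod.simulate_study`,
`nf1mod.GenotypeQC`, `nf1mod.TranscriptScreen`, `nf1mod.TiledRegression`,
`nf1mod.liptak_meta`, `nf1mod.mega_analysis`), written as
scikit-learn-style estimators with `fit`/`transform` and fitted attributes.

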
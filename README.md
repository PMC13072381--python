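# specklemap

Tools for dissecting the genetic architecture of a count-valued pigmentation
trait — the number of dark pronotum speckles segregating in laboratory
crosses of the red palm weevil (*Rhynchophorus ferrugineus*) — and for the
population-scale follow-up on a resequenced SNP panel.  The package is aimed
at quantitative and population geneticists who want the whole chain, from
cross phenotypes to candidate genes, as one scriptable, testable pipeline.

## What it computes

**Segregation analysis.**  F2 speckle counts are modelled as a finite normal
mixture whose mixing proportions are fixed Mendelian F2 ratios and whose
component means are linear functions of major-gene effects: for one major
gene the classes AA : Aa : aa arrive as (¼, ½, ¼) with means m+d, m+h, m−d;
for two independent major genes the nine two-locus classes have weights
(1,2,1,2,4,2,1,2,1)/16 and means m + x_a d_a + z_a h_a + x_b d_b + z_b h_b.
Named constraint patterns (equal additive effects, complete dominance, …)
define a model catalog; each model is fitted by an EM algorithm with fixed
weights and linearly constrained means, ranked by AIC = −2 lnL + 2k, and
checked with PIT-uniformity diagnostics (U₁², U₂², U₃², Cramér–von Mises
nW², Kolmogorov Dₙ).  Major-gene heritability is the between-component
variance of the fitted mixture over the phenotypic variance.

**Population genetics.**  SNP filtering (MAF < 0.05 or missingness > 0.5
removed), the VanRaden genomic relationship matrix
K = ZZᵀ / (2Σpⱼ(1−pⱼ)), block-relaxation admixture inference with the
number of ancestral clusters K chosen by cross-validation error,
p-distance neighbor joining, and composite LD r² decay with a
stable-distance readout.

**Association.**  Four scans per panel: `glm` (per-locus OLS), `glmq`
(+ ancestry covariates Q), `mlmk` (mixed model y = Xβ + gβ_snp + u + ε,
Var(u) = σ_g²K, exact per-marker REML via one spectral decomposition of K),
and `mlmkq` (both).  Diagnostics: QQ plots and genomic inflation λ; the
significant sets of the four models are intersected into a Venn/joint-
detection table.

**Integration and expression.**  Marker-scan QTL support intervals
(Q-\<prefix\>-\<chrom\>-\<serial\> naming), QTN-in-QTL overlap, ±250 kb
candidate-gene windows against a GFF3 gene set, variant functional
annotation (exon / splice-site / intron / upstream / downstream /
intergenic; synonymous / nonsynonymous / stop-gain / stop-loss /
frameshift), and qPCR relative expression by 2^−ΔΔCt with one-way ANOVA +
Tukey compact-letter display.

A synthetic-data module generates every input the pipeline needs (F2
phenotype samples under any catalog model, structured SNP panels with
Balding–Nichols differentiation and chain LD, triplicate Ct tables), so all
stages run and are tested without external data.

## Worked example

```python
from specklemap import synthgen as gen
from specklemap import segregation as seg

pheno = gen.simulate_f2_phenotypes(
    gen.F2SimSpec("2MG-EAD", m=10, effects={"d": 4}, sigma_e2=1.5, n=400, seed=7)
)
fits = seg.fit_catalog(pheno, n_restarts=5, seed=0)
for fit in seg.select_top_models(fits, 3):
    dec = seg.decompose_variance(fit, pheno)
    print(f"{fit.code:10s} lnL={fit.lnL:9.2f} AIC={fit.aic:9.2f} "
          f"h2_mg={dec.h2_mg_pct:5.1f}%")
```

prints

```
2MG-EAD    lnL=  -979.40 AIC=  1964.79 h2_mg= 96.7%
2MG-CD     lnL=  -979.39 AIC=  1966.78 h2_mg= 96.8%
MX2-AD-AD  lnL=  -978.98 AIC=  1969.95 h2_mg= 97.9%
```

i.e. the generating two-major-gene equal additive-dominance model wins on
AIC, its nesting relaxations almost tie in likelihood but pay for their
extra parameters, and ~97 % of the phenotypic variance is attributed to
the two major genes (the truth here: between-class variance 1.5·d² = 24
against σ² = 1.5 plus rounding noise).

The same stages are available from the shell:

```
specklemap simulate panel --out work --seed 1
specklemap popgen structure --vcf work/panel.vcf --kmin 2 --kmax 5 --out work/Q.tsv
specklemap assoc scan --vcf work/panel.vcf --pheno work/panel_pheno.tsv \
    --model mlmk --k work/kinship.tsv --out work/scan.tsv
specklemap pipeline run --config cfg.yaml
```

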
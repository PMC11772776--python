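# argos

Dosage-compensation and overexpression-toxicity analysis for amplified
genes in cancer.

Large copy-number gains drag dozens of bystander genes along with the
driver. Most of those genes are simply expressed in proportion to their
DNA dosage — but some are consistently expressed *below* expectation,
a signature of negative selection against their overexpression. `argos`
identifies these **ARGOS** genes (Amplification-Related Gain Of
Sensitivity): genes that are *compensated* when amplified and *toxic*
when overexpressed, a candidate class of collateral vulnerabilities.
It is written for computational cancer biologists working with bulk
RNA-seq count matrices, gene-level copy-number calls and pooled ORF
overexpression screens.

## The model

Copy number is encoded on the linear scale as euploid equivalents
`c = 2^log2ratio` and euploid deviation `d = c − 1`. Per gene, raw counts
`r` over copy-neutral (`|c − 1| ≤ 0.15`) and amplified (`c ≥ 1.85`)
samples follow a Bayesian Negative Binomial regression with identity
link:

    cell lines:  μ = Σ_t β₁ᵗ c + β₂ d,             r ~ NB(s·m·μ, σ)
    tumors:      μ = Σ_t β₁ᵗ c·p + β₂ d·p + Σ_t β₃ᵗ (1−p)

with library size factor `s` (median-of-ratios), gene mean `m`, tissue-
specific scaling `β₁ᵗ`, shared deviation `β₂`, purity `p` and a
non-cancer compartment `β₃ᵗ`. Priors: `β₁, β₃ ~ logN(0,1)`,
`β₂ ~ N(0, 0.5)` (cell lines) or `N(0, 0.2)` (tumors). The deviation is
normalized and shrunk by its posterior z-score into the compensation
score

    s = (1 − pseudo-p) · β₂* ,   β₂* = β₂ / mean_t(β₁ᵗ)

where −1 means a gain leaves expression unchanged, 0 pure dosage
scaling, +1 twice the per-copy increment. Genes scoring < −0.3 in both
of two cohorts are *compensated*; > +0.3 in both, *hyperactivated*.
Toxicity pools ORF-screen barcode log2 fold changes as independent
observations of an intercept-only linear model; a gene is *toxic* at
≥ 30% growth decrease (mean lfc ≤ log2 0.7) with P < 1e-5. ARGOS =
compensated AND toxic. Protein complexes are prioritized by one-sided
Fisher enrichment of compensated members (BH-adjusted) and the Wald
statistic of member ORF dropout.

Posterior inference runs on a seeded ensemble MCMC sampler with
differential-evolution moves and split-R-hat convergence checks; a fast
Laplace backend is available. See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

`examples/02_compensation_scores.py` simulates a 50-gene cell-line
cohort with three planted genes among null background genes and fits
them:

```
                 score  beta2_mean        z  pseudo_p  n_amplified  converged
gene
compensated    -1.0353     -1.0428 -15.4988    0.0000           50       True
scaling        -0.0041     -0.0181  -0.2336    0.8153           50       True
hyperactivated  0.9388      0.6318   6.9040    0.0000           50       True
```

The fully compensated gene (expression unchanged by the gain) recovers a
score near −1; the pure-dosage gene sits at 0 with pseudo-p ≈ 0.82
shrinking it further; the fully hyperactivated gene recovers ≈ +1.
`examples/04_argos_pipeline.py` runs the whole pipeline on a written
fixture set and ends with:

```
            compensated  toxic  argos  score_a  toxicity_lfc
gene
argos_gene         True   True   True   -0.960        -1.026
comp_only          True  False  False   -0.814         0.025
toxic_only        False   True  False    0.000        -0.981
null00            False  False  False    0.083        -0.006
```

Only the gene that is both compensated and depleted in the screens is
called ARGOS.

## Command line

```sh
argos simulate  --config sim.yaml --out fixtures/
argos compensate --counts counts.tsv --copy-number cn.tsv --meta meta.tsv \
                 --cohort cellline --out compensation.tsv
argos orf       --screens orf.tsv --out toxicity.tsv
argos integrate --compensation ccle.tsv tcga.tsv --toxicity toxicity.tsv \
                --complexes corum.tsv --out results/
argos run-all   --config pipeline.yaml
```

Counts are TSV or GCT 1.2; copy-number tables are gene-level log2-ratio
TSVs ("byGene" style, annotation columns tolerated); ORF tables carry
either precomputed `lfc` or `early_count`/`late_count` columns.

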
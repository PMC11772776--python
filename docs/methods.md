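# Methods

## The problem

Most copy-number gains in cancer genomes are large events that drag along
dozens of "bystander" genes. For most genes mRNA scales with DNA dosage, but
a minority are expressed consistently *below* the dosage expectation
(compensated) — a pattern expected when overexpression of the gene is
deleterious and negative selection suppresses it. This package quantifies
that pattern per gene, quantifies overexpression toxicity from pooled ORF
screens, and intersects the two into ARGOS calls (Amplification-Related Gain
Of Sensitivity): genes compensated when amplified *and* toxic when
overexpressed.

## Compensation model

Copy number enters on the linear scale, re-parameterized as euploid
equivalents `c = 2^log2ratio` and euploid deviation `d = c − 1`
(`c − d = 1` identically; `d = −1` means no DNA copies, `d = +1` one extra
copy set). For a gene with raw counts `r` over retained samples:

cell lines:

    mu = Σ_t β1_t · c  +  β2 · d
    r ~ NB(s · m · mu, σ)          with Var = μ + μ²/σ  (shape convention)

tumors, with purity `p` and a non-cancer expression compartment:

    mu = Σ_t β1_t · c · p  +  β2 · d · p  +  Σ_t β3_t · (1 − p)

`s` is the per-sample library size factor (median-of-ratios on raw counts,
geometric mean 1), `m` the mean normalized expression of the gene over
retained samples — together they make the coefficients comparable across
genes and libraries. `β1_t` is a per-tissue dosage-scaling term, `β2` the
shared deviation-from-scaling term, `β3_t` the per-tissue non-cancer
contribution. The two formulas coincide at `p = 1`, which is checked
numerically in the tests. Priors: `β1, β3 ~ logNormal(0, 1)`;
`β2 ~ Normal(0, 0.5)` for cell lines and `Normal(0, 0.2)` for tumors (the
tighter tumor prior counteracts purity-driven inflation of deviation
estimates); shape `σ ~ Gamma(0.01, 0.01)`, weakly informative. The identity
link can produce negative means, so any parameter draw implying `mu ≤ 0` on
a retained sample is rejected (log-posterior −inf). The residual term of the
mean model has no separate distribution; it is absorbed by the NB
observation noise.

### Sample inclusion and eligibility

Per gene, retained samples are copy-neutral (`|c − 1| ≤ 0.15`) or amplified
by at least one copy (`c ≥ 1.85`); everything in between, deletions and
missing entries are excluded. The 15% tolerance is interpreted as an
absolute band on the linear copy scale (the tolerance is stated next to
linear-scale copy values; relative vs absolute is otherwise ambiguous, and
the band is configurable). A gene is fit only with ≥ 3 (cell lines) or
≥ 5 (tumors) amplified samples.

### Score

    β2* = posterior-mean(β2) / mean_t posterior-mean(β1_t)
    z   = posterior-mean(β2) / posterior-sd(β2)
    pseudo-p = two-sided standard-normal tail of |z|
    score = (1 − pseudo-p) · β2*

The normalizer is the unweighted mean over fitted tissues (a sample-size
weighted variant is exposed as an option; the notation is ambiguous on this
point). The pseudo-p is two-sided — the simplest reading of a z-score
against the origin; shrinkage therefore never changes the sign and never
increases the magnitude of `β2*`, and is monotone in `|z|` (property-tested).
Score semantics: −1 means a gain leaves expression unchanged, 0 pure dosage
scaling, +1 twice the per-copy increment.

A gene is *compensated* iff its score is strictly below −0.3 in **both**
cohorts analysed (e.g. a cell-line and a tumor cohort), *hyperactivated* iff
strictly above +0.3 in both. "Strictly" follows the literal reading of the
boundary wording; the thresholds are configurable. A gene is *commonly
amplified* when gained in strictly more than 15% of cohort samples (in-house
gain call `c ≥ 1.85`, overridable by an external GISTIC-style call table).

## Posterior inference

No Stan-style front-end is used; the backend contract is anything that
returns posterior means/sds per coefficient plus a convergence diagnostic.

* **mcmc (default)** — affine-invariant ensemble sampling (`emcee`) with
  differential-evolution moves (80% `DEMove`, 20% `DESnookerMove`), which
  decorrelate roughly 3× faster than the stretch move on these near-Gaussian
  per-gene posteriors (τ ≈ 10 vs ≈ 30 steps). Walkers: `max(2·ndim + 2, 8)`.
  The configuration is expressed as chains × draws (default 4 × 1000 kept
  draws, 500 warmup) and mapped to walker steps so that the total kept draw
  count matches. Walkers start at the posterior mode (Nelder–Mead then BFGS
  polish) with small jitter. Convergence: split R-hat across walker chains,
  flagged above 1.1 (the classic Gelman–Rubin rule of thumb; at these chain
  lengths a 1.05 cut would mostly flag R-hat estimation noise). ESS is
  `N/τ` with τ from the sampler's autocorrelation estimate. Non-converged
  fits are reported but excluded from classification.
* **laplace** — MAP plus Gaussian curvature (finite-difference Hessian),
  sampled and transformed exactly like MCMC draws. Accurate here because
  the per-gene posteriors are near-Gaussian at the sample sizes the
  eligibility rule implies; useful for large cohorts and quick scans.

Sampling in log space for `β1`, `β3`, `σ` makes the log-normal priors
Gaussian and keeps the positivity constraints implicit.

## Toxicity model

Barcode log2 fold changes (late vs early time point) are the growth proxy.
From counts: `lfc = log2((late + 0.5)/N_late) − log2((early + 0.5)/N_early)`
with per-screen total reads `N` and a documented, configurable pseudocount
of 0.5 (standard for screen counts; disabled pseudocount drops barcodes
absent early). Precomputed lfc input bypasses this. Every barcode
measurement of a gene in any screen in scope is an independent observation
of an intercept-only linear model — identical to the one-sample t-test,
which serves as the independent oracle in the tests. No per-screen
recentering is applied by default (an optional median-centering flag
exists). A gene is *toxic* iff the pooled estimate is ≤ log2(0.7) ≈ −0.515
(at least a 30% growth decrease) **and** the two-sided p is < 1e-5. The
effect bound is inclusive, the significance bound strict; with fewer than
two observations or zero variance the p-value is undefined and the gene is
never called toxic.

## Integration

`argos = compensated AND toxic`; frequent amplification is annotated but not
required (amplified and non-amplified ARGOS genes are reported separately).
Gene universes are harmonized by identifier intersection with logged
attrition. Complex prioritization: one-sided (enrichment) Fisher's exact
test of compensated genes among complex members over the tested universe,
Benjamini–Hochberg adjusted (the FDR method is not otherwise pinned down;
BH is the default choice), plus the Wald statistic of the indicator linear
model on members' ORF dropout (negative = members drop out more). Ranking:
`fdr_q` ascending, ties broken by more negative toxicity Wald.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
ground truth retained for recovery testing:

| parameter | default | rationale |
|---|---|---|
| samples per tissue | 200 | enough amplified samples for stable per-gene fits at desk scale |
| base mean (tests) | 100–2000 | moderately-to-well expressed genes, where dosage analysis is meaningful |
| NB shape | 10 | gene-level overdispersion ~0.1, typical of bulk RNA-seq |
| amp_fraction | 0.25 | a commonly amplified locus; 50 amplified samples at n = 200 |
| amp_copies | 2.0 | one extra copy set, the canonical single gain |
| purity | Beta(6, 3) | mean ≈ 0.67 with realistic spread for bulk tumors |
| library factors | logN(0, 0.3) | ~±35% library-size variation |
| screens × barcodes | 3 × 2 | a desk-scale stand-in for a multi-screen compendium |
| lfc_noise_sd | 0.05 | see below |

Amplified samples are the first `floor(amp_fraction · n)` per tissue after a
seeded shuffle, so fixtures are bit-stable. The non-cancer compartment is a
per-gene constant (mirroring the single `β3_t` per tissue), defaulting to
the euploid base mean. Counts are NB draws around the exact mixture mean
`L · (p · cancer + (1 − p) · normal)` — no extra noise before the NB draw,
which the mean-function tests rely on.

`lfc_noise_sd = 0.05`: with 3 screens × 2 barcodes there are 6 observations
per gene (df = 5), and P < 1e-5 requires |t| > 17.9, i.e. a sample sd below
0.137 for a unit-LFC gene. Because the sd estimate itself is noisy at df = 5,
a barcode noise of 0.1 would miss ~10% of truly toxic genes on estimation
noise alone; 0.05 lets the 6-observation design carry the significance rule
the way a 17-screen compendium would. Real pooled screens are noisier per
barcode but have many more observations per gene.

Not emulated: focal vs arm-level event geometry, deletions, whole-genome
doubling, allele-specific copy number, batch or GC effects, read-level data.
Passing recovery tests therefore demonstrates correctness of the estimator
under the model's own assumptions, not robustness to real-data artifacts.

## Numerical and interface choices

* NB log-likelihood is computed directly via `gammaln` (batched across MCMC
  walkers); `scipy.stats.nbinom.logpmf` summation is the test oracle.
* Degenerate zero-residual-variance linear models report an undefined (NaN)
  p-value rather than an arbitrarily significant one.
* TSV dialect: tab-separated UTF-8, "." decimals, mandatory header; counts
  also readable as GCT 1.2; copy-number tables may carry leading annotation
  columns (kept as metadata). `-inf` log2 ratio is the zero-copy sentinel;
  NaN cells are flagged missing and excluded. Gene identifiers are matched
  as opaque strings.
* Missing purity defaults to 1 with a prominent warning (the tumor model
  reduces to the cell-line model there).
* A pipeline configured with a single cohort applies the dual-cohort score
  thresholds to that cohort alone and marks the run `single-cohort` in the
  manifest; with two cohorts the standard both-cohorts rule applies.
* Reruns with identical config and seed are byte-identical.

## Problem sizes used in the shipped tests

Recovery tests use 10 replicate genes per condition at n = 200 with ~40
null background genes anchoring size-factor estimation (median-of-ratios
needs a mostly-unperturbed gene population). The end-to-end study plants
10 ARGOS, 40 compensated-only, 40 toxic-only and 400 null genes across two
200-sample cohorts and 3 screens, fit at 750 kept draws per chain — chosen
as the package's own desk-scale benchmark where the planted/decoy structure
stresses both false negatives and false positives.

## Known limitations

* The tumor prior `β2 ~ N(0, 0.2)` shrinks large deviations noticeably at
  moderate sample sizes (a true +1 hyperactivation recovers ≈ +0.6 at
  n = 200); compensated calls at the −0.3 boundary are robust to this, but
  tumor-cohort scores are conservative in magnitude by construction.
* Tissue-specific mode simply restricts samples to one tissue; it does not
  pool information across tissues.
* In pan-cancer mode the deviation `β2` is shared across tissues while the
  scaling `β1_t` is not. When a gene's baseline expression differs strongly
  between tissues, the per-tissue deviations a compensated gene implies
  differ too, and the single `β2` lands at their precision-weighted average:
  the pan-cancer score magnitude is attenuated (e.g. ≈ −0.75 for a fully
  compensated gene with a 3× base-mean spread over two tissues). The
  tissue-specific mode recovers the full per-tissue score. This is a
  property of the shared-deviation model itself, not of the sampler.
* Eligibility and frequency calls use the in-house gain rule unless external
  (e.g. GISTIC) calls are supplied; segment-level calling is out of scope.
* One gene is fit at a time; there is no hierarchical sharing across genes.
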
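# Methods

`aeimix` detects allelic RNA expression imbalance (AEI) at heterozygous
SNPs from bulk RNA-seq allele counts. This note describes the statistical
model, the pipeline's stages and knobs, the synthetic-data generator used
for validation, and the numerical and design choices the implementation
makes.

## Model

At a heterozygous SNP the reference and variant read counts `(R, V)` are a
relabelling of the latent parental counts `(P, M)`. We model

    P = Y1 + Z,    M = Y2 + Z,

with `Y1 ~ Poisson(λ_p)`, `Y2 ~ Poisson(λ_m)` independent, and `Z` a shared
non-negative component of arbitrary distribution that carries everything
the two alleles have in common (transcriptional bursting, sample depth,
gene expression level). The difference

    Y = P − M = Y1 − Y2 ~ Skellam(λ_p, λ_m)

is free of `Z`, and since `|R − V| = |P − M|`, the absolute allelic
difference follows a *folded* Skellam distribution regardless of the
allele-to-reference assignment. AEI at a SNP means `λ_p ≠ λ_m`; under the
null of balanced expression `λ_p = λ_m = λ`, and `E(R−V)² = 2λ` gives a
method-of-moments estimate of the common rate.

Counts of very different magnitude cannot share one Skellam law, so SNPs
are first grouped into "comparable" coverage classes: per
(subject, tissue, gene) unit the mean adjusted read sum is computed, a
finite Poisson mixture is fitted to these unit averages by EM, and BIC
(−2·logL + p·ln n, with 2K−1 free parameters) picks the number of classes.
Within each class, and separately per genic region (3'UTR, 5'UTR, exon,
intron — regions differ systematically in expression), the absolute
adjusted differences are modelled as a K-component folded Skellam mixture

    p(y) = Σ_i π_i · FoldedSkellam(y; λ_i1, λ_i2),

again with BIC selection (3K−1 parameters). Each component is screened for
imbalance with a likelihood-ratio test: `L0` is the folded-Skellam
log-likelihood of the component's (argmax-assigned) SNPs at the MoM
equal-rates estimate, `L1` the log-likelihood at the component's fitted
rate pair, and `max(0, 2(L1−L0))` is referred to χ²₁. A significant
component is designated a signal component only if it also passes a
minimum-effect-size gate: its rate gap must exceed one standard deviation
of its own count difference, `|λ1−λ2| > √(λ1+λ2)` (`min_effect_sd`,
settable to 0 for the pure-LRT rule). The gate is needed because of the
ridge identifiability discussed below: in overlapping strata the
maximum-likelihood decomposition can hand the balanced bulk component a
small spurious gap (empirically bounded by about one sd), and the LRT —
evaluated on the component's truncated hard-assigned subset — then
rejects, which would flag an entire balanced stratum. Genuine imbalance
components sit several sd from parity (1.6–10 sd across every validation
scenario), so the gate costs no measured power. Components too small
to test inherit the signal label when their rate gap `|λ1−λ2|` exceeds the
smallest gap among designated components — they sit even further from
parity than a component already shown to be imbalanced.

Per SNP, the posterior over mixture components yields an aggregated signal
probability (mass on signal components). The default designation rule
calls a SNP `AEI` when its argmax component is a signal component
(`uncertain` when it is not but the aggregated probability still exceeds
α); a threshold rule (e.g. ≥ 0.80 or ≥ 0.99 aggregated probability) gives
higher-confidence tiers, and both tier flags are reported per call.

### Identifiability of the fold

Folding destroys the sign, so a component's rate pair is identifiable only
as an unordered pair; components store the larger rate first and which
allele is higher must be read off the sign of the raw difference (reported
per SNP), never from the fold. Near-symmetric components have a second,
softer degeneracy: the likelihood trades the rate gap against the total
rate along a curved ridge (a folded Skellam with a slightly larger gap and
smaller total looks almost identical). Consequences observed in
validation:

- refitting a many-component mixture on data simulated from it recovers
  well-separated components' rates well, but components that overlap near
  zero can be recombined by the maximum-likelihood solution into a
  different, equally likely decomposition — rates of such components are
  not individually trustworthy even when the fitted density is excellent;
- point estimates of near-equal rate pairs differ legitimately between
  estimation backends (EM maximum likelihood vs ABC posterior mean) by
  tens of percent while agreeing in distribution.

Signal designation is robust to both effects because it depends on the
fitted density, the posterior masses, and the LRT — not on which point of
the ridge a component's pair lands on.

## Pipeline stages and parameters

1. **Filter** (raw counts): keep `min(R, V) ≥ 3` (`min_low_allele`),
   drop intergenic SNPs (`exclude_regions`). The low-allele floor removes
   genotyping artefacts and counts too small to carry evidence.
2. **Library-size adjustment**: multiply each sample's pairs by
   median(total)/total(sample). Ratio-preserving by construction. The
   sample total defaults to the sum of R+V over the sample's retained SNPs
   and can be overridden with true library sizes (`library_totals`).
   The absolute adjusted difference is rounded half-away-from-zero to the
   integer support of the folded likelihood; the signed real difference is
   kept alongside.
3. **Coverage grouping**: unit averages (step above), trimming of the
   top `trim_fraction = 0.001` units (extreme-coverage genes distort the
   mixture), Poisson-mixture EM with BIC over `poisson_k_range = 1..10`,
   unit classification by posterior argmax. Unit averages are rounded
   half-up at fit time (the Poisson pmf needs integers; the averages are
   real).
4. **Per-stratum folded fits**: strata = coverage class × region;
   strata under `min_stratum_size = 50` SNPs are reported `unclassified`
   (mixture fits on tiny strata are meaningless). BIC over
   `skellam_k_range = 1..8`.
5. **Testing and designation**: per-component LRT (`min_test_n = 10`
   assigned SNPs to test, matching the practice of not testing 2–5-SNP
   components); designation at `alpha = 0.05` after Bonferroni correction
   across all component tests in the run (`multiple_testing =
   "bonferroni"`; `"raw"` reproduces single-stratum analyses — with one
   stratum and p-values far below α the two coincide). The pipeline tests
   one or more components in every stratum, so an uncorrected 5% level
   would flag a few percent of null strata wholesale; family-wise control
   is the appropriate default for a genome-wide screen.
6. **Reports**: cross-tissue consistency (a subject's SNP expressed in ≥ 2
   tissues is *consistent* when designated AEI in at least half of them)
   and read-ratio percentile tables per designation group (deciles by
   linear interpolation between order statistics, on raw counts — ratios
   are scale-invariant).

All randomness (EM restarts, ABC chains) descends from the single config
seed through a `SeedSequence` tree; identical config + input give
byte-identical outputs.

## Fitting backends

**EM (default).** Exact folded-Skellam pmf via the exponentially scaled
Bessel function (`log I_v` evaluated in log space; rates of several
hundred neither overflow nor lose the tail — where the scaled Bessel
underflows, the leading small-argument series term takes over). E-step
responsibilities are exact; the M-step maximises each component's weighted
log-likelihood over (log λ1, log λ2) by Nelder–Mead warm-started at the
current values and never accepts a worse point, so the observed-data
log-likelihood is monotone (generalized EM). Convergence: relative
improvement below 1e-7 or 300 iterations. Multi-start strategy: a
deterministic quantile-block start (block mean → gap; mean square minus
gap² → total rate, since `E y² = (λ1+λ2) + (λ1−λ2)²`), a jittered variant,
and random starts seeding gaps from random data points; each runs 40
iterations and the best continues to convergence. Rates are floored at
1e-6; degenerate (zero-rate) cases use the Poisson limit of the Skellam
pmf.

**Likelihood-free MCMC (ABC).** The backend the method was originally
fitted with, provided both as an alternative and as a cross-check of the
EM fit. Summaries: deciles, 95th/99th percentiles, low-count mass
(P(y=0), P(y≤2), P(y≤5)), mean, standard deviation; distance is RMS of
summary differences scaled by the observed summary magnitudes. Priors:
rates uniform on (0, 2·max(y)+5), weights via uniform stick-breaking;
proposals are Gaussian random walks in (log-rate, logit-stick) coordinates
with the Jacobian correction in the Metropolis ratio. The burn-in
tolerance tracks the chain's achieved distance (so an aggressive fixed
schedule cannot deadlock the chain); the sampling-phase tolerance is the
median re-simulated distance over the late burn-in — re-simulated, because
accepted distances are selection-biased low. Point estimates are
posterior means of the canonicalized parameters; acceptance rates and the
distance trace are reported as diagnostics.

## LRT calibration

Because the equal-rates null sits on the boundary of the folded
parameterization (gap ≥ 0), the LRT statistic's null law is approximately
`0.5·δ₀ + 0.5·χ²₁`, making the χ²₁ reference conservative: the measured
type-I error at nominal α = 0.05 is ≈ 0.022 (1000 replicates of n = 5000,
λ = 66). Power is high where it matters: against a (93, 166) component at
n = 400 the measured rejection rate is 1.0. The conservatism is accepted
rather than corrected (e.g. by halving the reference) to keep the screen's
false positives low and the published testing procedure intact.

## Synthetic-data generator

`SimConfig`/`simulate_dataset` emulate the structure of a multi-tissue
brain RNA-seq allele-count table:

- **Coverage classes**: genes draw a total-coverage rate from a weighted
  mixture, default `(0.77, 8), (0.19, 20), (0.03, 43), (0.01, 110)` —
  magnitudes mirroring the heavy-low-coverage profile of autopsy brain
  data (≈95% of pairs under 33 reads).
- **Sparsity**: SNPs per gene are geometric (p = 0.315, capped at 12), so
  ≈78% of genes carry ≤ 4 SNPs; heterozygosity per (subject, SNP) is
  Bernoulli(0.5) and expression per (sample, gene) Bernoulli(0.2), giving
  few observations per gene — exactly the regime the coverage-grouping
  step exists for.
- **Shared component**: `z_fraction` (default 0.1) of each allele's
  expected coverage comes from the shared `Z` (Poisson by default;
  gamma-mixed Poisson gives an over-dispersed option; `none` disables it).
  The default is deliberately modest: in real data the high overall
  correlation between allele counts (~0.9) is dominated by the
  orders-of-magnitude spread of coverage *across* SNPs, which the coverage
  classes already produce; `Z` adds within-SNP correlation on top. Setting
  `z_fraction` near 1 reproduces the strongly correlated regime.
- **Imbalance**: a fraction of genes (default 0.15) get `λ_p = ρ·λ_m`
  (default ρ = 3) consistently across their SNPs and tissues, raising the
  gene's total expression — imbalance is modelled as one allele gaining
  expression, not as redistribution at fixed total.
- **Fold symmetry**: which parental allele carries the reference base is
  Bernoulli(0.5) per (subject, SNP) (phase varies by subject), with an
  optional bias parameter for stress-testing; library depth multipliers
  are log-normal (σ = 0.25) per sample and the pipeline's adjustment
  approximately inverts them.

What the generator does **not** emulate: read-level artefacts
(mapping/reference bias beyond the optional assignment bias), isoform
structure within regions, genuinely over-dispersed allele-specific noise
beyond the `Z` options, linkage between SNPs of a gene beyond sharing the
gene's rates, and missingness mechanisms correlated with imbalance.
Passing the end-to-end checks therefore demonstrates that the pipeline
recovers the signal structure it models, under its own assumptions — not
that those assumptions hold for any particular real dataset.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` run everything at desk
scale on one CPU: the published-scale mixtures are refitted at their
original sample sizes (62326 unit averages; 10702 absolute differences);
LRT calibration uses 200 replicates (n = 5000 null, n = 400 alternative);
backend agreement uses n = 2000; the end-to-end null experiment uses 10
replicate datasets of ≈2000 retained SNPs and the power experiment one
dataset of ≈5000 SNPs (two coverage classes around 40×, 20% imbalanced
genes at ρ = 3).

## Known limitations

- Rate pairs of near-symmetric components are set-identified (ridge), as
  discussed above; report-level quantities (designations, posteriors,
  gaps) are the stable outputs.
- The LRT evaluates `L1` at the rates from the overall mixture fit (the
  published procedure) rather than refitting on the assigned subset; the
  χ²₁ reference is then approximate (and measured conservative).
- The coverage mixture treats unit averages as Poisson, which ignores
  within-unit averaging effects; it is a grouping device, not a generative
  claim, and downstream results are insensitive to the exact number of
  classes.
- ABC estimates are noisy for weights below a few percent; the EM backend
  is the default for a reason.
- Single-cell data (UMI counts, extreme sparsity) are out of scope of the
  defaults, though nothing in the machinery precludes refitting with
  adapted coverage classes.
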
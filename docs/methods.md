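# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the limits of what the test suite demonstrates.

## Sex classifier

The classifier is a densely connected feed-forward network predicting
P(male) from a standardized expression profile. "Densely connected" means
DenseNet-style concatenation: hidden layer ℓ receives `[x, h₁, …, h₋₁]`,
and the sigmoid output unit receives the full concatenation. With
`total_layers = L` there are L−1 hidden layers of `hidden_width` units and
one output unit; the default is L = 11.

Choices the architecture leaves open, fixed as defaults and configurable:

| parameter | default | rationale |
|---|---|---|
| hidden width | 64 (16 in the pipeline defaults) | expression signal is low-rank; narrow layers train fast and the dense concatenation preserves capacity |
| activation | ReLU (He init; tanh available) | standard for depth-11 nets |
| loss / output | binary cross-entropy / sigmoid | binary sex label, female = 0, male = 1 |
| optimizer | Adam, lr 1e-3, batch 32 | robust default for small tabular nets |
| epochs | 200 | one validation metric recorded per epoch |
| best-model rule | validation accuracy, argmax, earliest tie (AUC by flag) | the restored parameters are the best epoch's, not the last |

The implementation is numpy with hand-written backpropagation. That is a
deliberate feature, not a shortcut: attribution needs ∂P(male)/∂x, and the
same backward pass that yields parameter gradients yields exact analytic
input gradients (`output_and_input_grad`). The gradient is property-tested
against central finite differences at 1e-4 relative tolerance.

Scaling statistics (per-gene mean/sd) are fit on the training samples only
and applied to validation, avoiding leakage; a scale-all-first variant
exists for parity with workflows that standardize before splitting.
Zero-variance genes cannot be z-scaled and are dropped with their ids
recorded. The train/validation split holds out 10% and is stratified by
sex by default (plain random by flag).

## Integrated gradients

`IG_i(x) = (x_i − x′_i) ∫₀¹ ∂F/∂x_i(x′ + α(x − x′)) dα`, baseline x′ = 0
in z-scaled space — i.e. the population-mean expression profile, the
natural "typical sample" reference. The integral uses an m-step trapezoid
rule (default m = 128; m = 64 in the pipeline defaults). A left-endpoint
Riemann option is retained, but its O(1/m) completeness error measured
~2e-3 at m = 256 on trained toy nets, while the trapezoid's O(1/m²) error
sits well under the 1e-3 tolerance the tests enforce; the trapezoid is
therefore the default. On piecewise-linear (ReLU) networks the quadrature
error oscillates rather than decaying smoothly, so the decay test compares
coarse-vs-fine averages.

Attribution scores average IG over the male group (sign convention:
positive pushes toward male); female-group and signed-difference variants
are available. Top-k (default 100) is deterministic, boundary ties broken
lexicographically by gene id. The cross-cohort consensus reports the full
2^k Venn region decomposition and genes present in ≥ d lists.

## Preranked GSEA

Classical weighted Kolmogorov–Smirnov running sum: walking down the
ranking, set members add |score|^p / N_R (N_R = Σ members' |score|^p, p = 1
by default), non-members subtract 1/(N − |S|); the enrichment score is the
signed maximum-magnitude deviation. The null is gene-label permutation
(random same-size sets), the only null available to preranked input.
NES = ES / mean(|null ES| of the same sign). The nominal p is one-sided
within the same-sign null with +1 smoothing — counting against the full
signed null would let random sets reach p < 0.05 at a two-tailed ~10%
rate, which the calibration test (2–9% band) would reject. BH across sets.
All-zero score vectors degrade gracefully to equal hit mass.

## Differential expression and correlation

Per-gene Welch two-sample t tests on log2 expression; logFC is the
difference of group means; BH adjustment across genes. This deviates from
moderated (empirical-Bayes) linear-model statistics deliberately: variance
moderation is out of scope, and at the group sizes simulated here Welch
and moderated t agree closely. Genes constant in both groups get p = 1.

The screening filter keeps p < 0.05 AND |log2FC| > 0.5 (strict
inequalities). The fold-change threshold is read on the log2 scale by
default — a linear fold change > 0.5 would exclude almost nothing — with a
`scale="linear"` flag for the literal reading.

Pearson correlation uses the two-sided t approximation
t = r√((n−2)/(1−r²)), n ≥ 3, nonzero variance required.

## Survival analysis

* **Dichotomization.** "High" is strictly above the named quantile cutoff
  (median for AR, upper quartile for miR-125b, upper tertile for BIK,
  lower tertile for CASP6); ties go low, the cutoff is reported.
* **KM / log-rank / Cox** are delegated to lifelines: product-limit
  estimate, two-group log-rank with χ²(1) p, partial-likelihood Cox with
  Efron handling of ties and Wald 95% CIs (`exp(β ± 1.96·SE)`). Monotone
  likelihood (perfect separation) is surfaced as `converged = False`
  rather than silently returned.
* **LASSO-Cox** is implemented in-repo: coordinate descent with
  soft-thresholding on the IRLS quadratic approximation of the Breslow
  partial likelihood (the glmnet algorithm), features standardized
  internally, coefficients reported on the original scale. The default
  path is 50 log-spaced values from the data-derived λ_max down to
  1e-3·λ_max; a user path may include λ = 0, where the solver reduces to
  unpenalized IRLS and matches the Efron fit to 1e-4 on tie-free data
  (with continuous simulated times Breslow and Efron coincide).
  Cross-validation (tenfold default) scores each λ by the
  Verweij–van Houwelingen held-out deviance
  −2·[ℓ(β₋ₖ; all) − ℓ(β₋ₖ; train₋ₖ)]; the selected λ minimizes the mean
  deviance ("min" rule; "1se" by flag). The four-group AR × miR
  stratification and its merged binary (both-high vs rest) follow the
  dichotomization rules above.

## Sequence scanning

Seed patterns compile from a mature miRNA (RNA, 5′→3′, ≥ 8 nt):
7mer-m8 = DNA reverse complement of positions 2–8; 8mer = 7mer-m8 + "A";
6mer = reverse complement of positions 2–7; 7mer-A1 = 6mer + "A". The A1
adenine is literal (a property of the site, not complementarity). The UTR
scanner reports every occurrence, resolving overlaps in favour of the most
specific type (8mer > 7mer-m8 > 7mer-A1 > 6mer) so each position belongs
to at most one site; coordinates are 1-based inclusive. The bundled
default mature sequence is hsa-miR-125b-5p from miRBase (external
knowledge, configurable).

The ARE half-site scanner finds `AGAACA` on both strands of a promoter
(reverse-strand hits are forward `TGTTCT` occurrences), with TSS-relative
upstream coordinates: −1 is the base immediately 5′ of the TSS and a site
is reported as −near/−far with |near| < |far|. Inputs longer than the 2-kb
span are truncated to the TSS-proximal end with a warning. Strandedness of
the supplied sequence is the caller's responsibility.

Both scanners are verified against naive every-offset oracles on 1000
random sequences.

## Synthetic cohort generator

The generator defines the conditions under which everything above is
exercised. Expression is Gaussian on the log2 scale (array-like
log-intensities): per-gene baselines uniform in [4, 12], i.i.d. noise
sd = 1. Defaults: 5 cohorts × 300 samples × 2000 genes; male fraction
0.66 (the ~2:1 male:female incidence ratio — a modelling choice, since
cohort-level ratios are not published); 10 Y-linked genes (floor value in
every female), 5 XIST-like genes (floor in every male), 15 XCI-escape
genes (+1.0 log2 in females). The floor default 1.0 sits at the noise
floor rather than exact zero so per-gene scaling stays well-defined. The
hormone module overwrites designated rows with a latent-factor model:
corr(AR, miR) = 0.5 (inside the 0.4–0.6 band typical of receptor–effector
co-expression), corr(host-lncRNA, miR) = 0.6. Survival times are
exponential with hazard `baseline_rate · exp(β·x)` (0.02 events/month
baseline, planted HR ≈ 1.45 on the marker indicators); censoring is an
independent exponential clock whose rate is solved analytically by
bisection from `P(censored_i) = c/(c + λ_i)` to hit the target censored
fraction (default 20%). UTRs and promoters are rejection-sampled until a
scan reports exactly the planted site plan — no spurious sites, none
missing. One master seed spawns per-cohort and per-stage child seeds via
`numpy.random.SeedSequence`, making every output byte-reproducible.

What the generator does *not* emulate: probe effects, batch and platform
effects, count overdispersion structure beyond the optional NB mode,
copy-number or mutation signal, correlated background genes, non-
proportional hazards. Passing tests therefore demonstrate that the
*methods* recover planted structure under clean Gaussian conditions — not
that real microarray or RNA-seq cohorts would yield the same lists.

## Problem sizes in the checks

The end-to-end recovery check runs the five-cohort default (300 × 2000,
30 planted genes, 200 epochs at hidden width 16, IG with m = 64) and
requires ≥ 80% of planted genes in the consensus of ≥ 4/5 top-100 lists.
Null calibrations use 100–200 replicates; the LASSO recovery check uses
8 seeded replicates of n = 400 with two planted |β| = 0.6 among 40
features. `scripts/acceptance.py` runs the same five-cohort conditions.

## Known limitations

* No variance-moderated DE, multi-factor designs, or batch correction.
* No GPU path; training beyond a few thousand genes × hundreds of samples
  is CPU-bound minutes per cohort.
* TargetScan context scoring, conservation and free-energy filtering are
  out of scope; the screen is seed-match + expression evidence only.
* The Cox stack assumes proportional hazards and right censoring; no
  time-varying covariates or competing risks.
* lifelines' internal iteration trace is not re-exposed, so the
  monotone-likelihood-ascent property of the Newton solver is inherited
  from the library rather than asserted in our tests.
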
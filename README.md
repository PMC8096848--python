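# gcsex

Gastric cancer strikes men about twice as often as women, and survival
after treatment differs by sex as well. A productive way to interrogate
that disparity from expression data is to train a classifier to predict a
patient's sex from their tumour transcriptome and then ask *which genes the
classifier relies on*: genes carrying genuine sex-disparity signal (Y-linked
transcripts, XIST, X-inactivation escapees, hormone-receptor programs) rank
highly, and hormone-driven cancer biology — androgen receptor (AR) signaling
and its downstream microRNA effectors — can be pulled out of the ranking.

`gcsex` implements that discovery chain as a tested, reusable Python
package:

1. **Sex classifier** — an 11-layer densely connected feed-forward network
   (every hidden layer sees the concatenated outputs of all earlier layers
   plus the input) predicting P(male) from z-scaled expression; trained
   200 epochs with per-epoch validation and best-epoch restoration.
2. **Integrated-gradient attribution** — for sample *x* and baseline *x′*,

   `IG_i(x) = (x_i − x′_i) ∫₀¹ ∂F/∂x_i (x′ + α(x − x′)) dα`

   approximated by an m-step trapezoid rule, satisfying completeness
   (`Σ_i IG_i ≈ F(x) − F(x′)`). Per-gene attribution scores are averages
   over male samples; top-100 lists per cohort feed a Venn-style
   cross-cohort consensus.
3. **Preranked GSEA** — weighted Kolmogorov–Smirnov enrichment score with a
   gene-label permutation null, NES, same-sign nominal p (+1 smoothing) and
   Benjamini–Hochberg q.
4. **Differential expression** — per-gene Welch t tests with BH adjustment
   and the screening rule p < 0.05, |log2FC| > 0.5.
5. **Survival stack** — quantile dichotomization (median AR, upper-quartile
   miR-125b, tertile rules), Kaplan–Meier, log-rank, Cox proportional
   hazards (Efron ties, via lifelines), and an L1-penalized Cox path solved
   by coordinate descent with tenfold cross-validation on the held-out
   partial-likelihood deviance.
6. **miRNA target screen** — TargetScan-style seed sites (8mer, 7mer-m8,
   7mer-A1, 6mer) scanned in 3′-UTRs, inverse-correlation filtering, and a
   three-evidence intersection (sites ∧ down after mimic transfection ∧
   inversely correlated in patients); plus an `AGAACA` androgen-response-
   element half-site scan of 2-kb promoters on both strands.
7. **Synthetic cohorts** — a first-class generator planting exactly the
   structure above (male-biased cohorts, sex-chromosome strata, an
   AR–miR-125b–host-lncRNA module, proportional-hazards survival, UTRs with
   known seed sites), so the whole chain is testable without any downloads.

The classifier and penalized Cox model follow the scikit-learn estimator
protocol (`fit`, `predict_proba`, `get_params`, fitted `*_` attributes), so
they compose with sklearn pipelines and model selection.

## Worked example

```python
from gcsex.pipeline import demo_config, run_pipeline

summary = run_pipeline(demo_config("demo_out", seed=7))
for k in ("validation_accuracy", "planted_recovery_fraction",
          "pearson_ar_mir", "cox_hr_ar", "n_final_targets", "n_are_halfsites"):
    print(k, summary[k])
```

prints (three small cohorts, 120 samples × 400 genes, 18 planted sex genes):

```
validation_accuracy [0.9166666666666666, 0.8333333333333334, 0.9166666666666666]
planted_recovery_fraction 0.9444444444444444
pearson_ar_mir 0.4726654031466544
cox_hr_ar 1.578130355938587
n_final_targets 8
n_are_halfsites 4
```

Read: each cohort's classifier predicts held-out sex with 83–92% accuracy
on the 12-sample validation split; 17 of the 18 planted sex genes reach the
top-k consensus of most cohorts; the planted AR-like/miR-125b-like
correlation (population ρ = 0.5) is measured at r ≈ 0.47; the Cox hazard
ratio for AR-high lands near the planted ≈1.45; all 8 planted UTR targets
survive the three-evidence screen; and the promoter scan finds the 4
planted ARE half-sites.

The same stages are available from the shell:

```bash
gcsex run-all --demo --outdir demo_out --seed 7
gcsex attribute --config my_run.yaml     # run a prefix of the pipeline
```

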
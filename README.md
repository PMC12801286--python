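# tlsview

Quantification of tertiary lymphoid structures (TLS) from tissue-segmentation
heatmaps, multi-view fusion modelling, and relapse-risk stratification for
post-surgical cancer cohorts.

## The problem

In stage II colorectal cancer roughly one patient in five relapses after
surgery alone, and deciding who should receive adjuvant chemotherapy is hard.
TLSs — ectopic lymphoid aggregates graded by maturity as Agg (aggregate),
FL-1 (primary follicle) and FL-2 (secondary follicle) — are a promising
H&E-visible biomarker: their burden, maturity, and position relative to the
invasive tumor margin carry prognostic signal.

`tlsview` implements the computational core that sits *downstream* of tissue
segmentation.  Its input is a per-slide label heatmap in which each pixel is
one 256-px tile (0.064 mm at 0.25 µm/px) classified as
background/normal/tumor/TLS, with a parallel TLS-maturity channel.  From
there it provides:

* **Heatmap post-processing** — remove normal tissue, single-pixel specks and
  tumor domains under 20 px, fill interior holes; audited with SSIM so
  denoising provably preserves structure.
* **Spatial branch (SpB)** — each TLS component gets a maturity subtype
  (majority vote, ties to the more mature class), an area in mm², and a
  signed centroid-to-tumor-margin distance in mm (negative inside tumor).
  Distances and areas are discretized into seven bins each
  (≤0, (0,0.4], (0.4,1.0], (1.0,2.2], (2.2,4.5], (4.5,6.4], >6.4 mm and
  (0,0.03] … >0.28 mm²) and pooled per case into a named 226-feature vector.
* **Morphological branch (MpB)** — pluggable per-TLS embeddings (a
  deterministic shape/maturity descriptor ships as the default encoder),
  k-means-clustered into exactly 7 centers per case, pooled by gated
  attention.
* **Fusion networks** — gated-attention MIL over patch-feature bags
  (`S_i = softmax_i(W(tanh(W_a f_i) ⊙ σ(W_b f_i)))`), the SpB MLP
  (226→128→64→32), the two-branch fusion
  `f_fusion = concat(W_fusion(f_S ⊙ f_mvS), W_fusion(f_M ⊙ f_mvM))`, and a
  multimodal head that fuses a 32-wide clinical embedding (14 covariates
  through four FC+BatchNorm+ReLU layers) with the fusion penultimate.
* **Training/evaluation protocol** — class-weighted cross-entropy (0.5 no
  relapse / 1.2 relapse), stratified 5-fold case-level cross-validation with
  out-of-fold concatenation, cross-fold ensemble averaging, Equal-Error-Rate
  thresholding, AUROC with bootstrap CIs, DeLong's paired test, Kaplan–Meier
  curves and log-rank tests.
* **Interpretability** — top-50 attention tiles, 5-cluster patch summaries,
  and exact grouped Shapley attribution (full coalition enumeration over ≤12
  feature groups) for the spatial branch.
* **Synthetic cohorts** — a seed-reproducible generator that plants tumor
  blobs, TLS ellipses with controlled subtype/area/margin distance, clinical
  covariates, and relapse outcomes that depend on peritumoral mature-TLS
  burden, with a per-component ground-truth table for auditing.

## Worked example

```bash
tlsview run-all --out runs/demo --seed 7
```

generates a 60-case synthetic cohort (3 slides each), post-processes the
heatmaps, builds the 226-feature vectors and 7-center morphological bags,
trains the two-branch fusion model with 5-fold CV, and stratifies risk at the
EER threshold.  It prints:

```json
{
 "model_kind": "mvnet",
 "n_cases": 60,
 "oof_auroc": 0.8044444444444444,
 "oof_auroc_ci": [0.6599237091196438, 0.921875],
 "eer_threshold": 0.14554447020963,
 "logrank_chi2": 9.245206065223392,
 "logrank_p": 0.0023611272512201846,
 "mean_postprocess_ssim": 0.9202444078372597,
 "ensemble_mean_prob": 0.25957857256770567
}
```

Reading this: the out-of-fold AUROC (0.80) measures how well the fused
spatial+morphological model recovers the planted relapse signal at this small
cohort size; the EER threshold dichotomizes the ensemble probabilities into
high/low risk groups whose relapse-free-survival curves separate (log-rank
p ≈ 0.002); and the SSIM audit (0.92 on speckled copies) confirms
post-processing removes tile-level noise while preserving slide structure.
Artifacts (`features.csv`, `predictions.tsv`, `metrics.json`, `cases.csv`,
a config echo and a hash manifest) land in `runs/demo/`.

The same steps are available as a library (see `tlsview.io_cli.pipeline_run`,
`tlsview.train_eval.run_cv`) and as individual CLI verbs
(`synth`, `heatmap`, `features`, `morph`, `train`, `evaluate`, `explain`).

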
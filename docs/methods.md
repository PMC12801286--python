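# Methods

This note documents the models and procedures `tlsview` implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions used throughout.

## Heatmap representation and post-processing

A heatmap is an integer label grid (0 background, 1 normal, 2 tumor, 3 TLS)
with a parallel TLS-subtype grid (1 Agg, 2 FL-1, 3 FL-2) and a physical
pixel pitch, default 0.064 mm — one 256-px tile of a slide scanned at
0.25 µm/px.  Post-processing targets isolated tile mispredictions that would
otherwise distort distance and area statistics, in this order: normal tissue
is dropped entirely; single-pixel components of any class are erased; tumor
components below `min_tumor_px` (default 20) are erased; interior background
holes of the surviving tumor and TLS domains are filled with the enclosing
class.  Connected components use 8-connectivity; hole detection uses the
standard dual 4-connectivity of the background.  Hole filling applies to
both tumor and TLS domains, with the TLS fill applied last so the innermost
enclosing structure wins; hole-filled TLS pixels inherit the subtype of the
nearest original TLS pixel.  Erased pixels become background.  The operation
is idempotent, which the suite checks on random grids.

The structural-similarity audit treats the label grid as an intensity image
(7×7 uniform window, standard stabilizing constants, data range = max label).
The subtype channel is excluded.

## Spatial features (226-dimensional registry)

Each TLS component is summarized by three quantities:

* **subtype** — majority vote over the component's subtype pixels; ties break
  toward the more mature class (FL-2 > FL-1 > Agg);
* **area** — pixel count × pitch², in mm²;
* **signed margin distance** — Euclidean distance from the real-valued
  centroid to the nearest pixel of the tumor margin, negative when the
  centroid lies inside the tumor region.  The "tumor region" is the
  hole-filled union of tumor pixels, so a TLS fully surrounded by tumor
  counts as intratumoral and distances are measured to the invasive margin,
  not to internal rims.  Centroid-based distance is used rather than
  region-to-region minimum distance.

Distances fall into seven right-closed bins (≤0, 0.4, 1.0, 2.2, 4.5, 6.4, ∞
mm), areas into seven bins (0.03, 0.05, 0.07, 0.10, 0.15, 0.28, ∞ mm²).
Pooling over all slides of a case yields the canonical registry of exactly
226 named features:

| block | contents | count |
|---|---|---|
| distance × subtype | count, total area, mean area | 7·3·3 = 63 |
| area × subtype | count, total area, mean area | 7·3·3 = 63 |
| distance × area joint | count, total area | 7·7·2 = 98 |
| tumor globals | total area (mm²), mean area per slide | 2 |

Mean-area entries are zero where the count is zero.  The registry (names,
ordering, bin edges) ships as `tlsview/data/feature_registry.json` and the
suite asserts it matches the code.  Counts are invariant to slide order,
component order, and heatmap translation (checked).

## Morphological branch

The TLS-image encoder is a pluggable contract `(component, heatmap) → vector`
of fixed width `d_m` (default 64).  The shipped encoder is a deterministic
handcrafted descriptor — area (mm² and log px), perimeter (exposed 4-neighbor
edges × pitch), circularity 4πA/P², a maturity one-hot, and the signed margin
distance — lifted through a fixed Gaussian projection with a tanh squash.  It
exists so the full pipeline runs and is testable without any trained weights;
it is not a learned representation and carries no texture information.

Per case, embeddings are k-means-clustered (k-means++ init, ≤300 iterations,
tol 1e-6, seeded) into exactly 7 centers; cases with fewer than 7 TLSs are
padded by cyclic repetition, and TLS-free cases yield an all-zero, flagged
bag.  The fixed 7×d_m shape lets every fusion model train in full batches.
Center rows are sorted lexicographically so the representation does not
depend on k-means internals; downstream attention pooling is
permutation-invariant anyway (checked).

## Networks

All networks are small dense models on an in-package reverse-mode autodiff
engine (`tlsview.nn`), gradient-checked against central finite differences.

* **Gated-attention MIL**: instance features `f_i` come from two FC+ReLU
  layers; attention logits are `W(tanh(W_a f_i) ⊙ σ(W_b f_i))`,
  softmax-normalized over the bag; the pooled vector is `Σ S_i f_i` and a
  linear head gives two-class probabilities.  Defaults for patch bags:
  input 768, embed width 256, attention width 128.
* **SpB MLP**: 226→128→64→32, ReLU on hidden layers, linear output.
  Inputs are z-scored per feature with statistics from the training fold
  only.
* **MVNet**: with `r_mv = concat(r_S, r̂_M)`, four linear maps produce
  `f_S, f_M, f_mvS, f_mvM` (width 32 each) and the shared `W_fusion`
  (32→16) yields `f_fusion = concat(W_fusion(f_S ⊙ f_mvS),
  W_fusion(f_M ⊙ f_mvM))` — the 32-wide penultimate — followed by a linear
  two-class head.  Branches are pretrained standalone (100 epochs) before
  joint training, mirroring the develop-then-fuse recipe.
* **MMF**: the 14-covariate clinical vector passes through four
  FC+BatchNorm+ReLU layers (14→64→64→64→32); the 32-wide embedding is
  concatenated with the MVNet penultimate into a 64-wide vector and a final
  linear layer produces the prediction.  The tower and head are trained
  end-to-end with the final cross-entropy loss on top of a trained, frozen
  MVNet penultimate; batch-norm uses batch statistics in training and frozen
  running statistics (momentum 0.1) at evaluation, so eval calls are
  bit-identical.

Hidden widths other than the printed ones (768 input, 32 penultimate, 32/64
multimodal) are configuration, recorded in `ModelSpec`/`RunConfig`.

## Training and evaluation protocol

Relapse classification uses class weights 0.5 (no relapse) and 1.2 (relapse).
Optimization is full-batch Adam at 1e-3 with inverse-time decay
`lr0/(1+0.009·epoch)`; prognostic models default to 500 epochs and predictive
ones to 100.  A warm-up (10 epochs) + cosine schedule is available for the
patch-bag MIL model.  The emitted learning-rate trace is asserted in tests
rather than inferred from outcomes.

Because training is few-step and full-batch, decoupled (AdamW-style) weight
decay has almost no regularizing effect here — Adam's normalized updates keep
fitting regardless of the shrink.  Regularization is therefore a coupled L2
penalty added to the loss (default 3e-2), which passes through Adam's
preconditioner and effectively prunes weights on uninformative features; the
default was selected by cross-validation on independent synthetic cohort
draws.

Cross-validation is stratified 5-fold at case level (stratification prevents
single-class folds at cohort sizes in the hundreds); each case is predicted
once by the model not trained on it, and the same fold split is reused across
model variants.  Standardization statistics come from training folds only —
a leakage test verifies that flipping held-out labels leaves trained
parameters bit-identical.  External-style evaluation averages the five fold
models' probabilities and binarizes only the ensemble.  The decision
threshold is the Equal-Error-Rate point: among candidate thresholds (unique
probabilities plus +∞, rule "probability ≥ t ⇒ high risk"), the one
minimizing |FPR − FNR|, ties to the smaller threshold.  Thresholds are
computed per dataset by default; a fixed threshold can be supplied instead.

Metrics: AUROC by the Mann–Whitney statistic with half-credit for ties
(bootstrap percentile CIs, 2000 replicates); DeLong's paired test via the
structural-components variance estimator; Kaplan–Meier curves and two-group
log-rank tests via lifelines, with hand-tabulated oracles in the suite.
Cox regression and nomograms are intentionally out of scope; the package
exports the per-case table such analyses consume.

## Interpretability

Top-k (default 50) attention tiles are selected per case, ties broken by
instance index; selected tiles are k-means-clustered (default 5 clusters)
and summarized by cluster sizes.  Spatial-branch attribution is exact
grouped Shapley: the 226 features are partitioned into at most 12 groups and
all 2^g coalitions are enumerated, replacing out-of-coalition groups with
baseline values (cohort mean).  Efficiency holds to 1e-8 by construction.

The default 11-group partition keeps per-distance-bin resolution for the
FL-2 subtype (seven groups), pools the immature subtypes' distance features,
and keeps the area-bin, joint-bin, and tumor-global blocks whole.  This
granularity is what the planted-signal check needs; any other partition of
≤12 groups can be supplied.  Each group's direction is the sign of the
correlation between a case's group exposure (mean z-scored feature value)
and its attribution: negative = favorable (more of it lowers predicted
risk).  The mean signed attribution is near zero by construction when the
baseline is the cohort mean, which is why direction is reported via exposure
correlation instead.

## Synthetic cohorts: what they emulate and what they do not

Each slide carries one smoothed tumor blob (radius ≈ 1.7 mm, low-frequency
boundary wobble, ≥200 px) and a Poisson(6) number of elliptical TLSs.
Placement samples one of the seven distance bins uniformly (so every bin is
populated), then a distance within the bin; subtypes follow a 40/35/25
Agg/FL-1/FL-2 mixture; areas are log-normal (median 0.05 mm², σ=0.55,
clipped to [0.012, 0.55] mm²).  The grid is 224×224 px (≈14 mm) so distances
beyond 6.4 mm are realizable.  The generator records per-component ground
truth — sampled and achieved subtype, area, and signed distance, the latter
measured exactly as extraction measures it — and the suite checks the
extraction pipeline recovers planted distances within one pixel pitch and
areas exactly.

Outcomes are planted on the biology the models should recover: the linear
predictor is η = 2·z(FL-2 area 1.0–4.5 mm outside the margin) −
1·z(total tumor area) − 0.5·(insufficient lymph-node sampling), relapse is a
logistic draw on −η with the intercept solved for 25% prevalence, relapse
times are exponential with mean scaling in exp(0.4η) and non-relapse cases
are right-censored at their follow-up end (uniform 36–96 months, 15%
censored earlier).  Relapse label equals the observed event flag by
construction.  At these defaults the true-η AUROC is ≈0.93; at zero planted
effects labels are independent of all features.

Patch-feature bags are two-component Gaussian mixtures whose signal-
component weight increases with case risk, giving MIL attention a
recoverable target.

Generated heatmaps are noise-free so planted truth is exact; tile-level
segmentation noise is modeled separately by `add_speckle`, which plants
isolated single-pixel mispredictions on background away from tissue — post-
processing removes them exactly, features are unchanged, and the SSIM audit
becomes informative.  The demo uses a 0.2% speckle rate, consistent with a
tile classifier of very high accuracy.

**Limits.** Synthetic cohorts establish that the pipeline's machinery is
correct — bookkeeping, protocol integrity, recoverability of a planted
signal of known size.  They do not establish clinical performance: real
heatmaps have correlated segmentation errors, multifocal tumors, staining
and scanner effects, and biology far richer than one linear planted signal.
The default morphological encoder carries only shape/maturity descriptors,
so the morphological branch is weaker here than a trained image encoder
would be on real slides.

## Numerical choices and degenerate inputs

Problem sizes in the shipped tests and demos: planted-signal checks use one
n=300 cohort (3 slides/case) with a 19-permutation label null; the demo
pipeline and acceptance script use n=60.  Larger cohorts only tighten the
same checks.  Other conventions: probability-vs-threshold comparisons use ≥;
empty TLS blocks are zero-filled and TLS-free cases yield flagged all-zero
morphological bags; slides without tumor raise a per-slide error for margin
distances; zero predicted probabilities are clipped at 1e-12 with a warning
in the loss; EER on constant probabilities returns that value with a
warning; DeLong on identical score vectors returns z=0, p=1, and degenerate
variances otherwise raise.  All randomness flows through explicit seeds;
rerunning any stage with the same configuration is bit-identical, and every
artifact embeds the hash of the configuration that produced it.
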
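# ricesits

Phenology-aware paddy-rice mapping from satellite image time series (SITS),
for agricultural remote-sensing practitioners working in cloud-prone,
fragmented landscapes where single-date imagery fails. The package is a
tested end-to-end pipeline: reconstruct cloud-gapped vegetation-index time
series, derive a phenological feature set, classify per-pixel sequences
with an enhanced SITS-Former, and evaluate with paired statistics — all
exercisable on a built-in synthetic scene generator, so no downloads are
required.

## The method

Each sample is a sequence of Sentinel-2-style reflectances (B2, B4, B8,
B11) with day-of-year stamps *t* and quality codes. The pipeline:

1. **Reconstruction.** Cloud-coded steps are masked; the valid subsequence
   is Savitzky–Golay smoothed (window 7, order 2); a harmonic regression
   `y(t) = a₀ + Σₖ aₖ cos(2πkt/365) + bₖ sin(2πkt/365)` (K = 2), fitted by
   OLS on the valid points, fills only the gaps.
2. **Features.** Per timestep: NDVI = (B8−B4)/(B8+B4),
   LSWI = (B8−B11)/(B8+B11), EVI = 2.5(B8−B4)/(B8+6B4−7.5B2+1); between
   consecutive valid steps: the temporal difference
   TDVI = VI(t+Δt) − VI(t) and the normalized change rate
   NCRVI = (VI(t₂)−VI(t₁))/VI(t₁) × 100%. The `complete` preset carries all
   nine channels; ablation presets (`baseline`, `+tdvi`, `+ncrvi`) drop the
   derivative families.
3. **Classifier.** A 4-layer, 8-head transformer encoder (d_model 64,
   feed-forward 256, GELU, dropout 0.1) over per-timestep tokens, enhanced
   with a parallel three-branch embedding (direct / deep / pairwise
   interactions) recalibrated by channel attention, adaptive positional
   encodings (learnable phenological-stage embedding + DOY sinusoid
   projection), a phenology attention gate (sigmoid gating of encoder
   outputs conditioned on token ⊕ positional context), masked global
   average pooling, and a two-layer softmax head. An optional 3-D-conv
   patch branch embeds P×P×4 spatial patches per timestep. The network and
   its AdamW/cosine training loop (lr 10⁻³, batch 32, gradient-norm clip
   1.0) run on an in-package numpy autodiff engine — no deep-learning
   framework is required.
4. **Evaluation.** Splits are performed at polygon (field) granularity so
   spatially correlated points never straddle train/test. Metrics:
   accuracy, precision, recall, F1, Cohen's kappa
   κ = (P₀−Pₑ)/(1−Pₑ); paired model comparisons use the McNemar test on
   discordant counts, χ² = (|b−c|−1)²/(b+c) with continuity correction.

## Worked example

Simulate a scene, train, and evaluate in a few lines:

```python
from ricesits import (PipelineConfig, SceneConfig, TrainConfig,
                      ModelConfig, run_pipeline)

cfg = PipelineConfig(
    scene=SceneConfig(n_polygons_per_class=100, points_per_polygon=3,
                      patch_size=1, seed=5),        # 1,500 labeled points
    feature_preset="complete",
    model=ModelConfig(),
    train=TrainConfig(epochs=10),
    include_baseline=True,                          # McNemar comparison
    seed=5,
)
res = run_pipeline(cfg, outdir="example_out")
m = res["report"]["metrics"]
mc = res["report"]["baseline"]["mcnemar"]
print(f"test accuracy {m['accuracy']:.3f}  F1 {m['f1']:.3f} "
      f"kappa {m['kappa']:.3f}")
print(f"McNemar vs temporal-mean logistic: b={mc['b']} c={mc['c']} "
      f"chi2={mc['chi2']:.2f} p={mc['p_value']:.2e}")
```

Output:

```
test accuracy 0.997  F1 0.992 kappa 0.990
McNemar vs temporal-mean logistic: b=44 c=0 chi2=42.02 p=9.02e-11
```

The model nearly perfectly separates rice from the confusers on this
synthetic scene (an idealized version of the real task — see
`docs/methods.md` for what that does and does not demonstrate); the
McNemar test says the transformer corrected 44 of the logistic reference's
errors while introducing none, a significant paired improvement. The same
stages are available as a CLI for shell use:

```sh
ricesits simulate --seed 1 --polygons 100 --points 3 --out scene.csv
ricesits preprocess --in scene.csv --out recon.csv
ricesits featurize --in recon.csv --preset complete --out features.csv \
         --standardizer-out std.json
ricesits split --in features.csv --test-fraction 0.2 --seed 1 --out split.json
ricesits train --features features.csv --split split.json --epochs 10 \
         --checkpoint model.npz
ricesits predict --checkpoint model.npz --features features.csv --out pred.csv
ricesits evaluate --pred pred.csv --truth features.csv --out report.json
```

Metric arithmetic works standalone, e.g. for a published-style confusion
matrix:

```python
from ricesits import ConfusionCounts, classification_metrics
m = classification_metrics(ConfusionCounts(tp=2936, tn=2866, fp=135, fn=63))
# accuracy 0.967, precision 0.956, recall 0.979, F1 0.967, kappa 0.934
```

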
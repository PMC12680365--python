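# fundusgcn

Graph-enhanced, quality-aware, uncertainty-driven grading of fundus
images, for researchers who want to study how batch-graph refinement,
auxiliary confidence heads and Monte-Carlo-dropout uncertainty interact
in a five-grade diabetic-retinopathy (DR) classifier — without
downloading clinical data.  A seeded synthetic fundus-phantom generator
makes every stage runnable and testable on one CPU.

## The model

Each image `x` is pooled by a convolutional backbone into an embedding
`z = f(x) ∈ R^d` (global average pooling).  A mini-batch becomes a
graph: nodes are embeddings, and edges join mutual k-nearest
neighbours (k = 4) under the combined distance

    d_comb(i,j) = β·d_sp(i,j) + (1−β)·d_se(i,j),     β = 0.5,

(Euclidean + cosine, min–max normalised per batch) within the edge
threshold radius 0.1.  Two graph-convolution layers refine the
embeddings with symmetric degree normalisation,

    h_i^(l+1) = ReLU( Σ_{j∈N(i)} W_l h_j^(l) / √(deg(i)·deg(j)) + b_l ),

yielding `h ∈ R^256`, from which a softmax head predicts the grade
`ŷ = softmax(W_cls h + b_cls)` and a logistic quality-assessment head
predicts a confidence `q̂ = σ(W_QA h + b_QA)`.  Training minimises
`L_total = L_cls + λ·L_q` (cross-entropy plus binary cross-entropy of
q̂ against prediction correctness, λ = 0.1) with AdamW (lr 5e-5, weight
decay 0.01), plateau scheduling and early stopping.  At inference,
T = 10 stochastic passes with dropout active give the prediction
`ȳ = (1/T)Σ ŷ^(t)` and the per-class uncertainty
`σ = √((1/T)Σ(ŷ^(t)−ȳ)²)`; Grad-CAM heatmaps localise the evidence.
See `docs/methods.md` for the full treatment, including how the
built-in backbone and GCN are initialised as a multi-scale lesion
filter bank and a soft clinical grading rubric.

## Worked example

```python
import numpy as np
from fundusgcn import desk_spec, run_pipeline, TrainConfig

result = run_pipeline(desk_spec(seed=42), TrainConfig(epochs=10, seed=42))
r = result.report
print(f"acc {r.accuracy:.3f}  kappa {r.kappa:.3f}  "
      f"macro-F1 {r.f1_macro:.3f}  AUROC {r.auroc_macro:.3f}")
```

This generates 1,000 phantoms (APTOS-ratio class counts 492/273/101/
81/53, 64 px), splits 70/15/15 with stratification, oversamples the
training partition to balance, trains for 10 epochs and evaluates the
147-image held-out test split with MC dropout.  On one CPU it takes a
few minutes and prints

```
acc 0.912  kappa 0.863  macro-F1 0.908  AUROC 0.990
```

meaning: 91.2% of held-out phantoms received the correct grade, the
chance-corrected agreement κ is 0.86, and the near-unit AUROC says the
per-grade probability ranking is almost perfect even where the argmax
hesitates between neighbouring severities.  `result.bundles` holds the
per-sample probabilities, MC uncertainty and quality scores.

The same pipeline is scriptable from the shell:

```bash
fundusgcn simulate --out data/ --counts 492,273,101,81,53 --image-size 64 --seed 42
fundusgcn train    --data data/ --out run/   --config config.yaml --seed 42
fundusgcn evaluate --data data/ --checkpoint run/checkpoint.npz --out eval/ --seed 42
fundusgcn predict  --images data/ --checkpoint run/checkpoint.npz --out preds.csv
fundusgcn explain  --images data/ --checkpoint run/checkpoint.npz --out heatmaps/
```

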
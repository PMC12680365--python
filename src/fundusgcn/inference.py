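"""Monte-Carlo-dropout prediction, quality scoring and Grad-CAM maps.

Uncertainty is estimated by running T stochastic forward passes with
dropout kept active; the prediction is the arithmetic mean of the T
probability vectors and the per-class uncertainty is the population
standard deviation

    sigma = sqrt( (1/T) * sum_t (y_t - y_bar)^2 )

(divisor T, so a single pass yields sigma = 0).  The batch graph is
built once from the dropout-off features and reused across the passes,
so the spread reflects weight stochasticity rather than graph rewiring;
``rebuild_graph_per_pass=True`` restores the alternative.  The quality
score q̂ comes from the dropout-off pass — a stable confidence rather
than an MC average (``mc_quality=True`` averages instead).

Grad-CAM weights each channel of the final convolutional map by the
spatial mean of the gradient of the target-class score, rectifies the
weighted sum, upsamples to the input size and min-max normalises.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.transform import resize

from .gcnnet import GraphDRModel, N_CLASSES
from .phantoms import LabeledSample

__all__ = ["PredictionBundle", "Heatmap", "mc_dropout_predict", "gradcam", "write_predictions_csv"]


@dataclass
class PredictionBundle:
    """Per-sample outputs of MC-dropout inference."""

    id: str
    probs: np.ndarray  # single (dropout-off) pass ŷ, length 5
    mc_mean: np.ndarray  # ȳ, length 5
    sigma: np.ndarray  # per-class standard deviation, length 5
    quality: float  # q̂ ∈ (0, 1)
    t_passes: int

    @property
    def sigma_mean(self) -> float:
        """Scalar uncertainty summary: mean of the per-class sigmas."""
        return float(self.sigma.mean())

    @property
    def pred_grade(self) -> int:
        return int(self.mc_mean.argmax())


@dataclass
class Heatmap:
    """Grad-CAM saliency map, normalised to [0, 1] at input resolution."""

    id: str
    values: np.ndarray
    target_class: int


def mc_dropout_predict(
    samples: Sequence[LabeledSample] | np.ndarray,
    model: GraphDRModel,
    t_passes: int = 10,
    rng: np.random.Generator | None = None,
    rebuild_graph_per_pass: bool = False,
    mc_quality: bool = False,
) -> list[PredictionBundle]:
    """Predict one batch with T stochastic passes (dropout forced on).

    All samples form one batch graph; call batch-wise for larger sets.
    Deterministic for a fixed generator state.
    """
    if t_passes < 1:
        raise ValueError(f"t_passes must be >= 1, got {t_passes}")
    rng = np.random.default_rng(42) if rng is None else rng
    if isinstance(samples, np.ndarray):
        images = samples if samples.ndim == 4 else samples[None]
        ids = [str(i) for i in range(len(images))]
    else:
        images = np.stack([s.image for s in samples])
        ids = [s.id for s in samples]

    clean = model.forward(images, dropout_rng=None)
    passes = np.empty((t_passes, len(images), N_CLASSES))
    q_passes = np.empty((t_passes, len(images)))
    for t in range(t_passes):
        graph = None if rebuild_graph_per_pass else clean.graph
        res = model.forward(images, dropout_rng=rng, graph=graph)
        passes[t] = res.probs
        q_passes[t] = res.q_hat
    mc_mean = passes.mean(axis=0)
    sigma = np.sqrt(np.mean((passes - mc_mean[None]) ** 2, axis=0))
    # exact zero where the passes agree bit-for-bit (e.g. no dropout):
    # the mean of T identical doubles can differ from them by one ulp
    sigma[np.ptp(passes, axis=0) == 0.0] = 0.0
    quality = q_passes.mean(axis=0) if mc_quality else clean.q_hat
    return [
        PredictionBundle(
            id=ids[i],
            probs=clean.probs[i],
            mc_mean=mc_mean[i],
            sigma=sigma[i],
            quality=float(quality[i]),
            t_passes=t_passes,
        )
        for i in range(len(images))
    ]


def gradcam(
    sample: LabeledSample,
    model: GraphDRModel,
    target_class: int | None = None,
) -> Heatmap:
    """Class-activation heatmap for one image.

    A single-image batch degenerates to a self-loop-only graph, so the
    refinement acts as a per-sample transform.  A constant raw map (for
    example when the gradient vanishes) yields an all-zero heatmap.
    """
    res = model.forward(sample.image[None], dropout_rng=None)
    if target_class is None:
        target_class = int(res.probs[0].argmax())
    if not 0 <= target_class < N_CLASSES:
        raise ValueError(f"target_class must be in [0, {N_CLASSES}), got {target_class}")
    if res.maps is None or res.maps.size == 0:
        raise ValueError("backbone adapter does not expose a spatial activation map")

    # gradient of the target-class score (logit) w.r.t. the pooled z ...
    dlogits = np.zeros_like(res.logits)
    dlogits[0, target_class] = 1.0
    _, dz = model.backward(res, dlogits, dq_logit=None, return_dz=True)
    # ... and channel weights = spatial mean of the map gradient, which for
    # a GAP head is dz / (h*w) in every cell: alpha_c = dz_c / (h*w).
    _, c, h, w = res.maps.shape
    alpha = dz[0] / (h * w)
    raw = np.maximum((alpha[:, None, None] * res.maps[0]).sum(axis=0), 0.0)

    size = sample.image.shape[0]
    up = resize(raw, (size, size), order=1, mode="edge", anti_aliasing=False)
    lo, hi = up.min(), up.max()
    values = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return Heatmap(id=sample.id, values=values, target_class=target_class)


def write_predictions_csv(bundles: Sequence[PredictionBundle], path: str | Path) -> None:
    """``id,pred_grade,p0..p4,quality,uncertainty_sd`` — one row per sample."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(
            ["id", "pred_grade", "p0", "p1", "p2", "p3", "p4", "quality", "uncertainty_sd"]
        )
        for b in bundles:
            writer.writerow(
                [b.id, b.pred_grade]
                + [f"{p:.8f}" for p in b.mc_mean]
                + [f"{b.quality:.8f}", f"{b.sigma_mean:.8f}"]
            )
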
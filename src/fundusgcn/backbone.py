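"""Feature extraction: image -> pooled embedding z via a backbone + GAP.

The pipeline contract is that a backbone ``f`` maps an RGB image ``x`` to
a feature vector ``z = f(x) ∈ R^d``, where ``z`` is the global average
pool (GAP) of the final convolutional activation map.  The spatial map
itself is also exposed, because Grad-CAM needs it.

Adapters for large pretrained networks are an extension point: anything
implementing :class:`BackboneAdapter` plugs in.  The built-in
:class:`TinyConvBackbone` is a four-block CNN small enough to train on
one CPU in minutes.  Because the reference training recipe uses a
fine-tuning-scale learning rate (5e-5) — appropriate for a pretrained
network, far too small to learn filters from noise in a few hundred
steps — the built-in backbone ships with a domain-informed
initialisation rather than a purely random one, mirroring how classical
fundus CAD systems detect lesions:

* block 1 (stride 1) holds colour-opponent, polarity-specific 3x3
  centre-surround (Laplacian-of-Gaussian style) detectors with negative
  biases acting as contrast thresholds, evaluated at every pixel.
  Bright yellowish dots (R ≈ G, microaneurysm/exudate analog) and
  bright reddish neovascular tufts (R ≫ G) excite separate threshold
  ladders; colour planes needed at coarser scales pass through;
* block 2 (stride 2) downsamples the fine count maps and the colour
  planes with a binomial anti-aliasing kernel (uniform per-pixel
  weight — a plain mean kernel at stride 2 weights pixels 1x/2x/4x by
  parity and adds counting noise);
* block 3 (stride 1) applies second-scale centre-surround ladders at
  every half-resolution pixel, matched to the larger lesions: dark
  G-dominant hemorrhage blobs (on a vessel-nulled 0.7R-G plane) and
  broad bright patches;
* block 4 (stride 2) binomially pools everything down to the final
  map, so the GAP embedding approximates per-channel soft lesion
  counts at several contrast thresholds and two spatial scales.

All parameters remain trainable; the initialisation is a prior, not a
frozen extractor.  ``init="he"`` restores plain fan-in-scaled random
initialisation.  The indices of the threshold-ladder count channels are
exposed as :attr:`TinyConvBackbone.count_dims` so downstream layers can
build count-aware initialisations of their own.
"""

from __future__ import annotations

from abc import ABC, abstractmethod

import numpy as np

from . import _nn

__all__ = ["BackboneAdapter", "TinyConvBackbone", "extract_features"]

# centre-surround kernel: mean-removed 3x3 Laplacian
_LAPLACIAN = np.full((3, 3), -1.0 / 8.0)
_LAPLACIAN[1, 1] = 1.0

# binomial 3x3 anti-aliasing kernel; at stride 2 every input pixel
# receives the same total weight across output cells
_BINOMIAL = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]]) / 16.0

# contrast-threshold ladders (intensity units in [0,1] images)
_DOT_THRESHOLDS = (0.06, 0.09, 0.12, 0.15, 0.18, 0.21)  # bright dots, R+G
_TUFT_THRESHOLDS = (0.04, 0.07, 0.10, 0.13)  # reddish tufts, R-G
_BLOB_THRESHOLDS = (0.02, 0.04, 0.06, 0.08)  # dark blobs, 0.7R-G plane, scale 2
_PATCH_THRESHOLDS = (0.04, 0.07, 0.10, 0.13)  # bright patches, R+G, scale 2
_DARK_THRESHOLDS = (0.04, 0.08)  # dark lesions, inverted luminance, scale 2


def _colour_laplacian(direction, polarity: float) -> np.ndarray:
    return np.einsum("c,ij->cij", np.asarray(direction, dtype=np.float64),
                     polarity * _LAPLACIAN)


def _delta(direction) -> np.ndarray:
    w = np.zeros((3, 3, 3))
    w[:, 1, 1] = np.asarray(direction, dtype=np.float64)
    return w


def _line_kernel(orientation: str) -> np.ndarray:
    k = np.zeros((3, 3))
    if orientation == "h":
        k[1, :] = 1.0
    else:
        k[:, 1] = 1.0
    k = k / 3.0 - (1.0 - k) / 6.0
    return -k  # dark line -> positive response


class BackboneAdapter(ABC):
    """Contract every feature-extraction backbone must satisfy.

    ``forward`` must return the pooled vector *and* the pre-pool spatial
    activation map of the final convolutional stage; the pooled vector
    must equal the spatial mean of that map (GAP contract).
    """

    name: str = "adapter"
    output_dim: int = 0
    trainable: bool = False
    #: z indices that hold threshold-ladder lesion counts (may be empty)
    count_dims: tuple[int, ...] = ()

    @abstractmethod
    def forward(self, images: np.ndarray):
        """images (n, H, W, 3) in [0,1] -> (z (n, d), maps (n, d, h, w), cache)."""

    def backward(self, dz: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. adapter parameters given dL/dz."""
        raise NotImplementedError(f"backbone '{self.name}' is not trainable")

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {}


class TinyConvBackbone(BackboneAdapter):
    """Four 3x3 conv+ReLU blocks (strides 1,2,1,2) -> GAP -> z ∈ R^64.

    The stride-1 detection blocks matter: a point lesion about one
    pixel wide at its scale is seen off-centre three times out of four
    by a strided detector and its count statistics degrade badly, so
    each detection stage runs dense and downsampling is left to the
    pooling stages.
    """

    name = "tiny-cnn"
    trainable = True

    def __init__(
        self,
        channels: tuple[int, ...] = (16, 32, 64, 64),
        strides: tuple[int, ...] = (1, 2, 1, 2),
        init: str = "fundus-bank",
        rng: np.random.Generator | None = None,
    ):
        if len(channels) != len(strides):
            raise ValueError("channels and strides must have equal length")
        if init not in ("fundus-bank", "he"):
            raise ValueError(f"unknown init scheme {init!r}")
        rng = np.random.default_rng(42) if rng is None else rng
        self.channels = tuple(channels)
        self.strides = tuple(strides)
        self.init = init
        self.output_dim = self.channels[-1]
        self.count_dims: tuple[int, ...] = ()
        self._params: dict[str, np.ndarray] = {}
        c_prev = 3
        for i, c in enumerate(self.channels):
            self._params[f"conv{i}.w"] = _nn.he_init(rng, (c, c_prev, 3, 3), c_prev * 9)
            self._params[f"conv{i}.b"] = np.zeros(c)
            c_prev = c
        if init == "fundus-bank":
            if self.channels != (16, 32, 64, 64) or self.strides != (1, 2, 1, 2):
                raise ValueError(
                    "the fundus-bank initialisation is defined for "
                    "channels (16, 32, 64, 64) with strides (1, 2, 1, 2)"
                )
            self._apply_fundus_bank()

    def _apply_fundus_bank(self) -> None:
        # ---- block 1 (stride 1): fine detectors + colour passthroughs ----
        w0, b0 = self._params["conv0.w"], self._params["conv0.b"]
        w0[...] = 0.0
        b0[...] = 0.0
        rg = (0.5, 0.5, 0.0)
        ropp = (1.0, -1.0, 0.0)
        third = (1 / 3, 1 / 3, 1 / 3)
        ch = 0
        for th in _DOT_THRESHOLDS:  # 0-5: bright dot ladder
            w0[ch] = _colour_laplacian(rg, +1)
            b0[ch] = -th
            ch += 1
        for th in _TUFT_THRESHOLDS:  # 6-9: tuft ladder
            w0[ch] = _colour_laplacian(ropp, +1)
            b0[ch] = -th
            ch += 1
        w0[10] = _delta((0.7, -1.0, 0.0))  # 10: vessel-nulled blob plane
        w0[11] = _delta(rg)  # 11: R+G plane
        w0[12] = _delta((-1 / 3, -1 / 3, -1 / 3))  # 12: inverted luminance
        b0[12] = 1.0
        w0[13] = _delta(third)  # 13: luminance
        w0[14] = np.einsum("c,ij->cij", np.array(third), _line_kernel("h"))
        b0[14] = -0.05  # 14-15: dark vessel-line detectors
        w0[15] = np.einsum("c,ij->cij", np.array(third), _line_kernel("v"))
        b0[15] = -0.05

        # ---- block 2 (stride 2): binomial pooling of counts and planes --
        w1, b1 = self._params["conv1.w"], self._params["conv1.b"]
        w1 *= 0.05  # keep a whiff of the random init for trainability
        b1[...] = 0.0
        for c in range(16):  # 0-15: pooled block-1 channels
            w1[c] = 0.0
            w1[c, c] = _BINOMIAL
        # 16-31 stay mildly random (spare trainable capacity)

        # ---- block 3 (stride 1): coarse-scale detection ladders ----------
        w2, b2 = self._params["conv2.w"], self._params["conv2.b"]
        w2 *= 0.05
        b2[...] = 0.0
        for c in range(10):  # 0-9: fine ladders pass through
            w2[c] = 0.0
            w2[c, c, 1, 1] = 1.0
        ch = 10
        for th in _BLOB_THRESHOLDS:  # 10-13: blob ladder on pooled plane 10
            w2[ch] = 0.0
            w2[ch, 10] = _LAPLACIAN
            b2[ch] = -th
            ch += 1
        for th in _PATCH_THRESHOLDS:  # 14-17: patch ladder on pooled plane 11
            w2[ch] = 0.0
            w2[ch, 11] = _LAPLACIAN
            b2[ch] = -th
            ch += 1
        for th in _DARK_THRESHOLDS:  # 18-19: coarse dark-lesion ladder
            w2[ch] = 0.0
            w2[ch, 12] = _LAPLACIAN
            b2[ch] = -th
            ch += 1
        for src in (10, 11, 12, 13, 14, 15):  # 20-25: colour/line planes
            w2[ch] = 0.0
            w2[ch, src, 1, 1] = 1.0
            ch += 1
        # 26-63: replicas of the count channels.  Replicating informative
        # channels rather than leaving random spares keeps the batch-graph
        # distance, computed on the standardised embedding, dominated by
        # lesion counts instead of uninformative mixture channels.
        replica = (
            [("delta", src) for src in range(10)]
            + [("dog", 10, th) for th in _BLOB_THRESHOLDS]
            + [("dog", 11, th) for th in _PATCH_THRESHOLDS]
            + [("dog", 12, th) for th in _DARK_THRESHOLDS]
        )
        r = 0
        while ch < w2.shape[0]:
            spec = replica[r % len(replica)]
            w2[ch] = 0.0
            if spec[0] == "delta":
                w2[ch, spec[1], 1, 1] = 1.0
            else:
                w2[ch, spec[1]] = _LAPLACIAN
                b2[ch] = -spec[2]
            ch += 1
            r += 1

        # ---- block 4 (stride 2): binomial channel-preserving pooling -----
        w3 = self._params["conv3.w"]
        w3 *= 0.05
        self._params["conv3.b"][...] = 0.0
        for c in range(w3.shape[0]):
            w3[c] = 0.0
            w3[c, c] = _BINOMIAL
        self.count_dims = tuple(range(20))

    @property
    def params(self) -> dict[str, np.ndarray]:
        return self._params

    def forward(self, images: np.ndarray):
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[3] != 3:
            raise ValueError(f"expected batch (n, H, W, 3), got {images.shape}")
        x = images.transpose(0, 3, 1, 2)
        caches = []
        for i in range(len(self.channels)):
            x, c_conv = _nn.conv3x3_forward(
                x,
                self._params[f"conv{i}.w"],
                self._params[f"conv{i}.b"],
                stride=self.strides[i],
            )
            x, c_relu = _nn.relu_forward(x)
            caches.append((c_conv, c_relu))
        maps = x  # post-activation final spatial map
        z, c_gap = _nn.global_avg_pool_forward(maps)
        return z, maps, (caches, c_gap)

    def backward(self, dz: np.ndarray, cache) -> dict[str, np.ndarray]:
        caches, c_gap = cache
        dx = _nn.global_avg_pool_backward(dz, c_gap)
        grads: dict[str, np.ndarray] = {}
        for i in reversed(range(len(self.channels))):
            c_conv, c_relu = caches[i]
            dx = _nn.relu_backward(dx, c_relu)
            dx, dw, db = _nn.conv3x3_backward(dx, c_conv)
            grads[f"conv{i}.w"] = dw
            grads[f"conv{i}.b"] = db
        return grads


def extract_features(images: np.ndarray, adapter: BackboneAdapter):
    """Extract pooled feature vectors and spatial maps for a batch.

    Returns ``(Z, maps)`` where ``Z[i]`` is the GAP embedding of image i
    and ``maps[i]`` the final convolutional activation map.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    z, maps, _ = adapter.forward(images)
    return z, maps
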
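"""Dataset loading, stratified splitting and class balancing.

Grading datasets are heavily imbalanced (for APTOS2019: 1805 / 999 /
370 / 295 / 193 images for grades 0-4).  The preparation pipeline here
is: load images + label CSV, stratified 70/15/15 split on the original
samples, then oversample the *training* partition only — duplicating
minority-class images with random augmentation until every class
matches the majority count N_max.  Splitting before balancing keeps
augmented duplicates out of validation and test (no leakage) while the
evaluation sets retain their natural imbalance.  A
``balance_before_split`` flag on :func:`prepare_partition` reproduces
the alternative balance-then-split ordering for comparison.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import rotate

from .phantoms import GRADES, LabeledSample

__all__ = [
    "AugmentationPolicy",
    "DatasetPartition",
    "load_labeled_images",
    "stratified_split",
    "apply_augmentation",
    "balance_by_oversampling",
    "prepare_partition",
    "class_counts",
]

_IMG_EXTENSIONS = (".png", ".jpg", ".jpeg")


class LabelError(ValueError):
    """Bad or unresolvable label row."""


class StratificationError(ValueError):
    """A class is too small to populate every partition."""


@dataclass(frozen=True)
class AugmentationPolicy:
    """Random rotations, flips, blur and brightness/contrast jitter.

    Defaults are mild enough to preserve lesion visibility.  With all
    probabilities and ranges zero the policy is the identity.
    Augmentation never changes the grade label.
    """

    rotation_deg: float = 30.0
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    blur_prob: float = 0.3
    #: Gaussian-blur sigma range in pixels at the 224 px reference
    #: resolution; applied sigma scales with the actual image size so a
    #: blur that is mild at 224 px does not erase point lesions at 64 px.
    blur_sigma_range: tuple[float, float] = (0.8, 1.2)
    brightness_jitter: float = 0.2
    contrast_jitter: float = 0.2

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.vflip_prob, self.blur_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


IDENTITY_POLICY = AugmentationPolicy(
    rotation_deg=0.0,
    hflip_prob=0.0,
    vflip_prob=0.0,
    blur_prob=0.0,
    brightness_jitter=0.0,
    contrast_jitter=0.0,
)


@dataclass
class DatasetPartition:
    """Disjoint train/val/test lists plus the split bookkeeping."""

    train: list[LabeledSample]
    val: list[LabeledSample]
    test: list[LabeledSample]
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 42

    def manifest_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["id_code", "diagnosis", "split"])
            for name in ("train", "val", "test"):
                for s in getattr(self, name):
                    writer.writerow([s.id, s.grade, name])


def class_counts(samples: Sequence[LabeledSample]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for s in samples:
        counts[s.grade] = counts.get(s.grade, 0) + 1
    return counts


def load_labeled_images(
    image_dir: str | Path,
    label_csv: str | Path,
    target_size: int = 224,
) -> list[LabeledSample]:
    """Read an APTOS-style directory: PNG/JPEG images + ``id_code,diagnosis`` CSV.

    Images are resized to ``target_size`` (bilinear) and scaled to [0, 1];
    output order matches CSV row order.
    """
    image_dir = Path(image_dir)
    samples = []
    with open(label_csv, newline="") as fh:
        for row in csv.DictReader(fh):
            sid, raw_grade = row["id_code"], row["diagnosis"]
            try:
                grade = int(raw_grade)
            except ValueError:
                raise LabelError(f"non-integer grade {raw_grade!r} for id {sid!r}")
            if grade not in GRADES:
                raise LabelError(f"grade {grade} outside {GRADES} for id {sid!r}")
            for ext in _IMG_EXTENSIONS:
                path = image_dir / f"{sid}{ext}"
                if path.exists():
                    break
            else:
                raise LookupError(f"no image file found for id {sid!r} in {image_dir}")
            with Image.open(path) as im:
                im = im.convert("RGB").resize(
                    (target_size, target_size), Image.BILINEAR
                )
                arr = np.asarray(im, dtype=np.float64) / 255.0
            samples.append(LabeledSample(id=sid, image=arr, grade=grade))
    return samples


def stratified_split(
    samples: Sequence[LabeledSample],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 42,
) -> DatasetPartition:
    """Per-class 70/15/15 split preserving class distributions.

    Validation and test take ``floor(fraction * class size)`` samples per
    class; the remainder stays in train, keeping test deterministic and
    every partition non-empty for rare classes.  Deterministic under
    ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[LabeledSample]] = {}
    for s in samples:
        by_class.setdefault(s.grade, []).append(s)
    train, val, test = [], [], []
    for grade in sorted(by_class):
        members = by_class[grade]
        if len(members) < 3:
            raise StratificationError(
                f"class {grade} has {len(members)} samples; at least 3 required"
            )
        order = rng.permutation(len(members))
        n_val = int(np.floor(fractions[1] * len(members)))
        n_test = int(np.floor(fractions[2] * len(members)))
        shuffled = [members[i] for i in order]
        val.extend(shuffled[:n_val])
        test.extend(shuffled[n_val : n_val + n_test])
        train.extend(shuffled[n_val + n_test :])
    return DatasetPartition(
        train=train, val=val, test=test, split_fractions=fractions, seed=seed
    )


def apply_augmentation(
    sample: LabeledSample,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> LabeledSample:
    """One random augmentation draw; shape and grade are preserved."""
    img = sample.image
    if policy.rotation_deg > 0:
        angle = rng.uniform(-policy.rotation_deg, policy.rotation_deg)
        img = rotate(img, angle, mode="constant", cval=0.0, preserve_range=True)
    if policy.hflip_prob > 0 and rng.random() < policy.hflip_prob:
        img = img[:, ::-1]
    if policy.vflip_prob > 0 and rng.random() < policy.vflip_prob:
        img = img[::-1, :]
    if policy.blur_prob > 0 and rng.random() < policy.blur_prob:
        scale = sample.image.shape[0] / 224.0
        sigma = rng.uniform(*policy.blur_sigma_range) * scale
        img = gaussian_filter(img, sigma=(sigma, sigma, 0.0))
    if policy.brightness_jitter > 0:
        img = img + rng.uniform(-policy.brightness_jitter, policy.brightness_jitter)
    if policy.contrast_jitter > 0:
        factor = 1.0 + rng.uniform(-policy.contrast_jitter, policy.contrast_jitter)
        img = (img - 0.5) * factor + 0.5
    img = np.clip(np.ascontiguousarray(img, dtype=np.float64), 0.0, 1.0)
    return replace(sample, image=img)


def balance_by_oversampling(
    train_samples: Sequence[LabeledSample],
    policy: AugmentationPolicy | None = None,
    seed: int = 42,
) -> list[LabeledSample]:
    """Oversample minority classes to the majority count N_max.

    Originals are preserved untouched; additions are augmented duplicates
    cycling through the class's originals, tagged with an ``_aug{k}``
    suffix so their origin lineage stays visible.  Balancing a balanced
    set is the identity.
    """
    policy = AugmentationPolicy() if policy is None else policy
    counts = class_counts(train_samples)
    if not counts or min(counts.values()) == 0:
        raise ValueError("every class present must have at least one sample")
    n_max = max(counts.values())
    rng = np.random.default_rng(seed)
    out = list(train_samples)
    by_class: dict[int, list[LabeledSample]] = {}
    for s in train_samples:
        by_class.setdefault(s.grade, []).append(s)
    for grade in sorted(by_class):
        members = by_class[grade]
        deficit = n_max - len(members)
        for k in range(deficit):
            origin = members[k % len(members)]
            aug = apply_augmentation(origin, policy, rng)
            out.append(replace(aug, id=f"{origin.id}_aug{k // len(members)}"))
    return out


def prepare_partition(
    samples: Sequence[LabeledSample],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 42,
    policy: AugmentationPolicy | None = None,
    balance: bool = True,
    balance_before_split: bool = False,
) -> DatasetPartition:
    """Split, then balance the training partition (default ordering).

    ``balance_before_split=True`` instead balances the full dataset and
    splits afterwards (duplicates may then share lineage across
    partitions; provided for comparison only).
    """
    if balance and balance_before_split:
        balanced = balance_by_oversampling(samples, policy, seed)
        return stratified_split(balanced, fractions, seed)
    part = stratified_split(samples, fractions, seed)
    if balance:
        part.train = balance_by_oversampling(part.train, policy, seed)
    return part
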
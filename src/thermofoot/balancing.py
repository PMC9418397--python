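"""Class-imbalance handling: inverse-frequency weights and augmentation.

Offline augmentation tops every training class up to a common target count
by adding geometrically transformed copies of randomly chosen originals
(rotation, zoom, flip, shear, crop).  Online augmentation perturbs encoded
inputs per training draw (brightness, contrast, blur, small affine).  Both
are applied to the training split only; validation data is never touched.
Augmented copies inherit their source's label - they are never relabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import AffineTransform, resize, warp

from .cohort import CohortRecord, LabeledCohort
from .core import EncodedInput, Thermogram

__all__ = [
    "AugmentationPolicy",
    "inverse_frequency_weights",
    "offline_balance",
    "online_augment",
    "apply_brightness_contrast",
]


@dataclass
class AugmentationPolicy:
    # offline (geometric, on temperature matrices)
    rotation_deg: float = 15.0
    zoom: tuple[float, float] = (0.9, 1.1)
    hflip: bool = True
    vflip: bool = False
    shear_deg: float = 10.0
    crop_fraction: float = 0.9
    fill_temperature: float = 18.0  # exposed borders -> window low = intensity 0
    # online (photometric + small affine, on encoded [0,1] arrays)
    brightness: float = 0.1
    contrast: float = 0.1
    blur_sigma_max: float = 0.8  # quality degradation
    online_rotation_deg: float = 5.0
    online_translate_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.5 < self.crop_fraction <= 1.0):
            raise ValueError(f"crop_fraction must be in (0.5, 1], got {self.crop_fraction}")
        for name in ("rotation_deg", "shear_deg", "brightness", "contrast",
                     "blur_sigma_max", "online_rotation_deg", "online_translate_frac"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def inverse_frequency_weights(counts) -> np.ndarray:
    """Per-class weights w_c = N / (K * n_c); satisfies sum_c w_c * n_c = N."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("counts must be a non-empty 1-D sequence")
    if np.any(counts <= 0):
        raise ValueError("every class must have at least one sample")
    n_total = counts.sum()
    return n_total / (len(counts) * counts)


def _centered_affine(shape, *, rotation=0.0, zoom=1.0, shear=0.0) -> AffineTransform:
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    to_origin = AffineTransform(translation=-center)
    core = AffineTransform(
        rotation=np.deg2rad(rotation), scale=(zoom, zoom), shear=np.deg2rad(shear)
    )
    back = AffineTransform(translation=center)
    return to_origin + core + back


def _warp_temps(temps: np.ndarray, tform: AffineTransform, fill: float) -> np.ndarray:
    return warp(
        temps, tform.inverse, order=1, cval=fill, preserve_range=True, mode="constant"
    )


def _random_geometric(
    temps: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> tuple[np.ndarray, str]:
    """One random offline transform draw; returns (array, descriptor)."""
    desc = []
    out = temps
    rot = float(rng.uniform(-policy.rotation_deg, policy.rotation_deg))
    zoom = float(rng.uniform(*policy.zoom))
    shear = float(rng.uniform(-policy.shear_deg, policy.shear_deg))
    if rot != 0.0 or zoom != 1.0 or shear != 0.0:
        out = _warp_temps(
            out, _centered_affine(out.shape, rotation=rot, zoom=zoom, shear=shear),
            policy.fill_temperature,
        )
        desc.append(f"rot={rot:.2f};zoom={zoom:.3f};shear={shear:.2f}")
    if policy.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
        desc.append("hflip")
    if policy.vflip and rng.random() < 0.5:
        out = out[::-1, :]
        desc.append("vflip")
    if policy.crop_fraction < 1.0:
        h, w = out.shape
        ch = max(2, round(policy.crop_fraction * h))
        cw = max(2, round(policy.crop_fraction * w))
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        crop = out[top : top + ch, left : left + cw]
        out = resize(crop, (h, w), order=1, anti_aliasing=False, preserve_range=True)
        desc.append(f"crop={policy.crop_fraction:.2f}@({top},{left})")
    return np.ascontiguousarray(out), "|".join(desc) or "identity"


def offline_balance(
    train: LabeledCohort,
    policy: AugmentationPolicy,
    target_per_class: int | None = None,
    seed: int | None = None,
) -> LabeledCohort:
    """Top every class up to ``target_per_class`` with augmented copies.

    Originals are kept untouched; sources for the copies are drawn with
    replacement; each copy records its origin id and transform descriptor.
    Raw duplication and undersampling are not performed - a target below an
    existing class count is an error.
    """
    counts = train.class_counts()
    if not counts:
        raise ValueError("training cohort has no labeled samples")
    if any(r.label is None for r in train):
        raise ValueError("all training samples must be labeled before balancing")
    if target_per_class is None:
        target_per_class = max(counts.values())
    over = {c: n for c, n in counts.items() if n > target_per_class}
    if over:
        raise ValueError(
            f"target_per_class={target_per_class} is below existing counts {over}; "
            "undersampling is not supported"
        )
    rng = np.random.default_rng(policy.seed if seed is None else seed)

    by_class: dict[int, list[CohortRecord]] = {}
    for r in train:
        by_class.setdefault(r.label, []).append(r)

    new_records = list(train.records)
    for cls in sorted(by_class):
        sources = by_class[cls]
        needed = target_per_class - len(sources)
        for k in range(needed):
            src = sources[int(rng.integers(len(sources)))]
            aug_temps, desc = _random_geometric(
                src.thermogram.temperatures, policy, rng
            )
            aug_thermo = Thermogram(
                aug_temps,
                subject_id=f"{src.sample_id}#aug{k}",
                side=src.thermogram.side,
                group=src.thermogram.group,
            )
            new_records.append(
                CohortRecord(
                    thermogram=aug_thermo,
                    label=src.label,
                    tci_true=src.tci_true,
                    origin_id=src.sample_id,
                    transform=desc,
                )
            )
    prov = dict(train.provenance)
    prov["offline_balance"] = {
        "target_per_class": target_per_class,
        "seed": int(policy.seed if seed is None else seed),
        "policy": {k: v for k, v in vars(policy).items()},
    }
    return LabeledCohort(records=new_records, provenance=prov)


def apply_brightness_contrast(
    values: np.ndarray, brightness: float = 0.0, contrast: float = 1.0
) -> np.ndarray:
    """Additive brightness then contrast scaling about mid-gray, clipped to [0,1]."""
    out = values + brightness
    if contrast != 1.0:
        out = (out - 0.5) * contrast + 0.5
    return np.clip(out, 0.0, 1.0)


def online_augment(
    sample: EncodedInput,
    policy: AugmentationPolicy,
    rng: np.random.Generator | int | None = None,
) -> EncodedInput:
    """Per-draw photometric + small-affine perturbation of an encoded input.

    Shape is preserved and intensities stay in [0,1].  Ops whose policy range
    is zero are skipped entirely, so an all-zero policy is an exact identity.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(policy.seed if rng is None else rng)
    out = sample.values.astype(float)

    if policy.online_rotation_deg > 0 or policy.online_translate_frac > 0:
        rot = float(rng.uniform(-policy.online_rotation_deg, policy.online_rotation_deg))
        h, w = out.shape
        ty = float(rng.uniform(-1, 1) * policy.online_translate_frac * h)
        tx = float(rng.uniform(-1, 1) * policy.online_translate_frac * w)
        tform = _centered_affine(out.shape, rotation=rot) + AffineTransform(
            translation=(tx, ty)
        )
        out = warp(out, tform.inverse, order=1, cval=0.0, preserve_range=True)
    if policy.blur_sigma_max > 0:
        sigma = float(rng.uniform(0.0, policy.blur_sigma_max))
        if sigma > 1e-3:
            out = ndimage.gaussian_filter(out, sigma=sigma)
    b = float(rng.uniform(-policy.brightness, policy.brightness)) if policy.brightness else 0.0
    c = 1.0 + (float(rng.uniform(-policy.contrast, policy.contrast)) if policy.contrast else 0.0)
    out = apply_brightness_contrast(out, b, c)
    return replace(sample, values=out)
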
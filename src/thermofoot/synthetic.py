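"""Synthetic plantar thermogram phantoms with exact ground-truth grades.

Control (grade 0) phantoms carry the symmetric "butterfly" pattern: an
elevated arch on an otherwise flat foot, mirror-symmetric about the foot
axis, with regional means close to the control references.  Diabetic
phantoms (grades 1-5) progressively lose the arch pattern and gain
per-angiosome warming solved so that the exact analytic thermal change index
equals a requested target, plus optional asymmetric hotspots.

The phantom is deliberately simple - piecewise-adjusted smooth regions, an
arch ellipse and Gaussian hotspots - because its role is pipeline
verification, not physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .angiosomes import (
    DEFAULT_FRACTIONS,
    DEFAULT_REFERENCES,
    REGIONS,
    ReferenceTemperatures,
    partition_angiosomes,
)
from .cohort import CohortRecord, LabeledCohort
from .core import FootMask, Group, Side, Thermogram

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "GenerationError",
    "CLASS_TCI_INTERVALS",
    "generate_phantom",
    "generate_cohort",
]

#: Half-open (low, high] TCI sampling interval per diabetic grade; grade 5 is
#: open-ended in the grading rule and capped at 7 degC for sampling.
CLASS_TCI_INTERVALS: dict[int, tuple[float, float]] = {
    1: (0.0, 2.0),
    2: (2.0, 3.0),
    3: (3.0, 4.0),
    4: (4.0, 5.0),
    5: (5.0, 7.0),
}

_PHYSICAL_RANGE = (15.0, 45.0)

#: Spread template for per-angiosome warming weights; shuffled per phantom and
#: jittered, then normalized to mean 1 so the analytic TCI is exact.  The
#: built-in spread guarantees medial/lateral asymmetry for diabetic grades.
_WEIGHT_TEMPLATE = np.array([0.6, 0.9, 1.1, 1.4])


class GenerationError(ValueError):
    """Raised when a phantom cannot be built within physical temperature limits."""


@dataclass
class PhantomConfig:
    shape: tuple[int, int] = (180, 80)
    background_temp: float = 20.0
    base_foot_temp: float = 25.75  # grade-0 plantar-zone mean; heel runs 0.5 warmer
    arch_elevation: float = 1.5  # butterfly amplitude in degC
    target_grade: int = 0
    target_tci: float | None = None  # required for grades 1-5
    target_means: tuple[float, float, float, float] | None = None  # overrides tci
    hotspot_count: int = 2
    hotspot_amplitude: float = 1.5
    noise_sd: float = 0.0
    side: Side = Side.RIGHT
    fractions: tuple[float, float] = DEFAULT_FRACTIONS
    references: ReferenceTemperatures = field(default_factory=ReferenceTemperatures)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_grade not in range(6):
            raise ValueError("target_grade must be in 0..5")
        self.side = Side(self.side)
        if self.target_grade >= 1 and self.target_tci is None and self.target_means is None:
            raise ValueError("grades 1-5 need target_tci or target_means")
        if self.target_tci is not None and self.target_grade >= 1:
            lo, hi = CLASS_TCI_INTERVALS[self.target_grade]
            if not (lo < self.target_tci <= hi):
                raise ValueError(
                    f"target_tci {self.target_tci} outside grade-{self.target_grade} "
                    f"interval ({lo}, {hi}]"
                )


@dataclass
class PhantomTruth:
    footprint: np.ndarray  # bool mask, ground-truth foot pixels
    regional_means: np.ndarray  # (4,) exact noise-free regional means, REGIONS order
    tci: float  # analytic TCI against the references
    label: int
    side: Side
    seed: int


def _footprint(shape: tuple[int, int]) -> np.ndarray:
    """Biconvex foot silhouette: forefoot + heel ellipses, mirror-symmetrized."""
    h, w = shape
    rr = np.arange(h)[:, None] / (h - 1)
    cc = np.arange(w)[None, :] / (w - 1)
    cx = 0.5

    def ellipse(r0, c0, ra, ca):
        return ((rr - r0) / ra) ** 2 + ((cc - c0) / ca) ** 2 <= 1.0

    fore = ellipse(0.32, cx, 0.30, 0.40)
    heel = ellipse(0.75, cx, 0.22, 0.28)
    mask = fore | heel
    # exact mirror symmetry about the image's vertical center line
    return mask | mask[:, ::-1]


def _arch_bump(shape: tuple[int, int], amplitude: float) -> np.ndarray:
    """Centered Gaussian arch elevation (the butterfly pattern's bright arc)."""
    h, w = shape
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    r0, c0 = 0.52 * (h - 1), 0.5 * (w - 1)
    sr, sc = 0.16 * h, 0.22 * w
    return amplitude * np.exp(-(((r - r0) / sr) ** 2 + ((c - c0) / sc) ** 2))


def _hotspots(
    shape: tuple[int, int],
    mask: np.ndarray,
    count: int,
    amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    h, w = shape
    out = np.zeros(shape, dtype=float)
    foot_rows, foot_cols = np.nonzero(mask)
    for _ in range(count):
        i = rng.integers(len(foot_rows))
        r0, c0 = foot_rows[i], foot_cols[i]
        sigma = rng.uniform(2.0, 5.0)
        amp = amplitude * rng.uniform(0.5, 1.0)
        r = np.arange(h)[:, None]
        c = np.arange(w)[None, :]
        out += amp * np.exp(-(((r - r0) ** 2 + (c - c0) ** 2) / (2 * sigma**2)))
    return out


def _target_means(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    refs = cfg.references.as_array()
    if cfg.target_means is not None:
        return np.asarray(cfg.target_means, dtype=float)
    if cfg.target_grade == 0:
        base = cfg.base_foot_temp
        return np.array([base, base, base + 0.5, base + 0.5])
    weights = rng.permutation(_WEIGHT_TEMPLATE) + rng.uniform(-0.05, 0.05, size=4)
    weights /= weights.mean()  # all positive -> mean(|w|) = 1 exactly
    return refs + cfg.target_tci * weights


def generate_phantom(cfg: PhantomConfig) -> tuple[Thermogram, PhantomTruth]:
    """Build one phantom thermogram with exact regional-mean ground truth.

    The per-angiosome additive constants are solved after the smooth pattern
    (arch + hotspots) is laid down, so each noise-free regional mean equals
    its target exactly and the analytic TCI equals ``cfg.target_tci`` to
    machine precision.
    """
    rng = np.random.default_rng(cfg.seed)
    mask = _footprint(cfg.shape)
    part = partition_angiosomes(FootMask(mask), cfg.side, cfg.fractions)

    targets = _target_means(cfg, rng)
    lo, hi = _PHYSICAL_RANGE
    if targets.min() < lo or targets.max() > hi:
        raise GenerationError(
            f"regional mean targets {np.round(targets, 2)} outside physical "
            f"range {_PHYSICAL_RANGE}"
        )

    grade = cfg.target_grade
    arch_scale = 1.0 if grade == 0 else max(0.0, 1.0 - grade / 5.0)
    pattern = _arch_bump(cfg.shape, cfg.arch_elevation * arch_scale)
    if grade >= 1 and cfg.hotspot_count > 0:
        pattern = pattern + _hotspots(
            cfg.shape, mask, cfg.hotspot_count, cfg.hotspot_amplitude, rng
        )

    temps = np.full(cfg.shape, cfg.background_temp, dtype=float)
    for i, region in enumerate(REGIONS):
        sel = part.region_mask(region)
        temps[sel] = pattern[sel] + (targets[i] - pattern[sel].mean())

    if cfg.noise_sd > 0:
        temps = temps + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)

    refs = cfg.references.as_array()
    analytic_tci = float(np.abs(refs - targets).mean())
    if cfg.target_means is not None:
        from .angiosomes import assign_severity_class

        label = assign_severity_class(analytic_tci, Group.DIABETIC)
    else:
        label = grade

    group = Group.CONTROL if label == 0 else Group.DIABETIC
    thermo = Thermogram(
        temps, subject_id=f"phantom-{cfg.seed}", side=cfg.side, group=group
    )
    truth = PhantomTruth(
        footprint=mask,
        regional_means=targets,
        tci=analytic_tci,
        label=label,
        side=cfg.side,
        seed=cfg.seed,
    )
    return thermo, truth


def _sample_tci(grade: int, rng: np.random.Generator) -> float:
    lo, hi = CLASS_TCI_INTERVALS[grade]
    # uniform over the half-open (lo, hi]
    return float(hi - rng.uniform(0.0, hi - lo))


def generate_cohort(
    class_counts: dict[int, int],
    *,
    seed: int = 0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (180, 80),
    arch_elevation: float = 1.5,
    hotspot_count: int = 2,
    hotspot_amplitude: float = 1.5,
    out_dir: str | Path | None = None,
) -> LabeledCohort:
    """Generate a labeled cohort with the requested per-class counts.

    Per-phantom target TCIs are sampled uniformly inside each grade's
    interval.  Each phantom gets an independent child seed, a unique subject
    id and a random foot side.  When ``out_dir`` is given, CSV matrices,
    manifest and provenance are written there.
    """
    bad = [c for c in class_counts if c not in range(6)]
    if bad:
        raise ValueError(f"invalid class labels in counts: {bad}")
    if any(n < 0 for n in class_counts.values()):
        raise ValueError("class counts must be >= 0")
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("all class counts are zero")

    master = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    idx = 0
    for grade in sorted(class_counts):
        for _ in range(class_counts[grade]):
            child_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(child_seed)
            side = Side.LEFT if rng.random() < 0.5 else Side.RIGHT
            cfg = PhantomConfig(
                shape=shape,
                arch_elevation=arch_elevation,
                target_grade=grade,
                target_tci=None if grade == 0 else _sample_tci(grade, rng),
                hotspot_count=hotspot_count,
                hotspot_amplitude=hotspot_amplitude,
                noise_sd=noise_sd,
                side=side,
                seed=child_seed,
            )
            thermo, truth = generate_phantom(cfg)
            thermo.subject_id = f"S{idx:04d}"
            records.append(
                CohortRecord(
                    thermogram=thermo,
                    label=truth.label,
                    tci_true=truth.tci,
                    footprint=truth.footprint,
                )
            )
            idx += 1

    cohort = LabeledCohort(
        records=records,
        provenance={
            "generator": "thermofoot.synthetic.generate_cohort",
            "seed": seed,
            "noise_sd": noise_sd,
            "shape": list(shape),
            "class_counts": {str(k): v for k, v in sorted(class_counts.items())},
        },
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
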
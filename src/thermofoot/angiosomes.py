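"""Angiosome partitioning, regional means, thermal change index and grading.

The foot is divided into four arterial supply regions: medial plantar (MPA),
lateral plantar (LPA), medial calcaneal (MCA) and lateral calcaneal (LCA).
The thermal change index (TCI) of a foot is the mean absolute difference
between its four regional mean temperatures and fixed control-group reference
temperatures.  Diabetic feet are graded 1-5 from the TCI; control feet are
class 0 by group membership, never by TCI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FootMask, Group, Side, Thermogram, segment_foot

__all__ = [
    "REGIONS",
    "ReferenceTemperatures",
    "AngiosomePartition",
    "TCIResult",
    "PartitionError",
    "partition_angiosomes",
    "regional_mean_temperatures",
    "compute_tci",
    "assign_severity_class",
    "grade_thermogram",
    "DEFAULT_FRACTIONS",
]

#: Region order used for all 4-vectors: (MPA, LPA, MCA, LCA).
REGIONS: tuple[str, ...] = ("MPA", "LPA", "MCA", "LCA")

#: Label codes in the partition matrix; 0 is background.
REGION_CODES = {"MPA": 1, "LPA": 2, "MCA": 3, "LCA": 4}

#: (calcaneal length fraction, medial width fraction).  The posterior
#: `calcaneal` fraction of the foot's bounding-box length forms the heel zone;
#: the medial fraction of its width separates medial from lateral columns.
DEFAULT_FRACTIONS: tuple[float, float] = (0.27, 0.5)


class PartitionError(ValueError):
    """Raised when a foot cannot be split into four non-empty angiosomes."""


@dataclass(frozen=True)
class ReferenceTemperatures:
    """Control-group mean temperature per angiosome, in degC."""

    mpa: float = 25.8
    lpa: float = 25.7
    mca: float = 26.4
    lca: float = 26.1

    def as_array(self) -> np.ndarray:
        return np.array([self.mpa, self.lpa, self.mca, self.lca], dtype=float)


DEFAULT_REFERENCES = ReferenceTemperatures()


@dataclass
class AngiosomePartition:
    """Per-pixel assignment of foot pixels to the four angiosomes."""

    labels: np.ndarray  # int matrix over REGION_CODES values, 0 = background
    fractions: tuple[float, float]
    side: Side

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == REGION_CODES[region]

    def region_sizes(self) -> dict[str, int]:
        return {r: int(np.count_nonzero(self.region_mask(r))) for r in REGIONS}


@dataclass
class TCIResult:
    regional_means: np.ndarray  # (4,) degC, REGIONS order
    references: ReferenceTemperatures
    tci: float
    severity_class: int
    meta: dict = field(default_factory=dict)


def partition_angiosomes(
    mask: FootMask,
    side: Side | str,
    fractions: tuple[float, float] = DEFAULT_FRACTIONS,
) -> AngiosomePartition:
    """Split a foot mask into MPA/LPA/MCA/LCA over its bounding box.

    The posterior `calcaneal_fraction` of the bounding-box rows forms the
    calcaneal zone; both zones are split at `medial_fraction` of the
    bounding-box width.  Medial means low columns for a right foot and high
    columns for a left foot (mirrored image convention).
    """
    side = Side(side)
    cal_frac, med_frac = fractions
    if not (0.0 < cal_frac < 1.0 and 0.0 < med_frac < 1.0):
        raise ValueError(f"fractions must lie in (0,1), got {fractions}")
    if not mask.any_foot:
        raise PartitionError("cannot partition an empty mask")

    r0, r1, c0, c1 = mask.bounding_box()
    length = r1 - r0
    width = c1 - c0
    n_cal = min(max(1, round(cal_frac * length)), length - 1)
    n_med = min(max(1, round(med_frac * width)), width - 1)
    cal_start = r1 - n_cal

    rows = np.arange(mask.shape[0])[:, None]
    cols = np.arange(mask.shape[1])[None, :]
    posterior = rows >= cal_start
    if side is Side.RIGHT:
        medial = cols < c0 + n_med
    else:
        medial = cols >= c1 - n_med

    labels = np.zeros(mask.shape, dtype=np.int8)
    m = mask.mask
    labels[m & ~posterior & medial] = REGION_CODES["MPA"]
    labels[m & ~posterior & ~medial] = REGION_CODES["LPA"]
    labels[m & posterior & medial] = REGION_CODES["MCA"]
    labels[m & posterior & ~medial] = REGION_CODES["LCA"]

    part = AngiosomePartition(labels=labels, fractions=(cal_frac, med_frac), side=side)
    for region, size in part.region_sizes().items():
        if size == 0:
            raise PartitionError(f"angiosome {region} is empty for this foot")
    return part


def regional_mean_temperatures(t: Thermogram, p: AngiosomePartition) -> np.ndarray:
    """Arithmetic mean temperature over each angiosome, in REGIONS order."""
    if p.shape != t.shape:
        raise ValueError(f"partition shape {p.shape} != thermogram shape {t.shape}")
    means = np.empty(4, dtype=float)
    for i, region in enumerate(REGIONS):
        sel = p.region_mask(region)
        if not sel.any():
            raise PartitionError(f"angiosome {region} is empty")
        means[i] = t.temperatures[sel].mean()
    return means


def compute_tci(
    means: np.ndarray | tuple[float, float, float, float],
    refs: ReferenceTemperatures = DEFAULT_REFERENCES,
) -> float:
    """Mean absolute difference between regional means and the references."""
    means = np.asarray(means, dtype=float)
    if means.shape != (4,):
        raise ValueError(f"expected four regional means, got shape {means.shape}")
    if not np.all(np.isfinite(means)):
        raise ValueError("regional means must be finite")
    return float(np.abs(refs.as_array() - means).mean())


def assign_severity_class(tci: float, group: Group | str) -> int:
    """Map TCI to class 1-5 for diabetic feet; controls are class 0.

    Bins are upper-inclusive: TCI <= 2 -> 1, 2 < TCI <= 3 -> 2,
    3 < TCI <= 4 -> 3, 4 < TCI <= 5 -> 4, TCI > 5 -> 5.
    """
    if tci < 0:
        raise ValueError(f"TCI must be non-negative, got {tci}")
    if Group(group) is Group.CONTROL:
        return 0
    for upper, cls in ((2.0, 1), (3.0, 2), (4.0, 3), (5.0, 4)):
        if tci <= upper:
            return cls
    return 5


def grade_thermogram(
    t: Thermogram,
    mask: FootMask | None = None,
    *,
    fractions: tuple[float, float] = DEFAULT_FRACTIONS,
    refs: ReferenceTemperatures = DEFAULT_REFERENCES,
    ambient_ceiling: float = 22.0,
) -> TCIResult:
    """Full labeling pipeline: segment, partition, means, TCI, class.

    The TCI is computed and reported for control feet too (diagnostics), but
    their class is always 0.
    """
    if mask is None:
        mask = segment_foot(t, ambient_ceiling=ambient_ceiling)
    part = partition_angiosomes(mask, t.side, fractions)
    means = regional_mean_temperatures(t, part)
    tci = compute_tci(means, refs)
    cls = assign_severity_class(tci, t.group)
    return TCIResult(
        regional_means=means,
        references=refs,
        tci=tci,
        severity_class=cls,
        meta={"fractions": fractions, "region_sizes": part.region_sizes()},
    )
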
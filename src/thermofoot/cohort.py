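"""Labeled cohort container: thermograms + labels + provenance, on disk or in memory.

The on-disk layout is a directory of headerless CSV temperature matrices plus
a ``manifest.csv`` with columns ``subject_id, side, group, path, class,
tci_true, origin_id, transform``.  Externally acquired matrix-format cohorts
can be pointed at through the same manifest convention (class/tci columns may
be left blank and filled by the labeling stage).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Group, Side, Thermogram, read_temperature_matrix, write_temperature_matrix

__all__ = ["CohortRecord", "LabeledCohort", "load_cohort"]


@dataclass
class CohortRecord:
    thermogram: Thermogram
    label: int | None = None
    tci_true: float | None = None
    footprint: np.ndarray | None = None  # ground-truth mask when synthetic
    origin_id: str | None = None  # source sample for augmented copies
    transform: str | None = None  # human-readable transform descriptor

    @property
    def sample_id(self) -> str:
        return self.thermogram.subject_id

    @property
    def is_augmented(self) -> bool:
        return self.origin_id is not None


@dataclass
class LabeledCohort:
    records: list[CohortRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> CohortRecord:
        return self.records[i]

    @property
    def labels(self) -> np.ndarray:
        return np.array([-1 if r.label is None else r.label for r in self.records])

    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for r in self.records:
            if r.label is not None:
                counts[r.label] = counts.get(r.label, 0) + 1
        return dict(sorted(counts.items()))

    def subset(self, indices) -> "LabeledCohort":
        return LabeledCohort(
            records=[self.records[int(i)] for i in indices],
            provenance=dict(self.provenance),
        )

    def manifest(self, paths: dict[str, str] | None = None) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.sample_id,
                    "side": r.thermogram.side.value,
                    "group": r.thermogram.group.value,
                    "path": (paths or {}).get(r.sample_id, ""),
                    "class": r.label,
                    "tci_true": r.tci_true,
                    "origin_id": r.origin_id,
                    "transform": r.transform,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> Path:
        """Write matrices + manifest.csv + provenance.json; returns manifest path."""
        out_dir = Path(out_dir)
        matrices = out_dir / "matrices"
        matrices.mkdir(parents=True, exist_ok=True)
        paths = {}
        for r in self.records:
            rel = f"matrices/{r.sample_id}.csv"
            write_temperature_matrix(r.thermogram, out_dir / rel)
            paths[r.sample_id] = rel
        manifest_path = out_dir / "manifest.csv"
        self.manifest(paths).to_csv(manifest_path, index=False)
        with (out_dir / "provenance.json").open("w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)
        return manifest_path

    def with_updated_labels(self, labels: list[int]) -> "LabeledCohort":
        if len(labels) != len(self.records):
            raise ValueError("label count does not match cohort size")
        return LabeledCohort(
            records=[replace(r, label=int(l)) for r, l in zip(self.records, labels)],
            provenance=dict(self.provenance),
        )


def load_cohort(manifest_path: str | Path) -> LabeledCohort:
    """Load a cohort from a manifest CSV; matrix paths are manifest-relative."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"subject_id", "side", "group", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"manifest {manifest_path} has no rows")
    base = manifest_path.parent

    def _opt(row: dict, key: str, cast):
        val = row.get(key)
        if val is None or pd.isna(val):
            return None
        return cast(val)

    records = []
    for row in df.to_dict("records"):
        t = read_temperature_matrix(
            base / str(row["path"]),
            subject_id=str(row["subject_id"]),
            side=Side(str(row["side"])),
            group=Group(str(row["group"])),
        )
        records.append(
            CohortRecord(
                thermogram=t,
                label=_opt(row, "class", int),
                tci_true=_opt(row, "tci_true", float),
                origin_id=_opt(row, "origin_id", str),
                transform=_opt(row, "transform", str),
            )
        )
    return LabeledCohort(records=records, provenance={"manifest": str(manifest_path)})
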
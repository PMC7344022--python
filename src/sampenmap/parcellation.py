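"""Parcel-level aggregation of voxelwise entropy maps.

An integer label atlas assigns every voxel to a named ROI (0 = background).
Entropy is computed voxelwise first and then averaged within each parcel —
mean of voxel entropies, never entropy of the mean signal — and the
per-scan ROI summaries are assembled into the scans x ROIs table that all
group statistics consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DuplicateScanError, GridMismatchError, UnknownClassError
from .images import EntropyMap3D

ROI_CLASSES = ("cortical", "subcortical", "network")

CONDITIONS = ("rest", "task")


@dataclass
class AtlasLabels3D:
    """Integer parcel labels on a 3D grid with name/class metadata."""

    labels: np.ndarray
    label_names: dict[int, str]
    label_class: dict[int, str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D lattice")
        if np.any(self.labels < 0):
            raise ValueError("labels must be nonnegative (0 = background)")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        missing = present - set(self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        bad = {c for c in self.label_class.values() if c not in ROI_CLASSES}
        if bad:
            raise ValueError(f"unknown ROI classes: {sorted(bad)}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def parcel_labels(self) -> list[int]:
        """Declared labels, sorted."""
        return sorted(self.label_names)

    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass(frozen=True)
class ScanMetadata:
    subject_id: str
    condition: str
    scan_index: int
    phase_encode: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.scan_index not in (1, 2):
            raise ValueError("scan_index must be 1 or 2")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.condition, self.scan_index)


@dataclass
class AtlasValidationReport:
    grid_shape: tuple[int, int, int]
    parcel_labels: list[int]
    voxel_counts: dict[int, int]
    empty_labels: list[int]
    warnings: list[str]


def validate_atlas(atlas: AtlasLabels3D, grid_shape: Sequence[int]) -> AtlasValidationReport:
    """Check an atlas against a data grid; raise on shape mismatch.

    Empty parcels are flagged as warnings, not errors, so partial atlases
    stay usable.
    """
    grid_shape = tuple(grid_shape)
    if atlas.grid_shape != grid_shape:
        raise GridMismatchError(f"atlas grid {atlas.grid_shape} != data grid {grid_shape}")
    counts = np.bincount(atlas.labels.ravel())
    voxel_counts = {
        lab: int(counts[lab]) if lab < len(counts) else 0 for lab in atlas.parcel_labels
    }
    empty = [lab for lab, c in voxel_counts.items() if c == 0]
    warnings = [
        f"parcel {lab} ({atlas.label_names[lab]}) has zero voxels" for lab in empty
    ]
    return AtlasValidationReport(
        grid_shape=grid_shape,
        parcel_labels=atlas.parcel_labels,
        voxel_counts=voxel_counts,
        empty_labels=empty,
        warnings=warnings,
    )


def roi_summary(emap: EntropyMap3D, atlas: AtlasLabels3D) -> pd.DataFrame:
    """Per-parcel mean/SD over defined voxel entropies, plus valid counts.

    Parcels with no defined voxel yield NaN mean and SD; SD is the sample
    SD (ddof=1) and is NaN for single-voxel parcels.
    """
    if emap.grid_shape != atlas.grid_shape:
        raise GridMismatchError(f"map grid {emap.grid_shape} != atlas grid {atlas.grid_shape}")
    labels = atlas.labels.ravel()
    values = emap.values.ravel()
    ok = (labels > 0) & np.isfinite(values)
    lab_ok = labels[ok]
    val_ok = values[ok]
    size = max(atlas.parcel_labels, default=0) + 1
    n = np.bincount(lab_ok, minlength=size).astype(np.int64)
    s1 = np.bincount(lab_ok, weights=val_ok, minlength=size)
    s2 = np.bincount(lab_ok, weights=val_ok * val_ok, minlength=size)
    rows = []
    for lab in atlas.parcel_labels:
        count = int(n[lab])
        if count == 0:
            mean = sd = np.nan
        else:
            mean = s1[lab] / count
            sd = (
                float(np.sqrt(max(s2[lab] - count * mean * mean, 0.0) / (count - 1)))
                if count > 1
                else np.nan
            )
        rows.append(
            {
                "label": lab,
                "name": atlas.label_names[lab],
                "class": atlas.label_class.get(lab, "cortical"),
                "mean": mean,
                "sd": sd,
                "n_valid": count,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RoiEntropyTable:
    """Scans x ROIs entropy summaries plus per-scan metadata.

    ``mean``, ``sd`` and ``n_valid`` are DataFrames indexed like ``meta``
    (one row per scan, deterministic subject/condition/scan order) with
    one column per ROI name.  ``roi_info`` carries label/name/class per
    column.  A mean cell is NaN iff its n_valid is 0.
    """

    meta: pd.DataFrame
    mean: pd.DataFrame
    sd: pd.DataFrame
    n_valid: pd.DataFrame
    roi_info: pd.DataFrame

    @property
    def roi_names(self) -> list[str]:
        return list(self.mean.columns)

    def class_names(self, roi_class: str) -> list[str]:
        """ROI column names belonging to ``roi_class``."""
        if roi_class not in ROI_CLASSES:
            raise UnknownClassError(f"unknown ROI class {roi_class!r}")
        names = list(self.roi_info.loc[self.roi_info["class"] == roi_class, "name"])
        if not names:
            raise UnknownClassError(f"no ROI of class {roi_class!r} in table")
        return names

    def select(self, condition: str) -> "RoiEntropyTable":
        """Rows of one condition, as a new table."""
        keep = self.meta["condition"] == condition
        idx = np.flatnonzero(keep.to_numpy())
        return RoiEntropyTable(
            meta=self.meta.iloc[idx].reset_index(drop=True),
            mean=self.mean.iloc[idx].reset_index(drop=True),
            sd=self.sd.iloc[idx].reset_index(drop=True),
            n_valid=self.n_valid.iloc[idx].reset_index(drop=True),
            roi_info=self.roi_info,
        )

    def to_csv(self, path, roi_info_path=None) -> None:
        path = Path(path)
        wide = self.meta.copy()
        for prefix, frame in (("mean", self.mean), ("sd", self.sd), ("n", self.n_valid)):
            for col in frame.columns:
                wide[f"{prefix}.{col}"] = frame[col].to_numpy()
        wide.to_csv(path, index=False, float_format="%.17g")  # exact round trip
        sidecar = Path(roi_info_path) if roi_info_path else path.with_suffix(".roi.json")
        sidecar.write_text(
            json.dumps(self.roi_info.to_dict(orient="records"), indent=1)
        )

    @classmethod
    def from_csv(cls, path, roi_info_path=None) -> "RoiEntropyTable":
        path = Path(path)
        wide = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
        sidecar = Path(roi_info_path) if roi_info_path else path.with_suffix(".roi.json")
        roi_info = pd.DataFrame(json.loads(sidecar.read_text()))
        meta_cols = [c for c in wide.columns if "." not in c]
        names = list(roi_info["name"])
        return cls(
            meta=wide[meta_cols].copy(),
            mean=wide[[f"mean.{n}" for n in names]].rename(
                columns=lambda c: c.split(".", 1)[1]
            ),
            sd=wide[[f"sd.{n}" for n in names]].rename(columns=lambda c: c.split(".", 1)[1]),
            n_valid=wide[[f"n.{n}" for n in names]].rename(
                columns=lambda c: c.split(".", 1)[1]
            ),
            roi_info=roi_info,
        )


def build_cohort_table(
    maps: Iterable[tuple[EntropyMap3D, ScanMetadata]], atlas: AtlasLabels3D
) -> RoiEntropyTable:
    """Assemble per-scan ROI summaries into one deterministic table.

    Rows are sorted by (subject_id, condition, scan_index); duplicate scan
    keys raise DuplicateScanError.
    """
    entries = []
    seen = set()
    for emap, md in maps:
        if md.key in seen:
            raise DuplicateScanError(f"duplicate scan {md.key}")
        seen.add(md.key)
        entries.append((md, roi_summary(emap, atlas)))
    entries.sort(key=lambda e: e[0].key)
    if not entries:
        raise ValueError("no scans provided")
    roi_info = entries[0][1][["label", "name", "class"]].copy()
    names = list(roi_info["name"])
    meta = pd.DataFrame(
        {
            "subject_id": [md.subject_id for md, _ in entries],
            "condition": [md.condition for md, _ in entries],
            "scan_index": [md.scan_index for md, _ in entries],
        }
    )
    mean = pd.DataFrame([s["mean"].to_numpy() for _, s in entries], columns=names)
    sd = pd.DataFrame([s["sd"].to_numpy() for _, s in entries], columns=names)
    n_valid = pd.DataFrame(
        [s["n_valid"].to_numpy() for _, s in entries], columns=names
    )
    return RoiEntropyTable(meta=meta, mean=mean, sd=sd, n_valid=n_valid, roi_info=roi_info)


def class_aggregate(
    table: RoiEntropyTable, roi_class: str, weighted: bool = False
) -> pd.Series:
    """Per-scan scalar: mean entropy over all ROIs of one class.

    Unweighted by default (each ROI counts once); ``weighted=True``
    weights ROIs by their valid-voxel counts.
    """
    names = table.class_names(roi_class)
    sub = table.mean[names]
    if not weighted:
        return sub.mean(axis=1)
    w = table.n_valid[names].to_numpy(dtype=float)
    vals = sub.to_numpy()
    with np.errstate(invalid="ignore"):
        num = np.nansum(np.where(np.isfinite(vals), vals * w, 0.0), axis=1)
        den = np.where(np.isfinite(vals), w, 0.0).sum(axis=1)
    return pd.Series(num / den, index=sub.index)


# ---------------------------------------------------------------------------
# Atlas NIfTI round trip

def save_atlas(atlas: AtlasLabels3D, labels_path, sidecar_path=None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), atlas.affine)
    nib.save(img, str(labels_path))
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(labels_path)).with_suffix(
        ".labels.json"
    )
    payload = {
        str(lab): {"name": atlas.label_names[lab], "class": atlas.label_class[lab]}
        for lab in atlas.parcel_labels
    }
    sidecar.write_text(json.dumps(payload, indent=1))


def load_atlas(labels_path, sidecar_path=None) -> AtlasLabels3D:
    img = nib.load(str(labels_path))
    labels = np.asanyarray(img.dataobj).astype(np.int32)
    sidecar = Path(sidecar_path) if sidecar_path else Path(str(labels_path)).with_suffix(
        ".labels.json"
    )
    payload = json.loads(sidecar.read_text())
    return AtlasLabels3D(
        labels=labels,
        label_names={int(k): v["name"] for k, v in payload.items()},
        label_class={int(k): v["class"] for k, v in payload.items()},
        affine=img.affine,
    )
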
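"""Synthetic 4D fMRI-like cohorts with known complexity ground truth.

The generator emulates the statistical structure a brain-entropy analysis
assumes, without claiming hemodynamic realism.  Each parcel's voxels are
independent AR(1) series x_t = phi * x_{t-1} + eps_t; the coefficient phi
is the single complexity knob (higher phi => more temporal regularity =>
lower sample entropy).  The effective phi of a parcel in a given scan is

    phi = phi_base(condition) + subject_offset + scan_offset

clipped to [0, 0.98]:

* ``phi_task_delta >= 0`` raises regularity under task, encoding the
  rest-entropy > task-entropy direction;
* Gaussian per-subject offsets (``subject_sd``) are shared by all of a
  subject's scans and drive test-retest ICC;
* Gaussian per-scan global offsets (``shared_scan_sd``) hit every parcel
  in a scan at once and drive high between-ROI entropy correlations.

Every cohort is reproducible bit-for-bit from (config, seed), and the
returned ground-truth record stores each realized phi.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._kernels import ar1_batch
from .errors import GridTooSmallError, NonstationaryPhiError
from .images import Bold4D
from .parcellation import AtlasLabels3D, ScanMetadata

PHI_MAX = 0.98


@dataclass(frozen=True)
class ParcelSpec:
    """One synthetic parcel: label, class, size, and complexity knobs."""

    label: int
    name: str
    roi_class: str
    phi_rest: float
    phi_task_delta: float
    voxel_count: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi_rest <= PHI_MAX:
            raise ValueError(f"phi_rest must be in [0, {PHI_MAX}]")
        if self.phi_task_delta < 0 or self.phi_rest + self.phi_task_delta > PHI_MAX:
            raise ValueError("phi_task_delta must be >= 0 and keep phi within range")
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the target acquisition scale: 405 time points per
    scan (~5 min at TR = 0.72 s), two rest plus two task scans per
    subject, with random-effect SDs sized to yield moderate test-retest
    reliability and strong shared cross-subject variation.
    """

    n_subjects: int
    parcels: list[ParcelSpec]
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 405
    rest_timepoints: Optional[int] = None  # long-rest mode; None = matched lengths
    subject_sd: float = 0.045
    shared_scan_sd: float = 0.04
    innovation_sd: float = 1.0
    tr: float = 0.72
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if min(self.subject_sd, self.shared_scan_sd, self.innovation_sd) < 0:
            raise ValueError("SDs must be >= 0")
        labels = [p.label for p in self.parcels]
        if len(labels) != len(set(labels)) or 0 in labels:
            raise ValueError("parcel labels must be unique and nonzero")


@dataclass
class GroundTruthRecord:
    """Everything needed to recompute the cohort: realized phis and offsets."""

    seed: int
    phi: pd.DataFrame  # columns subject_id, condition, scan_index, label, phi
    subject_offsets: dict[str, float]
    scan_offsets: dict[tuple[str, str, int], float]
    n_clipped: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "n_clipped": self.n_clipped,
            "subject_offsets": self.subject_offsets,
            "scan_offsets": {
                f"{s}|{c}|{i}": v for (s, c, i), v in self.scan_offsets.items()
            },
            "phi": self.phi.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def demo_parcels(network_voxels: int = 160, region_voxels: int = 80) -> list[ParcelSpec]:
    """The default parcel set: 7 cortical networks plus cortical and
    subcortical region groups.

    phi is graded so that (a) entropy is higher at rest than under task in
    every parcel, (b) subcortical parcels are less regular (higher
    entropy) than cortical ones, and (c) the network ranking follows the
    frontoparietal-high / somatomotor-low rest pattern.
    """
    nets = [
        ("visual", 0.550, 0.09),
        ("somatomotor", 0.580, 0.05),
        ("dorsal_attention", 0.550, 0.05),
        ("ventral_attention", 0.550, 0.07),
        ("limbic", 0.565, 0.08),
        ("frontoparietal", 0.520, 0.10),
        ("default_mode", 0.545, 0.07),
    ]
    cort = [("frontal_ctx", 0.55, 0.08), ("parietal_ctx", 0.56, 0.08), ("temporal_ctx", 0.55, 0.08)]
    subc = [("thalamus", 0.45, 0.07), ("caudate", 0.46, 0.07), ("hippocampus", 0.44, 0.07)]
    parcels = []
    label = 1
    for name, phi, delta in nets:
        parcels.append(ParcelSpec(label, name, "network", phi, delta, network_voxels))
        label += 1
    for name, phi, delta in cort:
        parcels.append(ParcelSpec(label, name, "cortical", phi, delta, region_voxels))
        label += 1
    for name, phi, delta in subc:
        parcels.append(ParcelSpec(label, name, "subcortical", phi, delta, region_voxels))
        label += 1
    return parcels


def make_block_atlas(grid_shape, parcels: list[ParcelSpec], affine=None) -> AtlasLabels3D:
    """Deterministic contiguous-block label layout in C order.

    Each parcel receives exactly its voxel_count voxels; the remainder of
    the grid is background 0.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    total = int(np.prod(grid_shape))
    needed = sum(p.voxel_count for p in parcels)
    if needed > total:
        raise GridTooSmallError(f"parcels need {needed} voxels, grid has {total}")
    flat = np.zeros(total, dtype=np.int32)
    pos = 0
    for p in parcels:
        flat[pos : pos + p.voxel_count] = p.label
        pos += p.voxel_count
    return AtlasLabels3D(
        labels=flat.reshape(grid_shape),
        label_names={p.label: p.name for p in parcels},
        label_class={p.label: p.roi_class for p in parcels},
        affine=np.eye(4) if affine is None else affine,
    )


def simulate_voxel_series(phi: float, n: int, innovation_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """One stationary AR(1) series of length n, deterministic given seed."""
    if not -1.0 < phi < 1.0:
        raise NonstationaryPhiError(f"|phi| must be < 1, got {phi}")
    rng = np.random.default_rng(seed)
    innov = rng.standard_normal((1, n)) * innovation_sd
    out = np.empty((1, n))
    ar1_batch(np.array([float(phi)]), innov, out)
    return out[0]


def _scan_order(config: CohortConfig) -> list[ScanMetadata]:
    subjects = [f"sub-{i:03d}" for i in range(1, config.n_subjects + 1)]
    order = []
    for s in subjects:
        for cond in ("rest", "task"):
            for idx in (1, 2):
                order.append(ScanMetadata(subject_id=s, condition=cond, scan_index=idx))
    return order


def simulate_cohort(
    config: CohortConfig,
) -> tuple[list[tuple[Bold4D, ScanMetadata]], AtlasLabels3D, GroundTruthRecord]:
    """Generate a full cohort: 4 scans (2 rest + 2 task) per subject.

    Per scan, every voxel of a parcel is an independent AR(1) draw at the
    parcel's effective phi.  The random stream order is fixed (subject
    offsets, then all scan offsets in subject/condition/scan order, then
    innovations in the same scan order), so identical (config, seed) give
    bit-identical cohorts.  Innovations are drawn and propagated in
    multi-scan batches to amortise RNG and kernel calls; batching does
    not change the stream.
    """
    atlas = make_block_atlas(config.grid_shape, config.parcels)
    rng = np.random.default_rng(config.seed)
    order = _scan_order(config)
    n_scans = len(order)
    subjects = sorted({md.subject_id for md in order})
    subj_draw = rng.standard_normal(len(subjects)) * config.subject_sd
    subject_offsets = {s: float(v) for s, v in zip(subjects, subj_draw)}
    scan_draw = rng.standard_normal(n_scans) * config.shared_scan_sd
    scan_offsets = {md.key: float(v) for md, v in zip(order, scan_draw)}

    flat_labels = atlas.labels.ravel()
    in_mask = np.flatnonzero(flat_labels > 0)
    label_of_voxel = flat_labels[in_mask]
    labels = np.array([p.label for p in config.parcels])
    # voxel -> parcel position, for broadcasting per-scan parcel phis
    parcel_pos = {lab: i for i, lab in enumerate(labels)}
    voxel_parcel = np.array([parcel_pos[lab] for lab in label_of_voxel])

    phi_rest = np.array([p.phi_rest for p in config.parcels])
    phi_delta = np.array([p.phi_task_delta for p in config.parcels])
    is_task = np.array([md.condition == "task" for md in order])
    subj_of_scan = np.array([subject_offsets[md.subject_id] for md in order])
    phi_raw = (
        phi_rest[None, :]
        + np.where(is_task[:, None], phi_delta[None, :], 0.0)
        + subj_of_scan[:, None]
        + scan_draw[:, None]
    )
    phi_eff = np.clip(phi_raw, 0.0, PHI_MAX)
    n_clipped = int(np.count_nonzero(phi_eff != phi_raw))

    n_t_of_scan = [
        config.rest_timepoints
        if (md.condition == "rest" and config.rest_timepoints)
        else config.n_timepoints
        for md in order
    ]
    n_voxels = in_mask.size
    grid_vol = int(np.prod(config.grid_shape))
    scans: list[tuple[Bold4D, ScanMetadata]] = []
    # batch consecutive scans of equal length, capped for memory
    max_elements = 20_000_000
    start = 0
    while start < n_scans:
        stop = start + 1
        while (
            stop < n_scans
            and n_t_of_scan[stop] == n_t_of_scan[start]
            and (stop - start + 1) * n_voxels * n_t_of_scan[start] <= max_elements
        ):
            stop += 1
        n_t = n_t_of_scan[start]
        count = stop - start
        innov = rng.standard_normal((count * n_voxels, n_t)) * config.innovation_sd
        phi_flat = phi_eff[start:stop][:, voxel_parcel].reshape(-1)
        series = np.empty_like(innov)
        ar1_batch(phi_flat, innov, series)
        for k in range(count):
            data = np.zeros((grid_vol, n_t))
            data[in_mask] = series[k * n_voxels : (k + 1) * n_voxels]
            vol = Bold4D(
                data=data.reshape(config.grid_shape + (n_t,)),
                affine=atlas.affine,
                tr=config.tr,
            )
            scans.append((vol, order[start + k]))
        start = stop

    n_parcels = len(config.parcels)
    truth = GroundTruthRecord(
        seed=config.seed,
        phi=pd.DataFrame(
            {
                "subject_id": np.repeat([md.subject_id for md in order], n_parcels),
                "condition": np.repeat([md.condition for md in order], n_parcels),
                "scan_index": np.repeat([md.scan_index for md in order], n_parcels),
                "label": np.tile(labels, n_scans),
                "name": np.tile([p.name for p in config.parcels], n_scans),
                "class": np.tile([p.roi_class for p in config.parcels], n_scans),
                "phi": phi_eff.ravel(),
            }
        ),
        subject_offsets=subject_offsets,
        scan_offsets=scan_offsets,
        n_clipped=n_clipped,
    )
    return scans, atlas, truth


def entropy_phi_reference(
    phis,
    n: int = 405,
    n_reps: int = 50,
    m: int = 3,
    r_factor: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo reference curve phi -> expected sample entropy at length n.

    Ties the generator's phi knob to the entropy scale; used as ground
    truth for recovery tests because the mapping has no simple closed
    form.
    """
    from .core import SampEnParams, sample_entropy

    params = SampEnParams(m=m, r_factor=r_factor)
    rng = np.random.default_rng(seed)
    rows = []
    for phi in phis:
        vals = []
        for _ in range(n_reps):
            x = simulate_voxel_series(phi, n, 1.0, seed=int(rng.integers(2**31)))
            ev = sample_entropy(x, params)
            if ev.defined:
                vals.append(ev.value)
        rows.append({"phi": float(phi), "mean_sampen": float(np.mean(vals)), "n_reps": len(vals)})
    return pd.DataFrame(rows)
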
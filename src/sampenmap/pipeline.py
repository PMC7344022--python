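"""Pipeline stages: simulate -> map -> aggregate -> stats.

Stages are decoupled through on-disk artifacts (NIfTI volumes, CSV
tables) so the expensive entropy maps are computed once and the
statistics can be iterated cheaply.  Every stage writes a JSON run
report: config echo, seed, per-stage timing, undefined-voxel tallies and
an inventory of produced files with SHA-256 checksums.  Volumes default
to uncompressed ``.nii`` so reruns are checksum-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import images
from .core import SampEnParams, sample_entropy_map, truncate_series
from .errors import MissingInputError, SubjectMismatchError
from .parcellation import (
    RoiEntropyTable,
    ScanMetadata,
    build_cohort_table,
    class_aggregate,
    load_atlas,
    save_atlas,
)
from .simulate import CohortConfig, ParcelSpec, simulate_cohort
from .stats import (
    correlation_matrix,
    paired_ttest,
    scan_consistency,
    two_factor_anova,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_report(out_dir: Path, stage: str, payload: dict, files: Sequence[Path]) -> Path:
    payload = dict(payload)
    payload["stage"] = stage
    payload["files"] = {str(p.relative_to(out_dir)): _sha256(p) for p in sorted(files)}
    report = out_dir / f"report_{stage}.json"
    report.write_text(json.dumps(payload, indent=1, default=str))
    return report


def config_from_dict(raw: dict) -> CohortConfig:
    """Build a CohortConfig from a plain dict (YAML/JSON payload)."""
    parcels = [
        ParcelSpec(
            label=int(p["label"]),
            name=p["name"],
            roi_class=p.get("class", p.get("roi_class", "cortical")),
            phi_rest=float(p["phi_rest"]),
            phi_task_delta=float(p.get("phi_task_delta", 0.0)),
            voxel_count=int(p["voxel_count"]),
        )
        for p in raw["parcels"]
    ]
    kwargs = {k: raw[k] for k in (
        "n_subjects", "n_timepoints", "rest_timepoints", "subject_sd",
        "shared_scan_sd", "innovation_sd", "tr", "seed",
    ) if k in raw}
    if "grid_shape" in raw:
        kwargs["grid_shape"] = tuple(int(g) for g in raw["grid_shape"])
    return CohortConfig(parcels=parcels, **kwargs)


def config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["parcels"] = [
        {
            "label": p.label,
            "name": p.name,
            "class": p.roi_class,
            "phi_rest": p.phi_rest,
            "phi_task_delta": p.phi_task_delta,
            "voxel_count": p.voxel_count,
        }
        for p in config.parcels
    ]
    d["grid_shape"] = list(config.grid_shape)
    return d


def run_simulate(config: CohortConfig, out_dir) -> Path:
    """Write a synthetic cohort to disk; returns the manifest path.

    The manifest is written last, so a crashed run never leaves a cohort
    that looks complete.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    scans, atlas, truth = simulate_cohort(config)
    files: list[Path] = []
    rows = []
    for vol, md in scans:
        name = f"{md.subject_id}_{md.condition}_{md.scan_index}.nii"
        images.save_bold(vol, out_dir / name)
        files.append(out_dir / name)
        rows.append(
            {
                "subject_id": md.subject_id,
                "condition": md.condition,
                "scan_index": md.scan_index,
                "path": name,
                "n_timepoints": vol.n_timepoints,
            }
        )
    save_atlas(atlas, out_dir / "atlas.nii", out_dir / "atlas.labels.json")
    files += [out_dir / "atlas.nii", out_dir / "atlas.labels.json"]
    truth.to_json(out_dir / "ground_truth.json")
    files.append(out_dir / "ground_truth.json")
    cfg_path = out_dir / "config.json"
    cfg_path.write_text(json.dumps(config_to_dict(config), indent=1))
    files.append(cfg_path)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    files.append(manifest)
    _write_report(
        out_dir,
        "simulate",
        {
            "seed": config.seed,
            "config_sha256": hashlib.sha256(cfg_path.read_bytes()).hexdigest(),
            "n_scans": len(scans),
            "n_clipped_phi": truth.n_clipped,
            "elapsed_s": time.perf_counter() - t0,
        },
        files,
    )
    return manifest


def run_map(
    manifest_path,
    atlas_path,
    out_dir,
    params: SampEnParams = SampEnParams(),
    truncate_to: Optional[int] = None,
    force: bool = False,
) -> Path:
    """Entropy-map every scan in a manifest; returns the maps manifest.

    Scans longer than ``truncate_to`` are truncated to it first.  Per-scan
    failures are recorded and skipped; the stage raises at the end if any
    scan failed.  Refuses to overwrite an existing maps manifest unless
    ``force`` is given.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingInputError(f"manifest not found: {manifest_path}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps_manifest = out_dir / "manifest.csv"
    if maps_manifest.exists() and not force:
        raise FileExistsError(f"{maps_manifest} exists; use force to overwrite")
    atlas = load_atlas(atlas_path)
    mask = atlas.mask()
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str})
    t0 = time.perf_counter()
    rows = []
    failures = []
    files: list[Path] = []
    tallies = {}
    for rec in manifest.to_dict(orient="records"):
        stem = f"{rec['subject_id']}_{rec['condition']}_{rec['scan_index']}"
        try:
            vol = images.load_bold(manifest_path.parent / rec["path"])
            if truncate_to is not None and vol.n_timepoints > truncate_to:
                vol = truncate_series(vol, truncate_to)
            emap = sample_entropy_map(vol, mask, params)
        except Exception as exc:  # noqa: BLE001 - per-scan isolation is the point
            failures.append({"scan": stem, "error": f"{type(exc).__name__}: {exc}"})
            continue
        vpath = out_dir / f"{stem}_sampen.nii"
        rpath = out_dir / f"{stem}_reasons.nii"
        images.save_entropy_map(emap, vpath, rpath)
        tallies[stem] = emap.undefined_counts()
        files += [vpath, rpath]
        rows.append(
            {
                "subject_id": rec["subject_id"],
                "condition": rec["condition"],
                "scan_index": rec["scan_index"],
                "values_path": vpath.name,
                "reasons_path": rpath.name,
            }
        )
    sidecar = out_dir / "undefined_voxels.json"
    sidecar.write_text(json.dumps(tallies, indent=1))
    files.append(sidecar)
    pd.DataFrame(rows).to_csv(maps_manifest, index=False)
    files.append(maps_manifest)
    _write_report(
        out_dir,
        "map",
        {
            "params": dataclasses.asdict(params),
            "truncate_to": truncate_to,
            "n_scans": len(rows),
            "failures": failures,
            "elapsed_s": time.perf_counter() - t0,
        },
        files,
    )
    if failures:
        raise MissingInputError(
            f"{len(failures)} scan(s) failed entropy mapping; see report_map.json"
        )
    return maps_manifest


def run_aggregate(maps_dir, atlas_path, out_csv) -> Path:
    """Aggregate per-scan maps into one ROI entropy table CSV."""
    maps_dir = Path(maps_dir)
    maps_manifest = maps_dir / "manifest.csv"
    if not maps_manifest.exists():
        raise MissingInputError(f"maps manifest not found: {maps_manifest}")
    atlas = load_atlas(atlas_path)
    manifest = pd.read_csv(maps_manifest, dtype={"subject_id": str})
    pairs = []
    for rec in manifest.to_dict(orient="records"):
        emap = images.load_entropy_map(
            maps_dir / rec["values_path"], maps_dir / rec["reasons_path"]
        )
        md = ScanMetadata(
            subject_id=rec["subject_id"],
            condition=rec["condition"],
            scan_index=int(rec["scan_index"]),
        )
        pairs.append((emap, md))
    table = build_cohort_table(pairs, atlas)
    out_csv = Path(out_csv)
    out_csv.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_csv)
    return out_csv


# ---------------------------------------------------------------------------
# Statistics bundle


def _paired_frames(table: RoiEntropyTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rest and task rows aligned by (subject_id, scan_index)."""
    rest = table.select("rest")
    task = table.select("task")
    key_r = list(zip(rest.meta["subject_id"], rest.meta["scan_index"]))
    key_t = list(zip(task.meta["subject_id"], task.meta["scan_index"]))
    if key_r != key_t:
        raise SubjectMismatchError("rest and task scans do not pair by (subject, scan_index)")
    return rest, task


def _split_by_scan(table: RoiEntropyTable, condition: str):
    cond = table.select(condition)
    t1 = RoiEntropyTable(
        meta=cond.meta[cond.meta["scan_index"] == 1].reset_index(drop=True),
        mean=cond.mean[cond.meta["scan_index"] == 1].reset_index(drop=True),
        sd=cond.sd[cond.meta["scan_index"] == 1].reset_index(drop=True),
        n_valid=cond.n_valid[cond.meta["scan_index"] == 1].reset_index(drop=True),
        roi_info=cond.roi_info,
    )
    t2 = RoiEntropyTable(
        meta=cond.meta[cond.meta["scan_index"] == 2].reset_index(drop=True),
        mean=cond.mean[cond.meta["scan_index"] == 2].reset_index(drop=True),
        sd=cond.sd[cond.meta["scan_index"] == 2].reset_index(drop=True),
        n_valid=cond.n_valid[cond.meta["scan_index"] == 2].reset_index(drop=True),
        roi_info=cond.roi_info,
    )
    return t1, t2


def compute_stats_bundle(
    table: RoiEntropyTable, families: Optional[dict[str, int]] = None
) -> dict[str, pd.DataFrame]:
    """The full inferential battery on one cohort table.

    Emits class-level summaries and contrasts, network summaries with
    Bonferroni-adjusted paired tests, the two condition x class and
    condition x network ANOVA tables, per-network scan-consistency
    (ICC(3,1), r, two-tailed paired p) and per-scan means, and Pearson
    correlation matrices per condition.  ``families`` overrides the
    Bonferroni family sizes (keys "networks", "rois", "classes").
    """
    families = dict(families or {})
    out: dict[str, pd.DataFrame] = {}
    try:
        networks = table.class_names("network")
    except Exception:
        networks = None
    classes_present = []
    for cls in ("cortical", "subcortical"):
        try:
            table.class_names(cls)
            classes_present.append(cls)
        except Exception:
            pass
    rest, task = _paired_frames(table)

    # --- class-level summary and contrasts -------------------------------
    if classes_present:
        rows = []
        for cls in classes_present:
            for cond, tab in (("rest", rest), ("task", task)):
                series = class_aggregate(tab, cls)
                rows.append(
                    {
                        "class": cls,
                        "condition": cond,
                        "mean": series.mean(),
                        "sd": series.std(ddof=1),
                        "n_scans": series.size,
                    }
                )
        out["table1_class_summary"] = pd.DataFrame(rows)

        fam_cls = families.get("classes", 1)
        crows = []
        for cls in classes_present:
            res = paired_ttest(class_aggregate(rest, cls), class_aggregate(task, cls), fam_cls)
            crows.append(
                {
                    "contrast": f"{cls}: rest - task",
                    "test": "paired-t",
                    "t": res.t_stat,
                    "df": res.df,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "mean_diff": res.mean_diff,
                    "bonferroni_family": fam_cls,
                }
            )
        if set(classes_present) == {"cortical", "subcortical"}:
            for cond, tab in (("rest", rest), ("task", task)):
                res = paired_ttest(
                    class_aggregate(tab, "subcortical"),
                    class_aggregate(tab, "cortical"),
                    fam_cls,
                )
                crows.append(
                    {
                        "contrast": f"{cond}: subcortical - cortical",
                        "test": "paired-t",
                        "t": res.t_stat,
                        "df": res.df,
                        "p_raw": res.p_raw,
                        "p_adjusted": res.p_adjusted,
                        "mean_diff": res.mean_diff,
                        "bonferroni_family": fam_cls,
                    }
                )
            # condition x class ANOVA: one observation per scan per class
            values, fa, fb = [], [], []
            for cond, tab in (("rest", rest), ("task", task)):
                for cls in ("cortical", "subcortical"):
                    v = class_aggregate(tab, cls).to_numpy()
                    values.append(v)
                    fa += [cond] * v.size
                    fb += [cls] * v.size
            anova = two_factor_anova(
                np.concatenate(values), np.array(fa), np.array(fb), names=("condition", "class")
            )
            out["table3_anova_class"] = anova.table
        out["class_contrasts"] = pd.DataFrame(crows)

    # --- network-level battery -------------------------------------------
    if networks:
        fam_net = families.get("networks", len(networks))
        rows = []
        for name in networks:
            res = paired_ttest(rest.mean[name], task.mean[name], fam_net)
            rows.append(
                {
                    "network": name,
                    "rest_mean": rest.mean[name].mean(),
                    "rest_sd": rest.mean[name].std(ddof=1),
                    "task_mean": task.mean[name].mean(),
                    "task_sd": task.mean[name].std(ddof=1),
                    "t": res.t_stat,
                    "p_raw": res.p_raw,
                    "p_adjusted": res.p_adjusted,
                    "mean_diff": res.mean_diff,
                    "bonferroni_family": fam_net,
                }
            )
        out["table2_network_summary"] = pd.DataFrame(rows)

        values, fa, fb = [], [], []
        for cond, tab in (("rest", rest), ("task", task)):
            for name in networks:
                v = tab.mean[name].to_numpy()
                values.append(v)
                fa += [cond] * v.size
                fb += [name] * v.size
        out["table4_anova_network"] = two_factor_anova(
            np.concatenate(values), np.array(fa), np.array(fb), names=("condition", "network")
        ).table

        crows, grows, mrows = [], [], []
        for cond in ("rest", "task"):
            t1, t2 = _split_by_scan(table, cond)
            t1 = RoiEntropyTable(
                meta=t1.meta, mean=t1.mean[networks], sd=t1.sd[networks],
                n_valid=t1.n_valid[networks],
                roi_info=t1.roi_info[t1.roi_info["name"].isin(networks)].reset_index(drop=True),
            )
            t2 = RoiEntropyTable(
                meta=t2.meta, mean=t2.mean[networks], sd=t2.sd[networks],
                n_valid=t2.n_valid[networks],
                roi_info=t2.roi_info[t2.roi_info["name"].isin(networks)].reset_index(drop=True),
            )
            per_roi, group_r = scan_consistency(t1, t2)
            per_roi.insert(0, "condition", cond)
            crows.append(per_roi)
            grows.append({"condition": cond, "group_level_r": group_r})
            for name in networks:
                mrows.append(
                    {
                        "condition": cond,
                        "network": name,
                        "scan1_mean": t1.mean[name].mean(),
                        "scan1_sd": t1.mean[name].std(ddof=1),
                        "scan2_mean": t2.mean[name].mean(),
                        "scan2_sd": t2.mean[name].std(ddof=1),
                    }
                )
        out["table5_consistency"] = pd.concat(crows, ignore_index=True)
        out["consistency_group"] = pd.DataFrame(grows)
        out["table6_scan_means"] = pd.DataFrame(mrows)

        for cond in ("rest", "task"):
            cm = correlation_matrix(table, columns=networks, condition=cond)
            out[f"corr_networks_{cond}"] = cm.values

    # --- region-level correlation matrices --------------------------------
    if set(classes_present) == {"cortical", "subcortical"}:
        regions = table.class_names("cortical") + table.class_names("subcortical")
        for cond in ("rest", "task"):
            cm = correlation_matrix(table, columns=regions, condition=cond)
            out[f"corr_rois_{cond}"] = cm.values

    return out


def run_stats(table_csv, out_dir, families: Optional[dict[str, int]] = None) -> Path:
    """Compute the statistics bundle from a table CSV and write it out."""
    table_csv = Path(table_csv)
    if not table_csv.exists():
        raise MissingInputError(f"table not found: {table_csv}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    table = RoiEntropyTable.from_csv(table_csv)
    bundle = compute_stats_bundle(table, families)
    files = []
    for name, frame in bundle.items():
        path = out_dir / f"{name}.csv"
        if name.startswith("corr_"):
            frame.to_csv(path, index=True, index_label="roi")
        else:
            frame.to_csv(path, index=False)
        files.append(path)
    _write_report(
        out_dir,
        "stats",
        {
            "table": str(table_csv),
            "families": families or {},
            "n_tables": len(bundle),
            "elapsed_s": time.perf_counter() - t0,
        },
        files,
    )
    return out_dir
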
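"""File formats and run configuration.

Conventions: image stacks (phantom label grids, B-scans, mosaics) are
multi-page 16-bit grayscale TIFF with a JSON sidecar carrying geometry and
the dB window used for quantization; fringe datasets are NumPy ``.npz``
containers (platform-independent) with a JSON sidecar for plan, intrinsics
and stage positions; cohort tables are plain CSV.  Every CLI run writes a
manifest (config hash, seed, versions) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .acquisition import ScanDataset, ScanPlan
from .cohort import PolypRecord, TECHNIQUES
from .optics import ProbeIntrinsics, OpticalProperties
from .phantom import TissuePhantom, Vessel
from .mosaic import MosaicSlice


class SchemaError(ValueError):
    """A sidecar is missing or mistypes a required field."""

    def __init__(self, field_path: str, message: str = ""):
        self.field_path = field_path
        super().__init__(f"schema violation at '{field_path}'"
                         + (f": {message}" if message else ""))


def _require(d: dict, *path):
    cur = d
    walked = []
    for p in path:
        walked.append(str(p))
        if not isinstance(cur, dict) or p not in cur:
            raise SchemaError(".".join(walked))
        cur = cur[p]
    return cur


# ---------------------------------------------------------------------------
# fringe datasets

def write_dataset(dataset: ScanDataset, path) -> Path:
    """Write a ScanDataset as <path>.npz + <path>.json; returns the npz path."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix == ".npz" else path
    np.savez(base.with_suffix(".npz"),
             fringes=dataset.fringes, k_values=dataset.k_values,
             angles=dataset.angles, stage_positions=dataset.stage_positions)
    sidecar = {
        "plan": dataclasses.asdict(dataset.plan),
        "intrinsics": dataclasses.asdict(dataset.intrinsics_true),
        "origin_mm": list(dataset.origin_mm),
        "seed": dataset.seed,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npz")


def read_dataset(path) -> ScanDataset:
    """Read a dataset written by ``write_dataset`` (round-trip exact)."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npz", ".json") else path
    sidecar = json.loads(base.with_suffix(".json").read_text())
    plan = ScanPlan(**_require(sidecar, "plan"))
    intr = ProbeIntrinsics(**_require(sidecar, "intrinsics"))
    arrays = np.load(base.with_suffix(".npz"))
    for key in ("fringes", "k_values", "angles", "stage_positions"):
        if key not in arrays:
            raise SchemaError(key, "missing array")
    return ScanDataset(fringes=arrays["fringes"], k_values=arrays["k_values"],
                       angles=arrays["angles"], plan=plan,
                       intrinsics_true=intr,
                       stage_positions=arrays["stage_positions"],
                       origin_mm=tuple(_require(sidecar, "origin_mm")),
                       seed=int(sidecar.get("seed", 0)))


# ---------------------------------------------------------------------------
# phantoms

def write_phantom(phantom: TissuePhantom, path) -> Path:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".tif", ".tiff") else path
    tifffile.imwrite(base.with_suffix(".tif"),
                     phantom.label_grid.astype(np.uint16))
    sidecar = {
        "extent_mm": list(map(float, phantom.extent_mm)),
        "voxel_size": phantom.voxel_size,
        "properties": {str(k): dataclasses.asdict(v)
                       for k, v in phantom.properties.items()},
        "vessels": [{"center": list(v.center), "radii": list(v.radii)}
                    for v in phantom.vessels],
        "lesion_flags": phantom.lesion_flags,
        "seed": phantom.seed,
        "heterogeneity": phantom.heterogeneity,
        "heterogeneity_scale": phantom.heterogeneity_scale,
        "void_contrast": phantom.void_contrast,
        "void_scale": phantom.void_scale,
        "void_threshold": phantom.void_threshold,
        "boundaries": np.round(phantom.boundaries, 5).tolist(),
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar))
    return base.with_suffix(".tif")


def read_phantom(path) -> TissuePhantom:
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".tif", ".tiff", ".json") else path
    sidecar = json.loads(base.with_suffix(".json").read_text())
    labels = tifffile.imread(base.with_suffix(".tif"))
    props = {int(k): OpticalProperties(**v)
             for k, v in _require(sidecar, "properties").items()}
    return TissuePhantom(
        extent_mm=np.asarray(_require(sidecar, "extent_mm"), float),
        voxel_size=float(_require(sidecar, "voxel_size")),
        boundaries=np.asarray(_require(sidecar, "boundaries"), float),
        properties=props,
        vessels=[Vessel(tuple(v["center"]), tuple(v["radii"]))
                 for v in sidecar.get("vessels", [])],
        lesion_flags=_require(sidecar, "lesion_flags"),
        seed=int(sidecar.get("seed", 0)),
        heterogeneity=float(sidecar.get("heterogeneity", 0.0)),
        heterogeneity_scale=float(sidecar.get("heterogeneity_scale", 0.08)),
        void_contrast=float(sidecar.get("void_contrast", 0.0)),
        void_scale=float(sidecar.get("void_scale", 0.05)),
        void_threshold=float(sidecar.get("void_threshold", -0.45)),
        _label_grid=np.asarray(labels, dtype=np.uint16))


# ---------------------------------------------------------------------------
# image stacks (B-scans / mosaics): 16-bit dB-quantized TIFF + sidecar

def _quantize_db(db: np.ndarray, window):
    lo, hi = window
    scaled = np.clip((db - lo) / (hi - lo), 0, 1)
    out = np.where(np.isnan(db), 0, 1 + scaled * 65534).astype(np.uint16)
    return out  # 0 is the invalid sentinel


def write_mosaic_stack(slices, path, db_window=(-80.0, 0.0)) -> Path:
    """Write stitched slices as one multi-page 16-bit TIFF (log view,
    fixed dB window) + JSON sidecar with geometry and normalization."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".tif", ".tiff") else path
    slices = [slices] if isinstance(slices, MosaicSlice) else list(slices)
    peak = max(np.nanmax(s.image.pixels[s.image.valid_mask])
               for s in slices if s.image.valid_mask.any())
    pages = []
    for s in slices:
        with np.errstate(divide="ignore", invalid="ignore"):
            db = 20 * np.log10(s.image.pixels / peak)
        pages.append(_quantize_db(db, db_window))
    tifffile.imwrite(base.with_suffix(".tif"), np.stack(pages))
    sidecar = {
        "db_window": list(db_window), "peak": float(peak),
        "pixel_size": slices[0].image.pixel_size,
        "slices": [{"x_position": s.x_position,
                    "origin": list(map(float, s.image.origin)),
                    "normalization": s.normalization,
                    "contributing_bscans": [list(b) for b in
                                            s.contributing_bscans]}
                   for s in slices],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".tif")


# ---------------------------------------------------------------------------
# cohort tables

def read_cohort_csv(path) -> list:
    """Typed polyp records from a CSV with header
    patient_id,age,sex,technique,diagnosis,location,diameter
    (blank diameter = not reported).  Unknown technique values are rejected
    naming the offending row."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "age", "sex", "technique", "diagnosis",
                "location", "diameter"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(sorted(missing)[0], "missing column")
    if df.empty:
        raise ValueError("empty cohort table")
    records = []
    for i, row in df.iterrows():
        if row["technique"] not in TECHNIQUES:
            raise ValueError(
                f"row {i + 2}: unknown technique {row['technique']!r} "
                f"(expected one of {TECHNIQUES})")
        d = row["diameter"]
        records.append(PolypRecord(
            patient_id=row["patient_id"], age=float(row["age"]),
            sex=str(row["sex"]), technique=str(row["technique"]),
            diagnosis=str(row["diagnosis"]), location=str(row["location"]),
            diameter=None if pd.isna(d) else float(d)))
    return records


def packaged_cohort() -> list:
    """The cohort fixture shipped with the package (13 polyps, 9 patients)."""
    with resources.as_file(
            resources.files("coloct.data") / "cohort_table.csv") as p:
        return read_cohort_csv(p)


# ---------------------------------------------------------------------------
# manifest

def write_manifest(path, config: dict, seed: int, extra=None) -> Path:
    """Reproducibility manifest: canonical config hash, seed, versions."""
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {"coloct": _version(), "numpy": np.__version__},
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def _version() -> str:
    from . import __version__
    return __version__
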
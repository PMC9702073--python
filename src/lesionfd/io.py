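"""File formats: NIfTI-1 images, TCK/JSON tractograms, manifest CSV, truth JSON.

Images carry the grid in the NIfTI affine (axis-aligned only) and the
template-space label in the header description. The cohort manifest is a
CSV with one row per subject; its column schema is validated on read and a
missing column is reported by name.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import LESION_TYPES, BinaryMask, DensityImage, GridSpec, StreamlineSet, TBRMap
from .synthetic import CohortTruth, SubjectRecord

MANIFEST_COLUMNS = (
    "id", "group", "age", "gender", "education", "ecog", "months_since_rt",
    "vol_cavity_mL", "vol_ce_mL", "vol_fet_mL", "vol_flair_mL",
)


# ------------------------------------------------------------------- NIfTI


def grid_from_nifti(img: nib.Nifti1Image, space_id: str | None = None) -> GridSpec:
    aff = np.asarray(img.affine)
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3]))):
        raise ValueError("only axis-aligned affines are supported")
    h = np.diag(aff[:3, :3])
    if np.any(h <= 0):
        raise ValueError("voxel sizes in the affine must be positive")
    origin = aff[:3, 3] - h / 2.0
    if space_id is None:
        space_id = img.header["descrip"].tobytes().decode(errors="ignore").strip("\x00") or "unknown"
    return GridSpec(
        shape=tuple(int(s) for s in img.shape[:3]),
        voxel_size_mm=tuple(float(x) for x in h),
        space_id=space_id.split("|")[0],
        origin_mm=tuple(float(o) for o in origin),
    )


def _nifti(values: np.ndarray, grid: GridSpec, descrip: str) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(values), grid.affine)
    img.header["descrip"] = descrip.encode()[:79]
    return img


def save_density(fd: DensityImage, path) -> None:
    nib.save(_nifti(fd.values.astype(np.float32), fd.grid, fd.grid.space_id), str(path))


def load_density(path) -> DensityImage:
    img = nib.load(str(path))
    grid = grid_from_nifti(img)
    return DensityImage(grid=grid, values=np.asarray(img.dataobj, dtype=float))


def save_mask(mask: BinaryMask, path) -> None:
    descrip = f"{mask.grid.space_id}|{mask.lesion_type}"
    nib.save(_nifti(mask.values.astype(np.uint8), mask.grid, descrip), str(path))


def load_mask(path, lesion_type: str | None = None) -> BinaryMask:
    img = nib.load(str(path))
    grid = grid_from_nifti(img)
    if lesion_type is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore").strip("\x00")
        lesion_type = descrip.split("|")[-1]
        if lesion_type not in LESION_TYPES:
            raise ValueError(f"cannot infer lesion type from {path}")
    return BinaryMask(grid=grid, values=np.asarray(img.dataobj) > 0, lesion_type=lesion_type)


def save_tbr(tbr: TBRMap, path) -> None:
    nib.save(_nifti(tbr.values.astype(np.float32), tbr.grid, tbr.grid.space_id), str(path))


def load_tbr(path) -> TBRMap:
    img = nib.load(str(path))
    return TBRMap(grid=grid_from_nifti(img), values=np.asarray(img.dataobj, dtype=float))


# -------------------------------------------------------------- streamlines


def save_streamlines_tck(lines: StreamlineSet, path) -> None:
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in lines], affine_to_rasmm=np.eye(4)
    )
    nib.streamlines.save(tractogram, str(path))


def load_streamlines_tck(path) -> StreamlineSet:
    tck = nib.streamlines.load(str(path))
    return StreamlineSet(streamlines=[np.asarray(s, dtype=float) for s in tck.streamlines])


def save_streamlines_json(lines: StreamlineSet, path) -> None:
    payload = [np.asarray(s).tolist() for s in lines]
    Path(path).write_text(json.dumps(payload))


def load_streamlines_json(path) -> StreamlineSet:
    payload = json.loads(Path(path).read_text())
    return StreamlineSet(streamlines=[np.asarray(s, dtype=float) for s in payload])


def load_streamlines(path) -> StreamlineSet:
    p = str(path)
    return load_streamlines_json(p) if p.endswith(".json") else load_streamlines_tck(p)


# ----------------------------------------------------------------- manifest


def records_to_manifest(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "group": r.group, "age": r.age, "gender": r.gender,
            "education": r.education, "ecog": r.ecog,
            "months_since_rt": "" if r.months_since_rt is None else r.months_since_rt,
            **{f"vol_{lt}_mL": r.lesion_volumes_mL.get(lt, 0.0) for lt in LESION_TYPES},
        })
    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def save_manifest(records: list[SubjectRecord], path) -> None:
    records_to_manifest(records).to_csv(path, index=False)


def load_manifest(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required column(s): {', '.join(missing)}")
    records = []
    for _, row in df.iterrows():
        months = row["months_since_rt"]
        records.append(SubjectRecord(
            id=str(row["id"]), group=str(row["group"]), age=float(row["age"]),
            gender=str(row["gender"]), education=int(row["education"]),
            ecog=int(row["ecog"]),
            months_since_rt=None if pd.isna(months) or months == "" else float(months),
            lesion_volumes_mL={lt: float(row[f"vol_{lt}_mL"]) for lt in LESION_TYPES},
        ))
    return records


# -------------------------------------------------------------------- truth


def save_truth(truth: CohortTruth, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(truth), indent=2, sort_keys=True))


def load_truth(path) -> CohortTruth:
    return CohortTruth(**json.loads(Path(path).read_text()))
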
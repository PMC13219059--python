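"""Readers and writers: voxel tables, NIfTI images, CSV/JSON reports.

Coordinates are world millimetres everywhere; voxel indices never cross
this module's boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import SUV_THRESHOLD, Lesion, LesionSet, SUVImage

logger = logging.getLogger("petmpi")

VOXEL_TABLE_COLUMNS = ["patient_id", "lesion_id", "x_mm", "y_mm", "z_mm", "suv"]


class SchemaError(ValueError):
    pass


def read_voxel_table(
    path, voxel_volume_ml: float | None = None, threshold: float = SUV_THRESHOLD
) -> list[LesionSet]:
    """Read a flat per-voxel lesion table into per-patient lesion sets.

    Expected CSV columns: patient_id, lesion_id, x_mm, y_mm, z_mm, suv;
    an optional voxel_volume_ml column overrides the argument.  Rows at or
    below the segmentation threshold are rejected (count logged), and
    duplicate (patient, lesion, coordinate) rows are an error.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty voxel table") from exc
    missing = [c for c in VOXEL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no rows")
    if "voxel_volume_ml" in df.columns:
        vols = df["voxel_volume_ml"].unique()
        if len(vols) != 1:
            raise SchemaError(f"{path}: voxel_volume_ml must be constant")
        voxel_volume_ml = float(vols[0])
    if voxel_volume_ml is None:
        raise SchemaError("voxel_volume_ml required (column or argument)")

    dup = df.duplicated(subset=["patient_id", "lesion_id", "x_mm", "y_mm", "z_mm"])
    if dup.any():
        raise SchemaError(f"{path}: {int(dup.sum())} duplicate voxel rows")
    sub = df[df["suv"] <= threshold]
    if len(sub):
        logger.warning(
            "%s: rejected %d voxel rows at or below SUV threshold %.2f",
            path, len(sub), threshold,
        )
        df = df[df["suv"] > threshold]

    out: list[LesionSet] = []
    for pid, pdf in df.groupby("patient_id", sort=True):
        lesions = [
            Lesion(
                lesion_id=int(lid),
                coords_mm=ldf[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
                suv=ldf["suv"].to_numpy(float),
            )
            for lid, ldf in pdf.groupby("lesion_id", sort=True)
        ]
        out.append(
            LesionSet(
                patient_id=str(pid),
                lesions=lesions,
                voxel_volume_ml=voxel_volume_ml,
                threshold=threshold,
            )
        )
    return out


def write_voxel_table(lesion_sets: list[LesionSet], path) -> None:
    rows = []
    for ls in lesion_sets:
        for lesion in ls.lesions:
            for coord, suv in zip(lesion.coords_mm, lesion.suv):
                rows.append(
                    {
                        "patient_id": ls.patient_id,
                        "lesion_id": lesion.lesion_id,
                        "x_mm": coord[0],
                        "y_mm": coord[1],
                        "z_mm": coord[2],
                        "suv": suv,
                        "voxel_volume_ml": ls.voxel_volume_ml,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_nifti(image: SUVImage, path) -> None:
    """Write an SUV image with spacing in the affine (origin as offset)."""
    affine = np.diag(list(image.spacing) + [1.0])
    affine[:3, 3] = image.origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))


def read_nifti(path) -> SUVImage:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return SUVImage(values=np.asarray(img.dataobj, dtype=float), spacing=spacing, origin=origin)


def read_image_dir(path, pattern: str = "*.nii*") -> dict[str, SUVImage]:
    """Load every NIfTI in a directory; patient id = file stem."""
    images = {}
    for f in sorted(Path(path).glob(pattern)):
        pid = f.name.split(".")[0]
        images[pid] = read_nifti(f)
    if not images:
        raise FileNotFoundError(f"no NIfTI images matching {pattern} under {path}")
    return images


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="records")
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))


def write_csv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index)
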
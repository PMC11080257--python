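"""NIfTI-1 and tabular input/output.

Volumes are written uncompressed (.nii) so file checksums are reproducible;
b-values use the common sidecar convention (one whitespace-separated row,
volume order). Cohort tables are plain comma-separated text.
"""
from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .asl import ASLSeries
from .dwi import DWISeries
from .errors import FormatError
from .geometry import PhantomGeometry
from .masks import ROIMask


def _geometry_from_img(img) -> PhantomGeometry:
    zooms = img.header.get_zooms()[:3]
    aff = img.affine
    return PhantomGeometry(shape=tuple(int(s) for s in img.shape[:3]),
                           voxel_size_mm=tuple(float(z) for z in zooms),
                           origin_mm=tuple(float(v) for v in aff[:3, 3]))


def save_volume(data: np.ndarray, geometry: PhantomGeometry, path: str) -> str:
    img = nib.Nifti1Image(np.asarray(data), geometry.affine)
    img.header.set_zooms(tuple(geometry.voxel_size_mm) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)
    return path


def load_volume(path: str):
    """Returns (data, geometry); raises FormatError naming the file on parse failure."""
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:
        raise FormatError(f"could not read NIfTI file {path!r}: {exc}") from exc
    return data, _geometry_from_img(img)


def save_dwi(series: DWISeries, out_dir: str, stem: str = "dwi") -> dict:
    os.makedirs(out_dir, exist_ok=True)
    nii = os.path.join(out_dir, f"{stem}.nii")
    save_volume(series.volumes, series.geometry, nii)
    bval = os.path.join(out_dir, f"{stem}.bval")
    with open(bval, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in series.bvalues) + "\n")
    dirs = os.path.join(out_dir, f"{stem}.dirs")
    with open(dirs, "w") as fh:
        fh.write(" ".join(str(d) for d in series.direction_index) + "\n")
    return {"nii": nii, "bval": bval, "dirs": dirs}


def load_bvals(path: str) -> np.ndarray:
    try:
        with open(path) as fh:
            vals = [float(tok) for tok in fh.read().split()]
    except (OSError, ValueError) as exc:
        raise FormatError(f"could not read b-value sidecar {path!r}: {exc}") from exc
    if not vals:
        raise FormatError(f"b-value sidecar {path!r} is empty")
    return np.asarray(vals, dtype=float)


def load_dwi(nii_path: str, bval_path: str, dirs_path: str | None = None) -> DWISeries:
    data, geom = load_volume(nii_path)
    if data.ndim != 4:
        raise FormatError(f"{nii_path!r} is not a 4-D DWI series")
    bvals = load_bvals(bval_path)
    if len(bvals) != data.shape[3]:
        raise FormatError(
            f"{bval_path!r} lists {len(bvals)} b-values for {data.shape[3]} volumes")
    if dirs_path is not None and os.path.exists(dirs_path):
        with open(dirs_path) as fh:
            dirs = np.asarray([int(t) for t in fh.read().split()], dtype=int)
    else:
        # reconstruct per-shell direction indices in volume order
        dirs = np.zeros(len(bvals), dtype=int)
        for b in np.unique(bvals):
            sel = np.flatnonzero(bvals == b)
            dirs[sel] = np.arange(sel.size)
    return DWISeries(data, bvals, dirs, geom)


def save_masks(masks: ROIMask, path: str) -> str:
    return save_volume(masks.labels.astype(np.int16), masks.geometry, path)


def load_masks(path: str) -> ROIMask:
    data, geom = load_volume(path)
    if data.ndim != 3:
        raise FormatError(f"{path!r} is not a 3-D label volume")
    return ROIMask(labels=np.asarray(data, dtype=np.int16), geometry=geom)


def save_asl(series: ASLSeries, out_dir: str, stem: str = "asl") -> dict:
    os.makedirs(out_dir, exist_ok=True)
    nii = os.path.join(out_dir, f"{stem}.nii")
    m0 = os.path.join(out_dir, f"{stem}_m0.nii")
    save_volume(series.volumes, series.geometry, nii)
    save_volume(series.m0, series.geometry, m0)
    return {"nii": nii, "m0": m0, "order_flag": series.order_flag}


def load_asl(nii_path: str, m0_path: str, order_flag: str = "control_first") -> ASLSeries:
    data, geom = load_volume(nii_path)
    if data.ndim != 4:
        raise FormatError(f"{nii_path!r} is not a 4-D ASL series")
    m0, _ = load_volume(m0_path)
    return ASLSeries(volumes=data, m0=np.asarray(m0, dtype=float),
                     geometry=geom, order_flag=order_flag)


def write_cohort_table(table: pd.DataFrame, path: str) -> str:
    lead = ["subject_id", "group", "age", "sex", "true_D_suprasellar",
            "true_perfusion", "updrs", "moca"]
    cols = [c for c in lead if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)
    return path


def read_cohort_table(path: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not read cohort table {path!r}: {exc}") from exc
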
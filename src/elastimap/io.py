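"""Readers and writers: DICOM series in, NIfTI/NPZ/PNG/CSV out.

Displacement fields are stored as 2-component NIfTI (or NPZ) in pixel
units with a units tag in the header description, since no interchange
standard exists for 2D fields.  Contours travel as CSV polygons
(``name,x,y`` per vertex, 0-based pixel coordinates).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .ecv import ContourSet
from .qa import colorize
from .registration import RegistrationParams
from .t1map import MolliSeries

__all__ = [
    "StudyBundle",
    "read_molli_dicom",
    "write_molli_dicom",
    "save_series_npz",
    "load_series_npz",
    "write_maps",
    "roi_stats",
    "save_displacement_field",
    "load_displacement_field",
    "read_contours_csv",
    "write_contours_csv",
    "load_params",
]


@dataclass
class StudyBundle:
    """One patient/slice worth of inputs for ECV mapping."""

    native: MolliSeries
    post: MolliSeries
    contours: ContourSet
    hematocrit: float
    slice_level: str = "mid"  # basal | mid
    patient_id: str = "anon"

    def __post_init__(self) -> None:
        if self.native.shape != self.post.shape:
            raise ValueError("native and post series grids must match")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be a fraction in (0, 1)")


# ---------------------------------------------------------------------------
# DICOM


def read_molli_dicom(directory) -> MolliSeries:
    """Read a directory of single-frame DICOMs as one MOLLI series.

    Frames are sorted by the InversionTime attribute (ms); pixel spacing
    comes from PixelSpacing.  A file without InversionTime, or a mixed
    grid, raises with the offending file named.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    frames, tis, spacing, shape = [], [], None, None
    for path in files:
        ds = pydicom.dcmread(path)
        if "InversionTime" not in ds:
            raise ValueError(f"{path.name}: missing InversionTime attribute")
        arr = ds.pixel_array.astype(float)
        if ("RescaleSlope" in ds) or ("RescaleIntercept" in ds):
            arr = arr * float(getattr(ds, "RescaleSlope", 1.0)) + float(
                getattr(ds, "RescaleIntercept", 0.0)
            )
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(f"{path.name}: grid {arr.shape} differs from {shape}")
        if spacing is None and "PixelSpacing" in ds:
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        frames.append(arr)
        tis.append(float(ds.InversionTime))
    order = np.argsort(tis, kind="stable")
    return MolliSeries(
        np.stack([frames[i] for i in order]),
        np.asarray(tis)[order],
        magnitude=True,
        spacing=spacing or (1.0, 1.0),
    )


def write_molli_dicom(series: MolliSeries, directory) -> list:
    """Write a series as single-frame secondary-capture DICOMs (fixture
    writer).  Intensities are rounded to uint16, so lossless round-trips
    need integer-valued frames in [0, 65535]."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    series_uid = generate_uid()
    paths = []
    for i in range(series.n_frames):
        frame = np.round(series.frames[i])
        if frame.min() < 0 or frame.max() > 65535:
            raise ValueError("frame intensities must fit uint16 after rounding")
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        path = directory / f"frame_{i:03d}.dcm"
        ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "MR"
        ds.InstanceNumber = i + 1
        ds.InversionTime = float(series.inversion_times[i])
        ds.PixelSpacing = [series.spacing[0], series.spacing[1]]
        ds.Rows, ds.Columns = frame.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = frame.astype(np.uint16).tobytes()
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NPZ / NIfTI


def save_series_npz(series: MolliSeries, path) -> None:
    np.savez_compressed(
        path,
        frames=series.frames,
        inversion_times=series.inversion_times,
        magnitude=series.magnitude,
        scheme=series.scheme or "",
        heart_rate=series.heart_rate or 0.0,
        spacing=np.asarray(series.spacing),
    )


def load_series_npz(path) -> MolliSeries:
    with np.load(path, allow_pickle=False) as z:
        return MolliSeries(
            z["frames"],
            z["inversion_times"],
            magnitude=bool(z["magnitude"]),
            scheme=str(z["scheme"]) or None,
            heart_rate=float(z["heart_rate"]) or None,
            spacing=tuple(z["spacing"]),
        )


def _nifti(data: np.ndarray, spacing) -> nib.Nifti1Image:
    affine = np.diag([spacing[1], spacing[0], 1.0, 1.0])
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)


def write_maps(
    maps: dict,
    out_dir,
    spacing=(1.0, 1.0),
    formats=("nifti", "npz", "png"),
    windows: dict | None = None,
    params: RegistrationParams | None = None,
) -> dict:
    """Write named float maps as NIfTI + NPZ and display PNGs.

    ``windows`` optionally fixes the PNG window per map name (deterministic
    bytes for fixed input).  A run-parameters JSON is written when
    ``params`` is given.  Returns the mapping name -> list of paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    windows = windows or {}
    written: dict[str, list] = {}
    if "npz" in formats:
        np.savez_compressed(out_dir / "maps.npz", **{k: np.asarray(v) for k, v in maps.items()})
    for name, data in maps.items():
        data = np.asarray(data, dtype=float)
        paths = []
        if "nifti" in formats:
            p = out_dir / f"{name}.nii.gz"
            nib.save(_nifti(data, spacing), p)
            paths.append(p)
        if "npz" in formats:
            paths.append(out_dir / "maps.npz")
        if "png" in formats and data.ndim == 2:
            p = out_dir / f"{name}.png"
            rgb = colorize(data, window=windows.get(name), cmap="viridis")
            iio.imwrite(p, (rgb * 255).astype(np.uint8))
            paths.append(p)
        written[name] = paths
    if params is not None:
        (out_dir / "run_params.json").write_text(json.dumps(asdict(params), indent=2))
    return written


def roi_stats(maps: dict, rois: dict) -> pd.DataFrame:
    """Summary statistics of each map over each named ROI mask."""
    rows = []
    for roi_name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        for map_name, data in maps.items():
            vals = np.asarray(data, dtype=float)[mask]
            vals = vals[np.isfinite(vals)]
            rows.append(
                {
                    "roi": roi_name,
                    "map": map_name,
                    "n": int(vals.size),
                    "mean": float(np.mean(vals)) if vals.size else np.nan,
                    "median": float(np.median(vals)) if vals.size else np.nan,
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "min": float(np.min(vals)) if vals.size else np.nan,
                    "max": float(np.max(vals)) if vals.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def save_displacement_field(u: np.ndarray, path) -> None:
    """Store a field as NPZ (``.npz``) or 2-component NIfTI, pixel units."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, u=np.asarray(u, dtype=float), units="px")
    else:
        img = _nifti(np.asarray(u, dtype=float), (1.0, 1.0))
        img.header["descrip"] = b"displacement field, components last axis, units px"
        nib.save(img, path)


def load_displacement_field(path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            return np.asarray(z["u"], dtype=float)
    return np.asarray(nib.load(path).get_fdata(), dtype=float)


# ---------------------------------------------------------------------------
# Contours and config


def write_contours_csv(contours: ContourSet, path) -> None:
    rows = [("epicardial", x, y) for x, y in contours.epicardial]
    rows += [("endocardial", x, y) for x, y in contours.endocardial]
    for i, poly in enumerate(contours.exclusions):
        rows += [(f"exclusion_{i}", x, y) for x, y in poly]
    pd.DataFrame(rows, columns=["name", "x", "y"]).to_csv(path, index=False)


def read_contours_csv(path) -> ContourSet:
    df = pd.read_csv(path)
    if not {"name", "x", "y"}.issubset(df.columns):
        raise ValueError("contour CSV needs name,x,y columns")
    groups = {name: g[["x", "y"]].to_numpy(dtype=float) for name, g in df.groupby("name", sort=False)}
    try:
        epi = groups.pop("epicardial")
        endo = groups.pop("endocardial")
    except KeyError as exc:
        raise ValueError(f"contour CSV missing polygon {exc}") from exc
    return ContourSet(epi, endo, exclusions=list(groups.values()))


def load_params(path) -> RegistrationParams:
    """Registration parameters from a YAML or JSON config file; keys not
    present keep their defaults."""
    import yaml

    text = Path(path).read_text()
    cfg = yaml.safe_load(text) or {}
    known = {k: v for k, v in cfg.items() if k in RegistrationParams.__dataclass_fields__}
    return RegistrationParams(**known)
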
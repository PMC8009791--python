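"""Readers and writers for every pipeline artifact.

Plain-text formats throughout: outlines, curves, features, rater scores
and normative tables as CSV; landmarks and provenance as JSON; binary
masks as NIfTI (via nibabel) with a raw little-endian + JSON-header
fallback.  All numeric CSV output keeps full precision (9+ significant
digits); human-readable rounding happens only in report summaries.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curve import RadialCurve
from .features import CurveFeatures
from .geometry import LandmarkSet, Outline2D
from .icv import NormativeTable, VolumeMask

FLOAT_FMT = "%.17g"  # full double precision; files must round-trip exactly


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------- outlines

def write_outline_csv(outline: Outline2D, path) -> None:
    df = pd.DataFrame(outline.vertices, columns=["x_mm", "y_mm"])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_outline_csv(path, anterior_angle: float = np.pi) -> Outline2D:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["x_mm", "y_mm"]:
        extra = [c for c in df.columns if c not in ("x_mm", "y_mm")]
        raise FormatError(
            f"{path}: outline CSV must have exactly columns [x_mm, y_mm]; "
            f"unexpected: {extra or list(df.columns)}"
        )
    return Outline2D(vertices=df.to_numpy(dtype=float), anterior_angle=anterior_angle)


# ---------------------------------------------------------------- landmarks

LANDMARK_KEYS = ("left_porion", "left_exocanthion", "right_exocanthion")


def write_landmarks_json(lm: LandmarkSet, path) -> None:
    payload = {k: list(map(float, getattr(lm, k))) for k in LANDMARK_KEYS}
    payload["units"] = "mm"
    Path(path).write_text(json.dumps(payload, indent=2))


def read_landmarks_json(path) -> LandmarkSet:
    try:
        payload = json.loads(Path(path).read_text())
    except FileNotFoundError:
        raise FormatError(f"landmark file not found: {path}") from None
    missing = [k for k in LANDMARK_KEYS if k not in payload]
    if missing:
        raise FormatError(f"{path}: landmark JSON missing keys {missing}")
    vecs = {}
    for k in LANDMARK_KEYS:
        v = payload[k]
        if not (isinstance(v, (list, tuple)) and len(v) == 3):
            raise FormatError(f"{path}: landmark {k!r} must be a 3-vector, got {v!r}")
        vecs[k] = np.asarray(v, dtype=float)
    return LandmarkSet(**vecs)


# ---------------------------------------------------------------- curves

def write_curve_csv(curve: RadialCurve, path) -> None:
    """Curve CSV (theta_rad, y) plus a JSON sidecar with provenance."""
    path = Path(path)
    pd.DataFrame({"theta_rad": curve.theta, "y": curve.y}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    sidecar = {
        "n_samples": curve.n_samples,
        "normalized": curve.normalized,
        "aligned": curve.aligned,
        "alignment_shift_rad": curve.alignment_shift_rad,
        "scale_mm": curve.scale_mm,
        "anterior_angle": curve.anterior_angle,
        "left_angle": curve.left_angle,
        "smoothing_window": curve.smoothing_window,
        "warnings": list(curve.warnings),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_curve_csv(path) -> RadialCurve:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["theta_rad", "y"]:
        raise FormatError(f"{path}: curve CSV must have columns [theta_rad, y]")
    sidecar_path = path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return RadialCurve(
        theta=df["theta_rad"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        anterior_angle=float(meta.get("anterior_angle", np.pi)),
        left_angle=float(meta.get("left_angle", (np.pi + np.pi / 2) % (2 * np.pi))),
        normalized=bool(meta.get("normalized", False)),
        aligned=bool(meta.get("aligned", False)),
        alignment_shift_rad=float(meta.get("alignment_shift_rad", 0.0)),
        scale_mm=meta.get("scale_mm"),
        smoothing_window=meta.get("smoothing_window"),
        warnings=list(meta.get("warnings", [])),
    )


# ---------------------------------------------------------------- features

FEATURE_COLUMNS = [
    "F", "O", "R", "L", "XF", "XO", "XR", "XL",
    "width", "diff_occiput_sides", "diff_forehead_sides",
    "diff_forehead_occiput", "diff_forehead_occiput_signed",
    "Do", "Af", "Df", "Ao",
]


def features_to_frame(features: list[CurveFeatures], subject_ids=None) -> pd.DataFrame:
    if subject_ids is None:
        subject_ids = list(range(len(features)))
    rows = []
    for sid, f in zip(subject_ids, features):
        row = {"subject": sid}
        for col in FEATURE_COLUMNS:
            row[col] = getattr(f, col)
        row["abruptness_missing"] = ";".join(
            f"{k}:{v}" for k, v in sorted(f.abruptness_missing.items())
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject")


def write_features_csv(features: list[CurveFeatures], path, subject_ids=None) -> None:
    features_to_frame(features, subject_ids).to_csv(path, float_format=FLOAT_FMT)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject", float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: features CSV missing columns {missing}")
    return df


# ---------------------------------------------------------------- rater tables

RATER_COLUMNS = ["subject", "rater", "item", "score"]


def write_rater_csv(table: pd.DataFrame, path) -> None:
    table.loc[:, RATER_COLUMNS].to_csv(path, index=False)


def read_rater_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in RATER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: rater CSV missing columns {missing}")
    bad = df[~df["score"].isin([0, 1, 2])]
    if not bad.empty:
        raise FormatError(
            f"{path}: scores must be 0/1/2; offending rows (0-based): "
            f"{bad.index.tolist()[:10]}"
        )
    return df


# ---------------------------------------------------------------- normative tables

def write_normative_csv(table: NormativeTable, path) -> None:
    table.df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_normative_csv(path) -> NormativeTable:
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return NormativeTable(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------- volumes

def write_volume(mask: VolumeMask, path) -> None:
    """Write a binary mask as NIfTI (.nii) or raw uint8 + JSON header."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        affine = np.diag(list(mask.spacing_mm) + [1.0])
        affine[:3, 3] = mask.origin_mm
        nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))
    elif path.suffix == ".raw":
        path.write_bytes(mask.voxels.astype(np.uint8).tobytes(order="C"))
        header = {
            "shape": list(mask.voxels.shape),
            "dtype": "uint8",
            "order": "C",
            "spacing_mm": list(mask.spacing_mm),
            "origin_mm": list(mask.origin_mm),
        }
        path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    else:
        raise FormatError(f"unsupported volume format {path.suffix!r} (use .nii or .raw)")


def read_volume(path) -> VolumeMask:
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(o) for o in img.affine[:3, 3])
        return VolumeMask(
            voxels=np.asanyarray(img.dataobj) > 0, spacing_mm=spacing, origin_mm=origin
        )
    if path.suffix == ".raw":
        header_path = path.with_suffix(".json")
        if not header_path.exists():
            raise FormatError(f"raw volume {path} lacks its JSON header {header_path}")
        header = json.loads(header_path.read_text())
        vox = np.frombuffer(path.read_bytes(), dtype=header["dtype"]).reshape(
            header["shape"], order=header.get("order", "C")
        )
        return VolumeMask(
            voxels=vox > 0,
            spacing_mm=tuple(header["spacing_mm"]),
            origin_mm=tuple(header.get("origin_mm", (0.0, 0.0, 0.0))),
        )
    raise FormatError(f"unsupported volume format {path.suffix!r} (use .nii or .raw)")
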
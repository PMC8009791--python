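"""Intracranial volume from binary masks and normative SD-band classification.

The volume estimate is the Cavalieri sum: on every analyzed axial slice the
segmented intracranial area is multiplied by the slice spacing and the
products are summed.  The analysis range (start slice just above the foramen
magnum, end slice just beneath the vertex) is the caller's responsibility.
The result is compared against an age- and sex-specific normative table
(mean and SD in mL) and classified into one of seven SD bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage


class ICVError(ValueError):
    pass


# the seven band labels, superior to inferior of the normative range
BAND_ABOVE_2SD = "> + 2 SD"
BAND_1_TO_2SD = "+ 1 to + 2 SD"
BAND_MEAN_TO_P1SD = "Mean to + 1 SD"
BAND_AT_MEAN = "At mean"
BAND_MEAN_TO_M1SD = "Mean to − 1 SD"
BAND_M1_TO_M2SD = "− 1 to − 2 SD"
BAND_BELOW_2SD = "< − 2 SD"

ALL_BANDS = (
    BAND_BELOW_2SD,
    BAND_M1_TO_M2SD,
    BAND_MEAN_TO_M1SD,
    BAND_AT_MEAN,
    BAND_MEAN_TO_P1SD,
    BAND_1_TO_2SD,
    BAND_ABOVE_2SD,
)


@dataclass
class VolumeMask:
    """Binary voxel grid with physical spacing.

    ``voxels`` is indexed (x, y, z) with slices along the last axis;
    ``spacing_mm`` is (dx, dy, dz); ``origin_mm`` is the world position of
    the center of voxel (0, 0, 0).  ``start_slice``/``end_slice`` bound the
    analyzed range (half-open, like Python slices); None means full extent.
    ``analytic_volume_mm3`` may carry a known ground-truth volume for
    phantom grids.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    start_slice: int | None = None
    end_slice: int | None = None
    analytic_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ICVError("voxel grid must be 3-D")
        sp = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in sp):
            raise ICVError(f"voxel spacing must be positive, got {sp}")
        self.spacing_mm = sp
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def analyzed_range(self) -> tuple[int, int]:
        nz = self.voxels.shape[2]
        lo = 0 if self.start_slice is None else int(self.start_slice)
        hi = nz if self.end_slice is None else int(self.end_slice)
        if not (0 <= lo < hi <= nz):
            raise ICVError(f"analysis range [{lo}, {hi}) invalid for {nz} slices")
        return lo, hi


@dataclass(frozen=True)
class ICVResult:
    icv_ml: float
    method: str  # "slice_area_sum" | "voxel_count"
    n_slices: int
    slice_areas_mm2: np.ndarray | None = None
    band: str | None = None


class NormativeTable:
    """Age- and sex-specific normative intracranial volumes.

    Wraps a DataFrame with columns (sex, age_months, mean_ml, sd_ml); ages
    must be strictly increasing within each sex and SDs positive.  Values
    between tabulated ages are linearly interpolated; ages outside the
    tabulated range are rejected rather than extrapolated.
    """

    COLUMNS = ("sex", "age_months", "mean_ml", "sd_ml")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ICVError(f"normative table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["sex"] = df["sex"].astype(str).str.lower().str.strip()
        for sex, sub in df.groupby("sex"):
            ages = sub["age_months"].to_numpy(dtype=float)
            if not np.all(np.diff(ages) > 0):
                raise ICVError(f"ages not strictly increasing for sex={sex!r}")
            if np.any(sub["sd_ml"].to_numpy(dtype=float) <= 0):
                raise ICVError(f"non-positive SD in normative table for sex={sex!r}")
        self.df = df

    def lookup(self, age_months: float, sex: str) -> tuple[float, float]:
        """Interpolated (mean_ml, sd_ml) at ``age_months`` for ``sex``."""
        sub = self.df[self.df["sex"] == str(sex).lower().strip()]
        if sub.empty:
            raise ICVError(f"no normative rows for sex={sex!r}")
        ages = sub["age_months"].to_numpy(dtype=float)
        if not (ages[0] <= age_months <= ages[-1]):
            raise ICVError(
                f"age {age_months} months outside normative range "
                f"[{ages[0]}, {ages[-1]}] for sex={sex!r}; no extrapolation"
            )
        mean = float(np.interp(age_months, ages, sub["mean_ml"].to_numpy(dtype=float)))
        sd = float(np.interp(age_months, ages, sub["sd_ml"].to_numpy(dtype=float)))
        return mean, sd


def icv_from_mask(mask: VolumeMask, method: str = "slice_area_sum") -> ICVResult:
    """Intracranial volume of a binary mask, in mL.

    ``slice_area_sum`` is the Cavalieri estimate (foreground area per
    analyzed slice x slice spacing, summed); ``voxel_count`` multiplies the
    foreground voxel count by the voxel volume.  On an axis-aligned binary
    grid the two are algebraically identical; both are kept as mutual
    checks.
    """
    lo, hi = mask.analyzed_range()
    sub = mask.voxels[:, :, lo:hi]
    if not sub.any():
        raise ICVError(f"no foreground voxels in analyzed slice range [{lo}, {hi})")
    dx, dy, dz = mask.spacing_mm
    if method == "slice_area_sum":
        areas = sub.sum(axis=(0, 1)).astype(float) * dx * dy
        vol_mm3 = float(np.sum(areas * dz))
        return ICVResult(
            icv_ml=vol_mm3 / 1000.0,
            method=method,
            n_slices=hi - lo,
            slice_areas_mm2=areas,
        )
    if method == "voxel_count":
        vol_mm3 = float(sub.sum()) * mask.voxel_volume_mm3
        return ICVResult(icv_ml=vol_mm3 / 1000.0, method=method, n_slices=hi - lo)
    raise ICVError(f"unknown method {method!r}")


def normative_band(
    icv_ml: float,
    age_months: float,
    sex: str,
    table: NormativeTable,
    at_mean_tolerance: float = 0.05,
) -> str:
    """Classify a volume against the normative table into an SD band.

    The z-score uses the age-interpolated mean and SD.  |z| below
    ``at_mean_tolerance`` reads "At mean"; bands then step at 1 and 2 SD,
    with the open outer bands strictly beyond 2 SD.
    """
    mean, sd = table.lookup(age_months, sex)
    z = (icv_ml - mean) / sd
    if abs(z) < at_mean_tolerance:
        return BAND_AT_MEAN
    if z > 2:
        return BAND_ABOVE_2SD
    if z > 1:
        return BAND_1_TO_2SD
    if z > 0:
        return BAND_MEAN_TO_P1SD
    if z >= -1:
        return BAND_MEAN_TO_M1SD
    if z >= -2:
        return BAND_M1_TO_M2SD
    return BAND_BELOW_2SD


def classify_icv(
    mask: VolumeMask,
    age_months: float,
    sex: str,
    table: NormativeTable,
    at_mean_tolerance: float = 0.05,
) -> ICVResult:
    """Volume + band classification in one step."""
    res = icv_from_mask(mask)
    band = normative_band(res.icv_ml, age_months, sex, table, at_mean_tolerance)
    return ICVResult(
        icv_ml=res.icv_ml,
        method=res.method,
        n_slices=res.n_slices,
        slice_areas_mm2=res.slice_areas_mm2,
        band=band,
    )


def fill_holes(mask: VolumeMask) -> VolumeMask:
    """Close internal defects slice-by-slice (binary hole filling).

    Preprocessing convenience for masks whose inner-table outline has small
    gaps; the analysis itself assumes closed regions.
    """
    filled = np.stack(
        [ndimage.binary_fill_holes(mask.voxels[:, :, k]) for k in range(mask.voxels.shape[2])],
        axis=2,
    )
    return VolumeMask(
        voxels=filled,
        spacing_mm=mask.spacing_mm,
        origin_mm=mask.origin_mm,
        start_slice=mask.start_slice,
        end_slice=mask.end_slice,
        analytic_volume_mm3=mask.analytic_volume_mm3,
    )
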
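"""Volume and time-activity-curve I/O plus ROI statistics.

Dynamic PET studies deliver a 4-D activity volume (x, y, z, frame), a 3-D CT
volume calibrated in Hounsfield units, and an integer label mask drawn on the
fused image. This module extracts per-ROI mean time-activity curves (TACs)
and mean radiodensities, and reads/writes the plain-text exchange formats
used throughout the package (frame-schedule TSV, per-ROI TAC TSV, NIfTI
volumes via nibabel).

Conventions: masks are voxel-aligned with the volumes (array indexing,
0-based, no world-coordinate resampling) and the ROI statistic is the
unweighted arithmetic mean over mask voxels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Integer labels used in ROI masks (0 = background).
LABEL_BACKGROUND = 0
LABEL_SAT = 1
LABEL_BAT = 2
LABEL_BLOOD = 3
ROI_NAMES = {LABEL_SAT: "SAT", LABEL_BAT: "BAT", LABEL_BLOOD: "blood"}

#: Representable CT radiodensity range (12-bit scanner scale).
HU_MIN, HU_MAX = -1024.0, 3071.0

_TAC_COLUMNS = ["frame_start_min", "frame_duration_min", "activity_kBq_per_mL"]
_SCHEDULE_COLUMNS = ["frame_start_min", "frame_duration_min"]


@dataclasses.dataclass(frozen=True)
class FrameSchedule:
    """Frame timing of a dynamic PET acquisition, in minutes."""

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.atleast_1d(np.asarray(self.start, dtype=float))
        duration = np.atleast_1d(np.asarray(self.duration, dtype=float))
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape:
            raise ValueError("frame starts and durations must be 1-D and equally long")
        if start.size == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(duration <= 0):
            raise ValueError("frame durations must be positive")
        if start.size > 1 and np.any(np.diff(start) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if start.size > 1 and np.any(start[1:] < (start[:-1] + duration[:-1]) - 1e-9):
            raise ValueError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.start.size)

    @property
    def mid(self) -> np.ndarray:
        """Frame midpoints (min); the nominal sample times of a TAC."""
        return self.start + self.duration / 2.0

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def scan_end(self) -> float:
        return float(self.end[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (
            self.start.shape == other.start.shape
            and np.allclose(self.start, other.start)
            and np.allclose(self.duration, other.duration)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_start_min": self.start, "frame_duration_min": self.duration}
        )

    def to_tsv(self, path: str | Path) -> None:
        _write_fixed_tsv(self.to_frame(), path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FrameSchedule":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, _SCHEDULE_COLUMNS, path)
        return cls(df["frame_start_min"].to_numpy(), df["frame_duration_min"].to_numpy())


@dataclasses.dataclass(frozen=True)
class Tac:
    """A region-of-interest time-activity curve (kBq/mL per frame)."""

    schedule: FrameSchedule
    activity: np.ndarray
    roi_label: str = "ROI"

    def __post_init__(self) -> None:
        activity = np.atleast_1d(np.asarray(self.activity, dtype=float))
        object.__setattr__(self, "activity", activity)
        if activity.shape != self.schedule.start.shape:
            raise ValueError("activity length must match the frame schedule")
        if not np.all(np.isfinite(activity)):
            raise ValueError("TAC activity must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.schedule.mid

    def to_frame(self) -> pd.DataFrame:
        df = self.schedule.to_frame()
        df["activity_kBq_per_mL"] = self.activity
        return df

    def to_tsv(self, path: str | Path) -> None:
        _write_fixed_tsv(self.to_frame(), path)

    @classmethod
    def from_tsv(cls, path: str | Path, roi_label: str = "ROI") -> "Tac":
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, _TAC_COLUMNS, path)
        schedule = FrameSchedule(
            df["frame_start_min"].to_numpy(), df["frame_duration_min"].to_numpy()
        )
        return cls(schedule, df["activity_kBq_per_mL"].to_numpy(), roi_label)


@dataclasses.dataclass(frozen=True)
class RoiDensity:
    """Mean CT radiodensity of one ROI."""

    roi_label: str
    mean_hu: float
    voxel_count: int

    def __post_init__(self) -> None:
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if not (HU_MIN <= self.mean_hu <= HU_MAX):
            raise ValueError(
                f"mean HU {self.mean_hu:.1f} outside representable CT range "
                f"[{HU_MIN:.0f}, {HU_MAX:.0f}]"
            )


def as_array(volume) -> np.ndarray:
    """Accept a numpy array or a nibabel spatial image."""
    if isinstance(volume, nib.spatialimages.SpatialImage):
        return np.asarray(volume.get_fdata())
    return np.asarray(volume)


def extract_tac(pet_4d, mask, label: int, schedule: FrameSchedule) -> Tac:
    """ROI-mean TAC: per frame, the arithmetic mean of voxels where mask == label."""
    pet = as_array(pet_4d)
    msk = as_array(mask)
    if pet.ndim != 4:
        raise ValueError(f"PET volume must be 4-D (x, y, z, frame); got {pet.ndim}-D")
    if msk.shape != pet.shape[:3]:
        raise ValueError(f"mask shape {msk.shape} != PET spatial shape {pet.shape[:3]}")
    if pet.shape[3] != schedule.n_frames:
        raise ValueError(
            f"PET has {pet.shape[3]} frames but schedule has {schedule.n_frames}"
        )
    sel = msk == label
    if not sel.any():
        raise ValueError(f"empty ROI: label {label} absent from mask")
    values = pet[sel].mean(axis=0)
    return Tac(schedule, values, ROI_NAMES.get(label, f"label{label}"))


def extract_hu(ct_3d, mask, label: int) -> RoiDensity:
    """ROI-mean CT radiodensity over voxels where mask == label."""
    ct = as_array(ct_3d)
    msk = as_array(mask)
    if ct.ndim != 3:
        raise ValueError(f"CT volume must be 3-D; got {ct.ndim}-D")
    if msk.shape != ct.shape:
        raise ValueError(f"mask shape {msk.shape} != CT shape {ct.shape}")
    sel = msk == label
    if not sel.any():
        raise ValueError(f"empty ROI: label {label} absent from mask")
    voxels = ct[sel]
    return RoiDensity(
        ROI_NAMES.get(label, f"label{label}"),
        float(voxels.mean()),
        int(voxels.size),
    )


def save_nifti(array: np.ndarray, path: str | Path, voxel_size_mm: float = 0.8) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def _write_fixed_tsv(df: pd.DataFrame, path: str | Path) -> None:
    # Fixed 6-decimal format so that write -> read -> write is byte-identical.
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
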
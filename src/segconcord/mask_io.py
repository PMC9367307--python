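"""Reading, validating and writing binary 3D masks and cohort metadata.

Masks are exchanged as NIfTI volumes and compared strictly on their native
grid: two masks are only comparable when their dimensions, voxel spacing
and orientation agree.  Nothing here resamples — a geometry mismatch is a
hard error so that voxel tallies downstream are never silently corrupted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MaskVolume",
    "CaseRecord",
    "MaskGeometryError",
    "CompatibilityResult",
    "load_mask",
    "save_mask",
    "check_compatible",
    "mask_volume_mm3",
    "load_cohort_table",
    "save_cohort_table",
    "cohort_to_frame",
    "VENDOR_LEVELS",
    "FIELD_STRENGTH_LEVELS",
    "LOCATION_LEVELS",
    "SEQUENCE_LEVELS",
    "COHORT_COLUMNS",
]

VENDOR_LEVELS = ("Siemens", "Philips", "GE")
FIELD_STRENGTH_LEVELS = (1.5, 3.0)
LOCATION_LEVELS = ("abdominopelvic", "cervicothoracic")
SEQUENCE_LEVELS = ("T2w", "T2w-fat-sat")

COHORT_COLUMNS = (
    "case_id",
    "vendor",
    "field_strength",
    "location",
    "sequence",
    "age_months",
    "volume_mm3",
)

# Common spellings seen in acquisition spreadsheets, mapped onto the two
# canonical sequence levels.
_SEQUENCE_ALIASES = {
    "t2": "T2w",
    "t2w": "T2w",
    "t2-w": "T2w",
    "t2 fat sat": "T2w-fat-sat",
    "t2w fat sat": "T2w-fat-sat",
    "t2w-fat-sat": "T2w-fat-sat",
    "t2 fat-sat": "T2w-fat-sat",
    "t2w fatsat": "T2w-fat-sat",
    "t2 fatsat": "T2w-fat-sat",
}


class MaskGeometryError(ValueError):
    """Raised when a mask file or mask pair has unusable geometry."""


def normalize_sequence(value: str) -> str:
    """Map a free-form sequence label onto a canonical level.

    Raises ``ValueError`` for labels that cannot be interpreted.
    """
    key = str(value).strip().lower()
    if key in _SEQUENCE_ALIASES:
        return _SEQUENCE_ALIASES[key]
    raise ValueError(
        f"unknown sequence label {value!r}; expected one of {SEQUENCE_LEVELS}"
    )


@dataclass
class MaskVolume:
    """A 3D binary label grid with physical voxel spacing.

    Parameters
    ----------
    voxels
        3D array with values in {0, 1} (stored as ``uint8``).
    spacing
        Per-axis voxel edge length in millimetres, strictly positive.
    affine
        4x4 voxel-to-world affine.  Defaults to a diagonal affine built
        from the spacing.
    case_id
        Opaque identifier used to pair masks across directories.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise MaskGeometryError(
                f"mask grid must be 3D, got shape {arr.shape}"
            )
        if any(s < 1 for s in arr.shape):
            raise MaskGeometryError(f"degenerate grid shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(
                f"mask voxels must be 0/1 after binarization, found {uniq[:5]}"
            )
        self.voxels = arr.astype(np.uint8)
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise MaskGeometryError(f"spacing must be 3 positive lengths, got {sp}")
        self.spacing = sp
        if self.affine is None:
            self.affine = np.diag((*sp, 1.0))
        else:
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise MaskGeometryError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy_with(self, voxels: np.ndarray) -> "MaskVolume":
        """New mask with the same geometry and a replaced voxel grid."""
        return MaskVolume(
            voxels=voxels, spacing=self.spacing, affine=self.affine.copy(),
            case_id=self.case_id,
        )


@dataclass(frozen=True)
class CaseRecord:
    """One cohort row: identifier plus acquisition covariates."""

    case_id: str
    vendor: str
    field_strength: float
    location: str
    sequence: str
    age_months: float
    volume_mm3: float

    def __post_init__(self) -> None:
        if self.vendor not in VENDOR_LEVELS:
            raise ValueError(f"vendor {self.vendor!r} not in {VENDOR_LEVELS}")
        if float(self.field_strength) not in FIELD_STRENGTH_LEVELS:
            raise ValueError(
                f"field_strength {self.field_strength!r} not in {FIELD_STRENGTH_LEVELS}"
            )
        object.__setattr__(self, "field_strength", float(self.field_strength))
        if self.location not in LOCATION_LEVELS:
            raise ValueError(f"location {self.location!r} not in {LOCATION_LEVELS}")
        if self.sequence not in SEQUENCE_LEVELS:
            object.__setattr__(self, "sequence", normalize_sequence(self.sequence))
        if self.age_months < 0:
            raise ValueError("age_months must be nonnegative")
        if self.volume_mm3 < 0:
            raise ValueError("volume_mm3 must be nonnegative")


@dataclass(frozen=True)
class CompatibilityResult:
    """Outcome of a geometry comparison; truthy iff the grids agree."""

    ok: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.ok


def load_mask(path: str | Path, threshold: float = 0.0) -> MaskVolume:
    """Load a NIfTI mask and binarize it.

    Any voxel with value strictly greater than ``threshold`` (default 0,
    i.e. any nonzero label) becomes foreground.  4D volumes with a
    singleton trailing axis are squeezed; any other 4D shape is rejected.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise MaskGeometryError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4:
        if data.shape[3] == 1:
            data = data[..., 0]
        else:
            raise MaskGeometryError(
                f"{path}: 4D volume with non-singleton 4th axis {data.shape}"
            )
    if data.ndim != 3:
        raise MaskGeometryError(f"{path}: expected 3D geometry, got {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise MaskGeometryError(f"{path}: nonpositive voxel spacing {zooms}")
    case_id = path.name
    for suffix in (".nii.gz", ".nii"):
        if case_id.endswith(suffix):
            case_id = case_id[: -len(suffix)]
            break
    return MaskVolume(
        voxels=(data > threshold).astype(np.uint8),
        spacing=zooms,
        affine=np.asarray(img.affine, dtype=float),
        case_id=case_id,
    )


def save_mask(mask: MaskVolume, path: str | Path) -> Path:
    """Write a mask as a NIfTI volume (uint8 labels, original affine)."""
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path


def check_compatible(
    a: MaskVolume, b: MaskVolume, tol: float = 1e-3
) -> CompatibilityResult:
    """Decide whether two masks live on the same voxel grid.

    Grid dimensions must match exactly; spacing and affine must agree
    within ``tol`` (absolute, in mm).  Symmetric in its mask arguments.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    if a.shape != b.shape:
        return CompatibilityResult(False, f"shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=0.0, atol=tol):
        return CompatibilityResult(
            False, f"spacing mismatch {a.spacing} vs {b.spacing}"
        )
    if not np.allclose(a.affine, b.affine, rtol=0.0, atol=tol):
        return CompatibilityResult(False, "affine/orientation mismatch")
    return CompatibilityResult(True)


def mask_volume_mm3(mask: MaskVolume) -> float:
    """Physical foreground volume: voxel count x voxel volume (mm^3)."""
    return mask.foreground_count * mask.voxel_volume_mm3


def load_cohort_table(path: str | Path) -> list[CaseRecord]:
    """Read a cohort CSV into validated :class:`CaseRecord` rows.

    Required columns: ``case_id, vendor, field_strength, location,
    sequence, age_months, volume_mm3``.  Unknown categorical levels and
    duplicated case identifiers are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing columns {missing}")
    dupes = df["case_id"][df["case_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate case_id values: {sorted(set(map(str, dupes)))}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CaseRecord(
                case_id=str(row.case_id),
                vendor=str(row.vendor),
                field_strength=float(row.field_strength),
                location=str(row.location),
                sequence=str(row.sequence),
                age_months=float(row.age_months),
                volume_mm3=float(row.volume_mm3),
            )
        )
    return records


def cohort_to_frame(records: Iterable[CaseRecord]) -> pd.DataFrame:
    """Cohort records as a DataFrame with the canonical column order."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))
    return df[list(COHORT_COLUMNS)]


def save_cohort_table(records: Iterable[CaseRecord], path: str | Path) -> Path:
    path = Path(path)
    cohort_to_frame(records).to_csv(path, index=False)
    return path
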
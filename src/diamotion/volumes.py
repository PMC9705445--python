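"""Mask/intensity volume containers, NIfTI I/O, and tabular cohort I/O.

All geometry in this package runs on one fixed anatomical axis convention:

* axis 0 — subject right → left  (nibabel axis code ``L``)
* axis 1 — posterior → anterior  (``A``)
* axis 2 — caudal → cranial      (``S``)

Voxel indices are 0-based and the physical coordinate of a voxel center is
``index * spacing`` along each axis (millimetres).  Volumes loaded from disk
are reoriented to this convention from their header affine before any
measurement is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel import orientations as nio

#: nibabel axis codes of the package-wide convention (see module docstring).
AXIS_CODES = ("L", "A", "S")

#: Canonical names of the eight inspiration/expiration ratio outcomes.
OUTCOME_NAMES = (
    "lung_volume_ratio",
    "diaphragm_volume_ratio",
    "lung_area_ratio",
    "cranial_caudal_ratio",
    "anterior_posterior_ratio",
    "cc_ap_ratio",
    "diaphragm_height_ratio",
    "diaphragm_area_ratio",
)

VISIT_LABELS = ("initial", "follow-up")


class VolumeLoadError(ValueError):
    """Raised when a volume on disk violates the I/O contract."""


class CohortTableError(ValueError):
    """Raised when a cohort or outcomes table violates its schema."""


@dataclass
class MaskVolume:
    """A 3D boolean voxel grid with per-axis spacing in mm.

    Parameters
    ----------
    data
        Boolean array, axes per the package convention.
    spacing
        Voxel size in mm along each axis.
    convention
        Axis-convention tag; volumes produced by this package carry "LAS".
    labels
        Optional integer label image recording multi-label input
        (e.g. left=1 / right=2 segmentations) before binarization.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    convention: str = "LAS"
    labels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeLoadError(f"mask must be 3D, got {self.data.ndim} dims")
        if self.data.size == 0:
            raise VolumeLoadError("mask grid is empty")
        self.data = self.data.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeLoadError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def affine(self) -> np.ndarray:
        """NIfTI affine encoding the LAS convention with this spacing."""
        sx, sy, sz = self.spacing
        return np.diag([-sx, sy, sz, 1.0])


@dataclass
class ScalarVolume:
    """A 3D grayscale volume on the same grid contract as :class:`MaskVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    convention: str = "LAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise VolumeLoadError(f"volume must be 3D, got {self.data.ndim} dims")
        self.spacing = tuple(float(s) for s in self.spacing)

    def affine(self) -> np.ndarray:
        sx, sy, sz = self.spacing
        return np.diag([-sx, sy, sz, 1.0])


@dataclass
class BreathPair:
    """End-expiration and end-inspiration masks of one visit on a common grid."""

    expiration: MaskVolume
    inspiration: MaskVolume

    def __post_init__(self) -> None:
        if self.expiration.shape != self.inspiration.shape:
            raise VolumeLoadError(
                "breath pair grids differ: "
                f"{self.expiration.shape} vs {self.inspiration.shape}"
            )
        if not np.allclose(self.expiration.spacing, self.inspiration.spacing):
            raise VolumeLoadError(
                "breath pair spacings differ: "
                f"{self.expiration.spacing} vs {self.inspiration.spacing}"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.expiration.spacing


def _reorient(data: np.ndarray, affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reorient ``data`` to the package LAS convention; returns (data, ornt)."""
    try:
        src = nio.io_orientation(affine)
    except Exception as exc:  # pragma: no cover - nibabel internals
        raise VolumeLoadError(f"unrecognized orientation in affine: {exc}") from exc
    if np.any(np.isnan(src)):
        raise VolumeLoadError("unrecognized orientation: affine has degenerate axes")
    dst = nio.axcodes2ornt(AXIS_CODES)
    transform = nio.ornt_transform(src, dst)
    return nio.apply_orientation(data, transform), transform


def load_mask(path: str | Path) -> MaskVolume:
    """Load a NIfTI mask, binarize at > 0 and reorient to the LAS convention.

    Multi-label inputs (per-lung labels) are accepted; the original labels are
    kept on ``MaskVolume.labels`` after reorientation.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"{path.name}: expected a 3D single-channel volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeLoadError(f"{path.name}: missing or invalid spacing in header: {zooms}")
    data, transform = _reorient(data, img.affine)
    # spacing follows the axis permutation
    order = transform[:, 0].astype(int)
    spacing = tuple(float(zooms[np.where(order == i)[0][0]]) for i in range(3))
    labels = data.astype(np.int16) if data.max(initial=0) > 1 else None
    return MaskVolume(data > 0, spacing, labels=labels)


def save_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a mask (or its label image, if present) as NIfTI-1."""
    data = mask.labels if mask.labels is not None else mask.data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.uint8), mask.affine())
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_scalar(path: str | Path) -> ScalarVolume:
    """Load a grayscale NIfTI volume, reoriented to the LAS convention."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 3:
        raise VolumeLoadError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    data, transform = _reorient(data, img.affine)
    order = transform[:, 0].astype(int)
    spacing = tuple(float(zooms[np.where(order == i)[0][0]]) for i in range(3))
    return ScalarVolume(data, spacing)


def save_scalar(vol: ScalarVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine())
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

#: Required columns of the per-subject cohort CSV.
COHORT_REQUIRED = ("subject_id", "group", "sex")

#: Optional cohort columns (missing ones are reported, not fatal).
COHORT_OPTIONAL = (
    "age_years",
    "height_cm",
    "weight_kg",
    "ert_duration_years",
    "fvc_upright_pct_initial",
    "fvc_upright_pct_followup",
    "fvc_supine_pct_initial",
    "fvc_supine_pct_followup",
    "mip_pct_initial",
    "mip_pct_followup",
    "mep_pct_initial",
    "mep_pct_followup",
    "followup_interval_years",
)

GROUPS = ("patient", "control")


def cohort_schema() -> str:
    """Human-readable schema of the cohort CSV (printed by ``--help-schema``)."""
    lines = ["Cohort CSV schema (UTF-8, header row, decimal point):", "required:"]
    lines += [f"  {c}" for c in COHORT_REQUIRED]
    lines.append("optional:")
    lines += [f"  {c}" for c in COHORT_OPTIONAL]
    lines.append("group must be patient|control (case-insensitive);")
    lines.append("ert_duration_years is empty for controls and untreated patients.")
    return "\n".join(lines)


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Load and validate the per-subject cohort table.

    Returns a typed DataFrame with normalized group labels and an
    ``ert_status`` column (untreated / treated / empty for controls).
    A validation report of missing optional fields is attached as
    ``df.attrs["missing_fields"]``.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise CohortTableError(f"cohort table missing required columns: {missing}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"].unique())
        raise CohortTableError(f"duplicate subject ids: {dupes}")
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise CohortTableError(f"unknown group labels: {bad} (expected {GROUPS})")
    if "ert_duration_years" in df.columns:
        dur = pd.to_numeric(df["ert_duration_years"], errors="coerce")
        df["ert_duration_years"] = dur
        is_control = df["group"] == "control"
        if (is_control & dur.notna()).any():
            raise CohortTableError("ert_duration_years must be empty for controls")
        df["ert_status"] = np.where(
            is_control, "", np.where(dur.notna(), "treated", "untreated")
        )
    for col in COHORT_OPTIONAL:
        if col in df.columns and col != "ert_duration_years":
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df.attrs["missing_fields"] = [c for c in COHORT_OPTIONAL if c not in df.columns]
    return df


def outcomes_schema() -> str:
    lines = [
        "Per-subject outcomes CSV schema (one row per subject and visit):",
        "required columns:",
        "  subject_id, group, visit (initial|follow-up),",
    ]
    lines += [f"  {c}" for c in OUTCOME_NAMES]
    lines.append("extra columns (e.g. pulmonary-function values) are carried through.")
    return "\n".join(lines)


def load_supplementary_outcomes(path: str | Path) -> pd.DataFrame:
    """Load a per-subject outcomes table (CSV conversion of a study supplement).

    One row per subject per visit with the eight ratio outcomes; extra columns
    are tolerated and preserved so pulmonary-function values can ride along.
    """
    df = pd.read_csv(path)
    required = ["subject_id", "group", "visit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortTableError(f"outcomes table missing columns: {missing}")
    missing_outcomes = [c for c in OUTCOME_NAMES if c not in df.columns]
    if missing_outcomes:
        raise CohortTableError(
            "outcomes table missing outcome columns: "
            f"{missing_outcomes}; expected all of {list(OUTCOME_NAMES)}"
        )
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["group"] = df["group"].astype(str).str.strip().str.lower()
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise CohortTableError(f"unknown group labels: {bad}")
    df["visit"] = df["visit"].astype(str).str.strip().str.lower()
    bad_visits = sorted(set(df["visit"]) - set(VISIT_LABELS))
    if bad_visits:
        raise CohortTableError(
            f"unknown visit labels: {bad_visits} (expected {VISIT_LABELS})"
        )
    for col in OUTCOME_NAMES:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df
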
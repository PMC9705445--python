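"""The eight inspiration/expiration outcome ratios from a breath-hold pair.

3D outcomes (computed on both lungs):

1. lung volume ratio — relative increase in lung volume;
2. diaphragm volume ratio — fraction of the inspiratory volume gain swept by
   the diaphragm surface (caudal lung boundary) between phases.

2D outcomes, computed on the sagittal slice through the middle of the right
lung's left-right extent (the right mid hemi-diaphragm level, selected on
the expiratory mask and reused for the inspiratory mask of the same visit):

3. lung area ratio; 4. cranial-caudal ratio (diaphragm motion);
5. anterior-posterior ratio (thoracic-wall motion); 6. CC-AP ratio;
7. diaphragm height ratio and 8. diaphragm area ratio (curvature): height is
the maximum perpendicular distance from the diaphragm contour to the chord
joining its anterior- and posterior-most points, area is the shoelace area
of the closed contour+chord polygon.

Across visits, sagittal levels are matched by exhaustive integer-shift
Dice maximization of the expiratory right-lung masks.

Undefined outcomes (e.g. a flat expiratory dome, or no inspiratory volume
gain) are carried as NaN with a reason code, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .segmentation import split_sides
from .volumes import OUTCOME_NAMES, BreathPair, MaskVolume


class UndefinedMeasure(ValueError):
    """An outcome that is undefined for this input; carries a reason code."""

    def __init__(self, reason: str, message: str | None = None):
        self.reason = reason
        super().__init__(f"{reason}: {message}" if message else reason)


class MeasureError(ValueError):
    """A hard input error (empty mask, bad level)."""


# ---------------------------------------------------------------------------
# 3D outcomes
# ---------------------------------------------------------------------------


def lung_volume(mask: MaskVolume) -> float:
    """Total lung volume in mm^3 (voxel count x voxel volume)."""
    n = mask.count()
    if n == 0:
        raise MeasureError("empty lung mask")
    return n * mask.voxel_volume


def volume_ratio(pair: BreathPair) -> float:
    """Outcome (1): inspiratory / expiratory lung volume over both lungs."""
    return lung_volume(pair.inspiration) / lung_volume(pair.expiration)


def diaphragm_surface(mask: MaskVolume) -> np.ndarray:
    """Caudal lung boundary: per (axis0, axis1) column, the minimum axis-2
    index of lung voxels; NaN outside the lung footprint."""
    if not mask.data.any():
        raise MeasureError("empty lung mask")
    # argmax finds the first True along axis 2; guard columns without lung
    has_lung = mask.data.any(axis=2)
    first = mask.data.argmax(axis=2).astype(float)
    first[~has_lung] = np.nan
    return first


def diaphragm_volume_ratio(pair: BreathPair) -> float:
    """Outcome (2): diaphragm-swept volume / total lung-volume gain.

    Swept volume sums, over columns in the shared lung footprint,
    max(0, z_exp_surface - z_insp_surface) times the voxel cross-section.
    """
    v_exp = lung_volume(pair.expiration)
    v_insp = lung_volume(pair.inspiration)
    if v_insp <= v_exp:
        raise UndefinedMeasure(
            "nonpositive_volume_gain",
            "inspiratory volume does not exceed expiratory volume",
        )
    s_exp = diaphragm_surface(pair.expiration)
    s_insp = diaphragm_surface(pair.inspiration)
    shared = ~np.isnan(s_exp) & ~np.isnan(s_insp)
    sx, sy, sz = pair.spacing
    drop = np.maximum(0.0, s_exp[shared] - s_insp[shared])
    swept = float(drop.sum()) * sz * sx * sy
    return swept / (v_insp - v_exp)


# ---------------------------------------------------------------------------
# Sagittal level selection and cross-visit matching
# ---------------------------------------------------------------------------


def select_sagittal_level(right_lung_exp: MaskVolume) -> int:
    """Mid hemi-diaphragm level: rounded midpoint of the right lung's
    axis-0 extent on the expiratory mask."""
    idx = np.flatnonzero(right_lung_exp.data.any(axis=(1, 2)))
    if idx.size == 0:
        raise MeasureError("empty right-lung mask")
    lo, hi = int(idx[0]), int(idx[-1])
    return int(np.floor((lo + hi) / 2.0 + 0.5))


@dataclass(frozen=True)
class MatchResult:
    """Cross-visit level match: follow-up level, best shift and Dice."""

    level_followup: int
    shift: tuple[int, int, int]
    dice: float
    fallback: bool = False


def match_visits(
    exp_initial: MaskVolume,
    exp_followup: MaskVolume,
    level_initial: int,
    max_shift: int = 10,
) -> MatchResult:
    """Match the initial sagittal level onto the follow-up scan.

    Exhaustive integer-shift search (+-max_shift voxels per axis) maximizing
    the Dice overlap of the expiratory right-lung masks; the follow-up level
    is the initial level plus the best axis-0 shift.  Ties are broken toward
    the zero shift.  If the best Dice is below 0.5 a warning is emitted and
    the level falls back to :func:`select_sagittal_level` on the follow-up.
    """
    a = exp_initial.data.astype(np.float32)
    b = exp_followup.data.astype(np.float32)
    if a.shape != b.shape:
        raise MeasureError("visit masks must share one grid shape")
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 or nb == 0:
        raise MeasureError("empty mask in visit matching")
    # crop both masks to their joint bounding box (overlap sums are unchanged)
    union = exp_initial.data | exp_followup.data
    slices = []
    for axis in range(3):
        idx = np.flatnonzero(union.any(axis=tuple(i for i in range(3) if i != axis)))
        slices.append(slice(max(0, idx[0] - 1), idx[-1] + 2))
    a = a[tuple(slices)]
    b = b[tuple(slices)]
    if min(a.shape) <= max_shift:  # keep the shift window inside the correlation
        pad = [(0, max(0, max_shift + 1 - n)) for n in a.shape]
        a = np.pad(a, pad)
        b = np.pad(b, pad)
    # overlap(s) = sum_t b[t] a[t - s], all shifts at once via FFT correlation
    corr = fftconvolve(b, a[::-1, ::-1, ::-1], mode="full")
    center = np.array(a.shape) - 1
    m = max_shift
    window = corr[
        center[0] - m : center[0] + m + 1,
        center[1] - m : center[1] + m + 1,
        center[2] - m : center[2] + m + 1,
    ]
    overlap = np.rint(window).astype(np.int64)
    dice = 2.0 * overlap / (na + nb)
    best = dice.max()
    cands = np.argwhere(dice >= best - 1e-12) - m
    key = lambda s: (int(abs(s).sum()), *map(int, abs(s)), *map(int, s))
    shift = tuple(int(v) for v in min(cands, key=key))
    if best < 0.5:
        warnings.warn(
            f"visit matching weak (best Dice {best:.2f} < 0.5); "
            "falling back to follow-up level selection",
            stacklevel=2,
        )
        return MatchResult(select_sagittal_level(exp_followup), shift, float(best), True)
    return MatchResult(level_initial + shift[0], shift, float(best))


# ---------------------------------------------------------------------------
# 2D outcomes
# ---------------------------------------------------------------------------


def _slice(mask: MaskVolume, level: int) -> np.ndarray:
    if not 0 <= level < mask.shape[0]:
        raise MeasureError(f"sagittal level {level} outside grid of {mask.shape[0]} slices")
    return mask.data[level]


def slice_extent_ratios(pair: BreathPair, level: int) -> dict[str, float]:
    """Outcomes (3)-(6) at a sagittal level.

    area = pixel count x pixel area; extents use the inclusive index span
    (max - min + 1) x spacing along axis 2 (cranial-caudal) and axis 1
    (anterior-posterior); each ratio is inspiration / expiration and
    cc_ap_ratio is their quotient.
    """
    _, sy, sz = pair.spacing
    vals: dict[str, dict[str, float]] = {}
    for phase, mask in (("exp", pair.expiration), ("insp", pair.inspiration)):
        sl = _slice(mask, level)
        if not sl.any():
            raise UndefinedMeasure("empty_slice", f"no lung pixels on the {phase} slice")
        jj, kk = np.nonzero(sl)
        vals[phase] = {
            "area": sl.sum() * sy * sz,
            "ap": (jj.max() - jj.min() + 1) * sy,
            "cc": (kk.max() - kk.min() + 1) * sz,
        }
    out = {
        "lung_area_ratio": vals["insp"]["area"] / vals["exp"]["area"],
        "cranial_caudal_ratio": vals["insp"]["cc"] / vals["exp"]["cc"],
        "anterior_posterior_ratio": vals["insp"]["ap"] / vals["exp"]["ap"],
    }
    out["cc_ap_ratio"] = out["cranial_caudal_ratio"] / out["anterior_posterior_ratio"]
    out.update(
        {
            f"{k}_{phase}": vals[phase][k]
            for phase in ("exp", "insp")
            for k in ("area", "cc", "ap")
        }
    )
    return out


@dataclass(frozen=True)
class DomeGeometry2D:
    """Diaphragm contour, chord and curvature measures on a sagittal slice.

    contour : (N, 2) array of (y, z) mm points, one per anterior-posterior
              column, ordered posterior to anterior
    chord   : (2, 2) array, the anterior-most and posterior-most contour points
    height  : mm, maximum perpendicular contour-to-chord distance
    area    : mm^2, shoelace area of the closed contour+chord polygon
    """

    contour: np.ndarray
    chord: np.ndarray
    height: float
    area: float


def dome_geometry(slice2d: np.ndarray, spacing: tuple[float, float]) -> DomeGeometry2D:
    """Extract the diaphragm dome geometry from a 2D sagittal lung mask.

    ``slice2d`` has axes (anterior-posterior, cranial-caudal); ``spacing``
    is (mm per AP pixel, mm per CC pixel).  The contour takes, per AP
    column containing lung, the caudal-most lung pixel.
    """
    slice2d = np.asarray(slice2d, dtype=bool)
    if slice2d.ndim != 2:
        raise MeasureError("sagittal slice must be 2D")
    sy, sz = spacing
    cols = np.flatnonzero(slice2d.any(axis=1))
    if cols.size < 3:
        raise UndefinedMeasure("short_contour", f"diaphragm contour has {cols.size} point(s)")
    zmin = slice2d[cols].argmax(axis=1)  # first True along CC = caudal-most
    contour = np.column_stack([cols * sy, zmin * sz]).astype(float)
    chord = np.array([contour[0], contour[-1]])
    d = chord[1] - chord[0]
    norm = float(np.hypot(*d))
    if norm == 0:
        raise UndefinedMeasure("degenerate_chord", "chord endpoints coincide")
    # perpendicular distance of every contour point to the chord line
    rel = contour - chord[0]
    height = float(np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]).max() / norm)
    # shoelace; the implicit closing edge (last -> first point) is the chord
    x, y = contour[:, 0], contour[:, 1]
    area = 0.5 * float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return DomeGeometry2D(contour=contour, chord=chord, height=height, area=area)


def curvature_ratios(pair: BreathPair, level: int) -> dict[str, float]:
    """Outcomes (7)-(8): dome height and area ratios at a sagittal level.

    Undefined (reason ``flat_expiratory_dome``) when the expiratory dome
    height is below one voxel, since the ratio denominator is then dominated
    by rasterization.
    """
    _, sy, sz = pair.spacing
    geo_exp = dome_geometry(_slice(pair.expiration, level), (sy, sz))
    geo_insp = dome_geometry(_slice(pair.inspiration, level), (sy, sz))
    if geo_exp.height < sz:
        raise UndefinedMeasure(
            "flat_expiratory_dome",
            f"expiratory dome height {geo_exp.height:.2f} mm below one voxel",
        )
    return {
        "diaphragm_height_ratio": geo_insp.height / geo_exp.height,
        "diaphragm_area_ratio": geo_insp.area / geo_exp.area,
        "dome_height_exp": geo_exp.height,
        "dome_height_insp": geo_insp.height,
        "dome_area_exp": geo_exp.area,
        "dome_area_insp": geo_insp.area,
    }


# ---------------------------------------------------------------------------
# Per-visit and per-subject assembly
# ---------------------------------------------------------------------------


@dataclass
class SubjectMeasures:
    """All eight outcomes of one visit, with raw per-phase values.

    Undefined outcomes are NaN in ``ratios`` with a reason code in
    ``reasons``.
    """

    level: int
    ratios: dict[str, float]
    raw: dict[str, float] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, float]:
        return dict(self.ratios)


def compute_measures(pair: BreathPair, level: int | None = None) -> SubjectMeasures:
    """Compute all eight outcomes of one visit.

    The sagittal level defaults to the right mid hemi-diaphragm selected on
    the expiratory mask (right lung = smaller mean axis-0 coordinate).
    """
    if level is None:
        level = select_sagittal_level(split_sides(pair.expiration).right)
    ratios: dict[str, float] = {name: float("nan") for name in OUTCOME_NAMES}
    raw: dict[str, float] = {}
    reasons: dict[str, str] = {}

    raw["lung_volume_exp"] = lung_volume(pair.expiration)
    raw["lung_volume_insp"] = lung_volume(pair.inspiration)
    ratios["lung_volume_ratio"] = raw["lung_volume_insp"] / raw["lung_volume_exp"]
    try:
        ratios["diaphragm_volume_ratio"] = diaphragm_volume_ratio(pair)
    except UndefinedMeasure as exc:
        reasons["diaphragm_volume_ratio"] = exc.reason

    try:
        extent = slice_extent_ratios(pair, level)
        for name in (
            "lung_area_ratio",
            "cranial_caudal_ratio",
            "anterior_posterior_ratio",
            "cc_ap_ratio",
        ):
            ratios[name] = extent.pop(name)
        raw.update(extent)
    except UndefinedMeasure as exc:
        for name in ("lung_area_ratio", "cranial_caudal_ratio", "anterior_posterior_ratio", "cc_ap_ratio"):
            reasons[name] = exc.reason

    try:
        curv = curvature_ratios(pair, level)
        ratios["diaphragm_height_ratio"] = curv.pop("diaphragm_height_ratio")
        ratios["diaphragm_area_ratio"] = curv.pop("diaphragm_area_ratio")
        raw.update(curv)
    except UndefinedMeasure as exc:
        reasons["diaphragm_height_ratio"] = exc.reason
        reasons["diaphragm_area_ratio"] = exc.reason

    return SubjectMeasures(level=level, ratios=ratios, raw=raw, reasons=reasons)


@dataclass
class SubjectComparison:
    """Two visits of measures plus follow-up-minus-initial change scores."""

    initial: SubjectMeasures
    followup: SubjectMeasures
    changes: dict[str, float]
    match: MatchResult


def compute_subject(pair_initial: BreathPair, pair_followup: BreathPair) -> SubjectComparison:
    """Full per-subject longitudinal analysis.

    Selects the sagittal level on the initial expiratory scan, matches it
    onto the follow-up by integer-shift Dice registration of the expiratory
    right-lung masks, computes all eight outcomes per visit at the matched
    levels, and returns follow-up minus initial change scores (NaN where
    either visit's value is undefined).
    """
    right_initial = split_sides(pair_initial.expiration).right
    right_followup = split_sides(pair_followup.expiration).right
    level_initial = select_sagittal_level(right_initial)
    match = match_visits(right_initial, right_followup, level_initial)
    initial = compute_measures(pair_initial, level_initial)
    followup = compute_measures(pair_followup, match.level_followup)
    changes = {
        name: followup.ratios[name] - initial.ratios[name] for name in OUTCOME_NAMES
    }
    return SubjectComparison(initial=initial, followup=followup, changes=changes, match=match)
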
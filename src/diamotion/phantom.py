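"""Parametric thorax phantom with analytically known motion/curvature ratios.

The phantom builds paired end-expiration / end-inspiration two-lung masks on
a shared voxel grid.  Each lung is an elliptic cylinder (cross-section in the
axial plane) capped caudally by a diaphragm dome and cranially by a flat apex
plane.  The dome is an elliptic paraboloid by default,

    z_d(x, y) = base_level + h * max(0, 1 - ((x-cx)^2/a^2 + (y-cy)^2/b^2)),

or, optionally, a stretched spherical cap with ``sqrt`` in place of the linear
ramp.  Both admit closed forms for every outcome the measurement module
computes (cap volume, mid-sagittal dome height/area, extents), so each
phantom carries exact ground truth for all eight inspiration/expiration
ratios.  Between phases the diaphragm descends (base_level drops), the
dome flattens or steepens (h changes), and the chest wall expands
anterior-posteriorly (the lung ellipse widens); the lateral chest wall and
the lung apex are held per-phase parameters too.

A cohort simulator draws per-subject, per-visit phantom geometries with
group-specific one-year drift of the dome-height ratio.  Measurement noise
is applied to the geometry parameters, not to the masks, so each simulated
subject's true outcome values stay analytic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volumes import BreathPair, MaskVolume, ScalarVolume

DOME_KINDS = ("paraboloid", "spherical")

# closed-form coefficients per dome kind:
#   cap volume        = CAP_COEF * pi * a * b * h
#   sagittal segment  = SEG_COEF * b * h   (area between dome curve and chord)
_CAP_COEF = {"paraboloid": 0.5, "spherical": 2.0 / 3.0}
_SEG_COEF = {"paraboloid": 4.0 / 3.0, "spherical": math.pi / 2.0}


class PhantomGeometryError(ValueError):
    """Raised when a phantom specification cannot be rasterized or solved."""


@dataclass(frozen=True)
class DomeSpec:
    """Diaphragm dome: attachment ring level, apex elevation and footprint.

    base_level : mm, cranio-caudal position of the attachment ring
    height     : mm, apex elevation above base_level (>= 0)
    semiaxis_lr, semiaxis_ap : mm, elliptical footprint semiaxes (> 0)
    kind       : "paraboloid" (default) or "spherical"
    """

    base_level: float
    height: float
    semiaxis_lr: float
    semiaxis_ap: float
    kind: str = "paraboloid"

    def __post_init__(self) -> None:
        if self.height < 0:
            raise PhantomGeometryError(f"dome height must be >= 0, got {self.height}")
        if self.semiaxis_lr <= 0 or self.semiaxis_ap <= 0:
            raise PhantomGeometryError("dome footprint semiaxes must be positive")
        if self.kind not in DOME_KINDS:
            raise PhantomGeometryError(f"unknown dome kind {self.kind!r}")

    def surface(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Dome surface z_d at offsets (dx, dy) from the footprint center."""
        rho = (dx / self.semiaxis_lr) ** 2 + (dy / self.semiaxis_ap) ** 2
        bump = np.maximum(0.0, 1.0 - rho)
        if self.kind == "spherical":
            bump = np.sqrt(bump)
        return self.base_level + self.height * bump

    @property
    def cap_volume(self) -> float:
        """Closed-form volume between the dome surface and its base plane."""
        return _CAP_COEF[self.kind] * math.pi * self.semiaxis_lr * self.semiaxis_ap * self.height

    @property
    def sagittal_segment_area(self) -> float:
        """Closed-form area between the mid-sagittal dome curve and its chord."""
        return _SEG_COEF[self.kind] * self.semiaxis_ap * self.height

    def dome_integral(self, over_lr: float, over_ap: float) -> float:
        """∫∫ bump dA over the ellipse (over_lr, over_ap) ⊇ footprint.

        Only valid when the dome footprint is contained in the integration
        ellipse, in which case the integral equals cap_volume / height.
        """
        if over_lr + 1e-9 < self.semiaxis_lr or over_ap + 1e-9 < self.semiaxis_ap:
            raise PhantomGeometryError(
                "dome footprint exceeds the integration ellipse; no closed form"
            )
        return 0.0 if self.height == 0 else self.cap_volume / self.height


@dataclass(frozen=True)
class PhaseGeometry:
    """One breathing phase: dome, chest-wall AP depth and lung apex level."""

    dome: DomeSpec
    ap_depth: float  # mm, anterior-posterior chest-wall depth (= lung AP extent)
    apex_level: float  # mm, cranio-caudal position of the flat lung apex

    @property
    def lung_semiaxis_ap(self) -> float:
        return self.ap_depth / 2.0

    def __post_init__(self) -> None:
        if self.ap_depth <= 0:
            raise PhantomGeometryError("ap_depth must be positive")
        if self.apex_level <= self.dome.base_level + self.dome.height:
            raise PhantomGeometryError(
                "apex_level must lie above the dome apex "
                f"({self.apex_level} <= {self.dome.base_level + self.dome.height})"
            )
        if self.dome.semiaxis_ap > self.lung_semiaxis_ap + 1e-9:
            raise PhantomGeometryError("dome AP footprint exceeds the chest-wall depth")


@dataclass(frozen=True)
class PhantomParams:
    """Full two-phase thorax phantom specification.

    The two lungs are identical ellipses laterally offset from the box
    center; both phases share one voxel grid.  Defaults approximate an adult
    thorax scanned at 3 mm isotropic resolution with a deep breath:
    a ~3.5 L expiratory and ~7 L inspiratory total lung volume.
    """

    spacing: float | tuple[float, float, float] = 3.0
    box: tuple[float, float, float] = (300.0, 250.0, 300.0)  # mm
    lung_offsets: tuple[float, float] = (-65.0, 65.0)  # mm from box center, axis 0
    lung_semiaxis_lr: float = 55.0  # mm, lateral semiaxis of each lung ellipse
    expiration: PhaseGeometry = field(
        default_factory=lambda: PhaseGeometry(
            dome=DomeSpec(base_level=130.0, height=35.0, semiaxis_lr=50.0, semiaxis_ap=80.0),
            ap_depth=180.0,
            apex_level=260.0,
        )
    )
    inspiration: PhaseGeometry = field(
        default_factory=lambda: PhaseGeometry(
            dome=DomeSpec(base_level=50.0, height=40.0, semiaxis_lr=50.0, semiaxis_ap=80.0),
            ap_depth=220.0,
            apex_level=260.0,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_vec):
            raise PhantomGeometryError("spacing must be positive")
        if self.inspiration.dome.base_level > self.expiration.dome.base_level + 1e-9:
            raise PhantomGeometryError(
                "inspiratory base_level must not exceed expiratory base_level "
                "(the diaphragm never ascends on inspiration)"
            )
        for phase in (self.expiration, self.inspiration):
            if phase.dome.semiaxis_lr > self.lung_semiaxis_lr + 1e-9:
                raise PhantomGeometryError("dome LR footprint exceeds the lung ellipse")
        bx, by, bz = self.box
        cy = by / 2.0
        for name, phase in (("expiration", self.expiration), ("inspiration", self.inspiration)):
            if phase.apex_level >= bz:
                raise PhantomGeometryError(f"{name}: apex_level {phase.apex_level} outside box height {bz}")
            if phase.dome.base_level < 0:
                raise PhantomGeometryError(f"{name}: base_level below the grid")
            if cy - phase.lung_semiaxis_ap < 0 or cy + phase.lung_semiaxis_ap > by:
                raise PhantomGeometryError(f"{name}: chest-wall depth does not fit the box")
        for off in self.lung_offsets:
            cx = bx / 2.0 + off
            if cx - self.lung_semiaxis_lr < 0 or cx + self.lung_semiaxis_lr > bx:
                raise PhantomGeometryError("lung ellipse does not fit the box laterally")
        lo, hi = self.lung_offsets
        if (bx / 2 + lo) + self.lung_semiaxis_lr >= (bx / 2 + hi) - self.lung_semiaxis_lr:
            raise PhantomGeometryError("lungs overlap: increase lateral offsets")

    @property
    def spacing_vec(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (isotropic scalars are broadcast)."""
        if np.isscalar(self.spacing):
            return (float(self.spacing),) * 3
        return tuple(float(s) for s in self.spacing)

    @property
    def lung_centers_lr(self) -> tuple[float, float]:
        """Lateral (axis-0) centers of the right and left lung, mm."""
        bx = self.box[0]
        return (bx / 2.0 + self.lung_offsets[0], bx / 2.0 + self.lung_offsets[1])

    @property
    def center_ap(self) -> float:
        return self.box[1] / 2.0

    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(math.floor(d / s)) + 1 for d, s in zip(self.box, self.spacing_vec)
        )


@dataclass(frozen=True)
class AnalyticTruth:
    """Closed-form per-phase measures and the eight outcome ratios."""

    lung_volume_exp: float
    lung_volume_insp: float
    swept_volume: float
    cc_extent_exp: float
    cc_extent_insp: float
    ap_extent_exp: float
    ap_extent_insp: float
    lung_area_exp: float
    lung_area_insp: float
    dome_height_exp: float
    dome_height_insp: float
    dome_area_exp: float
    dome_area_insp: float

    @property
    def lung_volume_ratio(self) -> float:
        return self.lung_volume_insp / self.lung_volume_exp

    @property
    def diaphragm_volume_ratio(self) -> float:
        dv = self.lung_volume_insp - self.lung_volume_exp
        if dv <= 0:
            return float("nan")
        return self.swept_volume / dv

    @property
    def lung_area_ratio(self) -> float:
        return self.lung_area_insp / self.lung_area_exp

    @property
    def cranial_caudal_ratio(self) -> float:
        return self.cc_extent_insp / self.cc_extent_exp

    @property
    def anterior_posterior_ratio(self) -> float:
        return self.ap_extent_insp / self.ap_extent_exp

    @property
    def cc_ap_ratio(self) -> float:
        return self.cranial_caudal_ratio / self.anterior_posterior_ratio

    @property
    def diaphragm_height_ratio(self) -> float:
        return self.dome_height_insp / self.dome_height_exp

    @property
    def diaphragm_area_ratio(self) -> float:
        return self.dome_area_insp / self.dome_area_exp

    def ratios(self) -> dict[str, float]:
        from .volumes import OUTCOME_NAMES

        return {name: getattr(self, name) for name in OUTCOME_NAMES}


def _phase_mask(params: PhantomParams, phase: PhaseGeometry) -> np.ndarray:
    nx, ny, nz = params.grid_shape()
    sx, sy, sz = params.spacing_vec
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    z = np.arange(nz) * sz
    cy = params.center_ap
    b_l = phase.lung_semiaxis_ap
    a_l = params.lung_semiaxis_lr
    mask = np.zeros((nx, ny, nz), dtype=bool)
    zc = z[None, None, :]
    for cx in params.lung_centers_lr:
        dx = (x - cx)[:, None]
        dy = (y - cy)[None, :]
        inside = (dx / a_l) ** 2 + (dy / b_l) ** 2 <= 1.0
        zd = phase.dome.surface(dx, dy)  # (nx, ny)
        col = (zc > zd[:, :, None]) & (zc < phase.apex_level)
        mask |= inside[:, :, None] & col
    return mask


def build_phantom_pair(params: PhantomParams) -> BreathPair:
    """Rasterize the two-phase phantom to a :class:`BreathPair` of masks.

    A voxel belongs to a lung when its center lies inside the lung ellipse,
    strictly above the dome surface and strictly below the apex plane.
    """
    shape = params.grid_shape()
    if min(shape) < 4:
        raise PhantomGeometryError(f"grid {shape} too small to contain the geometry")
    exp = _phase_mask(params, params.expiration)
    insp = _phase_mask(params, params.inspiration)
    if not exp.any() or not insp.any():
        raise PhantomGeometryError("phantom geometry produced an empty lung mask")
    sp = params.spacing_vec
    return BreathPair(MaskVolume(exp, sp), MaskVolume(insp, sp))


def _phase_truth(params: PhantomParams, phase: PhaseGeometry) -> dict[str, float]:
    a_l = params.lung_semiaxis_lr
    b_l = phase.lung_semiaxis_ap
    dome = phase.dome
    column = math.pi * a_l * b_l * (phase.apex_level - dome.base_level)
    per_lung = column - dome.cap_volume
    cc = phase.apex_level - dome.base_level
    ap = phase.ap_depth
    area = 2.0 * b_l * cc - dome.sagittal_segment_area
    return {
        "volume": 2.0 * per_lung,
        "cc": cc,
        "ap": ap,
        "area": area,
        "height": dome.height,
        "dome_area": dome.sagittal_segment_area,
    }


def _swept_volume(params: PhantomParams) -> float:
    """Diaphragm-swept volume over both lungs, ∫∫ max(0, z_exp - z_insp).

    Closed form when both dome footprints lie inside the shared lung
    footprint and the surface gap is non-negative everywhere (checked on a
    fine grid); otherwise falls back to deterministic midpoint quadrature of
    the clipped integrand at sub-mm resolution.
    """
    e, i = params.expiration, params.inspiration
    a_s = params.lung_semiaxis_lr
    b_s = min(e.lung_semiaxis_ap, i.lung_semiaxis_ap)
    footprints_ok = all(
        dome.semiaxis_lr <= a_s + 1e-9 and dome.semiaxis_ap <= b_s + 1e-9
        for dome in (e.dome, i.dome)
    )
    u = np.linspace(-a_s, a_s, 201)[:, None]
    v = np.linspace(-b_s, b_s, 201)[None, :]
    inside = (u / a_s) ** 2 + (v / b_s) ** 2 <= 1.0
    gap = e.dome.surface(u, v) - i.dome.surface(u, v)
    if footprints_ok and gap[inside].min() >= -1e-6:
        area_s = math.pi * a_s * b_s
        descent = e.dome.base_level - i.dome.base_level
        per_lung = (
            area_s * descent
            + e.dome.height * e.dome.dome_integral(a_s, b_s)
            - i.dome.height * i.dome.dome_integral(a_s, b_s)
        )
        return 2.0 * per_lung
    # clipped or non-nested case: midpoint quadrature at ~0.1 mm cells
    n = 1201
    uu = np.linspace(-a_s, a_s, n)
    vv = np.linspace(-b_s, b_s, n)
    du = uu[1] - uu[0]
    dv = vv[1] - vv[0]
    U = uu[:, None]
    V = vv[None, :]
    inside = (U / a_s) ** 2 + (V / b_s) ** 2 <= 1.0
    gap = np.maximum(0.0, e.dome.surface(U, V) - i.dome.surface(U, V))
    per_lung = float((gap * inside).sum() * du * dv)
    return 2.0 * per_lung


def analytic_truth(params: PhantomParams) -> AnalyticTruth:
    """Closed-form ground truth for every outcome of this phantom."""
    te = _phase_truth(params, params.expiration)
    ti = _phase_truth(params, params.inspiration)
    return AnalyticTruth(
        lung_volume_exp=te["volume"],
        lung_volume_insp=ti["volume"],
        swept_volume=_swept_volume(params),
        cc_extent_exp=te["cc"],
        cc_extent_insp=ti["cc"],
        ap_extent_exp=te["ap"],
        ap_extent_insp=ti["ap"],
        lung_area_exp=te["area"],
        lung_area_insp=ti["area"],
        dome_height_exp=te["height"],
        dome_height_insp=ti["height"],
        dome_area_exp=te["dome_area"],
        dome_area_insp=ti["dome_area"],
    )


def render_intensity(
    pair: BreathPair, noise_scale: float = 0.0, seed: int = 0
) -> tuple[ScalarVolume, ScalarVolume]:
    """Render grayscale volumes from a mask pair: lungs dark, body bright.

    Additive Gaussian noise of standard deviation ``noise_scale`` (in units
    of the body/lung contrast, which is 1) is applied deterministically per
    seed; expiration and inspiration use independent substreams.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for mask in (pair.expiration, pair.inspiration):
        img = np.where(mask.data, 0.1, 1.0)
        if noise_scale > 0:
            img = img + rng.normal(0.0, noise_scale, size=img.shape)
        out.append(ScalarVolume(img, mask.spacing))
    return out[0], out[1]


def sample_phantom_params(
    rng: np.random.Generator, spacing: float = 1.0, kind: str = "paraboloid"
) -> PhantomParams:
    """Draw a randomized scaled-down phantom for oracle tests.

    Geometry is about half linear scale of the default adult thorax so that
    1 mm rasterizations stay small; all closed-form validity constraints
    (nested footprints, non-ascending diaphragm) are honoured by
    construction.
    """
    box = (150.0, 120.0, 150.0)
    a_l = rng.uniform(24.0, 32.0)
    offsets = (-(a_l + rng.uniform(4.0, 8.0)), a_l + rng.uniform(4.0, 8.0))
    ap_e = rng.uniform(80.0, 95.0)
    ap_i = ap_e + rng.uniform(5.0, 20.0)
    b_d = min(ap_e, ap_i) / 2.0 - rng.uniform(3.0, 6.0)
    a_d = a_l - rng.uniform(2.0, 4.0)
    h_e = rng.uniform(12.0, 22.0)
    h_i = h_e * rng.uniform(0.8, 1.4)
    base_e = rng.uniform(60.0, 75.0)
    descent = rng.uniform(max(18.0, h_i - h_e + 5.0), 40.0)
    apex = rng.uniform(120.0, 135.0)
    exp = PhaseGeometry(
        dome=DomeSpec(base_e, h_e, a_d, b_d, kind=kind), ap_depth=ap_e, apex_level=apex
    )
    insp = PhaseGeometry(
        dome=DomeSpec(base_e - descent, h_i, a_d, b_d, kind=kind),
        ap_depth=ap_i,
        apex_level=apex,
    )
    return PhantomParams(
        spacing=spacing,
        box=box,
        lung_offsets=offsets,
        lung_semiaxis_lr=a_l,
        expiration=exp,
        inspiration=insp,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupModel:
    """Baseline geometry distribution of one study group.

    Means/SDs are in mm except the dimensionless dome-height ratio.  Patients
    default to a weak diaphragm (small descent, height ratio > 1, i.e. the
    dome steepens paradoxically on inspiration); controls to a strong one.
    """

    descent_mean: float
    descent_sd: float
    height_ratio_mean: float
    height_ratio_sd: float
    exp_height_mean: float = 35.0
    exp_height_sd: float = 4.0
    ap_expansion_mean: float = 30.0
    ap_expansion_sd: float = 8.0


PATIENT_MODEL = GroupModel(
    descent_mean=45.0, descent_sd=10.0, height_ratio_mean=1.19, height_ratio_sd=0.15
)
CONTROL_MODEL = GroupModel(
    descent_mean=85.0, descent_sd=10.0, height_ratio_mean=1.12, height_ratio_sd=0.10
)


@dataclass(frozen=True)
class CohortSimSpec:
    """Simulated longitudinal study: two visits about one year apart.

    drift_* is the additive one-year change of the dome-height ratio
    (patients positive by default, controls zero).  noise_scale is the
    per-visit measurement SD of the height ratio (geometry-level noise);
    base/AP parameters get proportional per-visit jitter.
    """

    n_patients: int = 30
    n_controls: int = 10
    patient_model: GroupModel = PATIENT_MODEL
    control_model: GroupModel = CONTROL_MODEL
    drift_patients: float = 0.05
    drift_controls: float = 0.0
    noise_scale: float = 0.015
    spacing: float | tuple[float, float, float] = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")


@dataclass
class SimulatedSubject:
    """One simulated subject: cohort-row fields plus per-visit phantoms."""

    subject_id: str
    group: str
    sex: str
    age_years: float
    height_cm: float
    weight_kg: float
    ert_duration_years: float | None  # None = untreated or control
    followup_interval_years: float
    visit_params: tuple[PhantomParams, PhantomParams]
    true_measures: tuple[AnalyticTruth, AnalyticTruth]

    def build_masks(self) -> tuple[BreathPair, BreathPair]:
        """Rasterize both visits (deferred: masks are large)."""
        return tuple(build_phantom_pair(p) for p in self.visit_params)

    @property
    def ert_group(self) -> str:
        if self.group == "control":
            return ""
        if self.ert_duration_years is None:
            return "untreated"
        return "<=3y" if self.ert_duration_years <= 3.0 else ">3y"


def _clip(x: float, lo: float, hi: float) -> float:
    return float(min(max(x, lo), hi))


def _visit_params(
    base: PhantomParams,
    descent: float,
    h_exp: float,
    h_ratio: float,
    ap_expansion: float,
    spacing: float | tuple[float, float, float],
) -> PhantomParams:
    h_exp = _clip(h_exp, 15.0, 60.0)
    h_insp = _clip(h_ratio, 0.4, 2.8) * h_exp
    descent = _clip(descent, 10.0, 100.0)
    ap_expansion = _clip(ap_expansion, 5.0, 60.0)
    exp_dome = DomeSpec(base_level=130.0, height=h_exp, semiaxis_lr=50.0, semiaxis_ap=80.0)
    insp_dome = DomeSpec(
        base_level=130.0 - descent, height=_clip(h_insp, 5.0, 95.0),
        semiaxis_lr=50.0, semiaxis_ap=80.0,
    )
    exp = PhaseGeometry(dome=exp_dome, ap_depth=180.0, apex_level=260.0)
    insp = PhaseGeometry(dome=insp_dome, ap_depth=180.0 + ap_expansion, apex_level=260.0)
    return replace(base, spacing=spacing, expiration=exp, inspiration=insp)


def simulate_cohort(spec: CohortSimSpec) -> list[SimulatedSubject]:
    """Draw a reproducible two-visit cohort of phantom subjects.

    Each subject has a latent baseline geometry from their group model; the
    second visit shifts the latent dome-height ratio by the group drift.
    Per-visit measurement noise perturbs the geometry parameters, so the
    analytic truth of the drawn parameters is the subject's measured-without-
    voxelization value.
    """
    rng = np.random.default_rng(spec.seed)
    base = PhantomParams(spacing=spec.spacing)
    subjects: list[SimulatedSubject] = []
    groups = [("patient", spec.n_patients, spec.patient_model, spec.drift_patients)] + [
        ("control", spec.n_controls, spec.control_model, spec.drift_controls)
    ]
    counter = 0
    for group, n, model, drift in groups:
        for _ in range(n):
            counter += 1
            sid = f"{'P' if group == 'patient' else 'C'}{counter:03d}"
            descent = rng.normal(model.descent_mean, model.descent_sd)
            h_exp = rng.normal(model.exp_height_mean, model.exp_height_sd)
            ratio0 = rng.normal(model.height_ratio_mean, model.height_ratio_sd)
            ap_exp = rng.normal(model.ap_expansion_mean, model.ap_expansion_sd)
            latent = {"descent": descent, "h_exp": h_exp, "ap": ap_exp}
            visit_params = []
            for visit, ratio in enumerate((ratio0, ratio0 + drift)):
                ratio_obs = ratio + rng.normal(0.0, spec.noise_scale)
                jitter = 1.0 + rng.normal(0.0, spec.noise_scale, size=2)
                visit_params.append(
                    _visit_params(
                        base,
                        descent=latent["descent"] * jitter[0],
                        h_exp=latent["h_exp"],
                        h_ratio=ratio_obs,
                        ap_expansion=latent["ap"] * jitter[1],
                        spacing=spec.spacing,
                    )
                )
            truths = tuple(analytic_truth(p) for p in visit_params)
            if group == "patient":
                # ERT mix per the study design: ~1/4 untreated, ~1/4 short, ~1/2 long
                u = rng.uniform()
                if u < 7 / 30:
                    ert = None
                elif u < 15 / 30:
                    ert = float(np.round(rng.uniform(-0.1, 3.0), 2))
                else:
                    ert = float(np.round(rng.uniform(3.1, 13.0), 1))
            else:
                ert = None
            subjects.append(
                SimulatedSubject(
                    subject_id=sid,
                    group=group,
                    sex="m" if rng.uniform() < 0.47 else "f",
                    age_years=float(np.round(rng.uniform(18, 70), 0)),
                    height_cm=float(np.round(rng.normal(175, 9), 0)),
                    weight_kg=float(np.round(rng.normal(73, 10), 0)),
                    ert_duration_years=ert,
                    followup_interval_years=float(np.round(rng.normal(1.05, 0.1), 2)),
                    visit_params=tuple(visit_params),
                    true_measures=truths,
                )
            )
    return subjects


def cohort_frame(subjects: list[SimulatedSubject]) -> pd.DataFrame:
    """Cohort table (one row per subject) in the cohort CSV schema."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sex": s.sex,
                "age_years": s.age_years,
                "height_cm": s.height_cm,
                "weight_kg": s.weight_kg,
                "ert_duration_years": s.ert_duration_years,
                "followup_interval_years": s.followup_interval_years,
            }
        )
    return pd.DataFrame(rows)


def true_outcomes_frame(subjects: list[SimulatedSubject]) -> pd.DataFrame:
    """Per-subject, per-visit analytic outcome table (outcomes CSV schema)."""
    rows = []
    for s in subjects:
        for visit, truth in zip(("initial", "follow-up"), s.true_measures):
            row = {"subject_id": s.subject_id, "group": s.group, "visit": visit}
            row.update(truth.ratios())
            rows.append(row)
    return pd.DataFrame(rows)
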
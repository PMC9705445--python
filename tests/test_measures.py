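"""Morphometry operations against analytic phantom truth and closed forms."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from diamotion import measures, phantom
from diamotion.measures import (
    MeasureError,
    UndefinedMeasure,
    compute_measures,
    compute_subject,
    dome_geometry,
    match_visits,
    select_sagittal_level,
)
from diamotion.phantom import DomeSpec, PhantomParams, PhaseGeometry
from diamotion.volumes import OUTCOME_NAMES, BreathPair, MaskVolume

from test_phantom import descent_only_params


def ratio_tolerances(params: PhantomParams) -> dict[str, float]:
    """Voxelization tolerance per outcome ratio, from the phantom geometry.

    Extents carry one voxel of slack per phase; rasterized areas and volumes
    are good to ~3 percent; the dome quantities inherit a half-voxel band
    along the contour (height: one voxel per phase; area: 0.75*spacing/h per
    phase plus 1 percent interior).  A ratio's tolerance combines its
    numerator's and denominator's.
    """
    s = params.spacing
    truth = phantom.analytic_truth(params)
    tol = {
        "lung_volume_ratio": 0.06,
        "diaphragm_volume_ratio": 0.06,
        "lung_area_ratio": 0.06,
        "cranial_caudal_ratio": s / truth.cc_extent_exp + s / truth.cc_extent_insp,
        "anterior_posterior_ratio": s / truth.ap_extent_exp + s / truth.ap_extent_insp,
        "diaphragm_height_ratio": s / truth.dome_height_exp + s / truth.dome_height_insp,
        "diaphragm_area_ratio": 0.75 * s / truth.dome_height_exp
        + 0.75 * s / truth.dome_height_insp
        + 0.02,
    }
    tol["cc_ap_ratio"] = tol["cranial_caudal_ratio"] + tol["anterior_posterior_ratio"]
    return tol


def assert_measures_match_truth(params: PhantomParams, pair: BreathPair | None = None):
    pair = pair or phantom.build_phantom_pair(params)
    truth = phantom.analytic_truth(params).ratios()
    got = compute_measures(pair)
    assert not got.reasons, got.reasons
    tol = ratio_tolerances(params)
    for name in OUTCOME_NAMES:
        assert got.ratios[name] == pytest.approx(truth[name], rel=tol[name]), name


class TestVolumes:
    def test_solid_block_volume(self):
        mask = MaskVolume(np.ones((10, 10, 10), bool), (3.0, 3.0, 3.0))
        assert measures.lung_volume(mask) == pytest.approx(27_000.0)

    def test_phantom_volume_against_truth(self, small_phantom):
        params, pair, truth = small_phantom
        assert measures.lung_volume(pair.expiration) == pytest.approx(
            truth.lung_volume_exp, rel=0.03
        )

    def test_reorientation_invariance(self):
        data = np.zeros((8, 9, 10), bool)
        data[1:5, 2:7, 3:9] = True
        mask = MaskVolume(data, (3.0, 3.0, 3.0))
        rolled = MaskVolume(np.roll(data[::-1], 2, axis=1), (3.0, 3.0, 3.0))
        assert measures.lung_volume(mask) == measures.lung_volume(rolled)

    def test_empty_mask_rejected(self):
        with pytest.raises(MeasureError):
            measures.lung_volume(MaskVolume(np.zeros((4, 4, 4), bool), (1.0, 1.0, 1.0)))

    def test_identity_pair_unit_ratio(self, default_pair):
        same = BreathPair(default_pair.expiration, default_pair.expiration)
        assert measures.volume_ratio(same) == 1.0


class TestDiaphragmSurface:
    def test_solid_block_constant_surface(self):
        data = np.zeros((6, 6, 8), bool)
        data[:, :, 3:] = True
        surf = measures.diaphragm_surface(MaskVolume(data, (1.0, 1.0, 1.0)))
        assert np.all(surf == 3)

    def test_column_without_lung_absent(self):
        data = np.zeros((4, 4, 4), bool)
        data[1, 1, 2] = True
        surf = measures.diaphragm_surface(MaskVolume(data, (1.0, 1.0, 1.0)))
        assert np.isnan(surf[0, 0]) and surf[1, 1] == 2

    def test_phantom_surface_matches_dome_function(self, small_phantom):
        """The extracted surface tracks z_d(x, y) within one voxel on the
        dome footprint."""
        params, pair, _ = small_phantom
        s = params.spacing
        surf = measures.diaphragm_surface(pair.expiration)
        dome = params.expiration.dome
        cx = params.lung_centers_lr[0]
        cy = params.center_ap
        cols = np.argwhere(~np.isnan(surf))
        # restrict to right-lung columns strictly inside the footprint
        for i, j in cols[:: max(1, len(cols) // 500)]:
            dx, dy = i * s - cx, j * s - cy
            if (dx / dome.semiaxis_lr) ** 2 + (dy / dome.semiaxis_ap) ** 2 < 0.9:
                zd = dome.surface(np.array(dx), np.array(dy))
                assert abs(surf[i, j] * s - zd) <= 1.5 * s

    def test_descent_only_ratio_is_one(self):
        pair = phantom.build_phantom_pair(descent_only_params(descent=60.0))
        assert measures.diaphragm_volume_ratio(pair) == pytest.approx(1.0, abs=0.03)

    def test_half_wall_half_descent_decomposition(self):
        """A phantom constructed so AP-wall expansion supplies half the
        volume gain yields a diaphragm volume ratio of 0.5."""
        exp = PhaseGeometry(DomeSpec(130.0, 35.0, 50.0, 80.0), 180.0, 260.0)
        descent = 30.0
        # identical domes, so per lung: swept = pi*a_l*b_e*descent and
        # gain = pi*a_l*(b_i*cc_i - b_e*cc_e); solve gain = 2*swept for b_i
        b_e, cc_e, cc_i = 90.0, 130.0, 160.0
        b_i = (2 * b_e * descent + b_e * cc_e) / cc_i  # = 106.875
        insp = PhaseGeometry(
            DomeSpec(100.0, 35.0, 50.0, 80.0), ap_depth=2 * b_i, apex_level=260.0
        )
        params = PhantomParams(spacing=1.5, expiration=exp, inspiration=insp)
        truth = phantom.analytic_truth(params)
        assert truth.diaphragm_volume_ratio == pytest.approx(0.5, abs=0.02)
        pair = phantom.build_phantom_pair(params)
        assert measures.diaphragm_volume_ratio(pair) == pytest.approx(
            truth.diaphragm_volume_ratio, abs=0.03
        )

    def test_no_volume_gain_undefined(self, default_pair):
        same = BreathPair(default_pair.expiration, default_pair.expiration)
        with pytest.raises(UndefinedMeasure) as err:
            measures.diaphragm_volume_ratio(same)
        assert err.value.reason == "nonpositive_volume_gain"


class TestLevelSelection:
    def test_midpoint_of_extent(self):
        data = np.zeros((40, 6, 6), bool)
        data[10:31, 2:5, 2:5] = True  # spans indices 10..30
        assert select_sagittal_level(MaskVolume(data, (3.0, 3.0, 3.0))) == 20

    def test_translation_equivariance(self):
        data = np.zeros((40, 6, 6), bool)
        data[10:31, 2:5, 2:5] = True
        mask = MaskVolume(data, (3.0, 3.0, 3.0))
        shifted = MaskVolume(np.roll(data, 5, axis=0), (3.0, 3.0, 3.0))
        assert select_sagittal_level(shifted) == select_sagittal_level(mask) + 5

    def test_phantom_level_hits_dome_apex_column(self, default_params, default_pair):
        from diamotion.segmentation import split_sides

        right = split_sides(default_pair.expiration).right
        level = select_sagittal_level(right)
        apex_col = default_params.lung_centers_lr[0] / default_params.spacing
        assert abs(level - apex_col) <= 1


class TestMatchVisits:
    def _right(self, pair):
        from diamotion.segmentation import split_sides

        return split_sides(pair.expiration).right

    def test_exact_translation_recovered(self, default_pair):
        right = self._right(default_pair)
        moved = MaskVolume(np.roll(right.data, (3, -2, 4), axis=(0, 1, 2)), right.spacing)
        res = match_visits(right, moved, level_initial=28)
        assert res.shift == (3, -2, 4)
        assert res.dice == pytest.approx(1.0)
        assert res.level_followup == 31
        assert not res.fallback

    def test_identity_zero_shift(self, default_pair):
        right = self._right(default_pair)
        res = match_visits(right, right, level_initial=28)
        assert res.shift == (0, 0, 0)
        assert res.level_followup == 28

    def test_shape_change_plus_translation(self):
        """Axis-0 shift recovered exactly despite a small geometry change."""
        base = descent_only_params(descent=40.0)
        grown = dataclasses.replace(
            base,
            inspiration=PhaseGeometry(
                DomeSpec(88.0, 37.0, 50.0, 80.0), 182.0, 260.0
            ),
        )
        from diamotion.segmentation import split_sides

        a = split_sides(phantom.build_phantom_pair(base).inspiration).right
        b0 = split_sides(phantom.build_phantom_pair(grown).inspiration).right
        b = MaskVolume(np.roll(b0.data, 4, axis=0), b0.spacing)
        res = match_visits(a, b, level_initial=28)
        assert res.shift[0] == 4
        assert not res.fallback

    def test_weak_overlap_falls_back(self, default_pair):
        right = self._right(default_pair)
        far = MaskVolume(np.roll(right.data, 60, axis=2), right.spacing)
        with pytest.warns(UserWarning, match="Dice"):
            res = match_visits(right, far, level_initial=28)
        assert res.fallback
        assert res.level_followup == select_sagittal_level(far)


class TestSliceOutcomes:
    def test_identity_ratios_one(self, default_pair):
        same = BreathPair(default_pair.expiration, default_pair.expiration)
        out = measures.slice_extent_ratios(same, 28)
        for name in ("lung_area_ratio", "cranial_caudal_ratio", "anterior_posterior_ratio", "cc_ap_ratio"):
            assert out[name] == 1.0

    def test_caudal_stretch_at_fixed_ap(self):
        """CC extent stretched 1.5x with rigid AP wall: CC ratio 1.5, AP 1.0."""
        exp = PhaseGeometry(DomeSpec(160.0, 25.0, 50.0, 80.0), 180.0, 260.0)
        # cc_exp = 100; descend base by 50 -> cc_insp = 150
        insp = PhaseGeometry(DomeSpec(110.0, 25.0, 50.0, 80.0), 180.0, 260.0)
        params = PhantomParams(spacing=1.5, expiration=exp, inspiration=insp)
        pair = phantom.build_phantom_pair(params)
        from diamotion.segmentation import split_sides

        level = select_sagittal_level(split_sides(pair.expiration).right)
        out = measures.slice_extent_ratios(pair, level)
        s = params.spacing
        assert out["anterior_posterior_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert out["cranial_caudal_ratio"] == pytest.approx(1.5, abs=s / 100 + s / 150)
        assert out["cc_ap_ratio"] == pytest.approx(
            out["cranial_caudal_ratio"] / out["anterior_posterior_ratio"]
        )

    def test_empty_slice_undefined(self, default_pair):
        with pytest.raises(UndefinedMeasure, match="empty_slice"):
            measures.slice_extent_ratios(default_pair, 0)


class TestDomeGeometry:
    def test_semicircular_dome(self):
        """A semicircular contour of radius r: height -> r, area -> pi r^2/2."""
        r = 40.0
        step = 0.25
        n = int(2.5 * r / step)
        y = (np.arange(n) - n // 2) * step
        z = (np.arange(n) - 2) * step
        yy, zz = np.meshgrid(y, z, indexing="ij")
        dome = np.where(np.abs(yy) < r, np.sqrt(np.maximum(0.0, r**2 - yy**2)), 0.0)
        mask = (zz > dome) & (zz < 2.2 * r)
        geo = dome_geometry(mask, (step, step))
        assert geo.height == pytest.approx(r, rel=0.03)
        assert geo.area == pytest.approx(math.pi * r**2 / 2, rel=0.03)

    def test_flat_contour_degenerate(self):
        mask = np.zeros((30, 20), bool)
        mask[5:25, 8:15] = True
        geo = dome_geometry(mask, (1.0, 1.0))
        assert geo.height == 0.0
        assert geo.area == 0.0

    def test_paraboloid_mid_slice_closed_form(self, small_phantom):
        params, pair, truth = small_phantom
        from diamotion.segmentation import split_sides

        level = select_sagittal_level(split_sides(pair.expiration).right)
        s = params.spacing
        geo = dome_geometry(pair.expiration.data[level], (s, s))
        h = truth.dome_height_exp
        assert geo.height == pytest.approx(h, abs=1.5 * s)
        assert geo.area == pytest.approx(truth.dome_area_exp, rel=0.75 * s / h + 0.02)

    def test_short_contour_undefined(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        with pytest.raises(UndefinedMeasure, match="short_contour"):
            dome_geometry(mask, (1.0, 1.0))


class TestCurvatureRatios:
    def test_identity_unit_ratios(self, default_pair):
        same = BreathPair(default_pair.expiration, default_pair.expiration)
        out = measures.curvature_ratios(same, 28)
        assert out["diaphragm_height_ratio"] == 1.0
        assert out["diaphragm_area_ratio"] == 1.0

    def test_injected_height_ratio(self):
        """h_insp = 1.3 h_exp recovered within the voxel tolerance."""
        exp = PhaseGeometry(DomeSpec(130.0, 30.0, 50.0, 80.0), 180.0, 260.0)
        insp = PhaseGeometry(DomeSpec(90.0, 39.0, 50.0, 80.0), 180.0, 260.0)
        params = PhantomParams(spacing=1.5, expiration=exp, inspiration=insp)
        pair = phantom.build_phantom_pair(params)
        out = measures.curvature_ratios(pair, 57)  # right-lung center column
        assert out["diaphragm_height_ratio"] == pytest.approx(1.3, abs=1.5 / 30 + 1.5 / 39)

    def test_monotone_in_inspiratory_height(self):
        """The measured height ratio strictly increases with injected h_insp."""
        got = []
        for h in (30.0, 36.0, 42.0, 48.0):
            insp = PhaseGeometry(DomeSpec(80.0, h, 50.0, 80.0), 180.0, 260.0)
            params = PhantomParams(
                spacing=1.5,
                expiration=PhaseGeometry(DomeSpec(130.0, 30.0, 50.0, 80.0), 180.0, 260.0),
                inspiration=insp,
            )
            pair = phantom.build_phantom_pair(params)
            got.append(measures.curvature_ratios(pair, 56)["diaphragm_height_ratio"])
        assert all(b > a for a, b in zip(got, got[1:]))

    def test_flat_expiratory_dome_undefined(self):
        exp = PhaseGeometry(DomeSpec(130.0, 0.0, 50.0, 80.0), 180.0, 260.0)
        insp = PhaseGeometry(DomeSpec(100.0, 30.0, 50.0, 80.0), 180.0, 260.0)
        pair = phantom.build_phantom_pair(PhantomParams(expiration=exp, inspiration=insp))
        with pytest.raises(UndefinedMeasure, match="flat_expiratory_dome"):
            measures.curvature_ratios(pair, 28)


class TestComputeSubject:
    def test_identical_visits_zero_changes(self, default_pair):
        res = compute_subject(default_pair, default_pair)
        for name, change in res.changes.items():
            assert np.isnan(change) or change == 0.0, name
        # the default pair has a genuine inspiratory gain, so all defined
        assert not res.initial.reasons

    def test_translated_followup_zero_changes(self, default_pair):
        moved = BreathPair(
            MaskVolume(np.roll(default_pair.expiration.data, (2, -1, 3), axis=(0, 1, 2)),
                       default_pair.spacing),
            MaskVolume(np.roll(default_pair.inspiration.data, (2, -1, 3), axis=(0, 1, 2)),
                       default_pair.spacing),
        )
        res = compute_subject(default_pair, moved)
        assert res.match.shift == (2, -1, 3)
        for name, change in res.changes.items():
            assert change == pytest.approx(0.0, abs=1e-12), name

    def test_injected_drift_measured(self):
        """A +0.05 height-ratio drift between visits is measured within 0.02
        through the full rasterized pipeline (noise-free subject).

        Geometry chosen with a tall dome relative to the 1 mm grid so the
        worst-case quantization of the change (one voxel on the apex shift)
        stays provably below the tolerance.
        """
        h_e, h_i = 50.0, 55.0
        kw = dict(
            spacing=1.0,
            box=(170.0, 150.0, 170.0),
            lung_offsets=(-39.0, 39.0),
            lung_semiaxis_lr=35.0,
        )
        exp = PhaseGeometry(DomeSpec(100.3, h_e, 32.0, 48.0), 110.0, 165.0)
        base = PhantomParams(
            expiration=exp,
            inspiration=PhaseGeometry(DomeSpec(40.2, h_i, 32.0, 48.0), 110.0, 165.0),
            **kw,
        )
        drifted = dataclasses.replace(
            base,
            inspiration=PhaseGeometry(
                DomeSpec(40.2, h_i + 0.05 * h_e, 32.0, 48.0), 110.0, 165.0
            ),
        )
        truth_change = (
            phantom.analytic_truth(drifted).diaphragm_height_ratio
            - phantom.analytic_truth(base).diaphragm_height_ratio
        )
        assert truth_change == pytest.approx(0.05, abs=1e-9)
        res = compute_subject(
            phantom.build_phantom_pair(base), phantom.build_phantom_pair(drifted)
        )
        assert res.changes["diaphragm_height_ratio"] == pytest.approx(0.05, abs=0.02)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_randomized_phantom_matches_truth(self, seed):
        rng = np.random.default_rng(seed)
        params = phantom.sample_phantom_params(rng, spacing=1.0)
        assert_measures_match_truth(params)

    def test_spherical_dome_phantom_matches_truth(self):
        rng = np.random.default_rng(7)
        params = phantom.sample_phantom_params(rng, spacing=1.0, kind="spherical")
        assert_measures_match_truth(params)

    def test_translation_invariance_of_all_outcomes(self, default_pair):
        shift = (3, 2, -4)
        moved = BreathPair(
            MaskVolume(np.roll(default_pair.expiration.data, shift, axis=(0, 1, 2)),
                       default_pair.spacing),
            MaskVolume(np.roll(default_pair.inspiration.data, shift, axis=(0, 1, 2)),
                       default_pair.spacing),
        )
        a = compute_measures(default_pair)
        b = compute_measures(moved)
        for name in OUTCOME_NAMES:
            assert a.ratios[name] == pytest.approx(b.ratios[name], abs=1e-12), name
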
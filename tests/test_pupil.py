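"""Pupil-center extraction: tight rect, template bank, annulus refinement."""

import dataclasses

import numpy as np
import pytest

from ofrtrack import (Frame, FilterBank, LowConfidenceError, NoMatchError,
                      PupilLostError, ROIBox, crop, detect_regions,
                      match_filter_bank, pupil_center, pupil_diameter_change,
                      refine_annulus, shrink_to_pupil)
from ofrtrack.detect import detect_pupil_region
from ofrtrack import synth

from conftest import shift_eye


def _manual_eye_box(scene, half=62):
    return ROIBox(int(scene.eye.cx) - half, int(scene.eye.cy) - half,
                  2 * half, 2 * half, label="eye")


def _eye_patch_and_roi(scene, manual_box=False):
    """Eye patch + pupil ROI; ``manual_box`` bypasses the eye detector for
    control scenes without corneal reflections (the detector keys on them)."""
    frame = synth.render_scene(scene)
    eye_roi = (_manual_eye_box(scene) if manual_box
               else detect_regions(frame).eye)
    patch = crop(frame, eye_roi)
    return frame, patch, detect_pupil_region(patch)


class TestShrinkToPupil:
    def test_tight_rect_matches_bounding_box(self, quiet_scene):
        scene = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye, pupil_a=40.0, pupil_b=36.0, iris_radius=60.0))
        _, patch, roi = _eye_patch_and_roi(scene)
        rect = shrink_to_pupil(patch, roi)
        cx = scene.eye.cx - patch.origin[0]
        cy = scene.eye.cy - patch.origin[1]
        assert rect.x0 == pytest.approx(cx - 40, abs=1.5)
        assert rect.y0 == pytest.approx(cy - 36, abs=1.5)
        assert rect.w == pytest.approx(81, abs=2)
        assert rect.h == pytest.approx(73, abs=2)

    def test_no_dark_region_raises(self):
        patch = Frame(np.full((60, 60), 150, dtype=np.uint8))
        with pytest.raises(PupilLostError):
            shrink_to_pupil(patch, ROIBox(5, 5, 50, 50, label="pupil"))

    def test_reflection_on_edge_leaves_rect_stable(self, quiet_scene):
        """A bright blob overlapping the pupil boundary is masked before
        thresholding, so the rectangle matches the reflection-free render."""
        clean = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye, reflections=()))
        edge_refl = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye,
            reflections=((quiet_scene.eye.pupil_a - 1.0, 0.0, 3.0, 250.0),)))
        _, patch_c, roi_c = _eye_patch_and_roi(clean, manual_box=True)
        _, patch_r, roi_r = _eye_patch_and_roi(edge_refl, manual_box=True)
        rect_c = shrink_to_pupil(patch_c, roi_c)
        rect_r = shrink_to_pupil(patch_r, roi_r)
        off_c, off_r = patch_c.origin, patch_r.origin
        assert rect_r.x0 + off_r[0] == pytest.approx(rect_c.x0 + off_c[0],
                                                     abs=1)
        assert rect_r.w == pytest.approx(rect_c.w, abs=1)


class TestFilterBank:
    def test_clean_ellipse_center_within_half_pixel(self, quiet_scene):
        _, patch, roi = _eye_patch_and_roi(quiet_scene)
        rect = shrink_to_pupil(patch, roi)
        sub = crop(patch, ROIBox(rect.x0 - 6, rect.y0 - 6,
                                 rect.w + 12, rect.h + 12))
        fit = match_filter_bank(sub.astype_float(), a_hint=rect.w / 2)
        cx = quiet_scene.eye.cx - sub.origin[0]
        cy = quiet_scene.eye.cy - sub.origin[1]
        assert fit.cx == pytest.approx(cx, abs=0.5 + 1e-9)
        assert fit.cy == pytest.approx(cy, abs=0.5 + 1e-9)
        assert fit.stage == "filter_bank"

    def test_pure_noise_patch_rejected(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(140, 8, size=(70, 70))
        with pytest.raises(NoMatchError):
            match_filter_bank(noise, FilterBank(radii=(16.0, 20.0, 24.0)))

    def test_intermediate_size_snaps_to_neighbor_radius(self, quiet_scene):
        # true semi-major 21 px sits between the 20 and 22 bank entries
        scene = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye, pupil_a=21.0, pupil_b=20.0))
        _, patch, roi = _eye_patch_and_roi(scene)
        rect = shrink_to_pupil(patch, roi)
        sub = crop(patch, ROIBox(rect.x0 - 6, rect.y0 - 6,
                                 rect.w + 12, rect.h + 12))
        fit = match_filter_bank(sub.astype_float(), a_hint=rect.w / 2)
        assert fit.a in (20.0, 22.0)


class TestRefineAnnulus:
    def test_subpixel_truth_recovered(self, quiet_scene):
        truth = (0.30, 0.75)
        scene = shift_eye(quiet_scene, *truth, seed=quiet_scene.seed)
        frame = synth.render_scene(scene)
        fit = pupil_center(frame, detect_regions(frame).eye)
        assert fit.cx == pytest.approx(scene.eye.cx, abs=0.05)
        assert fit.cy == pytest.approx(scene.eye.cy, abs=0.05)
        assert fit.stage == "annulus"

    def test_fixed_point_on_noiseless_render(self, quiet_scene):
        frame = synth.render_scene(quiet_scene)
        det = detect_regions(frame)
        patch = crop(frame, det.eye)
        from ofrtrack.pupil import PupilFit
        init = PupilFit(cx=quiet_scene.eye.cx - patch.origin[0],
                        cy=quiet_scene.eye.cy - patch.origin[1],
                        a=quiet_scene.eye.pupil_a, b=quiet_scene.eye.pupil_b,
                        score=1.0)
        out = refine_annulus(patch.astype_float(), init)
        assert abs(out.cx - init.cx) < 0.01
        assert abs(out.cy - init.cy) < 0.01

    def test_monte_carlo_center_sd_at_nominal_noise(self, nominal_scene):
        """Repeated noisy renders at a fixed truth: per-axis center SD must
        stay within the 0.15 px budget."""
        centers = []
        for s in range(100):
            scene = dataclasses.replace(nominal_scene, seed=2000 + s)
            frame = synth.render_scene(scene)
            fit = pupil_center(frame, detect_regions(frame).eye)
            centers.append([fit.cx, fit.cy])
        sd = np.std(centers, axis=0)
        assert sd[0] <= 0.15 and sd[1] <= 0.15

    def test_semiaxes_stay_within_one_pixel_of_init(self, nominal_scene):
        frame = synth.render_scene(nominal_scene)
        fit = pupil_center(frame, detect_regions(frame).eye)
        # filter bank radii step by 2, so the annulus stage may move at
        # most 1 px from the snapped template size
        assert abs(fit.a - nominal_scene.eye.pupil_a) <= 1.0 + 1e-6
        assert abs(fit.b - nominal_scene.eye.pupil_b) <= 1.0 + 1e-6


class TestComposition:
    def test_full_frame_coordinates(self, nominal_scene):
        frame = synth.render_scene(nominal_scene)
        fit = pupil_center(frame, detect_regions(frame).eye)
        assert fit.cx == pytest.approx(nominal_scene.eye.cx, abs=0.1)
        assert fit.cy == pytest.approx(nominal_scene.eye.cy, abs=0.1)

    def test_occluded_pupil_discarded(self, nominal_scene):
        scene = dataclasses.replace(nominal_scene, eye=dataclasses.replace(
            nominal_scene.eye, occlusion_fraction=0.55))
        frame = synth.render_scene(scene)
        det = detect_regions(frame)
        eye_roi = det.eye
        if eye_roi.confidence == 0.0:
            eye_roi = ROIBox(int(scene.eye.cx) - 60, int(scene.eye.cy) - 60,
                             120, 120, label="eye")
        with pytest.raises((LowConfidenceError, PupilLostError, NoMatchError)):
            pupil_center(frame, eye_roi)


class TestInvariances:
    def test_integer_translation_equivariance(self, nominal_scene):
        frame = synth.render_scene(nominal_scene)
        det = detect_regions(frame)
        fit = pupil_center(frame, det.eye)
        dx, dy = 9, -4
        rolled = Frame(np.roll(frame.pixels, (dy, dx), axis=(0, 1)))
        det2 = detect_regions(rolled)
        fit2 = pupil_center(rolled, det2.eye)
        assert fit2.cx - fit.cx == pytest.approx(dx, abs=1e-6)
        assert fit2.cy - fit.cy == pytest.approx(dy, abs=1e-6)

    def test_center_insensitive_to_diameter_change(self, quiet_scene):
        """Growing the pupil by 1 px diameter while holding the center must
        not move the estimated center — the reason the marker's
        correlation trick cannot be used for the pupil."""
        fits = []
        for da in (0.0, 0.5):
            scene = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
                quiet_scene.eye, pupil_a=quiet_scene.eye.pupil_a + da,
                pupil_b=quiet_scene.eye.pupil_b + da))
            frame = synth.render_scene(scene)
            fits.append(pupil_center(frame, detect_regions(frame).eye))
        assert abs(fits[1].cx - fits[0].cx) <= 0.05
        assert abs(fits[1].cy - fits[0].cy) <= 0.05

    def test_reflection_near_boundary_shifts_center_little(self, quiet_scene):
        clean = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye, reflections=()))
        blob = dataclasses.replace(quiet_scene, eye=dataclasses.replace(
            quiet_scene.eye,
            reflections=((quiet_scene.eye.pupil_a - 2.0, 3.0, 3.5, 250.0),)))
        fc = synth.render_scene(clean)
        fb = synth.render_scene(blob)
        fit_c = pupil_center(fc, _manual_eye_box(clean))
        fit_b = pupil_center(fb, _manual_eye_box(blob))
        assert abs(fit_b.cx - fit_c.cx) <= 0.1
        assert abs(fit_b.cy - fit_c.cy) <= 0.1


class TestDiameterChange:
    def test_identical_fits_give_zero(self, nominal_scene):
        frame = synth.render_scene(nominal_scene)
        fit = pupil_center(frame, detect_regions(frame).eye)
        assert pupil_diameter_change(fit, fit) == 0.0

    def test_programmed_step_recovered(self, nominal_scene):
        deltas = []
        for s in range(5):
            base = dataclasses.replace(nominal_scene, seed=600 + s)
            grown = dataclasses.replace(base, seed=700 + s,
                                        eye=dataclasses.replace(
                                            base.eye,
                                            pupil_a=base.eye.pupil_a + 0.5,
                                            pupil_b=base.eye.pupil_b + 0.5))
            f1, f2 = synth.render_scene(base), synth.render_scene(grown)
            deltas.append(pupil_diameter_change(
                pupil_center(f1, detect_regions(f1).eye),
                pupil_center(f2, detect_regions(f2).eye)))
        assert np.mean(deltas) == pytest.approx(1.0, abs=0.1)

    def test_fluctuation_sd_in_physiological_band(self, nominal_scene):
        """Programmed diameter changes with SD 0.21 px (the physiological
        within-epoch regime) must be recovered with an SD in [0.15, 0.30]."""
        rng = np.random.default_rng(31)
        measured = []
        for s in range(30):
            dd = rng.normal(0.0, 0.21)
            base = dataclasses.replace(nominal_scene, seed=800 + s)
            moved = dataclasses.replace(base, seed=900 + s,
                                        eye=dataclasses.replace(
                                            base.eye,
                                            pupil_a=base.eye.pupil_a + dd / 2,
                                            pupil_b=base.eye.pupil_b + dd / 2))
            f1, f2 = synth.render_scene(base), synth.render_scene(moved)
            measured.append(pupil_diameter_change(
                pupil_center(f1, detect_regions(f1).eye),
                pupil_center(f2, detect_regions(f2).eye)))
        sd = np.std(measured, ddof=1)
        assert 0.15 <= sd <= 0.30
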
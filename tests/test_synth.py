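"""Renderer ground truth and trial/calibration simulation."""

import dataclasses

import numpy as np
import pytest

from ofrtrack import GeometryConfig
from ofrtrack import synth


class TestRenderScene:
    def test_deterministic_given_seed(self, nominal_scene):
        a = synth.render_scene(nominal_scene)
        b = synth.render_scene(nominal_scene)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_background_only_matches_formula(self):
        p = synth.SceneParams(frame_size=(100, 80), marker=None, eye=None,
                              noise=synth.NoiseSpec(gaussian_sd=0.0,
                                                    poisson_scale=0.0),
                              psf_sigma_px=0.0)
        frame = synth.render_scene(p)
        xs = np.arange(100)
        ys = np.arange(80)
        expect = (p.background.base
                  + p.background.slope_x * (xs[None, :] / 100 - 0.5)
                  + p.background.slope_y * (ys[:, None] / 80 - 0.5))
        np.testing.assert_allclose(frame.pixels, np.rint(expect), atol=0)

    def test_half_pixel_marker_is_symmetric_about_center(self):
        p = synth.SceneParams(frame_size=(200, 160),
                              marker=synth.MarkerSpec(cx=100.5, cy=80.0),
                              eye=None,
                              background=synth.Background(slope_x=0.0,
                                                          slope_y=0.0),
                              noise=synth.NoiseSpec(gaussian_sd=0.0,
                                                    poisson_scale=0.0))
        img = synth.render_scene(p).pixels.astype(float)
        profile = img[40:120].sum(axis=0)
        for k in range(1, 35):
            assert profile[100 - k + 1] == pytest.approx(profile[100 + k],
                                                         abs=2.0)

    def test_centroid_oracle_recovers_programmed_center(self, quiet_scene):
        """Intensity-weighted centroid of the darkness deficit on a
        noiseless render must sit on the programmed marker center to
        0.01 px — the renderer's own self-consistency check."""
        m = quiet_scene.marker
        scene = dataclasses.replace(
            quiet_scene,
            marker=dataclasses.replace(m, cx=m.cx + 0.37, cy=m.cy - 0.21),
            background=synth.Background(slope_x=0.0, slope_y=0.0))
        img = synth.render_scene(scene).pixels.astype(float)
        y0, y1 = int(m.cy) - 45, int(m.cy) + 46
        x0, x1 = int(m.cx) - 45, int(m.cx) + 46
        win = img[y0:y1, x0:x1]
        weight = win.max() - win
        ys, xs = np.mgrid[y0:y1, x0:x1]
        cx = (weight * xs).sum() / weight.sum()
        cy = (weight * ys).sum() / weight.sum()
        assert cx == pytest.approx(m.cx + 0.37, abs=0.01)
        assert cy == pytest.approx(m.cy - 0.21, abs=0.01)

    def test_geometry_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            synth.SceneParams(frame_size=(100, 100),
                              marker=synth.MarkerSpec(cx=5.0, cy=50.0),
                              eye=None)
        with pytest.raises(ValueError):
            synth.SceneParams(supersample=2)


class TestSimulateTrial:
    def test_zero_paths_render_identically(self, geom_clinical):
        sim = synth.TrialSim((0.0, 80.0, 160.0), np.zeros((3, 2)),
                             np.zeros((3, 2)), np.zeros(3), geom_clinical)
        scene = synth.SceneParams(
            seed=4, noise=synth.NoiseSpec(gaussian_sd=0.0, poisson_scale=0.0))
        res = synth.simulate_trial(sim, scene)
        np.testing.assert_array_equal(res.frames[0].pixels,
                                      res.frames[1].pixels)
        np.testing.assert_array_equal(res.frames[0].pixels,
                                      res.frames[2].pixels)

    def test_head_translation_moves_marker_and_pupil_equally(self,
                                                             geom_clinical):
        head = np.array([[0.0, 0.0], [20.0, 0.0], [20.0, 0.0]])
        sim = synth.TrialSim((0.0, 80.0, 160.0), head, np.zeros((3, 2)),
                             np.zeros(3), geom_clinical)
        res = synth.simulate_trial(sim, synth.SceneParams(seed=4))
        t = res.truth
        d_marker = t.marker_cx[1] - t.marker_cx[0]
        d_pupil = t.pupil_cx[1] - t.pupil_cx[0]
        assert d_marker == pytest.approx(d_pupil, rel=1e-12)
        assert d_marker == pytest.approx(20.0 / geom_clinical.footprint_um_per_px,
                                         rel=1e-12)

    def test_ofr_truth_scaling(self, geom_clinical):
        rng = np.random.default_rng(0)
        sim = synth.make_ofr_trial(rng, geom_clinical, amplitude_deg=0.2,
                                   stimulus_label="down")
        res = synth.simulate_trial(sim, synth.SceneParams(seed=4))
        t = res.truth
        eye_motion_px = ((t.pupil_cy[2] - t.pupil_cy[1])
                         - (t.head_y_px[2] - t.head_y_px[1]))
        assert eye_motion_px == pytest.approx(0.2 / geom_clinical.deg_per_px,
                                              rel=1e-9)
        # no eye rotation before the reflex latency
        assert sim.eye_path_deg[0, 1] == 0.0
        assert sim.eye_path_deg[1, 1] == 0.0

    def test_mismatched_paths_rejected(self, geom_clinical):
        with pytest.raises(ValueError):
            synth.TrialSim((0.0, 80.0), np.zeros((3, 2)), np.zeros((2, 2)),
                           np.zeros(2), geom_clinical)
        with pytest.raises(ValueError):
            synth.TrialSim((80.0, 0.0), np.zeros((2, 2)), np.zeros((2, 2)),
                           np.zeros(2), geom_clinical)


class TestSimulateCalibration:
    def test_series_layout(self, marker_scene, geom40):
        series = synth.simulate_calibration(marker_scene, geom40, seed=0)
        by_key = {(s.axis, s.step_um): s for s in series}
        assert set(by_key) == {("h", 7.5), ("h", 22.5), ("v", 7.5),
                               ("v", 22.5), ("diag", 7.5)}
        assert len(by_key[("h", 7.5)].frames) == 25   # reference + 24
        assert len(by_key[("h", 22.5)].frames) == 9   # reference + 8
        assert by_key[("h", 7.5)].truth_um[-1, 0] == pytest.approx(180.0)
        assert by_key[("v", 22.5)].truth_um[-1, 1] == pytest.approx(180.0)

    def test_diagonal_moves_both_axes_equally(self, marker_scene, geom40):
        series = synth.simulate_calibration(marker_scene, geom40,
                                            axes=("diag",), seed=0)
        truth = series[0].truth_um
        np.testing.assert_allclose(truth[:, 0], truth[:, 1])
        assert series[0].step_um == 7.5

    def test_step_must_divide_total(self, marker_scene, geom40):
        with pytest.raises(ValueError):
            synth.simulate_calibration(marker_scene, geom40,
                                       fine_step_um=7.0, seed=0)


def test_write_trial_emits_manifest_truth_geometry(tmp_path, geom_clinical):
    rng = np.random.default_rng(1)
    sim = synth.make_ofr_trial(rng, geom_clinical, trial_id="trialA")
    res = synth.simulate_trial(sim, synth.SceneParams(seed=9))
    manifest = synth.write_trial(res, tmp_path)
    import pandas as pd
    mf = pd.read_csv(manifest)
    assert list(mf.frame_id) == [f.frame_id for f in res.frames]
    assert (tmp_path / "truth.csv").exists()
    assert (tmp_path / "geometry.cfg").exists()
    from ofrtrack import read_frame
    back = read_frame(tmp_path / f"{res.frames[0].frame_id}.png")
    np.testing.assert_array_equal(back.pixels, res.frames[0].pixels)
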
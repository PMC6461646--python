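"""Bleed-through calibration and sensitized-emission index."""

import numpy as np
import pytest

from nucleomech.core_io import BackgroundSpec, Image2D
from nucleomech.fret import (
    BleedThroughCalibration,
    FretAcquisition,
    FretResult,
    compare_groups,
    fit_bleedthrough,
    fit_crossexcitation,
    fret_index_map,
    mean_fret_per_cell,
    merge_calibrations,
    run_fret_pipeline,
)
from nucleomech.synthetic import make_fret_scene


def _acq(donor, fret, acceptor, registered=False):
    return FretAcquisition(Image2D(donor), Image2D(fret), Image2D(acceptor),
                           registered=registered)


def _ramp(shape=(100, 100), top=1000.0):
    return np.tile(np.linspace(0, top, shape[1]), (shape[0], 1))


class TestCalibrationFits:
    def test_noiseless_slope_exact(self):
        D = _ramp()
        acq = _acq(D, 0.25 * D, np.zeros_like(D))
        cal = fit_bleedthrough(acq, noise_floor=1.0)
        assert cal.x == pytest.approx(0.25, abs=1e-9)
        assert cal.intercept == pytest.approx(0.0, abs=1e-6)

    def test_zero_fret_channel_gives_zero(self):
        D = _ramp()
        cal = fit_bleedthrough(_acq(D, np.zeros_like(D), np.zeros_like(D)),
                               noise_floor=1.0)
        assert cal.x == 0.0

    def test_noisy_recovery_within_tolerance(self, rng):
        D = _ramp()  # 10^4 px
        F = 0.25 * D + rng.normal(0, 5, D.shape)
        cal = fit_bleedthrough(_acq(D, F, np.zeros_like(D)), noise_floor=1.0)
        assert abs(cal.x - 0.25) < 0.01

    def test_crossexcitation_noisy(self, rng):
        A = _ramp()
        F = 0.10 * A + rng.normal(0, 5, A.shape)
        cal = fit_crossexcitation(_acq(np.zeros_like(A), F, A), noise_floor=1.0)
        assert abs(cal.y - 0.10) < 0.01

    def test_contaminated_acceptor_sample_warns(self, rng):
        A = _ramp()
        with pytest.warns(UserWarning, match="donor signal"):
            fit_crossexcitation(_acq(0.5 * A, 0.1 * A, A), noise_floor=1.0)

    def test_unrelated_response_rejected(self, rng):
        D = _ramp()
        F = rng.uniform(0, 250, D.shape)  # no linear relation at all
        with pytest.raises(ValueError, match="unsuitable"):
            fit_bleedthrough(_acq(D, F, np.zeros_like(D)), noise_floor=1.0)

    def test_too_few_pixels_rejected(self):
        D = np.zeros((100, 100))
        D[:3, :] = 500.0
        with pytest.raises(ValueError, match="foreground"):
            fit_bleedthrough(_acq(D, 0.2 * D, np.zeros_like(D)), noise_floor=100.0)

    def test_diagnostics_populated(self, rng):
        D = _ramp()
        F = 0.3 * D + rng.normal(0, 5, D.shape)
        cal = fit_bleedthrough(_acq(D, F, np.zeros_like(D)), noise_floor=1.0)
        assert cal.n_pixels >= 1000
        assert 0.9 < cal.r2 <= 1.0


class TestIndexMap:
    def _cal(self, x=0.25, y=0.10):
        return BleedThroughCalibration(x=x, y=y, n_pixels=10000, r2=0.99)

    def test_no_transfer_gives_zero_index(self, rng):
        D = rng.uniform(100, 500, (64, 64))
        A = rng.uniform(100, 500, (64, 64))
        F = 0.25 * D + 0.10 * A
        acq = _acq(D, F, A, registered=True)
        res = fret_index_map(acq, self._cal(), acceptor_floor=50.0)
        assert np.nanmax(np.abs(res.index_map)) < 1e-9

    def test_pure_sensitized_emission(self):
        A = _ramp(top=800.0)
        acq = _acq(np.zeros_like(A), 0.2 * A, A, registered=True)
        res = fret_index_map(acq, self._cal(x=0.25, y=0.0), acceptor_floor=50.0)
        defined = np.isfinite(res.index_map)
        assert defined.any()
        assert np.allclose(res.index_map[defined], 0.2)

    def test_low_acceptor_pixels_undefined_not_zero(self):
        A = np.full((64, 64), 10.0)
        A[:32] = 500.0
        acq = _acq(np.zeros_like(A), 0.2 * A, A, registered=True)
        res = fret_index_map(acq, self._cal(x=0.0, y=0.0), acceptor_floor=50.0)
        assert np.isnan(res.index_map[40, 0])
        assert res.index_map[10, 0] == pytest.approx(0.2)

    def test_scale_invariance_exact(self, rng):
        D = rng.uniform(100, 500, (64, 64))
        A = rng.uniform(100, 500, (64, 64))
        F = 0.25 * D + 0.18 * A
        r1 = fret_index_map(_acq(D, F, A, registered=True), self._cal(), acceptor_floor=50.0)
        c = 3.7
        r2 = fret_index_map(_acq(c * D, c * F, c * A, registered=True), self._cal(),
                            acceptor_floor=c * 50.0)
        assert np.allclose(r1.index_map, r2.index_map, rtol=1e-12, equal_nan=True)

    def test_unregistered_rejected(self):
        A = _ramp()
        with pytest.raises(ValueError, match="registered"):
            fret_index_map(_acq(A, A, A, registered=False), self._cal())

    def test_missing_calibration_rejected(self):
        A = _ramp()
        with pytest.raises(ValueError, match="calibration"):
            fret_index_map(_acq(A, A, A, registered=True),
                           BleedThroughCalibration(x=0.25, y=None))


class TestPerCellMeans:
    def test_uniform_index(self):
        idx = np.full((50, 50), 0.1)
        masks = np.zeros((50, 50), dtype=int)
        masks[10:30, 10:30] = 1
        means = mean_fret_per_cell(FretResult(index_map=idx), masks)
        assert means == [(1, pytest.approx(0.1))]

    def test_half_and_half_averages(self):
        idx = np.zeros((40, 40))
        idx[:, 20:] = 0.2
        masks = np.zeros((40, 40), dtype=int)
        masks[10:30, 10:30] = 1  # straddles the boundary symmetrically
        means = mean_fret_per_cell(FretResult(index_map=idx), masks)
        assert means[0][1] == pytest.approx(0.1)

    def test_small_cells_dropped(self):
        idx = np.full((50, 50), 0.1)
        masks = np.zeros((50, 50), dtype=int)
        masks[0, :10] = 1
        masks[20:40, 20:40] = 2
        with pytest.warns(UserWarning, match="dropped"):
            means = mean_fret_per_cell(FretResult(index_map=idx), masks)
        assert [m[0] for m in means] == [2]

    def test_group_separation_power(self, rng):
        # tension-sensor vs headless contrast at the observed noise scale:
        # 30 cells/group, per-cell SD 0.05
        hits = 0
        for _ in range(200):
            ts = rng.normal(0.15, 0.05, 30)
            hl = rng.normal(0.0, 0.05, 30)
            if compare_groups(list(ts), list(hl))["p"] < 1e-4:
                hits += 1
        assert hits >= 190


class TestEndToEnd:
    def _pipeline(self, **kw):
        scene, gt = make_fret_scene(**kw)
        bg = BackgroundSpec("constant", value=100.0)
        return run_fret_pipeline(scene["sensor"], scene["donor_only"],
                                 scene["acceptor_only"], scene["masks"], bg)

    def test_sensitized_emission_recovered(self):
        cal, _, means = self._pipeline(true_se_fraction=0.15, x=0.25, y=0.10,
                                       snr=20.0, seed=11)
        assert abs(cal.x - 0.25) < 0.02
        assert abs(cal.y - 0.10) < 0.02
        assert np.mean([m for _, m in means]) == pytest.approx(0.15, abs=0.01)

    def test_headless_scene_near_zero(self):
        _, _, means = self._pipeline(true_se_fraction=0.0, x=0.25, y=0.10,
                                     snr=20.0, seed=3)
        assert abs(np.mean([m for _, m in means])) < 0.01

    def test_self_consistency_on_calibration_sample(self):
        # applying the calibration to the acceptor-only sample itself must
        # give an index statistically indistinguishable from zero
        scene, _ = make_fret_scene(true_se_fraction=0.15, snr=20.0, seed=5)
        bg = {k: BackgroundSpec("constant", value=100.0)
              for k in ("donor", "fret", "acceptor")}
        from nucleomech.fret import correct_acquisition

        for acq in scene.values():
            if isinstance(acq, FretAcquisition):
                acq.background = bg
        cal = merge_calibrations(
            fit_bleedthrough(correct_acquisition(scene["donor_only"])),
            fit_crossexcitation(correct_acquisition(scene["acceptor_only"])),
        )
        res = fret_index_map(correct_acquisition(scene["acceptor_only"]), cal)
        vals = res.index_map[np.isfinite(res.index_map)]
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean()) < max(2 * se, 0.01)

    def test_gradient_correction_tightens_cells(self):
        # a 30% illumination gradient inflates inter-cell spread unless
        # corrected; with correction the spread must be strictly smaller
        from nucleomech.fret import correct_acquisition, fit_bleedthrough as fbt

        for seed in (0, 1):
            scene, _ = make_fret_scene(true_se_fraction=0.15, x=0.25, y=0.10,
                                       gradient_amplitude=0.3, snr=20.0, seed=seed)
            bg = {k: BackgroundSpec("constant", value=100.0)
                  for k in ("donor", "fret", "acceptor")}
            sds = {}
            for illum in (True, False):
                for acq in scene.values():
                    if isinstance(acq, FretAcquisition):
                        acq.background = bg
                cal = merge_calibrations(
                    fbt(correct_acquisition(scene["donor_only"], illumination=illum)),
                    fit_crossexcitation(
                        correct_acquisition(scene["acceptor_only"], illumination=illum)),
                )
                res = fret_index_map(
                    correct_acquisition(scene["sensor"], illumination=illum), cal)
                means = [m for _, m in mean_fret_per_cell(res, scene["masks"])]
                sds[illum] = np.std(means)
            assert sds[True] < sds[False]
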
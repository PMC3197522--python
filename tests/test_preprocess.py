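"""Cleaning stages: overlap exclusion, smoothing, regression, filtering."""

import numpy as np
import pytest

from rsntopo.preprocess import (NuisanceDesign, PreprocessError,
                                VoxelTimeSeriesSet, bandpass,
                                build_nuisance_design, exclude_overlap,
                                extract_timeseries, regress_nuisance,
                                smooth_volumes, FWHM_TO_SIGMA)
from rsntopo.simulate import BoldDataset, RSNAtlas

from conftest import tiny_config
from rsntopo.simulate import generate_atlas, generate_cohort


def _mini_dataset(t=40, rng=None):
    rng = rng or np.random.default_rng(0)
    return BoldDataset(
        subject_id="sub-01",
        volumes=rng.standard_normal((5, 5, 4, t)).astype(np.float32),
        tr=2.0, motion=rng.standard_normal((t, 6)),
        wm_signal=rng.standard_normal(t),
        ventricle_signal=rng.standard_normal(t),
        global_signal=rng.standard_normal(t),
    )


def _ts(data, tr=2.0):
    k = data.shape[0]
    return VoxelTimeSeriesSet(network="X", subject_id="sub-01",
                              voxel_ids=np.zeros((k, 3), int),
                              data=np.asarray(data, float), tr=tr)


class TestExcludeOverlap:
    def test_set_difference_example(self):
        shape = (3, 3, 1)
        a = np.zeros(shape, bool); a[0, 0] = a[0, 1] = a[0, 2] = True
        b = np.zeros(shape, bool); b[0, 2] = b[1, 0] = True
        atlas = RSNAtlas(shape=shape, masks={"A": a, "B": b},
                         groups={"A": "cognitive", "B": "perceptual"})
        out = exclude_overlap(atlas)
        assert {tuple(v) for v in out["A"]} == {(0, 0, 0), (0, 1, 0)}
        assert {tuple(v) for v in out["B"]} == {(1, 0, 0)}

    def test_disjoint_sets_unchanged(self):
        cfg = tiny_config(seed=1)
        cfg.overlap_fraction = 0.0
        atlas = generate_atlas(cfg)
        out = exclude_overlap(atlas)
        for name in atlas.names:
            assert len(out[name]) == atlas.masks[name].sum()

    def test_exclusive_count_matches_label_census(self):
        cfg = tiny_config(seed=7)
        cfg.overlap_fraction = 0.2
        atlas = generate_atlas(cfg)
        counts = atlas.label_counts()
        out = exclude_overlap(atlas)
        for name in atlas.names:
            multi = int((counts[atlas.masks[name]] > 1).sum())
            assert len(out[name]) == atlas.masks[name].sum() - multi

    def test_emptied_network_raises(self):
        shape = (2, 2, 1)
        a = np.zeros(shape, bool); a[0, 0] = True
        b = np.zeros(shape, bool); b[0, 0] = b[1, 1] = True
        atlas = RSNAtlas(shape=shape, masks={"A": a, "B": b},
                         groups={"A": "cognitive", "B": "perceptual"})
        with pytest.raises(PreprocessError, match="'A'"):
            exclude_overlap(atlas)


class TestSmoothing:
    def test_fwhm_zero_is_identity(self):
        ds = _mini_dataset()
        out = smooth_volumes(ds, 0.0)
        assert out.volumes is ds.volumes

    def test_impulse_peak_matches_gaussian(self):
        t = 4
        vol = np.zeros((15, 15, 15, t), np.float32)
        vol[7, 7, 7, :] = 1.0
        ds = _mini_dataset(t)
        ds = type(ds)(subject_id="s", volumes=vol, tr=2.0, motion=ds.motion,
                      wm_signal=ds.wm_signal,
                      ventricle_signal=ds.ventricle_signal,
                      global_signal=ds.global_signal)
        out = smooth_volumes(ds, fwhm_mm=8.0, voxel_size_mm=3.0)
        sigma = 8.0 / FWHM_TO_SIGMA / 3.0
        peak = (1.0 / (sigma * np.sqrt(2 * np.pi))) ** 3
        assert out.volumes[7, 7, 7, 0] == pytest.approx(peak, rel=1e-3)

    def test_constant_volume_preserved_in_interior(self):
        ds = _mini_dataset(t=3)
        ds.volumes[:] = 5.0
        out = smooth_volumes(ds, fwhm_mm=4.0, voxel_size_mm=3.0)
        assert out.volumes[2, 2, 2, :] == pytest.approx(5.0, rel=1e-4)

    def test_bad_voxel_size_raises(self):
        with pytest.raises(PreprocessError):
            smooth_volumes(_mini_dataset(), 8.0, voxel_size_mm=0.0)


class TestNuisanceDesign:
    def test_dimensions_and_order(self):
        ds = _mini_dataset(t=250)
        design = build_nuisance_design(ds)
        assert design.columns.shape == (250, 19)
        assert design.column_names[0] == "intercept"
        assert design.column_names[1:10] == [
            "mot1", "mot2", "mot3", "mot4", "mot5", "mot6",
            "wm", "ventricle", "global"]
        assert all(n.startswith("d_") for n in design.column_names[10:])

    def test_constant_source_has_zero_derivative(self):
        ds = _mini_dataset()
        ds.motion[:, 0] = 3.14
        design = build_nuisance_design(ds)
        d = design.columns[:, design.column_names.index("d_mot1")]
        assert np.allclose(d, 0.0)

    def test_ramp_source_has_constant_derivative(self):
        ds = _mini_dataset()
        ds.wm_signal = np.arange(ds.n_timepoints, dtype=float) * 0.5
        design = build_nuisance_design(ds)
        d = design.columns[:, design.column_names.index("d_wm")]
        # after mean-centring, entries 1.. are equal and entry 0 differs
        assert np.ptp(d[1:]) == pytest.approx(0.0, abs=1e-12)

    def test_columns_mean_centred(self):
        design = build_nuisance_design(_mini_dataset())
        means = design.columns[:, 1:].mean(axis=0)
        assert np.allclose(means, 0.0, atol=1e-12)


class TestRegression:
    def test_series_equal_to_regressor_vanishes(self):
        ds = _mini_dataset()
        design = build_nuisance_design(ds)
        ts = _ts(np.tile(ds.global_signal, (3, 1)))
        out = regress_nuisance(ts, design)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_orthogonal_series_unchanged(self, rng):
        ds = _mini_dataset(t=60)
        design = build_nuisance_design(ds)
        x = rng.standard_normal(60)
        # project out the design, leaving a series orthogonal to it
        beta, *_ = np.linalg.lstsq(design.columns, x, rcond=None)
        x_perp = x - design.columns @ beta
        out = regress_nuisance(_ts(x_perp[None, :]), design)
        assert np.allclose(out.data[0], x_perp, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        ds = _mini_dataset(t=20)
        design = build_nuisance_design(ds)
        X = design.columns
        data = rng.standard_normal((5, 20))
        out = regress_nuisance(_ts(data), design)
        # independent solve via normal equations with pinv
        beta = np.linalg.pinv(X.T @ X) @ X.T @ data.T
        oracle = data - (X @ beta).T
        assert np.allclose(out.data, oracle, atol=1e-10)

    def test_residual_orthogonal_to_all_columns(self, rng):
        ds = _mini_dataset(t=80)
        design = build_nuisance_design(ds)
        out = regress_nuisance(_ts(rng.standard_normal((7, 80))), design)
        inner = out.data @ design.columns
        norms = (np.linalg.norm(out.data, axis=1)[:, None]
                 * np.linalg.norm(design.columns, axis=0)[None, :])
        assert np.all(np.abs(inner) < 1e-8 * np.maximum(norms, 1e-30))

    def test_regression_idempotent(self, rng):
        ds = _mini_dataset(t=50)
        design = build_nuisance_design(ds)
        once = regress_nuisance(_ts(rng.standard_normal((4, 50))), design)
        twice = regress_nuisance(once, design)
        assert np.allclose(once.data, twice.data, atol=1e-10)

    def test_clean_generator_path_barely_changes_variance(self):
        # with all nuisance amplitudes zero only chance correlation is removed
        cfg = tiny_config(seed=13, n_subjects=1)
        cfg.nuisance_amplitudes = {k: 0.0 for k in cfg.nuisance_amplitudes}
        atlas = generate_atlas(cfg)
        ds = generate_cohort(cfg, atlas)[0]
        design = build_nuisance_design(ds)
        vox = exclude_overlap(atlas)["DMN"]
        ts = extract_timeseries(ds, "DMN", vox)
        out = regress_nuisance(ts, design)
        v0 = ts.data.var(axis=1)
        v1 = out.data.var(axis=1)
        assert np.all(np.abs(v1 - v0) / v0 < 0.20)


class TestBandpass:
    def _sine(self, hz, t=250, tr=2.0):
        tt = np.arange(t) * tr
        return _ts(np.sin(2 * np.pi * hz * tt)[None, :], tr)

    def test_passband_sinusoid_retained(self):
        ts = self._sine(0.04)
        out = bandpass(ts)
        rms_in = np.sqrt((ts.data ** 2).mean())
        rms_out = np.sqrt((out.data ** 2).mean())
        assert rms_out >= 0.9 * rms_in

    def test_stopband_sinusoid_suppressed(self):
        ts = self._sine(0.2)
        out = bandpass(ts)
        assert np.sqrt((out.data ** 2).mean()) <= 0.1 * np.sqrt(
            (ts.data ** 2).mean())

    def test_dc_removed(self):
        ts = _ts(np.full((2, 250), 3.0))
        out = bandpass(ts)
        assert np.all(np.abs(out.data) < 1e-6)

    def test_preserves_length_no_nan(self, rng):
        ts = _ts(rng.standard_normal((6, 250)))
        out = bandpass(ts)
        assert out.data.shape == ts.data.shape
        assert np.isfinite(out.data).all()

    def test_band_outside_nyquist_rejected(self):
        ts = _ts(np.random.default_rng(0).standard_normal((1, 100)))
        with pytest.raises(PreprocessError):
            bandpass(ts, 0.01, 0.3)  # Nyquist is 0.25
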
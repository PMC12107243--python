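import numpy as np
import pytest

from voxelgraph.prep import (
    ConfoundMatrix, Exclusion, VoxelTimeSeries, bandpass, build_confounds,
    framewise_displacement, motion_confounds, preprocess_subject,
    regress_confounds, select_volumes,
)


def _motion(n, **cols):
    m = np.zeros((n, 6))
    names = ["tx", "ty", "tz", "rx", "ry", "rz"]
    for k, v in cols.items():
        m[:, names.index(k)] = v
    return m


def _ts(data, tr=2.0):
    data = np.asarray(data, float)
    coords = np.column_stack([np.arange(data.shape[1]),
                              np.zeros(data.shape[1], int),
                              np.zeros(data.shape[1], int)])
    return VoxelTimeSeries(data, coords, tr)


class TestFramewiseDisplacement:
    def test_zero_motion_nothing_scrubbed(self):
        ms = framewise_displacement(_motion(20))
        assert np.all(ms.fd == 0)
        assert ms.scrubbed_volume_ids == set()
        assert ms.usable_volumes == 20

    def test_translation_jump_scrubs_terminating_volume(self):
        tx = np.zeros(20)
        tx[11:] = 0.6             # jump between volumes 10 -> 11
        ms = framewise_displacement(_motion(20, tx=tx))
        assert ms.fd[10] == pytest.approx(0.6)
        assert ms.scrubbed_volume_ids == {11}

    def test_rotation_at_exact_threshold_not_scrubbed(self):
        rx = np.zeros(5)
        rx[2:] = 0.01             # 0.01 rad * 50 mm = 0.5 mm, strict >
        ms = framewise_displacement(_motion(5, rx=rx), rotation_radius_mm=50)
        assert ms.fd[1] == pytest.approx(0.5)
        assert ms.scrubbed_volume_ids == set()

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="6 columns"):
            framewise_displacement(np.zeros((10, 5)))


class TestRegressConfounds:
    def test_intercept_only_mean_centres(self, rng):
        ts = _ts(rng.normal(size=(50, 4)) + 10)
        conf = ConfoundMatrix(np.ones((50, 1)), ["const"])
        out = regress_confounds(ts, conf)
        assert np.allclose(out.data, ts.data - ts.data.mean(0), atol=1e-10)

    def test_perfect_fit_residual_zero(self, rng):
        c = rng.normal(size=50)
        ts = _ts(np.column_stack([c, rng.normal(size=50)]))
        conf = ConfoundMatrix(np.column_stack([np.ones(50), c]), ["const", "c"])
        out = regress_confounds(ts, conf)
        assert np.abs(out.data[:, 0]).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self, rng):
        ts = _ts(rng.normal(size=(80, 10)))
        x = np.column_stack([np.ones(80), rng.normal(size=(80, 4))])
        out = regress_confounds(ts, ConfoundMatrix(x, list("abcde")))
        assert np.abs(x.T @ out.data).max() < 1e-8

    def test_idempotent(self, rng):
        ts = _ts(rng.normal(size=(60, 6)))
        conf = ConfoundMatrix(np.column_stack([np.ones(60),
                                               rng.normal(size=(60, 3))]),
                              list("abcd"))
        once = regress_confounds(ts, conf)
        twice = regress_confounds(once, conf)
        assert np.abs(twice.data - once.data).max() < 1e-10

    def test_rank_deficient_columns_dropped_with_warning(self, rng):
        c = rng.normal(size=40)
        x = np.column_stack([np.ones(40), c, 2 * c])
        ts = _ts(rng.normal(size=(40, 3)))
        with pytest.warns(UserWarning, match="dependent confound"):
            out = regress_confounds(ts, ConfoundMatrix(x, ["const", "c", "2c"]))
        assert np.abs(x[:, :2].T @ out.data).max() < 1e-8


class TestBandpass:
    def test_constant_series_removed(self):
        ts = _ts(np.full((200, 2), 5.0))
        out = bandpass(ts)
        assert np.abs(out.data).max() < 1e-6

    @pytest.mark.parametrize("freq,lo,hi", [(0.04, 0.9, 1.1), (0.2, 0.0, 0.1)])
    def test_sinusoid_amplitude_by_fft(self, freq, lo, hi):
        tr = 2.0
        t = np.arange(1000) * tr
        x = np.sin(2 * np.pi * freq * t)
        out = bandpass(_ts(x[:, None], tr=tr))
        k = int(round(freq * len(t) * tr))
        ratio = np.abs(np.fft.rfft(out.data[:, 0]))[k] / np.abs(np.fft.rfft(x))[k]
        assert lo <= ratio <= hi

    def test_rejects_band_above_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_ts(np.zeros((100, 1)), tr=2.0), high_hz=0.3)


class TestSelectVolumes:
    def test_clean_run_keeps_first_120(self, rng):
        run = _ts(rng.normal(size=(150, 3)))
        ms = framewise_displacement(_motion(150))
        out = select_volumes([run], [ms])
        assert out.data.shape[0] == 120
        assert np.array_equal(out.kept_volume_ids, np.arange(120))

    def test_too_few_usable_is_motion_exclusion(self, rng):
        run = _ts(rng.normal(size=(130, 3)))
        tx = np.zeros(130)
        tx[np.arange(10, 40, 2)] = np.arange(1, 16)   # 15 big jumps
        ms = framewise_displacement(_motion(130, tx=tx))
        assert ms.usable_volumes < 120
        out = select_volumes([run], [ms])
        assert isinstance(out, Exclusion)
        assert out.reason == "motion"

    def test_two_runs_concatenate_in_order(self, rng):
        r1 = _ts(np.arange(70 * 2).reshape(70, 2))
        r2 = _ts(1000 + np.arange(70 * 2).reshape(70, 2))
        ms = framewise_displacement(_motion(70))
        out = select_volumes([r1, r2], [ms, ms])
        assert out.data.shape[0] == 120
        assert np.array_equal(out.data[:70], r1.data)
        assert np.array_equal(out.data[70:], r2.data[:50])
        assert np.array_equal(out.kept_volume_ids,
                              np.concatenate([np.arange(70), 70 + np.arange(50)]))

    def test_mismatched_voxel_index_rejected(self, rng):
        r1 = _ts(rng.normal(size=(130, 3)))
        r2 = VoxelTimeSeries(rng.normal(size=(130, 3)),
                             r1.voxel_index[::-1], 2.0)
        ms = framewise_displacement(_motion(130))
        with pytest.raises(ValueError, match="voxel_index"):
            select_volumes([r1, r2], [ms, ms])


class TestPipelineOrder:
    def test_scrubbing_happens_after_filtering(self, rng):
        """Regression fixture: the cleaned output equals filter-then-scrub,
        and differs from scrub-then-filter (the orders are not exchangeable)."""
        shape = (4, 4, 4)
        mask = np.zeros(shape, bool)
        mask[1:3, 1:3, 1:3] = True
        img = rng.normal(size=shape + (140,))
        tx = np.zeros(140)
        tx[60:] = 0.7
        motion = _motion(140, tx=tx)

        out = preprocess_subject(img, mask, motion, tr_seconds=2.0)
        ts = VoxelTimeSeries(img[mask].T, np.argwhere(mask), 2.0)
        conf = build_confounds(motion)
        clean = regress_confounds(ts, conf)
        filt = bandpass(clean)
        ms = framewise_displacement(motion)
        expected = select_volumes([filt], [ms])
        assert np.allclose(out.data, expected.data, atol=1e-10)

        keep = [t for t in range(140) if t not in ms.scrubbed_volume_ids][:121]
        scrub_first = bandpass(VoxelTimeSeries(clean.data[keep],
                                               clean.voxel_index, 2.0))
        assert not np.allclose(out.data, scrub_first.data[:120], atol=1e-3)

    def test_output_is_120_rows_or_exclusion(self, small_dataset):
        from voxelgraph.pipeline import PipelineParams, prep_stage
        cleaned, subjects = prep_stage(small_dataset, PipelineParams())
        assert all(ts.data.shape[0] == 120 for ts in cleaned.values())
        for s in subjects:
            assert s.included or s.exclusion_reason == "motion"


def test_compcor_components_orthonormal(rng):
    from voxelgraph.prep import compcor_components
    block = rng.normal(size=(100, 30))
    comp = compcor_components(block, 5)
    assert comp.shape == (100, 5)
    assert np.allclose(comp.T @ comp, np.eye(5), atol=1e-10)


def test_motion_confounds_have_twelve_motion_columns():
    conf = motion_confounds(_motion(50))
    assert conf.columns.shape[1] == 1 + 12 + 2   # const, 6+6 motion, trends
    assert conf.names[0] == "const"
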
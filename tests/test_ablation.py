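import math

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from scipy.ndimage import shift as nd_shift
from scipy.signal import correlate2d

from cellfoam.ablation import (
    AblationEvent,
    VelocityField,
    filter_vectors,
    fit_tip_recoil,
    kymograph,
    piv_field,
    preablation_mask,
    radial_velocity,
    recoil_duration,
    resample_stack,
    summarize_radial,
    tip_distance_series,
    top_fraction,
)
from cellfoam.image import TimeLapse
from cellfoam.synthetic import (
    SyntheticSceneConfig,
    _render_spots,
    make_recoil_movie,
    make_tip_recoil_movie,
)


def texture(seed=0, size=256, sigma=1.0):
    rng = np.random.default_rng(seed)
    return gaussian_filter(rng.normal(size=(size, size)), sigma)


class TestPIV:
    def test_integer_shift_recovered(self):
        big = texture(0)
        a = big[64:192, 64:192]
        b = big[64:192, 61:189]  # content moves +3 px in x
        field = piv_field(a, b, window_px=32, overlap_px=16, dt=1.0,
                          pixel_size=1.0)
        assert np.abs(field.u - 3).max() < 0.2
        assert np.abs(field.v).max() < 0.2

    def test_identical_frames_zero_field(self):
        a = texture(1)[:96, :96]
        field = piv_field(a, a, dt=1.0, pixel_size=1.0)
        assert np.abs(field.u).max() == 0
        assert np.abs(field.v).max() == 0

    def test_subpixel_shift(self):
        big = texture(2)
        a = big[64:192, 64:192]
        b = nd_shift(big, (0, 0.4), order=3)[64:192, 64:192]
        field = piv_field(a, b, dt=1.0, pixel_size=1.0)
        assert field.u.mean() == pytest.approx(0.4, abs=0.1)

    def test_units_conversion(self):
        big = texture(3)
        a = big[64:192, 64:192]
        b = big[64:192, 62:190]
        field = piv_field(a, b, dt=2.0, pixel_size=0.11)
        assert field.u.mean() == pytest.approx(2 * 0.11 / 2.0, abs=0.02)

    def test_direct_correlation_oracle_equivalence(self):
        # same windows pushed through scipy's direct spatial correlation
        big = texture(4)
        a = big[32:96, 32:96]
        b = big[32:96, 30:94]
        field = piv_field(a, b, window_px=32, overlap_px=0, dt=1.0,
                          pixel_size=1.0)
        k = 0
        for r0 in (0, 32):
            for c0 in (0, 32):
                wa = a[r0:r0 + 32, c0:c0 + 32]
                wb = b[r0:r0 + 32, c0:c0 + 32]
                corr = correlate2d(wb - wb.mean(), wa - wa.mean(), mode="full")
                pr, pc = np.unravel_index(np.argmax(corr), corr.shape)
                assert math.hypot(field.u[k] - (pc - 31),
                                  field.v[k] - (pr - 31)) < 1.0
                k += 1

    def test_phase_correlation_oracle_agreement(self):
        # independent established implementation on the full frames
        from skimage.registration import phase_cross_correlation

        big = texture(5)
        a = big[64:192, 64:192]
        b = big[64:192, 61:189]
        shift_rc, _, _ = phase_cross_correlation(a, b, upsample_factor=100)
        field = piv_field(a, b, dt=1.0, pixel_size=1.0)
        assert field.u.mean() == pytest.approx(-shift_rc[1], abs=0.1)
        assert field.v.mean() == pytest.approx(-shift_rc[0], abs=0.1)

    def test_window_larger_than_frame(self):
        a = texture(6)[:24, :24]
        with pytest.raises(ValueError):
            piv_field(a, a, window_px=32)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            piv_field(texture(7)[:64, :64], texture(7)[:32, :32])


class TestFilterAndTop:
    def _field(self, u, snr):
        n = len(u)
        return VelocityField(np.arange(n), np.zeros(n), np.asarray(u, float),
                             np.zeros(n), np.asarray(snr, float), dt=1.0,
                             pixel_size=1.0)

    def test_zero_field_filtered_empty(self):
        assert len(filter_vectors(self._field([0, 0], [9, 9]))) == 0

    def test_snr_threshold(self):
        out = filter_vectors(self._field([1, 1], [1.0, 2.5]), snr_min=1.3)
        assert len(out) == 1
        assert out.snr[0] == 2.5

    def test_shifted_scene_retention(self):
        big = texture(8)
        a = big[64:192, 64:192]
        b = big[64:192, 61:189]
        field = piv_field(a, b, dt=1.0, pixel_size=1.0)
        kept = filter_vectors(field, snr_min=1.3)
        assert len(kept) >= 0.9 * len(field)

    def test_top_fraction_single_max(self):
        f = self._field(list(range(1, 11)), [2] * 10)
        out = top_fraction(f, q=0.1)
        assert len(out) == 1
        assert out.u[0] == 10

    def test_top_fraction_ties_included(self):
        f = self._field([2.0] * 8, [2] * 8)
        assert len(top_fraction(f, q=0.25)) == 8

    def test_top_fraction_identity(self):
        f = self._field([1, 2, 3], [2, 2, 2])
        assert len(top_fraction(f, q=1.0)) == 3


class TestRadialVelocity:
    def _one_vector(self, x, y, u, v):
        return VelocityField([x], [y], [u], [v], [2.0], dt=1.0, pixel_size=1.0)

    EVENT = AblationEvent(point=(0.0, 0.0), start=0.0, end=1.0)

    def test_outward_positive(self):
        rec = radial_velocity(self._one_vector(10, 0, 0.05, 0), self.EVENT)
        assert rec.v_rad_um_s.iloc[0] == pytest.approx(0.05)

    def test_inward_negative(self):
        rec = radial_velocity(self._one_vector(10, 0, -0.05, 0), self.EVENT)
        assert rec.v_rad_um_s.iloc[0] == pytest.approx(-0.05)

    def test_tangential_zero(self):
        rec = radial_velocity(self._one_vector(10, 0, 0, 0.07), self.EVENT)
        assert rec.v_rad_um_s.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_at_site_skipped(self):
        rec = radial_velocity(self._one_vector(0, 0, 1, 1), self.EVENT)
        assert len(rec) == 0

    def test_distance_in_micrometres(self):
        f = VelocityField([3], [4], [0.1], [0], [2.0], dt=1.0, pixel_size=0.11)
        rec = radial_velocity(f, self.EVENT)
        assert rec.d_um.iloc[0] == pytest.approx(5 * 0.11)

    def test_rotation_equivariance(self, rng):
        n = 40
        x, y = rng.uniform(-20, 20, n), rng.uniform(-20, 20, n)
        u, v = rng.normal(size=n), rng.normal(size=n)
        base = radial_velocity(
            VelocityField(x, y, u, v, np.full(n, 2.0), 1.0, 1.0), self.EVENT)
        th = 1.1
        c, s = math.cos(th), math.sin(th)
        rot = radial_velocity(VelocityField(
            c * x - s * y, s * x + c * y, c * u - s * v, s * u + c * v,
            np.full(n, 2.0), 1.0, 1.0), self.EVENT)
        assert np.allclose(np.sort(base.v_rad_um_s), np.sort(rot.v_rad_um_s))
        assert np.allclose(np.sort(base.d_um), np.sort(rot.d_um))

    def test_divergent_and_solenoidal_fields(self, rng):
        n = 500
        x, y = rng.uniform(-30, 30, n), rng.uniform(-30, 30, n)
        r = np.hypot(x, y)
        ok = r > 1
        x, y, r = x[ok], y[ok], r[ok]
        speed = 0.1 * np.exp(-r / 10)
        div = radial_velocity(VelocityField(
            x, y, speed * x / r, speed * y / r, np.full(len(x), 2.0), 1, 1),
            self.EVENT)
        assert np.allclose(div.v_rad_um_s, speed, atol=1e-12)
        sol = radial_velocity(VelocityField(
            x, y, -speed * y / r, speed * x / r, np.full(len(x), 2.0), 1, 1),
            self.EVENT)
        assert np.abs(sol.v_rad_um_s).max() < 1e-12


class TestSummarizeRadial:
    def test_constant_records(self):
        rec = pd.DataFrame({"t_s": [1.0] * 8, "d_um": np.linspace(0.2, 3.8, 8),
                            "v_rad_um_s": [0.05] * 8})
        out = summarize_radial(rec, distance_bins_um=1.0, time_bins_s=1.0,
                               seed=0)
        defined = out[out.defined]
        assert np.allclose(defined.mean_v_um_s, 0.05)
        assert np.allclose(defined.ci_hi - defined.ci_lo, 0.0)

    def test_empty_bin_flagged(self):
        rec = pd.DataFrame({"t_s": [1.0, 1.0], "d_um": [0.5, 3.5],
                            "v_rad_um_s": [0.1, 0.2]})
        out = summarize_radial(rec, distance_bins_um=1.0, time_bins_s=1.0,
                               seed=0)
        gap = out[(out.d_lo_um == 1.0)]
        assert not gap.defined.iloc[0]
        assert gap.n.iloc[0] == 0

    def test_empty_records_fail(self):
        with pytest.raises(ValueError):
            summarize_radial(pd.DataFrame(columns=["t_s", "d_um",
                                                   "v_rad_um_s"]))


class TestResampleStack:
    def _stack(self, times):
        frames = np.arange(len(times))[:, None, None] * np.ones((1, 4, 4))
        return TimeLapse(frames, times=np.asarray(times, float))

    def test_one_hz_to_three_seconds(self):
        out = resample_stack(self._stack(np.arange(10.0)), 3.0)
        assert out.times.tolist() == [0, 3, 6, 9]

    def test_identity_interval(self):
        st = self._stack(np.arange(5.0))
        out = resample_stack(st, 1.0)
        assert np.array_equal(out.times, st.times)

    def test_irregular_nearest_no_duplicates(self):
        times = [0.0, 0.9, 3.2, 5.9, 6.4, 9.1]
        out = resample_stack(self._stack(times), 3.0)
        # brute-force nearest for grid 0,3,6,9
        expected = []
        for g in [0, 3, 6, 9]:
            i = int(np.argmin(np.abs(np.asarray(times) - g)))
            if times[i] not in expected:
                expected.append(times[i])
        assert out.times.tolist() == expected

    def test_interval_too_fine(self):
        with pytest.raises(ValueError):
            resample_stack(self._stack(np.arange(5.0)), 0.5)


class TestPreablationMask:
    def test_static_network_covered(self):
        img = _render_spots((64, 64), np.array([[20, 20], [40, 40]]), 2.0)
        stack = TimeLapse(np.stack([img] * 4), times=np.arange(4.0))
        event = AblationEvent(point=(32, 32), start=3.5, end=5.0)
        mask = preablation_mask(stack, event)
        assert mask[20, 20] and mask[40, 40]
        assert not mask[5, 60]

    def test_no_preframes(self):
        stack = TimeLapse(np.ones((3, 8, 8)), times=np.arange(3.0))
        with pytest.raises(ValueError):
            preablation_mask(stack, AblationEvent((4, 4), -1.0, 0.5))

    def test_all_zero_stack_fails(self):
        stack = TimeLapse(np.zeros((3, 16, 16)), times=np.arange(3.0))
        with pytest.raises(ValueError):
            preablation_mask(stack, AblationEvent((4, 4), 2.5, 3.5))

    def test_mask_area_monotone_in_frames(self):
        rng = np.random.default_rng(0)
        imgs = [_render_spots((48, 48), np.array([[10 + 8 * i, 24]]), 2.0)
                for i in range(4)]
        areas = []
        for k in (1, 2, 3, 4):
            stack = TimeLapse(np.stack(imgs[:k] + [np.zeros((48, 48))]),
                              times=np.arange(k + 1.0))
            event = AblationEvent((24, 24), k - 0.5, k + 0.5)
            areas.append(preablation_mask(stack, event).sum())
        assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


class TestKymograph:
    def test_static_spot_vertical_stripe(self):
        img = _render_spots((64, 64), np.array([[32, 32]]), 2.0)
        stack = TimeLapse(np.stack([img] * 6), times=np.arange(6.0))
        km = kymograph(stack, ((10, 32), (54, 32)), width_px=5)
        cols = np.argmax(km.data, axis=1)
        assert np.all(cols == cols[0])
        assert abs(cols[0] - 22) <= 1  # spot sits 22 px along the line

    def test_moving_spot_diagonal(self):
        frames = [
            _render_spots((64, 64), np.array([[12 + 4 * t, 32]]), 2.0)
            for t in range(8)
        ]
        stack = TimeLapse(np.stack(frames), times=np.arange(8.0))
        km = kymograph(stack, ((10, 32), (54, 32)), width_px=5)
        cols = np.argmax(km.data, axis=1)
        slopes = np.diff(cols)
        assert np.allclose(slopes, 4, atol=1)

    def test_blank_rows_for_ablation_frames(self):
        img = _render_spots((64, 64), np.array([[32, 32]]), 2.0)
        frames = np.stack([img, np.zeros((64, 64)), img])
        stack = TimeLapse(frames, times=np.arange(3.0))
        km = kymograph(stack, ((10, 32), (54, 32)), width_px=5)
        assert km.data[1].max() == 0
        assert km.data[0].max() > 0

    def test_band_exits_frame(self):
        stack = TimeLapse(np.ones((2, 32, 32)), times=np.arange(2.0))
        with pytest.raises(ValueError, match="band exits"):
            kymograph(stack, ((0, 1), (31, 1)), width_px=10)

    def test_uses_sum_across_band(self):
        stack = TimeLapse(np.ones((1, 32, 32)), times=[0.0])
        km5 = kymograph(stack, ((5, 16), (25, 16)), width_px=5)
        km11 = kymograph(stack, ((5, 16), (25, 16)), width_px=11)
        assert km11.data.mean() > 2 * km5.data.mean()


class TestTips:
    def test_two_static_spots(self):
        sep_um, px = 5.0, 0.11
        cx, cy = 48, 32
        centers = np.array([[cx - sep_um / 2 / px, cy],
                            [cx + sep_um / 2 / px, cy]])
        img = _render_spots((64, 96), centers, 2.0)
        stack = TimeLapse(np.stack([img] * 5), pixel_size=px,
                          times=np.arange(5.0))
        series = tip_distance_series(stack, ((5, cy), (90, cy)), width_px=10)
        assert series.valid.all()
        assert np.allclose(series.distances, 5.0, atol=0.1)

    def test_single_peak_flagged(self):
        img = _render_spots((64, 96), np.array([[48, 32]]), 2.0)
        stack = TimeLapse(img[None], pixel_size=0.11, times=[0.0])
        series = tip_distance_series(stack, ((5, 32), (90, 32)), width_px=10)
        assert not series.valid[0]
        assert np.isnan(series.distances[0])

    def test_recoil_movie_fit_within_ten_percent(self):
        cfg = SyntheticSceneConfig(
            shape=(96, 192), seed=3, read_noise_sd=0.02,
            params={"D0_um": 2.0, "A_um": 2.0, "tau_s": 5.0, "n_frames": 40})
        stack, truth = make_tip_recoil_movie(cfg)
        series = tip_distance_series(stack, truth["line"], width_px=10)
        fit = fit_tip_recoil(series)
        assert fit["A"] == pytest.approx(truth["A_um"], rel=0.1)
        assert fit["tau"] == pytest.approx(truth["tau_s"], rel=0.1)


class TestRecoilPipeline:
    @pytest.fixture(scope="class")
    @staticmethod
    def radial_records():
        cfg = SyntheticSceneConfig(
            shape=(160, 160), seed=21, read_noise_sd=0.02,
            params={"v0_um_s": 0.25, "tau_s": 4.0, "d_peak_um": 3.0,
                    "n_pre": 4, "n_blank": 2, "n_post": 30})
        stack, event, truth = make_recoil_movie(cfg)
        sub = stack.subset([i for i in range(len(stack))
                            if i not in event.blank_frames])
        recs = []
        for i in range(len(sub) - 1):
            dt = float(sub.times[i + 1] - sub.times[i])
            field = piv_field(sub[i], sub[i + 1], dt=dt,
                              pixel_size=cfg.pixel_size)
            field.t = float(0.5 * (sub.times[i] + sub.times[i + 1])
                            - event.start)
            kept = filter_vectors(field, snr_min=1.3)
            if len(kept):
                recs.append(radial_velocity(kept, event))
        return pd.concat(recs, ignore_index=True), truth

    def test_fastest_recoil_between_two_and_four_um(self, radial_records):
        radial, _ = radial_records
        summary = summarize_radial(radial, distance_bins_um=1.0,
                                   time_bins_s=3.0, n_boot=500, seed=1)
        early = summary[(summary.t_lo_s >= 0) & (summary.t_lo_s < 3)
                        & summary.defined]
        best = early.loc[early.mean_v_um_s.idxmax()]
        assert 2.0 <= best.d_lo_um and best.d_hi_um <= 4.0

    def test_recoil_duration_within_one_bin_of_crossing(self, radial_records):
        radial, truth = radial_records
        summary = summarize_radial(radial,
                                   distance_bins_um=np.array([0.0, 1e9]),
                                   time_bins_s=3.0, n_boot=1000, seed=2)
        est = recoil_duration(summary)
        g = truth["g"]
        gbar = float(np.mean(g(radial.d_um)))
        defined = summary[summary.defined]
        w = float((defined.ci_hi - defined.ci_lo).median() / 2)
        t_star = truth["tau_s"] * math.log(truth["v0_um_s"] * gbar / w)
        assert abs(est - t_star) <= 3.0  # one time bin

    def test_decay_to_zero_late(self, radial_records):
        radial, truth = radial_records
        late = radial[radial.t_s > 6 * truth["tau_s"]]
        assert abs(late.v_rad_um_s.mean()) < 0.005
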
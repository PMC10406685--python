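"""Direct FT, virtual echo and IST reconstruction."""

import numpy as np
import pytest

from diffcs import (
    AxisMeta,
    Peak,
    ReconConfig,
    SamplingSchedule,
    TimeDomain2D,
    cs_reconstruct_2d,
    direct_ft,
    ft2d,
    generate_fid,
    ist_reconstruct,
    poisson_gap_schedule,
    undersample,
    virtual_echo,
)
from diffcs._fft import cos2_window, hz_to_index, spectrum_from_time
from diffcs.cs_recon import ist_time_estimate
from diffcs.sampling import full_schedule


class TestDirectFt:
    def test_delta_in_t2_gives_flat_rows(self, axes_small):
        ax1, ax2 = axes_small
        data = np.zeros((64, 64), dtype=complex)
        data[:, 0] = 1.0
        interf = direct_ft(TimeDomain2D(data, ax1, ax2), ReconConfig(apodization=None))
        assert np.allclose(np.abs(interf.data), np.abs(interf.data[:, :1]), rtol=1e-9)

    def test_linearity(self, axes_small):
        ax1, ax2 = axes_small
        x = generate_fid([Peak(300.0, 200.0, 12.0, 20.0)], ax1, ax2)
        y = generate_fid([Peak(-500.0, -300.0, 15.0, 25.0)], ax1, ax2)
        combo = x.copy()
        combo.data = x.data + 2.0 * y.data
        assert np.allclose(
            direct_ft(combo).data,
            direct_ft(x).data + 2.0 * direct_ft(y).data,
            rtol=1e-9,
            atol=1e-12,
        )

    def test_single_peak_column_carries_t1_modulation(self, axes_small):
        ax1, ax2 = axes_small
        fid = generate_fid([Peak(300.0, 200.0, 0.0, 20.0)], ax1, ax2)
        interf = direct_ft(fid)
        i2 = hz_to_index(200.0, interf.data.shape[1], ax2.spectral_width)
        column = interf.data[:, i2]
        expected = np.exp(2j * np.pi * 300.0 * ax1.times)
        # the column is the t1 modulation scaled by the (complex) lineshape value
        ratio = column / expected
        assert np.allclose(ratio, ratio[0], rtol=1e-9)


class TestVirtualEcho:
    def test_real_constant_input_symmetric_real_output(self):
        sched = full_schedule(8)
        ve, ext = virtual_echo(np.ones(8), sched)
        assert np.allclose(ve.imag, 0.0)
        assert np.allclose(ve[1:], ve[1:][::-1])

    def test_spectrum_of_full_virtual_echo_is_real(self):
        ax = AxisMeta(128, 1000.0)
        col = np.exp((2j * np.pi * 137.0 - 10.0) * ax.times)
        ve, _ = virtual_echo(col, full_schedule(128))
        spec = spectrum_from_time(ve)
        assert np.abs(spec.imag).max() <= 1e-9 * np.abs(spec.real).max()

    def test_extended_schedule_counts_center_once(self):
        sched = poisson_gap_schedule(64, 16, seed=1)
        ve, ext = virtual_echo(np.ones(16, dtype=complex), sched)
        assert ext.size == 2 * 16 - 1


class TestIst:
    def test_full_sampling_equals_plain_ft(self, three_peak_column):
        sched = full_schedule(256)
        rec = ist_reconstruct(three_peak_column, sched)
        full = np.real(spectrum_from_time(three_peak_column, 512))
        assert np.abs(rec - full).max() <= 1e-6 * np.abs(full).max()

    def test_zero_input_gives_zero_output(self):
        sched = poisson_gap_schedule(256, 32, seed=0)
        rec = ist_reconstruct(np.zeros(32, dtype=complex), sched)
        assert np.all(rec == 0.0)

    def test_single_peak_m16_position_exact_height_within_1pct(self, axes_column):
        col = np.exp((2j * np.pi * 300.0 - 12.0) * axes_column.times)
        w = cos2_window(256)
        full = np.real(spectrum_from_time(col * w, 512))
        errs = []
        for seed in range(5):
            sched = poisson_gap_schedule(256, 16, seed=seed)
            x = ist_time_estimate(col[sched.indices], sched)
            rec = np.real(spectrum_from_time(x * w, 512))
            assert np.argmax(rec) == np.argmax(full)
            errs.append(abs(rec.max() - full.max()) / full.max())
        assert np.mean(errs) < 0.01

    def test_three_peak_m64_correlates_with_full_ft(self, three_peak_column):
        w = cos2_window(256)
        full = np.real(spectrum_from_time(three_peak_column * w, 512))
        rs = []
        for seed in range(5):
            sched = poisson_gap_schedule(256, 64, seed=seed)
            x = ist_time_estimate(three_peak_column[sched.indices], sched)
            rec = np.real(spectrum_from_time(x * w, 512))
            rs.append(np.corrcoef(rec, full)[0, 1])
        assert np.mean(rs) > 0.999

    def test_data_consistency_at_measured_points(self, three_peak_column):
        sched = poisson_gap_schedule(256, 32, seed=3)
        x = ist_time_estimate(three_peak_column[sched.indices], sched)
        assert np.array_equal(x[sched.indices], three_peak_column[sched.indices])

    def test_non_finite_input_rejected(self):
        sched = poisson_gap_schedule(16, 4, seed=0)
        bad = np.array([1.0, np.nan, 1.0, 1.0], dtype=complex)
        with pytest.raises(ValueError, match="non-finite"):
            ist_reconstruct(bad, sched)


class TestCsReconstruct2d:
    def test_fully_sampled_equals_ft2d(self, two_peak_fid):
        nus = undersample(two_peak_fid, full_schedule(64))
        rec = cs_reconstruct_2d(nus)
        full = ft2d(two_peak_fid)
        assert np.abs(rec.data - full.data).max() <= 1e-6 * np.abs(full.data).max()
        assert rec.provenance == "cs_rec"

    def test_noise_only_input_stays_near_noise_floor(self, axes_small):
        ax1, ax2 = axes_small
        fid = generate_fid([], ax1, ax2, noise_sigma=1.0, seed=9)
        nus = undersample(fid, poisson_gap_schedule(64, 16, seed=2))
        rec = cs_reconstruct_2d(nus)
        full = ft2d(fid)
        assert np.abs(rec.data).max() <= 5.0 * np.std(full.data)

    def test_fifty_peak_positions_recovered_as_local_maxima(self):
        ax1 = AxisMeta(256, 2700.0)
        ax2 = AxisMeta(32, 1500.0)
        rng = np.random.default_rng(0)
        # well-separated positions so every true apex is an isolated maximum
        cells = rng.choice(10 * 8, size=50, replace=False)
        df1, df2 = 2700.0 / 10, 1500.0 / 8
        peaks = [
            Peak(
                -0.45 * 2700.0 + (c // 8 + 0.5) * df1 * 0.9,
                -0.45 * 1500.0 + (c % 8 + 0.5) * df2 * 0.9,
                12.0,
                20.0,
                a,
            )
            for c, a in zip(cells, rng.uniform(0.5, 1.5, 50))
        ]
        fid = generate_fid(peaks, ax1, ax2)
        nus = undersample(fid, poisson_gap_schedule(256, 64, seed=1))
        rec = cs_reconstruct_2d(nus)
        z1, z2 = rec.data.shape
        for p in peaks:
            i1 = hz_to_index(p.f1, z1, 2700.0)
            i2 = hz_to_index(p.f2, z2, 1500.0)
            box = rec.data[i1 - 2 : i1 + 3, i2 - 2 : i2 + 3]
            apex = np.unravel_index(np.argmax(box), box.shape)
            # a local maximum within one point of the true position
            assert abs(apex[0] - 2) <= 1 and abs(apex[1] - 2) <= 1

    def test_reconstruction_error_non_increasing_in_sampling_level(self, three_peak_column):
        # the more points sampled, the better the average reconstruction
        w = cos2_window(256)
        full = np.real(spectrum_from_time(three_peak_column * w, 512))
        levels = [8, 16, 24, 32, 40, 48, 56, 64, 128]
        means = []
        for m in levels:
            errs = []
            for seed in range(20):
                sched = poisson_gap_schedule(256, m, seed=seed)
                x = ist_time_estimate(three_peak_column[sched.indices], sched)
                rec = np.real(spectrum_from_time(x * w, 512))
                errs.append(np.linalg.norm(rec - full) / np.linalg.norm(full))
            means.append(np.mean(errs))
        # non-increasing up to Monte-Carlo fluctuation on the converged plateau
        assert all(b <= a * 1.10 for a, b in zip(means, means[1:]))
        assert means[-1] < 0.1 * means[0]

    def test_sparser_columns_reconstruct_more_accurately(self, axes_column):
        # 2 peaks vs 20 peaks at fixed M=16: sparsity controls difficulty
        t = axes_column.times
        rng = np.random.default_rng(1)
        sparse = sum(np.exp((2j * np.pi * f - 12.0) * t) for f in (300.0, -700.0))
        crowded = sum(
            np.exp((2j * np.pi * f - 12.0) * t)
            for f in rng.uniform(-1200.0, 1200.0, 20)
        )
        w = cos2_window(256)

        def mean_err(col):
            full = np.real(spectrum_from_time(col * w, 512))
            errs = []
            for seed in range(20):
                sched = poisson_gap_schedule(256, 16, seed=seed)
                x = ist_time_estimate(col[sched.indices], sched)
                rec = np.real(spectrum_from_time(x * w, 512))
                errs.append(np.linalg.norm(rec - full) / np.linalg.norm(full))
            return np.mean(errs)

        assert mean_err(sparse) < mean_err(crowded)


def test_recon_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(n_iterations=0)
    with pytest.raises(ValueError):
        ReconConfig(threshold_decay=1.5)
    with pytest.raises(ValueError):
        ReconConfig(threshold_schedule="bogus")
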
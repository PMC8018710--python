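"""Passive cavitation mapping: steering, correlation, robust Capon, maps."""
import numpy as np
import pytest
from scipy.optimize import minimize

from histopam import field_model as fm
from histopam import pam as pm
from histopam import synthetic_data as sd
from histopam.exceptions import GridMismatchError, UndefinedCentroidError


@pytest.fixture()
def medium1500():
    return fm.Medium(density=1000.0, sound_speed=1500.0)


def _pair_geometry():
    pos = np.array([[0.0, 0.0, 0.0], [3e-3, 0.0, 0.0]])
    return pm.ArrayGeometry(pos, pitch=3e-3)


class TestSteering:
    def test_three_four_five_triangle_delay(self, medium1500):
        """Elements at x=0 and 3 mm, point 4 mm down the first element's
        axis: relative delay (5-4) mm / c ~ 0.667 us aligns the channels."""
        geom = _pair_geometry()
        fs = 50e6
        t = np.arange(512) / fs
        pulse = lambda tt: sd.gaussian_pulse(tt - 4e-6, 2e6, 1.0)
        delay = 1e-3 / 1500.0
        data = pm.ChannelData(
            np.vstack([pulse(t), pulse(t - delay)]), sampling_rate=fs
        )
        steered = pm.steer_signals(data, [0.0, 0.0, 4e-3], medium1500, geom)
        np.testing.assert_allclose(steered.distances, [4e-3, 5e-3], rtol=1e-12)
        # after steering both channels carry the un-delayed pulse
        err = np.abs(steered.steered[1] - pulse(t)).max()
        assert err < 1e-3 * np.abs(pulse(t)).max()

    def test_equidistant_point_is_identity(self, medium1500):
        geom = _pair_geometry()
        rng = np.random.default_rng(0)
        data = pm.ChannelData(rng.normal(size=(2, 256)), sampling_rate=50e6)
        steered = pm.steer_signals(data, [1.5e-3, 0.0, 10e-3], medium1500, geom)
        np.testing.assert_allclose(steered.steered, data.samples, atol=1e-9)

    def test_energy_preserved_for_noise(self, medium1500):
        """Band-limited delay is unitary: per-channel energy kept to 1%.

        Leading zeros exceed the largest steering shift so no content is
        moved out of the record (which would be truncation, not
        interpolation loss)."""
        geom = _pair_geometry()
        rng = np.random.default_rng(1)
        raw = rng.normal(size=(2, 1024))
        raw[:, :64] = 0.0
        data = pm.ChannelData(raw, sampling_rate=50e6)
        steered = pm.steer_signals(data, [0.0, 0.0, 4e-3], medium1500, geom)
        e_in = (raw**2).sum(axis=1)
        e_out = (steered.steered**2).sum(axis=1)
        np.testing.assert_allclose(e_out, e_in, rtol=0.01)


class TestCorrelationMatrix:
    def test_hand_example(self):
        s = pm.SteeredSet(
            steered=np.array([[1.0, 0.0], [0.0, 2.0]]),
            point=np.zeros(3), distances=np.ones(2), sampling_rate=1.0,
        )
        R = pm.correlation_matrix(s)
        np.testing.assert_allclose(R.matrix, [[1.0, 0.0], [0.0, 4.0]])
        assert R.duration == 2.0

    def test_coherent_rank_one(self):
        sig = np.sin(np.linspace(0, 20, 200))
        s = pm.SteeredSet(
            steered=np.tile(sig, (4, 1)), point=np.zeros(3),
            distances=np.ones(4), sampling_rate=1e6,
        )
        R = pm.correlation_matrix(s).matrix
        assert np.allclose(R, R[0, 0])
        ev = np.linalg.eigvalsh(R)
        assert ev[-1] > 0 and np.allclose(ev[:-1], 0, atol=1e-9 * ev[-1])

    def test_zero_record(self):
        s = pm.SteeredSet(
            steered=np.zeros((3, 16)), point=np.zeros(3),
            distances=np.ones(3), sampling_rate=1e6,
        )
        assert not pm.correlation_matrix(s).matrix.any()


class TestRCBPower:
    def test_white_noise_closed_form(self, medium1500):
        """R = sigma^2 I at epsilon -> 0 gives the Capon value sigma^2/N
        times the geometric prefactor."""
        sigma2, n = 2.5, 8
        R = pm.CorrelationMatrix(np.eye(n) * sigma2, duration=1.0)
        p = pm.rcb_power(
            R, params=pm.RCBParams(epsilon=1e-9, loading=0.0),
            d_mean=1.0, medium=medium1500,
        )
        pre = 4 * np.pi / (1.0 * 1000.0 * 1500.0)
        assert p == pytest.approx(pre * sigma2 / n, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_brute_force_constrained_optimization_oracle(self, seed, medium1500):
        """Matches min_{||a-abar||^2<=eps} a'R^-1 a found by numeric
        optimization on small SPD matrices, within 0.1%."""
        rng = np.random.default_rng(seed)
        n, eps = 4, 0.5
        A = rng.normal(size=(n, n))
        M = A @ A.T + 0.5 * np.eye(n)
        R = pm.CorrelationMatrix(M, duration=1.0)
        p = pm.rcb_power(
            R, params=pm.RCBParams(epsilon=eps, loading=0.0),
            d_mean=1.0, medium=medium1500,
        )
        Minv = np.linalg.inv(M)
        abar = np.ones(n)
        cons = {"type": "ineq", "fun": lambda a: eps - np.sum((a - abar) ** 2)}
        best = np.inf
        for _ in range(15):
            x0 = abar + rng.normal(0, 0.3, n)
            res = minimize(
                lambda a: a @ Minv @ a, x0, constraints=[cons],
                method="SLSQP", options={"maxiter": 500, "ftol": 1e-14},
            )
            if res.success:
                best = min(best, res.fun)
        pre = 4 * np.pi / (1.0 * 1000.0 * 1500.0)
        assert p == pytest.approx(pre / best, rel=1e-3)

    def test_epsilon_zero_limit_is_capon(self, medium1500):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        M = A @ A.T + np.eye(5)
        R = pm.CorrelationMatrix(M, duration=1.0)
        p = pm.rcb_power(
            R, params=pm.RCBParams(epsilon=1e-10, loading=0.0),
            d_mean=1.0, medium=medium1500,
        )
        abar = np.ones(5)
        capon = 1.0 / (abar @ np.linalg.inv(M) @ abar)
        pre = 4 * np.pi / (1.0 * 1000.0 * 1500.0)
        assert p == pytest.approx(pre * capon, rel=1e-4)

    def test_rank_one_aligned_vs_misaligned(self, medium1500):
        n = 6
        aligned = np.ones(n)
        R = pm.CorrelationMatrix(np.outer(aligned, aligned) * 2.0, duration=1.0)
        params = pm.RCBParams(epsilon=0.05, loading=1e-9)
        p_aligned = pm.rcb_power(R, aligned, params, 1.0, medium1500)
        mis = np.ones(n)
        mis[::2] *= -1.0
        p_mis = pm.rcb_power(R, mis, params, 1.0, medium1500)
        assert p_mis < p_aligned

    def test_zero_energy_matrix_gives_zero(self, medium1500):
        R = pm.CorrelationMatrix(np.zeros((4, 4)), duration=1.0)
        assert pm.rcb_power(R, medium=medium1500) == 0.0

    def test_quadratic_amplitude_scaling(self, medium1500):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(4, 4))
        M = A @ A.T + np.eye(4)
        p1 = pm.rcb_power(pm.CorrelationMatrix(M, 1.0), medium=medium1500)
        p3 = pm.rcb_power(pm.CorrelationMatrix(9 * M, 1.0), medium=medium1500)
        assert p3 == pytest.approx(9 * p1, rel=1e-9)


class TestMaps:
    fs = 31.25e6

    def _frame(self, positions_mm, medium, geom, snr_db=np.inf, seed=0):
        em = sd.EmitterSet(
            positions=np.atleast_2d(positions_mm),
            amplitudes=np.ones(np.atleast_2d(positions_mm).shape[0]),
        )
        t0 = 0.016 / medium.sound_speed - 2e-6
        return sd.simulate_emissions(
            em, geom, medium, fs=self.fs, duration=320 / self.fs,
            snr_db=snr_db, seed=seed, t0=t0,
        )

    def test_single_emitter_peak_on_its_azimuth_column(self, water37):
        geom = pm.ArrayGeometry.linear(n_elements=32)
        data = self._frame([1.0, 0.0, 20.0], water37, geom, snr_db=20, seed=5)
        az = np.arange(-4.0, 4.01, 0.5)
        rg = np.arange(17.0, 23.01, 0.5)
        m = pm.pam_map(data, az, rg, geom, water37)
        i, _ = np.unravel_index(m.power.argmax(), m.power.shape)
        assert az[i] == pytest.approx(1.0, abs=0.5)

    def test_zero_signal_frame_gives_zero_map(self, water37):
        geom = pm.ArrayGeometry.linear(n_elements=8)
        data = pm.ChannelData(np.zeros((8, 128)), sampling_rate=self.fs)
        m = pm.pam_map(data, np.arange(-2, 2.1, 1.0), np.arange(18, 22.1, 1.0),
                       geom, water37)
        assert not m.power.any()

    def test_two_emitters_two_azimuth_maxima(self, water37):
        geom = pm.ArrayGeometry.linear(n_elements=48)
        data = self._frame([[-2.5, 0.0, 20.0], [2.5, 0.0, 20.0]], water37, geom,
                           snr_db=30, seed=6)
        az = np.arange(-4.0, 4.01, 0.5)
        rg = np.arange(18.0, 22.01, 1.0)
        m = pm.pam_map(data, az, rg, geom, water37)
        prof = m.power.max(axis=1)
        order = np.argsort(prof)[::-1]
        tops = sorted(az[order[:4]].tolist())
        assert any(abs(a + 2.5) <= 0.5 for a in tops)
        assert any(abs(a - 2.5) <= 0.5 for a in tops)

    def test_das_and_rcb_agree_on_source_azimuth(self, water37):
        geom = pm.ArrayGeometry.linear(n_elements=32)
        data = self._frame([-1.5, 0.0, 20.0], water37, geom, snr_db=25, seed=7)
        az = np.arange(-4.0, 4.01, 0.5)
        rg = np.arange(18.0, 22.01, 1.0)
        m_rcb = pm.pam_map(data, az, rg, geom, water37, beamformer="rcb")
        m_das = pm.pam_map(data, az, rg, geom, water37, beamformer="das")
        i_rcb = np.unravel_index(m_rcb.power.argmax(), m_rcb.power.shape)[0]
        i_das = np.unravel_index(m_das.power.argmax(), m_das.power.shape)[0]
        assert az[i_rcb] == pytest.approx(az[i_das], abs=0.5)

    def test_map_scales_quadratically_with_amplitude(self, water37):
        geom = pm.ArrayGeometry.linear(n_elements=16)
        d1 = self._frame([0.0, 0.0, 20.0], water37, geom)
        d2 = pm.ChannelData(3 * d1.samples, d1.sampling_rate)
        az, rg = np.arange(-1, 1.1, 1.0), np.arange(19, 21.1, 1.0)
        m1 = pm.pam_map(d1, az, rg, geom, water37)
        m2 = pm.pam_map(d2, az, rg, geom, water37)
        np.testing.assert_allclose(m2.power, 9 * m1.power, rtol=1e-6)

    def test_common_time_shift_invariance(self, water37):
        """A common shift of all channels leaves the map unchanged (the
        correlation window sees the same waveforms)."""
        geom = pm.ArrayGeometry.linear(n_elements=16)
        em = sd.EmitterSet(positions=np.array([[0.0, 0.0, 20.0]]),
                           amplitudes=np.array([1.0]))
        t0 = 0.016 / water37.sound_speed - 2e-6
        d1 = sd.simulate_emissions(em, geom, water37, fs=self.fs,
                                   duration=320 / self.fs, seed=0, t0=t0)
        d2 = sd.simulate_emissions(em, geom, water37, fs=self.fs,
                                   duration=320 / self.fs, seed=0,
                                   t0=t0 - 32 / self.fs)
        az, rg = np.arange(-1, 1.1, 1.0), np.arange(19, 21.1, 1.0)
        m1 = pm.pam_map(d1, az, rg, geom, water37)
        m2 = pm.pam_map(d2, az, rg, geom, water37)
        np.testing.assert_allclose(m2.power, m1.power, rtol=0.02)


class TestMapReductions:
    def _map(self, power):
        power = np.asarray(power, dtype=float)
        return pm.AcousticPowerMap(
            np.arange(power.shape[0], dtype=float) * 2.0,
            np.arange(power.shape[1], dtype=float) * 2.0,
            power,
        )

    def test_frame_average_identity_and_mean(self):
        m = self._map([[1.0, 2.0], [3.0, 4.0]])
        assert np.array_equal(pm.frame_average([m]).power, m.power)
        m2 = self._map([[3.0, 2.0], [1.0, 0.0]])
        avg = pm.frame_average([m, m2])
        np.testing.assert_allclose(avg.power, [[2.0, 2.0], [2.0, 2.0]])
        assert avg.frames_averaged == 2

    def test_frame_average_constant_conservation(self):
        maps = [self._map(np.full((3, 3), 7.0)) for _ in range(50)]
        avg = pm.frame_average(maps)
        np.testing.assert_allclose(avg.power, 7.0)
        assert avg.frames_averaged == 50

    def test_frame_average_grid_mismatch(self):
        a = self._map(np.ones((2, 2)))
        b = pm.AcousticPowerMap([0.0, 1.0], [0.0, 2.0], np.ones((2, 2)))
        with pytest.raises(GridMismatchError):
            pm.frame_average([a, b])

    def test_centroid_single_pixel(self):
        p = np.zeros((3, 3))
        p[2, 1] = 5.0
        c = pm.emission_centroid(self._map(p))
        np.testing.assert_allclose(c, [4.0, 2.0])

    def test_centroid_weighted_mean_hand_example(self):
        """Pixels at azimuth 0 and 4 mm with powers 1 and 3 -> 3 mm."""
        m = pm.AcousticPowerMap([0.0, 4.0], [0.0], np.array([[1.0], [3.0]]))
        assert pm.emission_centroid(m)[0] == pytest.approx(3.0)

    def test_centroid_symmetric_map(self):
        p = np.ones((5, 5))
        c = pm.emission_centroid(self._map(p))
        np.testing.assert_allclose(c, [4.0, 4.0])

    def test_centroid_zero_map_raises(self):
        with pytest.raises(UndefinedCentroidError):
            pm.emission_centroid(self._map(np.zeros((2, 2))))

    def test_one_dB_region_uniform_and_single_peak(self):
        uniform = self._map(np.ones((4, 4)))
        assert pm.one_dB_region(uniform).count == 16
        p = np.full((4, 4), 0.5)
        p[1, 2] = 1.0
        assert pm.one_dB_region(self._map(p)).count == 1

    def test_one_dB_region_gaussian_radius(self):
        """Gaussian power map: the 1 dB (power) contour sits at
        r = sigma sqrt(2 ln 10^0.1)."""
        ax = np.arange(-60, 60.1, 0.25)
        X, Z = np.meshgrid(ax, ax, indexing="ij")
        sigma = 10.0
        power = np.exp(-(X**2 + Z**2) / (2 * sigma**2))
        m = pm.AcousticPowerMap(ax, ax, power)
        mask = pm.one_dB_region(m)
        r_expect = sigma * np.sqrt(2 * np.log(10**0.1))
        rr = np.hypot(*mask.world_coords().T)
        assert rr.max() == pytest.approx(r_expect, abs=0.25)
        area_expect = np.pi * r_expect**2
        assert mask.count * 0.25**2 == pytest.approx(area_expect, rel=0.02)
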
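import numpy as np
import pytest

from anesgc import (SurrogateConfig, gc_significance_threshold, granger_pair,
                    phase_randomize, sobi, source_shift_surrogate,
                    volume_conduction_check)
from conftest import ar1, make_coupled_pair


class TestPhaseRandomize:
    def test_periodogram_preserved(self):
        rng = np.random.default_rng(0)
        for n in (256, 255, 1024):
            x = np.cumsum(rng.normal(size=n))
            y = phase_randomize(x, 7)
            px = np.abs(np.fft.rfft(x)) ** 2
            py = np.abs(np.fft.rfft(y)) ** 2
            assert np.allclose(px, py, rtol=1e-8, atol=1e-8)

    def test_sinusoid_amplitude_unchanged(self):
        t = np.arange(512)
        x = 3.0 * np.sin(2 * np.pi * 10 * t / 512)
        y = phase_randomize(x, 3)
        # a pure tone stays a pure tone of the same amplitude (RMS equal)
        assert np.sqrt(np.mean(y ** 2)) == pytest.approx(
            np.sqrt(np.mean(x ** 2)), rel=1e-9)
        assert np.abs(np.fft.rfft(y))[10] == pytest.approx(
            np.abs(np.fft.rfft(x))[10], rel=1e-9)

    def test_autocovariance_preserved(self):
        rng = np.random.default_rng(1)
        n = 2048
        for seed in range(20):
            x = ar1(n, 0.7, rng)
            y = phase_randomize(x, seed)
            for lag in range(1, 7):
                ax = np.corrcoef(x[lag:], x[:-lag])[0, 1]
                ay = np.corrcoef(y[lag:], y[:-lag])[0, 1]
                assert abs(ax - ay) < 3 / np.sqrt(n)

    def test_cross_coupling_destroyed(self):
        rng = np.random.default_rng(2)
        n = 2048
        collapsed = 0
        for seed in range(30):
            x1, x2 = make_coupled_pair(n, 0.8, rng)
            s1 = phase_randomize(x1, 2 * seed)
            s2 = phase_randomize(x2, 2 * seed + 1)
            r = np.corrcoef(s1[1:], s2[:-1])[0, 1]
            if abs(r) < 4 / np.sqrt(n):
                collapsed += 1
        assert collapsed >= 27

    def test_deterministic_given_seed(self):
        x = np.random.default_rng(3).normal(size=256)
        assert np.array_equal(phase_randomize(x, 5), phase_randomize(x, 5))


class TestSignificanceThreshold:
    def test_single_surrogate_equals_its_gc(self):
        rng = np.random.default_rng(4)
        x1, x2 = make_coupled_pair(512, 0.5, rng)
        cfg = SurrogateConfig(n_surrogates=1, seed=9)
        thr = gc_significance_threshold(x1, x2, 6, cfg)
        srng = np.random.default_rng(np.random.SeedSequence(9))
        est = granger_pair(phase_randomize(x1, srng),
                           phase_randomize(x2, srng), 6)
        assert thr[0] == pytest.approx(est.gc_12)
        assert thr[1] == pytest.approx(est.gc_21)

    def test_coupled_direction_detected_null_direction_not(self):
        rng = np.random.default_rng(5)
        cfg = SurrogateConfig(n_surrogates=19, seed=0)
        hits_21 = hits_12 = 0
        n_win = 40
        for i in range(n_win):
            x1, x2 = make_coupled_pair(1024, 0.5, rng)
            est = granger_pair(x1, x2, 6)
            thr_12, thr_21 = gc_significance_threshold(
                x1, x2, 6, SurrogateConfig(n_surrogates=19, seed=i))
            hits_21 += est.gc_21 > thr_21
            hits_12 += est.gc_12 > thr_12
        assert hits_21 >= 0.95 * n_win
        assert hits_12 <= 0.25 * n_win

    def test_null_exceedance_rate_near_nominal(self):
        # max of 19 surrogates -> one-sided level 1/20 per direction
        rng = np.random.default_rng(6)
        hits = total = 0
        for i in range(100):
            x1 = rng.normal(size=512)
            x2 = rng.normal(size=512)
            est = granger_pair(x1, x2, 6)
            thr_12, thr_21 = gc_significance_threshold(
                x1, x2, 6, SurrogateConfig(n_surrogates=19, seed=1000 + i))
            hits += (est.gc_12 > thr_12) + (est.gc_21 > thr_21)
            total += 2
        assert 0.01 <= hits / total <= 0.11


class TestSOBI:
    def mixed_independent(self, seed, n=4000, k=3):
        rng = np.random.default_rng(seed)
        phis = [0.8, 0.5, -0.6, 0.3][:k]
        s = np.vstack([ar1(n, phi, rng) for phi in phis])
        mixing = rng.normal(size=(k, k)) + 2 * np.eye(k)
        return mixing @ s, mixing, s

    def test_recovers_source_subspace(self):
        x, mixing, s = self.mixed_independent(0)
        a_hat, s_hat = sobi(x)
        # each true source should correlate ~1 with some recovered source
        c = np.abs(np.corrcoef(np.vstack([s, s_hat]))[:3, 3:])
        assert np.all(c.max(axis=1) > 0.95)

    def test_zero_shift_identity(self):
        x, _, _ = self.mixed_independent(1)
        surr = source_shift_surrogate(x, SurrogateConfig(shift_t=0, seed=0))
        assert np.allclose(surr, x, atol=1e-8)

    def test_shift_preserves_channel_covariance(self):
        x, _, _ = self.mixed_independent(2)
        surr = source_shift_surrogate(x, SurrogateConfig(shift_t=100, seed=0))
        c0, c1 = np.cov(x), np.cov(surr)
        assert np.linalg.norm(c1 - c0) / np.linalg.norm(c0) < 0.1

    def test_lag_coupling_attenuated(self):
        rng = np.random.default_rng(3)
        x1, x2 = make_coupled_pair(4000, 0.6, rng)
        x = np.vstack([x1, x2, ar1(4000, 0.5, rng)])
        surr = source_shift_surrogate(x, SurrogateConfig(shift_t=150, seed=0))
        orig = granger_pair(x[0, :1024], x[1, :1024], 6).gc_21
        shif = granger_pair(surr[0, :1024], surr[1, :1024], 6).gc_21
        assert shif < orig

    def test_too_short_recording_rejected(self):
        x, _, _ = self.mixed_independent(4, n=400)
        with pytest.raises(ValueError, match="too short"):
            source_shift_surrogate(x, SurrogateConfig(shift_t=200, seed=0))


class TestVolumeConductionCheck:
    def test_identical_vectors_perfect_fit(self):
        x = np.array([0.1, 0.5, 0.9, 0.2])
        res = volume_conduction_check(x, x.copy())
        assert res.r2 == 1.0
        assert res.verdict == "cannot-exclude-volume-conduction"

    def test_attenuated_surrogate_strongly_negative(self):
        x = np.array([0.2, 0.4, 0.6])
        y = np.array([0.02, 0.04, 0.06])
        res = volume_conduction_check(x, y)
        ss_res = float(np.sum((y - x) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        assert res.ss_res == pytest.approx(ss_res)
        assert res.ss_tot == pytest.approx(ss_tot)
        assert res.r2 == pytest.approx(1 - ss_res / ss_tot)
        assert res.r2 < 0
        assert res.verdict == "volume-conduction-rejected"

    def test_zero_variance_surrogate_undefined(self):
        res = volume_conduction_check(np.array([0.1, 0.2, 0.3]),
                                      np.full(3, 0.5))
        assert np.isnan(res.r2) and "undefined" in res.verdict

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            volume_conduction_check(np.zeros(4), np.zeros(5))


class TestEndToEndDiscrimination:
    """Instantaneous mixtures must look like volume conduction (r2 >= 0);
    genuinely lag-coupled sources must be rejected (r2 < 0)."""

    def pooled_gc(self, x, order=6, win=1024, step=512):
        vals = []
        starts = range(0, x.shape[1] - win + 1, step)
        for s in starts:
            for i in range(x.shape[0] - 1):
                for j in range(i + 1, x.shape[0]):
                    est = granger_pair(x[i, s:s + win], x[j, s:s + win], order)
                    if not est.undefined:
                        vals.extend([est.gc_12, est.gc_21])
        return np.asarray(vals)

    def r2_for(self, x, seed):
        surr = source_shift_surrogate(x, SurrogateConfig(shift_t=120,
                                                         seed=seed))
        return volume_conduction_check(self.pooled_gc(x),
                                       self.pooled_gc(surr)).r2

    def test_instantaneous_mixture_not_excluded(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            s = np.vstack([ar1(4000, phi, rng) for phi in (0.9, 0.6, -0.5)])
            mixing = rng.normal(size=(3, 3)) + 2 * np.eye(3)
            if self.r2_for(mixing @ s, seed) >= 0.0:
                hits += 1
        assert hits >= 8

    def test_lag_coupled_sources_rejected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            x1, x2 = make_coupled_pair(4000, 0.6, rng)
            x = np.vstack([x1, x2, ar1(4000, 0.5, rng)])
            if self.r2_for(x, seed) < 0.0:
                hits += 1
        assert hits >= 8
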
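import numpy as np
import pytest

from palmpulse.evalmorph import (
    average_waveform,
    build_cycle_set,
    compare_sites,
    compute_metrics,
    detect_valleys,
    morphology_indices,
)
from palmpulse.synth import PulseModelParams, generate_clean_ppg


def textbook_pearson(a, b):
    am, bm = a - a.mean(), b - b.mean()
    return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))


def textbook_cosine(a, b):
    return float(np.sum(a * b) / (np.sqrt(np.sum(a**2)) * np.sqrt(np.sum(b**2))))


class TestComputeMetrics:
    def test_identity(self, rng):
        x = rng.normal(0, 1, 100)
        r = compute_metrics(x, x)
        assert r.mape == 0 and r.rmse == 0
        assert r.pearson_rho == pytest.approx(1.0)
        assert r.cosine_similarity == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        x = rng.normal(0, 1, 100)
        x -= x.mean()
        r = compute_metrics(-x, x)
        assert r.pearson_rho == pytest.approx(-1.0)
        assert r.cosine_similarity == pytest.approx(-1.0)

    def test_hand_arithmetic_4_vectors(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        rec = np.array([1.0, 2.0, 3.0, 5.0])
        r = compute_metrics(rec, ref)
        assert r.rmse == pytest.approx(0.5)
        assert r.pearson_rho == pytest.approx(textbook_pearson(rec, ref))

    def test_agrees_with_textbook_formulas(self, rng):
        for _ in range(20):
            a = rng.normal(0, 2, 50)
            b = rng.normal(1, 3, 50)
            r = compute_metrics(a, b)
            assert r.pearson_rho == pytest.approx(textbook_pearson(a, b), abs=1e-10)
            assert r.cosine_similarity == pytest.approx(textbook_cosine(a, b), abs=1e-10)
            assert r.rmse == pytest.approx(np.sqrt(np.mean((a - b) ** 2)), abs=1e-10)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            compute_metrics(np.arange(4.0), np.ones(4))


class TestDetectValleys:
    def test_recovers_synthetic_cycle_starts(self):
        pulse = generate_clean_ppg(
            PulseModelParams(heart_rate_bpm=60.0, hrv_cv=0.0), 20.0, 100.0, seed=0
        )
        valleys = detect_valleys(pulse.samples, 100.0)
        assert 19 <= len(valleys) <= 21
        # strictly periodic at 1 Hz: every true cycle boundary is a multiple of 100
        true_starts = np.arange(0, 2001, 100)
        for v in valleys:
            assert np.min(np.abs(true_starts - v)) <= 3

    def test_monotone_empty(self):
        assert len(detect_valleys(np.linspace(0, 1, 500), 100.0)) == 0

    def test_constant_empty(self):
        assert len(detect_valleys(np.zeros(500), 100.0)) == 0

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_valleys(np.zeros(100), 100.0)


class TestBuildCycleSet:
    def test_clean_signal_zero_rejections(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        assert all(cs.quality)
        for c in cs.cycles:
            assert c.min() == pytest.approx(0.0, abs=1e-12)
            assert c.max() == pytest.approx(1.0, abs=1e-12)

    def test_cycle_count_is_valleys_minus_one(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        assert len(cs.quality) == len(valleys) - 1

    def test_transient_cycle_rejected(self, clean_pulse):
        x = clean_pulse.samples.copy()
        valleys = detect_valleys(x, 100.0)
        a, b = valleys[4], valleys[5]
        x[(a + b) // 2] += 25.0  # large transient inside one cycle
        cs = build_cycle_set(x, valleys, 100.0)
        assert not cs.quality[4]
        assert sum(cs.quality) >= len(cs.quality) - 2

    def test_all_rejected_raises_with_reasons(self):
        x = np.zeros(1000)
        with pytest.raises(ValueError):
            build_cycle_set(x, np.array([0, 100, 500]), 100.0)


class TestAverageWaveform:
    def test_identical_cycles_idempotent(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        cs.cycles = [cs.cycles[0].copy() for _ in range(5)]
        assert np.allclose(average_waveform(cs), cs.cycles[0])

    def test_single_cycle_passthrough(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        cs.cycles = cs.cycles[:1]
        assert np.array_equal(average_waveform(cs), cs.cycles[0])

    def test_averaging_reduces_noise(self, clean_pulse, rng):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        template = cs.cycles[0]
        noisy = [np.clip(template + rng.normal(0, 0.05, len(template)), 0, 1) for _ in range(20)]
        cs.cycles = noisy
        avg = average_waveform(cs)
        worst = max(noisy, key=lambda c: np.linalg.norm(c - template))
        assert np.linalg.norm(avg - template) < np.linalg.norm(worst - template)

    def test_empty_rejected(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        cs.cycles = []
        with pytest.raises(ValueError):
            average_waveform(cs)


class TestMorphologyIndices:
    def test_peak_at_30_percent(self):
        n = 100
        t = np.linspace(0, 1, n)
        cycle = np.exp(-((t - 0.3) ** 2) / (2 * 0.05**2))
        cycle = (cycle - cycle.min()) / (cycle.max() - cycle.min())
        m = morphology_indices(cycle, fs_effective=n)
        assert m.t1 == pytest.approx(0.3, abs=2.0 / n)

    def test_h1_is_one_for_normalized(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        m = morphology_indices(cs.cycles[0], cs.fs_effective)
        assert m.h1 == 1.0

    def test_single_lobe_missing_notch(self):
        t = np.linspace(0, 1, 100)
        cycle = np.exp(-((t - 0.3) ** 2) / (2 * 0.08**2))
        cycle = (cycle - cycle.min()) / (cycle.max() - cycle.min())
        m = morphology_indices(cycle, fs_effective=100)
        assert m.h2 is None and m.h3 is None
        assert m.t1 > 0 and m.t2 > 0

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            morphology_indices(np.linspace(0, 2, 100), 100)


class TestCompareSites:
    @staticmethod
    def _avg(params, seed):
        pulse = generate_clean_ppg(params, 20.0, 100.0, seed=seed)
        valleys = detect_valleys(pulse.samples, 100.0)
        cs = build_cycle_set(pulse.samples, valleys, 100.0)
        return average_waveform(cs), cs.fs_effective

    def test_identical_sites(self, clean_pulse):
        valleys = detect_valleys(clean_pulse.samples, 100.0)
        cs = build_cycle_set(clean_pulse.samples, valleys, 100.0)
        avg = average_waveform(cs)
        c = compare_sites(avg, avg, cs.fs_effective)
        assert c.delta_t1_ms == 0 and c.delta_t2_ms == 0
        assert c.delta_h1 == 0
        assert c.rho == pytest.approx(1.0)

    def test_shift_decreases_rho(self):
        avg, fs_eff = self._avg(PulseModelParams(), 5)
        rhos = [compare_sites(avg, np.roll(avg, k), fs_eff).rho for k in (1, 2, 5)]
        assert rhos[0] < 1.0
        assert rhos[0] > rhos[1] > rhos[2]

    def test_notch_depth_difference_recovered(self):
        avg_a, fs_eff = self._avg(PulseModelParams(notch_depth=0.15), 5)
        avg_b, _ = self._avg(PulseModelParams(notch_depth=0.25), 7)
        c = compare_sites(avg_a, avg_b, fs_eff)
        assert c.delta_h2 == pytest.approx(0.1, abs=0.02)
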
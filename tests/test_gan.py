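import numpy as np
import pytest

from palmpulse.gan import (
    Discriminator,
    DiscriminatorConfig,
    GatedSkip,
    Generator,
    GeneratorConfig,
    LossWeights,
    PeakAnnotation,
    annotate_peaks,
    discriminator_loss,
    generator_loss,
    spectral_magnitude,
)
from palmpulse.nn import Tensor
from palmpulse.synth import PulseModelParams, generate_clean_ppg, minmax_normalize


def reference_dft_magnitude(x, n=1024):
    """Independent DFT by explicit matrix multiplication."""
    x = np.asarray(x, dtype=float)
    padded = np.zeros(n)
    padded[: min(len(x), n)] = x[:n]
    k = np.arange(n)
    dft = np.exp(-2j * np.pi * np.outer(k, k) / n)
    return np.abs(dft @ padded)


@pytest.fixture(scope="module")
def gen():
    return Generator(GeneratorConfig(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def disc():
    return Discriminator(DiscriminatorConfig(), np.random.default_rng(1))


class TestGenerator:
    @pytest.mark.parametrize("length", [256, 512, 1024])
    def test_length_preserved(self, gen, length, rng):
        x = Tensor(rng.normal(0, 0.3, (2, 1, length)))
        assert gen(x).shape == (2, 1, length)

    def test_batch_independence(self, gen, rng):
        a = rng.normal(0, 0.3, (1, 1, 512))
        b = rng.normal(0, 0.3, (1, 1, 512))
        joint = gen(Tensor(np.concatenate([a, b]))).data
        sep = np.concatenate([gen(Tensor(a)).data, gen(Tensor(b)).data])
        assert np.allclose(joint, sep)

    def test_output_in_tanh_range(self, gen):
        out = gen(Tensor(np.zeros((1, 1, 256)))).data
        assert np.all(np.isfinite(out))
        assert np.all(np.abs(out) <= 1.0)

    def test_bad_length_rejected(self, gen):
        with pytest.raises(ValueError, match="multiple"):
            gen(Tensor(np.zeros((1, 1, 1000))))


class TestGatedSkip:
    def test_gate_saturation_to_identity(self, rng):
        skip = GatedSkip(4, np.random.default_rng(2))
        enc = Tensor(rng.normal(0, 1, (2, 4, 16)))
        dec = Tensor(rng.normal(0, 1, (2, 4, 16)))
        skip.proj_enc.weight.data[:] = 0
        skip.proj_dec.weight.data[:] = 0
        skip.proj_enc.bias.data[:] = 50.0  # sigmoid -> 1
        assert np.allclose(skip(enc, dec).data, enc.data)
        skip.proj_enc.bias.data[:] = -50.0  # sigmoid -> 0
        assert np.allclose(skip(enc, dec).data, 0.0)

    def test_gate_strictly_open_interval(self, rng):
        skip = GatedSkip(4, np.random.default_rng(3))
        enc = Tensor(rng.normal(0, 1, (2, 4, 16)))
        dec = Tensor(rng.normal(0, 1, (2, 4, 16)))
        g = skip.gate(enc, dec).data
        assert np.all(g > 0) and np.all(g < 1)

    def test_length_mismatch_rejected(self, rng):
        skip = GatedSkip(4, np.random.default_rng(4))
        with pytest.raises(ValueError, match="length"):
            skip(Tensor(np.zeros((1, 4, 16))), Tensor(np.zeros((1, 4, 8))))


class TestDiscriminator:
    def test_channel_order_matters(self, disc, rng):
        a = Tensor(rng.normal(0, 0.3, (1, 1, 512)))
        b = Tensor(rng.normal(0, 0.3, (1, 1, 512)))
        assert disc(a, b).item() != pytest.approx(disc(b, a).item())

    def test_per_item_scores_order_preserving(self, disc, rng):
        a = rng.normal(0, 0.3, (3, 1, 512))
        c = rng.normal(0, 0.3, (3, 1, 512))
        batch = disc(Tensor(a), Tensor(c)).data
        single = np.array(
            [disc(Tensor(a[i : i + 1]), Tensor(c[i : i + 1])).item() for i in range(3)]
        )
        assert np.allclose(batch, single)

    def test_deterministic(self, disc, rng):
        a = Tensor(rng.normal(0, 0.3, (1, 1, 512)))
        c = Tensor(rng.normal(0, 0.3, (1, 1, 512)))
        assert disc(a, c).item() == disc(a, c).item()

    def test_length_mismatch_rejected(self, disc):
        with pytest.raises(ValueError, match="identical"):
            disc(Tensor(np.zeros((1, 1, 512))), Tensor(np.zeros((1, 1, 256))))


class TestAnnotatePeaks:
    def test_recovers_known_fiducials(self):
        pulse = generate_clean_ppg(PulseModelParams(), 20.0, 100.0, seed=10)
        x, _, _ = minmax_normalize(pulse.samples)
        ann = annotate_peaks(x, 100.0)
        gt = pulse.fiducial_indices("systolic_peak")
        det = np.array(ann.systolic)
        hits = sum(1 for g in gt if det.size and np.min(np.abs(det - g)) <= 3)
        assert hits / len(gt) >= 0.9

    def test_single_lobe_gives_systolic_only(self):
        params = PulseModelParams(notch_depth=0.0, second_peak_amp=0.0)
        pulse = generate_clean_ppg(params, 20.0, 100.0, seed=11)
        ann = annotate_peaks(pulse.samples, 100.0)
        assert len(ann.systolic) > 0
        assert ann.notch == [] and ann.second == []

    def test_pure_noise_empty(self, rng):
        ann = annotate_peaks(rng.normal(0, 1, 1024), 100.0)
        assert len(ann) == 0

    def test_flat_window_empty(self):
        assert len(annotate_peaks(np.zeros(1024), 100.0)) == 0

    def test_indices_strictly_increasing(self):
        pulse = generate_clean_ppg(PulseModelParams(), 20.0, 100.0, seed=12)
        ann = annotate_peaks(pulse.samples, 100.0)
        idx = ann.indices
        assert np.all(np.diff(idx) > 0)


class TestSpectralMagnitude:
    def test_zero_signal(self):
        assert np.allclose(spectral_magnitude(np.zeros(512)), 0.0)

    def test_pure_bin_sine(self):
        k = 40
        t = np.arange(1024)
        x = np.sin(2 * np.pi * k * t / 1024)
        mag = spectral_magnitude(x)
        others = np.delete(mag, [0, k - 1, k, k + 1, 1024 - k - 1, 1024 - k, 1024 - k + 1])
        assert mag[k] >= 10 * others.max()

    def test_circular_shift_invariance(self, rng):
        x = rng.normal(0, 1, 1024)
        assert np.allclose(
            spectral_magnitude(x), spectral_magnitude(np.roll(x, 137)), atol=1e-8
        )

    def test_matches_reference_dft(self, rng):
        x = rng.normal(0, 1, 256)
        assert np.allclose(
            spectral_magnitude(x, n=256), reference_dft_magnitude(x, n=256), atol=1e-8
        )


class TestLosses:
    def test_perfect_generator_fixed_point(self, rng):
        ref = rng.normal(0, 1, (2, 128))
        w = LossWeights()
        loss = generator_loss(1.0, ref, ref, np.array([5, 20]), w, n_fft=128)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_tiny_vectors(self):
        ref = np.array([0.0, 1.0, 0.0, -1.0, 0.0, 1.0, 0.0, -1.0])
        gen = np.zeros(8)
        w = LossWeights()
        loss = generator_loss(0.0, gen, ref, np.array([1, 5]), w, n_fft=8)
        spec_term = np.mean(
            np.abs(reference_dft_magnitude(ref, 8) - reference_dft_magnitude(gen, 8))
        )
        expected = 0.5 + w.alpha * 0.5 + w.beta * spec_term + w.gamma * 1.0
        assert loss.item() == pytest.approx(expected, abs=1e-12)

    def test_linear_in_gamma(self, rng):
        ref = rng.normal(0, 1, 64)
        gen = rng.normal(0, 1, 64)
        peaks = np.array([3, 17, 40])
        base = generator_loss(0.2, gen, ref, peaks, LossWeights(gamma=0.5), n_fft=64).item()
        double = generator_loss(0.2, gen, ref, peaks, LossWeights(gamma=1.0), n_fft=64).item()
        peak_term = np.mean(np.abs(ref[peaks] - gen[peaks]))
        assert double - base == pytest.approx(0.5 * peak_term, rel=1e-9)

    def test_empty_peaks_zero_term(self, rng):
        ref = rng.normal(0, 1, 64)
        gen = rng.normal(0, 1, 64)
        a = generator_loss(0.2, gen, ref, None, LossWeights(gamma=5.0), n_fft=64).item()
        b = generator_loss(0.2, gen, ref, PeakAnnotation(), LossWeights(gamma=0.0), n_fft=64).item()
        assert a == pytest.approx(b)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-1.0)

    @pytest.mark.parametrize(
        "fake,real,expected", [(0.0, 1.0, 0.0), (1.0, 0.0, 1.0), (0.5, 0.5, 0.25)]
    )
    def test_discriminator_loss_formula(self, fake, real, expected):
        assert discriminator_loss(fake, real).item() == pytest.approx(expected)

    def test_loss_terms_nonnegative_random(self, rng):
        for _ in range(5):
            ref = rng.normal(0, 1, 64)
            gen = rng.normal(0, 1, 64)
            assert generator_loss(rng.normal(), gen, ref, None, LossWeights(), n_fft=64).item() >= 0
            assert discriminator_loss(rng.normal(), rng.normal()).item() >= 0
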
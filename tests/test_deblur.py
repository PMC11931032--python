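"""Deblurring GAN: architecture contracts, Wasserstein machinery, training."""
import numpy as np
import pytest

from catdeblur import autodiff as ad, nn
from catdeblur.autodiff import Tensor
from catdeblur.deblur import (DeblurCritic, DeblurGenerator, NetworkSpec, TrainConfig,
                              apply_deblur, build_deblur_critic, build_deblur_generator,
                              critic_loss, generator_loss_wasserstein, train_deblur,
                              wasserstein_distance_1d)
from catdeblur.exceptions import CatDeblurError, ShapeError, TrainingDivergenceError

TINY = NetworkSpec(initial_filters=4, down_filters=(6, 8), up_filters=(6, 4),
                   n_residual_blocks=2, disc_filters=(4, 6, 8, 8), critic_norm="none")


class TestGeneratorArchitecture:
    def test_default_build_has_nine_residual_blocks(self):
        gen = build_deblur_generator(NetworkSpec(), seed=0)
        assert gen.n_residual_blocks == 9

    def test_shape_preserved_and_tanh_bounded(self, rng):
        gen = DeblurGenerator(TINY, rng)
        x = Tensor(rng.uniform(-1, 1, size=(2, 1, 16, 16)).astype(np.float32))
        out = gen(x)
        assert out.shape == (2, 1, 16, 16)
        assert np.max(np.abs(out.data)) <= 1.0

    def test_indivisible_size_rejected(self, rng):
        gen = DeblurGenerator(TINY, rng)
        with pytest.raises(ShapeError):
            gen(Tensor(np.zeros((1, 1, 18, 18), dtype=np.float32)))

    def test_near_identity_at_initialization(self, rng):
        gen = DeblurGenerator(TINY, rng)
        x = rng.uniform(20, 230, size=(16, 16))
        out = apply_deblur(gen, x)
        assert np.mean(np.abs(out - x)) < 10.0


class TestCriticArchitecture:
    def test_leaky_slope_matches_spec(self):
        critic = build_deblur_critic(NetworkSpec(), input_size=64, seed=0)
        slopes = [l.slope for l in critic.features.layers if isinstance(l, nn.LeakyReLU)]
        assert slopes == [0.2] * 4
        # activation itself: f(x)/x = 0.2 for negative inputs
        assert ad.leaky_relu(Tensor(np.array([-3.0])), 0.2).data[0] == pytest.approx(-0.6)

    def test_one_scalar_score_per_image(self, rng):
        critic = DeblurCritic(TINY, input_size=16, rng=rng)
        scores = critic(Tensor(rng.normal(size=(5, 1, 16, 16)).astype(np.float32)))
        assert scores.shape == (5, 1)

    def test_sensitive_to_input_at_init(self, rng):
        critic = DeblurCritic(TINY, input_size=16, rng=rng)
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        a = critic(Tensor(x)).data
        b = critic(Tensor(x + 0.1)).data
        assert not np.allclose(a, b)


class TestWasserstein1D:
    def test_identity_and_translation(self, rng):
        s = rng.normal(size=20)
        assert wasserstein_distance_1d(s, s) == pytest.approx(0.0)
        assert wasserstein_distance_1d([0.0], [3.5]) == pytest.approx(3.5)

    def test_two_point_optimal_coupling(self):
        # brute force over both couplings of {0,1} vs {2,5}:
        # min( (|0-2|+|1-5|)/2, (|0-5|+|1-2|)/2 ) = 3.0
        assert wasserstein_distance_1d([0, 1], [2, 5]) == pytest.approx(3.0)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(25):
            a, b, c = (rng.normal(size=rng.integers(2, 8)) for _ in range(3))
            dab = wasserstein_distance_1d(a, b)
            assert dab == pytest.approx(wasserstein_distance_1d(b, a))
            assert dab >= 0
            assert dab <= (wasserstein_distance_1d(a, c)
                           + wasserstein_distance_1d(c, b) + 1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(CatDeblurError):
            wasserstein_distance_1d([], [1.0])


class _ConstantCritic(nn.Module):
    def __init__(self, c):
        super().__init__()
        self.c = c

    def forward(self, x):
        return Tensor(np.full((x.shape[0], 1), self.c))


class _UnitNormLinearCritic(nn.Module):
    def __init__(self, shape, rng):
        super().__init__()
        w = rng.normal(size=shape)
        self.w = Tensor(w / np.linalg.norm(w), requires_grad=True)

    def forward(self, x):
        return ad.tsum(ad.mul(x, ad.reshape(self.w, (1,) + self.w.shape)),
                       axis=tuple(range(1, x.ndim)))


class TestCriticLoss:
    def test_constant_critic_loss_equals_gp_weight(self, rng):
        real = rng.normal(size=(4, 1, 8, 8))
        fake = rng.normal(size=(4, 1, 8, 8))
        for lam in (1.0, 10.0):
            loss, parts = critic_loss(_ConstantCritic(2.5), real, fake, lam, rng)
            # zero gradient -> penalty (0-1)^2 = 1; score terms cancel
            assert loss.item() == pytest.approx(lam, abs=1e-4)
            assert parts["gradient_penalty"] == pytest.approx(1.0, abs=1e-4)

    def test_unit_norm_linear_critic_has_zero_penalty(self, rng):
        critic = _UnitNormLinearCritic((1, 8, 8), rng)
        real = rng.normal(size=(4, 1, 8, 8))
        fake = rng.normal(size=(4, 1, 8, 8))
        _, parts = critic_loss(critic, real, fake, 10.0, rng)
        assert parts["gradient_penalty"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_when_scores_equal_and_no_penalty(self, rng):
        real = rng.normal(size=(3, 1, 8, 8))
        loss, _ = critic_loss(_ConstantCritic(1.0), real, real.copy(), 0.0, rng)
        assert loss.item() == pytest.approx(0.0, abs=1e-12)

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ShapeError):
            critic_loss(_ConstantCritic(0.0), np.zeros((2, 1, 8, 8)),
                        np.zeros((2, 1, 4, 4)), 1.0, rng)


class TestGeneratorLoss:
    def test_constant_critic_values(self, rng):
        fake = rng.normal(size=(3, 1, 8, 8))
        assert generator_loss_wasserstein(_ConstantCritic(0.0), fake).item() == 0.0
        assert generator_loss_wasserstein(_ConstantCritic(2.0), fake).item() == pytest.approx(-2.0)

    def test_shift_in_scores_shifts_loss(self, rng):
        fake = rng.normal(size=(3, 1, 8, 8))
        base = generator_loss_wasserstein(_ConstantCritic(1.0), fake).item()
        shifted = generator_loss_wasserstein(_ConstantCritic(1.0 + 0.7), fake).item()
        assert shifted - base == pytest.approx(-0.7)


def _tiny_pairs(rng, n=8, size=16):
    xs = rng.uniform(0, 255, size=(n, size, size))
    return [(x, np.clip(x * 1.05, 0, 255)) for x in xs]


class TestTraining:
    def test_seeded_rerun_is_bit_identical(self, rng):
        pairs = _tiny_pairs(rng)
        cfg = TrainConfig(critic_steps_per_gen=1, batch_size=4, epochs=5, seed=7)
        _, h1 = train_deblur(pairs, TINY, cfg)
        _, h2 = train_deblur(pairs, TINY, cfg)
        assert h1 == h2

    def test_history_length_is_epochs_times_steps(self, rng):
        pairs = _tiny_pairs(rng)
        cfg = TrainConfig(critic_steps_per_gen=1, batch_size=4, epochs=5, seed=7)
        _, hist = train_deblur(pairs, TINY, cfg)
        assert len(hist) == 5 * (8 // 4)
        assert all(np.isfinite(h["critic_loss"]) and np.isfinite(h["gen_loss"])
                   for h in hist)

    def test_empty_corpus_rejected(self):
        with pytest.raises(CatDeblurError):
            train_deblur([], TINY, TrainConfig())

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_learning_rate_raises(self, rng):
        pairs = _tiny_pairs(rng)
        cfg = TrainConfig(lr_generator=1e6, lr_discriminator=1e6,
                          critic_steps_per_gen=1, batch_size=4, epochs=40, seed=0)
        with pytest.raises(TrainingDivergenceError):
            train_deblur(pairs, TINY, cfg)


class TestApplyDeblur:
    def test_shape_range_and_determinism(self, rng):
        gen = DeblurGenerator(TINY, rng)
        sketch = rng.uniform(0, 255, size=(16, 16))
        a = apply_deblur(gen, sketch)
        b = apply_deblur(gen, sketch)
        assert a.shape == sketch.shape
        assert np.array_equal(a, b)
        assert a.min() >= 0 and a.max() <= 255

    def test_indivisible_input_rejected(self, rng):
        gen = DeblurGenerator(TINY, rng)
        with pytest.raises(ShapeError):
            apply_deblur(gen, np.zeros((18, 18)))


class TestScaledDownRun:
    """Properties of the shared smoke-scale training run (session fixture)."""

    def test_deblurred_sketches_beat_blurred_inputs(self, deblur_smoke):
        assert deblur_smoke["ssim_output"] > deblur_smoke["ssim_input"]

    def test_critic_separates_real_from_fake(self, deblur_smoke):
        # the recorded critic terms estimate E D(real) - E D(fake); a
        # positive late-training average means the critic still tells
        # target sketches from generated ones
        hist = deblur_smoke["history"][-50:]
        gaps = [-h["real_term"] - h["fake_term"] for h in hist]
        assert np.mean(gaps) > 0.0

    def test_loss_history_complete_and_finite(self, deblur_smoke):
        hist = deblur_smoke["history"]
        assert len(hist) >= 200
        assert all(np.isfinite(h["critic_loss"]) for h in hist)
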
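"""Loss operations and the two-stage training procedure."""

import numpy as np
import pytest

from spectraits import (
    DomainShiftConfig,
    TrainConfig,
    adapt,
    composite_loss,
    contrastive_attention,
    domain_adaptation_loss,
    make_domain_pair,
    mse_loss,
    pretrain,
)
from spectraits.adapt import DomainDiscriminator
from spectraits.models import EncoderConfig
from spectraits.synth import ParamRanges

RNG = np.random.default_rng(0)

ENC = EncoderConfig("small", seed=0)


def fast_cfg(**kw):
    base = dict(stage1_epochs=2, stage1_batch=16, stage2_epochs=2,
                stage2_batch=16, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestMseLoss:
    def test_perfect_prediction_zero(self):
        y = RNG.random((5, 3))
        total, per = mse_loss(y, y)
        assert total == 0
        np.testing.assert_array_equal(per, 0)

    def test_hand_arithmetic(self):
        total, per = mse_loss(np.array([[2.0]]), np.array([[5.0]]))
        assert total == 9 and per[0] == 9

    def test_total_sums_traits(self):
        y = np.zeros((1, 3))
        yhat = np.array([[1.0, np.sqrt(2), np.sqrt(3)]])
        total, per = mse_loss(y, yhat)
        np.testing.assert_allclose(per, [1, 2, 3], atol=1e-12)
        assert total == pytest.approx(6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 3)), np.zeros((3, 3)))


class TestContrastiveAttention:
    def test_identical_batches_full_weight(self):
        F = RNG.random((4, 6)) + 0.1
        wFs, wFt, ws, wt = contrastive_attention(F, F)
        np.testing.assert_allclose(ws, 1, atol=1e-12)
        np.testing.assert_allclose(wFs, F, atol=1e-12)
        np.testing.assert_allclose(wFt, F, atol=1e-12)

    def test_orthogonal_domains_zero_weight(self):
        Fs = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        Ft = np.array([[0, 0, 1.0]])
        wFs, wFt, ws, wt = contrastive_attention(Fs, Ft)
        np.testing.assert_array_equal(ws, 0)
        np.testing.assert_array_equal(wt, 0)
        np.testing.assert_array_equal(wFs, 0)

    def test_scale_invariant_weights(self):
        Fs = RNG.normal(size=(3, 5))
        Ft = RNG.normal(size=(4, 5))
        _, _, ws, _ = contrastive_attention(Fs, Ft)
        Fs2 = Fs.copy()
        Fs2[1] *= 37.0
        _, _, ws2, _ = contrastive_attention(Fs2, Ft)
        np.testing.assert_allclose(ws, ws2, atol=1e-12)

    def test_zero_norm_row_weight_zero(self):
        Fs = np.vstack([np.zeros(4), np.ones(4)])
        Ft = np.ones((2, 4))
        _, _, ws, _ = contrastive_attention(Fs, Ft)
        assert ws[0] == 0 and ws[1] == pytest.approx(1)

    def test_weights_in_unit_interval(self):
        Fs = RNG.normal(size=(10, 8))
        Ft = RNG.normal(size=(7, 8))
        _, _, ws, wt = contrastive_attention(Fs, Ft)
        assert np.all((ws >= 0) & (ws <= 1))
        assert np.all((wt >= 0) & (wt <= 1))


class TestDomainAdaptationLoss:
    def test_maximally_confused_discriminator_ln2(self):
        disc = DomainDiscriminator(4, seed=0)
        for p in disc.params():
            p.data[...] = 0.0  # logits 0 -> probability 0.5 everywhere
        wFs = RNG.random((5, 4))
        wFt = RNG.random((3, 4))
        loss = domain_adaptation_loss(wFs, wFt, "discriminator", disc)
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_cosine_identical_prototypes_zero(self):
        F = RNG.random((4, 6))
        assert domain_adaptation_loss(F, F, "cosine") == pytest.approx(0, abs=1e-12)

    def test_cosine_opposite_prototypes_two(self):
        F = RNG.random((4, 6)) + 0.5
        assert domain_adaptation_loss(F, -F, "cosine") == pytest.approx(2, abs=1e-12)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            domain_adaptation_loss(np.ones((1, 2)), np.ones((1, 2)), "foo")


class TestCompositeLoss:
    def test_arithmetic(self):
        assert composite_loss(2, 4, 0.5, 0.5) == 3
        assert composite_loss(7, 100, 1.0, 0.0) == 7

    def test_linear_in_each_term(self):
        l1 = composite_loss(1, 1, 0.7, 0.3)
        l2 = composite_loss(2, 1, 0.7, 0.3)
        l3 = composite_loss(1, 2, 0.7, 0.3)
        assert l2 - l1 == pytest.approx(0.7)
        assert l3 - l1 == pytest.approx(0.3)

    def test_defaults_are_one_and_point_three(self):
        cfg = TrainConfig()
        assert cfg.lambda1 == 1.0 and cfg.lambda2 == 0.3
        assert cfg.lambda_grl == 0.3

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(1, 1, -0.1, 0.3)


class TestPretrain:
    def test_zero_epochs_leaves_parameters_at_init(self, tiny_corpus):
        model, history = pretrain(tiny_corpus, fast_cfg(stage1_epochs=0),
                                  encoder_cfg=ENC)
        from spectraits.models import TraitNet
        fresh = TraitNet(ENC)
        for pa, pb in zip(model.net.params(), fresh.params()):
            np.testing.assert_array_equal(pa.data, pb.data)
        assert history["train_loss"] == []

    def test_loss_decreases_on_small_corpus(self, tiny_corpus):
        model, history = pretrain(tiny_corpus, fast_cfg(stage1_epochs=5),
                                  encoder_cfg=ENC)
        assert history["train_loss"][-1] < history["train_loss"][0]

    def test_deterministic_given_seed(self, tiny_corpus):
        _, h1 = pretrain(tiny_corpus, fast_cfg(stage1_epochs=3), encoder_cfg=ENC)
        _, h2 = pretrain(tiny_corpus, fast_cfg(stage1_epochs=3), encoder_cfg=ENC)
        assert h1 == h2

    def test_empty_or_unlabeled_corpus_rejected(self, tiny_corpus):
        empty = tiny_corpus.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            pretrain(empty, fast_cfg())
        unlabeled = tiny_corpus.subset(np.arange(10))
        unlabeled.traits = np.full_like(unlabeled.traits, np.nan)
        with pytest.raises(ValueError):
            pretrain(unlabeled, fast_cfg())


@pytest.fixture(scope="module")
def domain_pair(small_constants):
    cfg = DomainShiftConfig(
        target_ranges=ParamRanges().shifted(Cab=15.0),
        gain_low=0.95, gain_high=1.05, noise_sd=0.01,
        n_source=40, n_target=40, fewshot_fraction=0.2, seed=6,
    )
    return make_domain_pair(cfg, small_constants)


class TestAdapt:
    def test_histories_record_both_losses(self, domain_pair):
        source, target = domain_pair
        model, history = adapt(None, source, target, fast_cfg(), encoder_cfg=ENC)
        assert len(history["mse_loss"]) == 2
        assert len(history["da_loss"]) == 2
        assert all(l >= 0 for l in history["da_loss"])

    def test_lambda2_zero_never_evaluates_da(self, domain_pair, monkeypatch):
        import sys
        mod = sys.modules["spectraits.adapt"]
        calls = []
        orig = mod.contrastive_attention
        monkeypatch.setattr(mod, "contrastive_attention",
                            lambda *a: calls.append(1) or orig(*a))
        source, target = domain_pair
        _, history = adapt(None, source, target, fast_cfg(lambda2=0.0),
                           encoder_cfg=ENC)
        assert calls == []
        assert all(l == 0 for l in history["da_loss"])

    def test_cosine_mode_runs(self, domain_pair):
        source, target = domain_pair
        _, history = adapt(None, source, target,
                           fast_cfg(da_mode="cosine"), encoder_cfg=ENC)
        assert all(0 <= l <= 2 for l in history["da_loss"])

    def test_deterministic_given_seed(self, domain_pair):
        source, target = domain_pair
        _, h1 = adapt(None, source, target, fast_cfg(), encoder_cfg=ENC)
        _, h2 = adapt(None, source, target, fast_cfg(), encoder_cfg=ENC)
        assert h1 == h2

    def test_missing_domain_rejected(self, domain_pair):
        source, target = domain_pair
        empty = source.subset(np.array([], dtype=int))
        with pytest.raises(ValueError, match="target"):
            adapt(None, source, empty, fast_cfg())
        with pytest.raises(ValueError, match="both domains"):
            adapt(None, empty, target, fast_cfg())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lambda2=-0.5)
        with pytest.raises(ValueError):
            TrainConfig(stage2_batch=0)
        with pytest.raises(ValueError):
            TrainConfig(da_mode="entropy")
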
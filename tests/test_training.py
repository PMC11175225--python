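"""Training loop contracts: schedule, alternation, determinism, checkpoints."""

import warnings

import numpy as np
import pytest

from rdagan.adversaries import FeatureExtractorSpec
from rdagan.data import synthesize_paired_samples
from rdagan.errors import ConfigurationError, InvalidStateError
from rdagan.generator import GeneratorSpec
from rdagan.image import RasterImage
from rdagan.losses import (adversarial_generator_loss, generator_total_loss,
                           perceptual_loss)
from rdagan.training import (LOG_COLUMNS, TrainConfig, Trainer,
                             clip_grad_norm, fit, infer, load_generator,
                             lr_schedule, read_checkpoint, stack_samples)


def micro_config(seed=0, **overrides):
    gen = GeneratorSpec(num_blocks=1, convs_per_block=2, growth_rate=8,
                        base_channels=16, cbam_reduction=4,
                        head_kernel_size=3, second_shallow_conv=False)
    ext = FeatureExtractorSpec(layer_tag="conv1_2", seed=seed)
    base = dict(epochs=2, steps_per_epoch=2, batch_size=2, hr_crop=32,
                lr=1e-3, seed=seed, disc_base_width=8, generator=gen,
                extractor=ext, feature_weight=0.0)
    base.update(overrides)
    return TrainConfig(**base)


def micro_dataset(seed=0, n=4):
    return synthesize_paired_samples(n, seed=seed, canvas_side=32,
                                     cell_count=6, cell_radius=(2, 5))


def snapshot(module):
    return {k: v.copy() for k, v in module.state_dict().items()}


def assert_state_equal(module, before):
    for k, v in module.state_dict().items():
        np.testing.assert_array_equal(v, before[k], err_msg=k)


# ---------------------------------------------------------------------------
# schedule and config
# ---------------------------------------------------------------------------

def test_learning_rate_schedule_single_halving():
    cfg = TrainConfig()
    assert lr_schedule(1, cfg) == 2e-4
    assert lr_schedule(200, cfg) == 2e-4
    assert lr_schedule(201, cfg) == 1e-4
    assert lr_schedule(1000, cfg) == 1e-4   # no further decay


def test_repeated_decay_flag():
    cfg = TrainConfig(lr_decay_every=200)
    assert lr_schedule(401, cfg) == 5e-5


def test_schedule_rejects_epoch_zero():
    with pytest.raises(ValueError):
        lr_schedule(0, TrainConfig())


def test_config_defaults_follow_the_recipe():
    cfg = TrainConfig()
    assert cfg.lam == 1e-3
    assert (cfg.beta1, cfg.beta2) == (0.9, 0.999)
    assert cfg.hr_crop == 192 and cfg.scale == 2


def test_config_yaml_round_trip(tmp_path):
    cfg = micro_config(seed=3, lam=0.5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    assert TrainConfig.from_yaml(path) == cfg
    assert TrainConfig.from_yaml(path).config_hash() == cfg.config_hash()


def test_config_hash_tracks_content():
    assert micro_config().config_hash() != \
        micro_config(lam=0.123).config_hash()


def test_invalid_configs_are_rejected():
    with pytest.raises(ConfigurationError):
        micro_config(hr_crop=33)            # not divisible by scale
    with pytest.raises(ConfigurationError):
        micro_config(lr=0.0)
    with pytest.raises(ConfigurationError):
        micro_config(scale=4)               # disagrees with generator spec


def test_grad_clip_caps_the_global_norm():
    from rdagan.nn.tensor import Tensor
    p = Tensor(np.zeros(3), requires_grad=True)
    p.grad = np.array([3.0, 4.0, 0.0])
    total = clip_grad_norm([p], 1.0)
    assert abs(total - 5.0) < 1e-6
    assert abs(np.linalg.norm(p.grad) - 1.0) < 1e-6


# ---------------------------------------------------------------------------
# alternation and freeze contracts
# ---------------------------------------------------------------------------

def test_generator_phase_leaves_discriminators_bitwise_unchanged():
    trainer = Trainer(micro_config(), micro_dataset())
    hr, lr = stack_samples(trainer.sample_batch())
    di_before = snapshot(trainer.disc_image)
    df_before = snapshot(trainer.disc_feature)
    ext_before = snapshot(trainer.extractor)
    gen_before = snapshot(trainer.generator)

    sr = trainer.generator(lr)
    trainer.opt_g.zero_grad()
    cp = perceptual_loss(sr, hr, trainer.extractor, 1.0, 0.0)
    trainer.disc_image.eval()
    cai = adversarial_generator_loss(trainer.disc_image(sr))
    trainer.disc_feature.eval()
    caf = adversarial_generator_loss(
        trainer.disc_feature(trainer.extractor(sr)))
    generator_total_loss(cp, cai, caf, 1e-3).backward()
    trainer.opt_g.step()

    assert_state_equal(trainer.disc_image, di_before)
    assert_state_equal(trainer.disc_feature, df_before)
    assert_state_equal(trainer.extractor, ext_before)
    assert any(not np.array_equal(v, gen_before[k])
               for k, v in trainer.generator.state_dict().items())


def test_discriminator_phase_leaves_generator_bitwise_unchanged():
    from rdagan.losses import discriminator_loss
    trainer = Trainer(micro_config(), micro_dataset())
    hr, lr = stack_samples(trainer.sample_batch())
    gen_before = snapshot(trainer.generator)
    sr_detached = trainer.generator(lr).detach()
    trainer.opt_di.zero_grad()
    loss = discriminator_loss(trainer.disc_image(hr),
                              trainer.disc_image(sr_detached))
    loss.backward()
    trainer.opt_di.step()
    assert_state_equal(trainer.generator, gen_before)


def test_full_steps_never_touch_the_extractor():
    trainer = Trainer(micro_config(), micro_dataset())
    before = snapshot(trainer.extractor)
    for _ in range(3):
        trainer.train_step(trainer.sample_batch())
    assert_state_equal(trainer.extractor, before)


def test_seeded_runs_reproduce_loss_traces_bitwise():
    traces = []
    for _ in range(2):
        trainer = Trainer(micro_config(seed=9), micro_dataset(seed=9))
        rows = [trainer.train_step(trainer.sample_batch()) for _ in range(10)]
        traces.append([(b.cp, b.cai, b.caf, b.cdi, b.cdf, b.cg)
                       for b in rows])
    assert traces[0] == traces[1]


def test_lambda_zero_update_equals_pure_perceptual_step():
    ds = micro_dataset(seed=5)
    t1 = Trainer(micro_config(seed=5, lam=0.0), ds)
    t2 = Trainer(micro_config(seed=5, lam=0.0), ds)
    batch = t1.sample_batch()
    t1.train_step(batch)

    hr, lr = stack_samples(batch)
    sr = t2.generator(lr)
    t2.opt_g.zero_grad()
    perceptual_loss(sr, hr, t2.extractor, 1.0, 0.0).backward()
    t2.opt_g.step()

    for (k1, v1), (_, v2) in zip(sorted(t1.generator.state_dict().items()),
                                 sorted(t2.generator.state_dict().items())):
        np.testing.assert_array_equal(v1, v2, err_msg=k1)


def test_disabled_feature_discriminator_skips_its_phase():
    cfg = micro_config(feature_discriminator=False)
    trainer = Trainer(cfg, micro_dataset())
    assert trainer.disc_feature is None
    losses = trainer.train_step(trainer.sample_batch())
    assert losses.caf == 0.0 and losses.cdf == 0.0
    assert losses.cg == pytest.approx(losses.cp + cfg.lam * losses.cai)


# ---------------------------------------------------------------------------
# fit, checkpoints, inference
# ---------------------------------------------------------------------------

def test_fit_writes_checkpoints_and_loss_log(tmp_path):
    cfg = micro_config(checkpoint_every=1)
    final = fit(cfg, tmp_path, dataset=micro_dataset())
    assert final.exists()
    assert (tmp_path / "epoch0001.npz").exists()
    log = (tmp_path / "losses.csv").read_text().strip().splitlines()
    assert log[0].split(",") == LOG_COLUMNS
    assert len(log) == 1 + 2 * 2   # header + epochs × steps


def test_zero_epoch_fit_emits_initial_checkpoint_and_empty_log(tmp_path):
    cfg = micro_config(epochs=0)
    final = fit(cfg, tmp_path, dataset=micro_dataset())
    header, _ = read_checkpoint(final)
    assert header["epoch"] == 0 and header["global_step"] == 0
    log = (tmp_path / "losses.csv").read_text().strip().splitlines()
    assert len(log) == 1   # header only


def test_checkpoint_resume_reproduces_the_uninterrupted_trace(tmp_path):
    ds = micro_dataset(seed=7)
    full = Trainer(micro_config(seed=7), ds)
    interrupted = Trainer(micro_config(seed=7), ds)
    for _ in range(3):
        full.train_step(full.sample_batch())
        interrupted.train_step(interrupted.sample_batch())
    ckpt = interrupted.save_checkpoint(tmp_path / "mid.npz")

    reference = full.train_step(full.sample_batch())
    resumed = Trainer.from_checkpoint(ckpt, ds)
    continued = resumed.train_step(resumed.sample_batch())

    assert (reference.cp, reference.cdi, reference.cg) == \
        (continued.cp, continued.cdi, continued.cg)
    for (k, v1), (_, v2) in zip(sorted(full.generator.state_dict().items()),
                                sorted(resumed.generator.state_dict().items())):
        np.testing.assert_array_equal(v1, v2, err_msg=k)


def test_unrecognized_checkpoint_schema_is_a_versioned_error(tmp_path):
    import json
    path = tmp_path / "bad.npz"
    header = np.frombuffer(json.dumps({"schema": "other-v9"}).encode(),
                           dtype=np.uint8)
    np.savez(path, __header__=header)
    with pytest.raises(InvalidStateError, match="rdagan-checkpoint-v1"):
        read_checkpoint(path)


def test_infer_round_trip(tmp_path):
    ckpt = Trainer(micro_config(), micro_dataset()).save_checkpoint(
        tmp_path / "g.npz")
    in_dir = tmp_path / "in"
    in_dir.mkdir()
    rng = np.random.default_rng(0)
    RasterImage(rng.random((24, 24, 3), dtype=np.float32)).to_file(
        in_dir / "a.png")
    out1 = tmp_path / "out1"
    written = infer(ckpt, in_dir, out1)
    assert [p.name for p in written] == ["a_sr.png"]
    sr = RasterImage.from_file(out1 / "a_sr.png")
    assert sr.shape == (48, 48, 3)
    assert "checkpoint_hash" in (out1 / "manifest.csv").read_text()
    out2 = tmp_path / "out2"
    infer(ckpt, in_dir, out2)
    assert (out1 / "a_sr.png").read_bytes() == (out2 / "a_sr.png").read_bytes()


def test_infer_on_empty_directory_warns(tmp_path):
    ckpt = Trainer(micro_config(), micro_dataset()).save_checkpoint(
        tmp_path / "g.npz")
    empty = tmp_path / "empty"
    empty.mkdir()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        written = infer(ckpt, empty, tmp_path / "out")
    assert written == []
    assert any("no images" in str(w.message) for w in caught)


def test_loaded_generator_matches_the_saved_one(tmp_path):
    trainer = Trainer(micro_config(), micro_dataset())
    trainer.train_step(trainer.sample_batch())
    ckpt = trainer.save_checkpoint(tmp_path / "g.npz")
    gen = load_generator(ckpt)
    x = np.random.default_rng(0).random((1, 3, 16, 16), dtype=np.float32)
    from rdagan.nn.tensor import Tensor
    trainer.generator.eval()
    np.testing.assert_array_equal(gen(Tensor(x)).data,
                                  trainer.generator(Tensor(x)).data)
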
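import json

import numpy as np
import pytest

from gfssnet.network import (NetConfig, TrainConfig, build_model,
                             ds_alpha_at, learning_rate_at, load_checkpoint,
                             predict, save_checkpoint, train)
from gfssnet.phantom_io import (LabelScheme, LabelVolume, PhantomConfig,
                                VolumePair, generate_phantom, to_three_class)
from gfssnet.see_encoder import EncoderConfig

TINY = NetConfig(
    encoder=EncoderConfig(stage_channels=(4, 6, 8, 12),
                          d_state=(2, 2, 2, 2), d_conv=(1, 1, 1, 1),
                          n_kernels=2, attention_reduction=2),
    graph_h_dim=8, seed=0)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY)


def _input(shape=(16, 16, 16), channels=2, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(1, channels) + shape).astype(np.float32)


class TestBuildModel:
    def test_forward_contract(self, tiny_model):
        out = tiny_model(_input())
        assert out.shape == (1, 3, 16, 16, 16)
        np.testing.assert_allclose(out.numpy().sum(axis=1), 1.0, atol=1e-5)

    def test_indivisible_shape_named_error(self, tiny_model):
        with pytest.raises(ValueError, match="divisible by 16"):
            tiny_model(_input(shape=(16, 24, 16)))

    def test_single_modality_variant(self):
        cfg = NetConfig(encoder=TINY.encoder, graph_h_dim=8, modality="t1")
        model = build_model(cfg)
        out = model(_input(channels=1))
        assert out.shape == (1, 3, 16, 16, 16)
        with pytest.raises(ValueError):
            model(_input(channels=2))

    def test_parameter_count_deterministic(self):
        m1 = build_model(TINY)
        m2 = build_model(TINY)
        assert m1.n_parameters() == m2.n_parameters()
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(),
                                      m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_deep_supervision_heads(self, tiny_model):
        probs, aux = tiny_model(_input(), return_aux=True)
        assert len(aux) == 2
        for a, s in zip(aux, tiny_model.cfg.ds_stages):
            np.testing.assert_allclose(a.numpy().sum(axis=1), 1.0, atol=1e-5)
            assert a.shape[1] == 3

    def test_full_gradient_flow(self):
        model = build_model(TINY)
        from gfssnet.network import _case_loss
        labels = np.random.default_rng(1).integers(
            0, 3, size=(1, 16, 16, 16))
        loss = _case_loss(model, _input(), labels, TrainConfig(), 0.4)
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert not missing, missing


class TestSchedules:
    def test_learning_rate_closed_form(self):
        assert learning_rate_at(0) == pytest.approx(1e-3)
        assert learning_rate_at(29) == pytest.approx(1e-3)
        assert learning_rate_at(30) == pytest.approx(8e-4)
        assert learning_rate_at(60) == pytest.approx(6.4e-4)

    def test_ds_alpha_closed_form(self):
        assert ds_alpha_at(0) == pytest.approx(0.4)
        assert ds_alpha_at(30) == pytest.approx(0.32)
        assert ds_alpha_at(60) == pytest.approx(0.256)

    def test_logged_schedules_match(self, tmp_path):
        pair, mask10 = generate_phantom(
            PhantomConfig(shape=(16, 16, 16), n_vertebrae=2, seed=2))
        mask = to_three_class(mask10)
        model = build_model(TINY)
        log = tmp_path / "log.jsonl"
        train(model, [(pair, mask)], TrainConfig(max_epochs=3, seed=0),
              log_path=log)
        records = [json.loads(l) for l in log.read_text().splitlines()]
        assert len(records) == 3
        for rec in records:
            assert rec["lr"] == pytest.approx(
                learning_rate_at(rec["epoch"]))
            assert rec["alpha_ds"] == pytest.approx(
                ds_alpha_at(rec["epoch"]))


class TestTraining:
    def _phantom_case(self):
        pair, mask10 = generate_phantom(
            PhantomConfig(shape=(16, 16, 16), n_vertebrae=2, seed=3))
        return pair, to_three_class(mask10)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_model(TINY), [], TrainConfig())

    def test_seeded_first_epoch_reproducible(self):
        case = self._phantom_case()
        losses = []
        for _ in range(2):
            model = build_model(TINY)
            res = train(model, [case], TrainConfig(max_epochs=1, seed=5))
            losses.append(res["history"][0]["loss"])
        assert losses[0] == pytest.approx(losses[1], rel=1e-6)

    def test_loss_decreases(self):
        case = self._phantom_case()
        model = build_model(TINY)
        res = train(model, [case],
                    TrainConfig(max_epochs=8, seed=0, learning_rate=2e-3))
        hist = [r["loss"] for r in res["history"]]
        assert hist[-1] < hist[0]

    def test_early_stopping_counts(self):
        case = self._phantom_case()
        model = build_model(TINY)
        cfg = TrainConfig(max_epochs=30, patience=2, learning_rate=0.0)
        res = train(model, [case], cfg, val_dataset=[case])
        # zero LR -> no improvement after epoch 0 -> stop at patience
        assert len(res["history"]) <= 4


class TestPredictEvaluate:
    def test_predict_shapes_and_scheme(self, tiny_model):
        pair, mask10 = generate_phantom(
            PhantomConfig(shape=(16, 16, 16), n_vertebrae=2, seed=4))
        pred = predict(tiny_model, pair)
        assert pred.scheme is LabelScheme.THREE_CLASS
        assert pred.shape == pair.shape
        assert set(np.unique(pred.labels)) <= {0, 1, 2}

    def test_evaluate_gt_vs_gt(self):
        from gfssnet.network import evaluate_cases
        labels = np.random.default_rng(5).integers(0, 3, size=(8, 8, 8))
        gt = LabelVolume(labels, scheme=LabelScheme.THREE_CLASS)
        rows = evaluate_cases([("case0", gt, gt)])
        assert len(rows) == 3  # case + mean + std
        assert rows[0]["dsc_vertebra"] == 1.0
        assert rows[0]["hd95_disc"] == 0.0

    def test_checkpoint_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path)
        loaded = load_checkpoint(path)
        x = _input(seed=9)
        np.testing.assert_allclose(loaded(x).numpy(),
                                   tiny_model(x).numpy(), atol=1e-6)


class TestCLI:
    def test_generate_phantom_command(self, tmp_path):
        from click.testing import CliRunner
        from gfssnet.cli import main
        out_dir = tmp_path / "case0"
        res = CliRunner().invoke(main, [
            "generate-phantom", "--shape", "12,40,24", "--seed", "3",
            "--three-class", "--out-dir", str(out_dir)])
        assert res.exit_code == 0, res.output
        for name in ("t1.nii.gz", "t2.nii.gz", "mask.nii.gz"):
            assert (out_dir / name).exists()

    def test_train_and_predict_commands(self, tmp_path):
        from click.testing import CliRunner
        from gfssnet.cli import main
        runner = CliRunner()
        case_dir = tmp_path / "data" / "case0"
        res = runner.invoke(main, [
            "generate-phantom", "--shape", "16,16,16", "--seed", "1",
            "--n-vertebrae", "2", "--three-class",
            "--out-dir", str(case_dir)])
        assert res.exit_code == 0, res.output
        ckpt = tmp_path / "model.npz"
        res = runner.invoke(main, [
            "train", "--data-dir", str(tmp_path / "data"), "--test-profile",
            "--epochs", "1", "--seed", "0", "--out", str(ckpt)])
        assert res.exit_code == 0, res.output
        assert ckpt.exists()
        pred_path = tmp_path / "pred.nii.gz"
        res = runner.invoke(main, [
            "predict", "--checkpoint", str(ckpt),
            "--t1", str(case_dir / "t1.nii.gz"),
            "--t2", str(case_dir / "t2.nii.gz"), "--out", str(pred_path)])
        assert res.exit_code == 0, res.output
        assert pred_path.exists()

    def test_evaluate_command(self, tmp_path):
        from click.testing import CliRunner
        from gfssnet.cli import main
        from gfssnet.phantom_io import write_volume
        labels = np.random.default_rng(6).integers(
            0, 3, size=(8, 8, 8)).astype(np.int64)
        (tmp_path / "gt").mkdir()
        (tmp_path / "pred").mkdir()
        write_volume(labels, tmp_path / "gt" / "c.nii.gz")
        write_volume(labels, tmp_path / "pred" / "c.nii.gz")
        out_csv = tmp_path / "metrics.csv"
        res = CliRunner().invoke(main, [
            "evaluate", "--pred-dir", str(tmp_path / "pred"),
            "--gt-dir", str(tmp_path / "gt"), "--out", str(out_csv)])
        assert res.exit_code == 0, res.output
        lines = out_csv.read_text().splitlines()
        assert len(lines) == 4  # header + case + mean + std
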
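"""Full segmentation network and training/inference entry points.

Pipeline: one spatial-enhancement encoder per modality, position-aware
attention fusion of the two bottlenecks, anatomical-graph enhancement,
four depth-aware progressive upsampling stages against the fused skips,
and a pointwise softmax head.  Training follows the published protocol:
Adam at 1e-3 with the rate scaled by 0.8 every 30 epochs, a deep
supervision coefficient starting at 0.4 on the same decay, the hybrid
Tversky objective, and early stopping on the mean validation Dice of
vertebra and disc.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dapu_decoder import DAPUConfig, DAPUStage
from .losses import LossConfig, hfd_tversky_loss, one_hot, tversky_loss
from .metrics import dsc
from .nn import (Adam, Conv3d, Module, Tensor, as_tensor, concatenate,
                 no_grad)
from .paaf import PAAF, PAAFConfig, EnhancedPositionAttention
from .phantom_io import LabelScheme, LabelVolume, VolumePair
from .see_encoder import EncoderConfig, SEEEncoder
from .spine_graph import GraphModule

__all__ = [
    "NetConfig", "TrainConfig", "GFSSNet", "build_model",
    "learning_rate_at", "ds_alpha_at", "train", "predict",
    "evaluate_cases", "TEST_PROFILE",
]


@dataclass(frozen=True)
class NetConfig:
    n_classes: int = 3
    modality: str = "t1+t2"          # "t1", "t2", or "t1+t2"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    graph_h_dim: int = 128
    dilation_rates: tuple[int, ...] = (1, 2, 4)
    deep_supervision: bool = True
    ds_stages: tuple[int, ...] = (1, 2)   # indices of DAPU stages with heads
    paaf_before_graph: bool = True
    seed: int = 0

    @property
    def in_channels(self) -> int:
        return 2 if self.modality == "t1+t2" else 1


# reduced-width profile so CPU-only runs stay inside test budgets
TEST_PROFILE = NetConfig(
    encoder=EncoderConfig(stage_channels=(8, 16, 32, 64),
                          d_state=(4, 4, 4, 4), d_conv=(1, 1, 1, 1),
                          n_kernels=2, attention_reduction=2),
    graph_h_dim=16,
)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    lr_decay: float = 0.8
    lr_decay_every: int = 30
    ds_alpha: float = 0.4
    ds_alpha_decay: float = 0.8
    ds_alpha_every: int = 30
    max_epochs: int = 300
    patience: int = 20
    batch_size: int = 1
    n_classes: int = 3
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)


def learning_rate_at(epoch: int, cfg: TrainConfig = TrainConfig()) -> float:
    """1e-3 * 0.8^floor(epoch / 30) under the defaults."""
    return cfg.learning_rate * cfg.lr_decay ** (epoch // cfg.lr_decay_every)


def ds_alpha_at(epoch: int, cfg: TrainConfig = TrainConfig()) -> float:
    """0.4 * 0.8^floor(epoch / 30) under the defaults."""
    return cfg.ds_alpha * cfg.ds_alpha_decay ** (epoch // cfg.ds_alpha_every)


class GFSSNet(Module):
    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        enc_cfg = cfg.encoder
        ch = enc_cfg.stage_channels
        self.dual = cfg.modality == "t1+t2"
        self.encoder_t1 = SEEEncoder(enc_cfg, rng)
        self.encoder_t2 = SEEEncoder(enc_cfg, rng) if self.dual else None
        bott = ch[3]
        paaf_cfg = PAAFConfig(bott, d_state=enc_cfg.d_state[3],
                              d_conv=enc_cfg.d_conv[3])
        if self.dual:
            self.paaf = PAAF(paaf_cfg, rng)
            self.skip_fuse = [Conv3d(2 * c, c, 1, rng) for c in ch]
        else:
            from .paaf import RotationalEnhance
            self.enhance = RotationalEnhance(paaf_cfg, rng)
            self.epa = EnhancedPositionAttention(bott, rng)
            self.skip_fuse = None
        self.graph = GraphModule(bott, rng, h_dim=cfg.graph_h_dim)
        dec_ch = (ch[2], ch[1], ch[0], ch[0])
        skip_ch = (ch[3], ch[2], ch[1], ch[0])
        ins = (bott,) + dec_ch[:3]
        self.decoder = [
            DAPUStage(DAPUConfig(ins[i], dec_ch[i],
                                 dilation_rates=cfg.dilation_rates), rng,
                      skip_channels=skip_ch[i])
            for i in range(4)]
        self.head = Conv3d(dec_ch[3], cfg.n_classes, 1, rng)
        self.aux_heads = [Conv3d(dec_ch[s], cfg.n_classes, 1, rng)
                          for s in cfg.ds_stages] if cfg.deep_supervision \
            else []

    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 5:
            raise ValueError("expected (batch, channels, D, H, W) input")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"modality mode {self.cfg.modality!r} expects "
                f"{self.cfg.in_channels} input channel(s), got {x.shape[1]}")
        bad = [s for s in x.shape[2:] if s % 16 != 0]
        if bad:
            raise ValueError(
                f"spatial dims {tuple(x.shape[2:])} must each be divisible "
                f"by 16 (four x2 downsamplings)")

    def forward(self, x, return_aux: bool = False):
        x = as_tensor(x)
        self._check_input(x)
        if self.dual:
            skips1, b1 = self.encoder_t1(x[:, 0:1])
            skips2, b2 = self.encoder_t2(x[:, 1:2])
            bott = self.paaf(b1, b2)
            skips = [fuse(concatenate([s1, s2], axis=1))
                     for fuse, s1, s2 in zip(self.skip_fuse, skips1, skips2)]
        else:
            skips, b1 = self.encoder_t1(x)
            bott = self.epa(self.enhance(b1))
        bott = self.graph(bott)
        feats = []
        out = bott
        for stage, skip in zip(self.decoder, reversed(skips)):
            out = stage(out, skip)
            feats.append(out)
        probs = self.head(out).softmax(axis=1)
        if not return_aux:
            return probs
        aux = [head(feats[s]).softmax(axis=1)
               for head, s in zip(self.aux_heads, self.cfg.ds_stages)]
        return probs, aux


def build_model(cfg: NetConfig) -> GFSSNet:
    return GFSSNet(cfg)


def _downsample_labels(labels: np.ndarray, target: tuple[int, ...]) -> np.ndarray:
    """Nearest-neighbour label downsampling for auxiliary heads."""
    idx = tuple(np.round(np.linspace(0, s - 1, t)).astype(int)
                for s, t in zip(labels.shape[1:], target))
    return labels[:, idx[0][:, None, None], idx[1][None, :, None],
                  idx[2][None, None, :]]


def _case_loss(model: GFSSNet, x: np.ndarray, labels: np.ndarray,
               cfg: TrainConfig, alpha_ds: float) -> Tensor:
    n_c = cfg.n_classes
    if model.cfg.deep_supervision:
        probs, aux = model(x, return_aux=True)
    else:
        probs, aux = model(x), []
    g = one_hot(labels, n_c)
    loss = hfd_tversky_loss(probs, g, cfg.loss, check=False)
    for a in aux:
        ga = one_hot(_downsample_labels(labels, a.shape[2:]), n_c)
        loss = loss + alpha_ds * hfd_tversky_loss(a, ga, cfg.loss,
                                                  check=False)
    return loss


def _pair_to_input(pair: VolumePair, modality: str) -> np.ndarray:
    chans = {"t1": [pair.t1], "t2": [pair.t2],
             "t1+t2": [pair.t1, pair.t2]}[modality]
    return np.stack(chans, axis=0)[None].astype(np.float32)


def _mean_fg_dice(pred_labels: np.ndarray, gt_labels: np.ndarray,
                  n_classes: int) -> float:
    scores = [dsc(gt_labels == c, pred_labels == c)
              for c in range(1, n_classes)]
    return float(np.mean(scores))


def train(model: GFSSNet, dataset, cfg: TrainConfig,
          val_dataset=None, log_path: str | Path | None = None,
          max_steps: int | None = None,
          dice_stop: float | None = None) -> dict:
    """Seeded full-volume training loop.

    ``dataset``: sequence of (VolumePair, LabelVolume) in the model's label
    scheme.  Returns a history dict with per-epoch logs and the best state.
    ``max_steps`` caps total optimizer steps (for overfitting runs);
    ``dice_stop`` ends training early once the training-set mean
    foreground Dice reaches the threshold.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: list[dict] = []
    best = {"dice": -1.0, "state": None, "epoch": -1}
    stall = 0
    step = 0
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.max_epochs):
            lr = learning_rate_at(epoch, cfg)
            alpha = ds_alpha_at(epoch, cfg)
            opt.lr = lr
            order = rng.permutation(len(dataset))
            losses = []
            train_dice = []
            for i in order:
                pair, mask = dataset[i]
                x = _pair_to_input(pair, model.cfg.modality)
                labels = mask.labels[None]
                loss = _case_loss(model, x, labels, cfg, alpha)
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: "
                        f"{loss.item()}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                step += 1
                if dice_stop is not None:
                    with no_grad():
                        probs = model(x)
                    pred = probs.data.argmax(axis=1)
                    train_dice.append(
                        _mean_fg_dice(pred, labels, cfg.n_classes))
                if max_steps is not None and step >= max_steps:
                    break
            record = {"epoch": epoch, "lr": lr, "alpha_ds": alpha,
                      "loss": float(np.mean(losses)), "steps": step}
            if train_dice:
                record["train_dice"] = float(np.mean(train_dice))
            if val_dataset:
                vds = []
                for pair, mask in val_dataset:
                    pred = predict(model, pair)
                    vds.append(_mean_fg_dice(pred.labels[None],
                                             mask.labels[None],
                                             cfg.n_classes))
                record["val_dice"] = float(np.mean(vds))
                if record["val_dice"] > best["dice"] + 1e-6:
                    best.update(dice=record["val_dice"],
                                state=model.state_dict(), epoch=epoch)
                    stall = 0
                else:
                    stall += 1
            history.append(record)
            if log_f:
                log_f.write(json.dumps(record) + "\n")
                log_f.flush()
            if dice_stop is not None and train_dice \
                    and record["train_dice"] >= dice_stop:
                break
            if max_steps is not None and step >= max_steps:
                break
            if val_dataset and stall >= cfg.patience:
                break
    finally:
        if log_f:
            log_f.close()
    if best["state"] is None:
        best.update(state=model.state_dict(), epoch=len(history) - 1)
    return {"history": history, "best": best, "steps": step}


def predict(model: GFSSNet, pair: VolumePair) -> LabelVolume:
    x = _pair_to_input(pair, model.cfg.modality)
    with no_grad():
        probs = model(x)
    labels = probs.data.argmax(axis=1)[0].astype(np.int64)
    scheme = LabelScheme.THREE_CLASS if model.cfg.n_classes == 3 \
        else LabelScheme.TEN_CLASS
    return LabelVolume(labels, scheme=scheme, spacing=pair.spacing)


def evaluate_cases(cases) -> list[dict]:
    """Rows of per-case metrics for (gt, pred) LabelVolume pairs, plus an
    aggregate mean/std row per column."""
    from .metrics import evaluate_case
    rows = []
    for name, gt, pred in cases:
        row = {"case": name}
        row.update(evaluate_case(gt, pred).as_row())
        rows.append(row)
    if rows:
        keys = [k for k in rows[0] if k != "case"]
        agg_mean = {"case": "mean"}
        agg_std = {"case": "std"}
        for k in keys:
            vals = [r[k] for r in rows if r[k] is not None]
            agg_mean[k] = float(np.mean(vals)) if vals else None
            agg_std[k] = float(np.std(vals)) if vals else None
        rows.extend([agg_mean, agg_std])
    return rows


def save_checkpoint(model: GFSSNet, path: str | Path) -> None:
    state = model.state_dict()
    cfg_dict = asdict(model.cfg)
    cfg_dict["encoder"].pop("directions", None)  # scan axes are not config-portable
    meta = json.dumps({"config": cfg_dict})
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> GFSSNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        cfg_dict = meta["config"]
        enc = cfg_dict.pop("encoder")
        enc.pop("directions", None)
        cfg_dict["encoder"] = EncoderConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in enc.items()})
        cfg_dict = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in cfg_dict.items()}
        cfg = NetConfig(**cfg_dict)
        model = GFSSNet(cfg)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
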
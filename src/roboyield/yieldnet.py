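"""Plot-yield regression from fused counting features.

Rather than summing per-image seed counts, plot yield (MT/ha) is regressed
directly from the counting backbone's feature maps: the 10 feature maps of a
side are summed elementwise, the two side-sums are concatenated along the
channel axis (side A first), and the fused map feeds a small regressor — one
convolution, a 2x2 max-pool, flatten, then three fully connected layers down
to a scalar. The backbone stays frozen throughout regressor training; seed
counts are never computed on this path.

Training uses Adam on elementwise MSE, batch size 8, 50 epochs by default.
Targets are z-scored during optimisation and the transform inverted at
prediction time, which stabilises MSE training across yield scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._net import Adam, Conv2D, Flatten, Linear, MaxPool2, ReLU, Sequential, state_hash
from .plotframes import SampledPlotImages
from .seedcount import CountModel


class YieldNetError(ValueError):
    pass


@dataclass
class FusedPlotFeatures:
    """Per-side summed feature maps, channel-concatenated (A then B)."""

    fused: np.ndarray  # (H, W, 2C)
    plot_id: tuple[int, int] | None = None


def fuse_features(
    maps_by_side: dict[str, list[np.ndarray]],
    plot_id: tuple[int, int] | None = None,
    n_per_side: int = 10,
) -> FusedPlotFeatures:
    """Sum each side's feature maps elementwise and concatenate the two sums
    along channels, side A before side B."""
    for side in ("A", "B"):
        maps = maps_by_side.get(side)
        if maps is None or len(maps) != n_per_side:
            raise YieldNetError(
                f"plot {plot_id}: side {side} needs exactly {n_per_side} "
                f"feature maps, got {0 if maps is None else len(maps)}"
            )
        shapes = {m.shape for m in maps}
        if len(shapes) != 1:
            raise YieldNetError(f"plot {plot_id}: side {side} maps differ in shape: {shapes}")
    side_sums = {s: np.sum(maps_by_side[s], axis=0) for s in ("A", "B")}
    if side_sums["A"].shape != side_sums["B"].shape:
        raise YieldNetError(f"plot {plot_id}: side sums differ in shape")
    fused = np.concatenate([side_sums["A"], side_sums["B"]], axis=-1)
    return FusedPlotFeatures(fused=fused.astype(np.float32), plot_id=plot_id)


@dataclass(frozen=True)
class RegressorConfig:
    """Yield-regressor widths and training settings."""

    conv_channels: int = 64
    fc1: int = 256
    fc2: int = 64
    batch_size: int = 8
    epochs: int = 50
    lr: float = 1e-3
    normalize_targets: bool = True
    seed: int = 0


class YieldRegressor:
    """conv -> max-pool -> flatten -> fc1 -> fc2 -> fc3 -> scalar MT/ha."""

    def __init__(self, in_channels: int, feat_shape: tuple[int, int],
                 cfg: RegressorConfig = RegressorConfig()):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w = feat_shape
        ph, pw = (h + 1) // 2, (w + 1) // 2
        flat = ph * pw * cfg.conv_channels
        self.net = Sequential([
            Conv2D(in_channels, cfg.conv_channels, 3, rng), ReLU(), MaxPool2(),
            Flatten(),
            Linear(flat, cfg.fc1, rng), ReLU(),
            Linear(cfg.fc1, cfg.fc2, rng), ReLU(),
            Linear(cfg.fc2, 1, rng),
        ])
        # target normalisation (identity until fitted)
        self.y_mean = 0.0
        self.y_sd = 1.0

    def forward(self, fused_batch: np.ndarray) -> np.ndarray:
        return self.net.forward(fused_batch.astype(np.float32))[:, 0]

    def predict(self, fused_batch: np.ndarray) -> np.ndarray:
        return self.forward(fused_batch) * self.y_sd + self.y_mean


def _plot_fused(plot_images: SampledPlotImages, backbone: CountModel) -> FusedPlotFeatures:
    maps = {}
    for side in ("A", "B"):
        images = plot_images.images(side)
        if any(img is None for img in images):
            raise YieldNetError(f"plot {plot_images.plot_id}: missing images on side {side}")
        batch = np.stack(images).astype(np.float32)
        feats = backbone.backbone.forward(batch)
        maps[side] = [feats[i] for i in range(len(images))]
    return fuse_features(maps, plot_id=plot_images.plot_id,
                         n_per_side=len(maps["A"]))


def predict_yield(
    plot_images: SampledPlotImages, backbone: CountModel, regressor: YieldRegressor
) -> float:
    """Predicted plot yield in MT/ha from the 20 sampled images. The backbone
    is only read, never updated."""
    fused = _plot_fused(plot_images, backbone)
    return float(regressor.predict(fused.fused[None])[0])


def train_regressor(
    train_plots: list[tuple[SampledPlotImages, float]],
    backbone: CountModel,
    cfg: RegressorConfig = RegressorConfig(),
) -> tuple[YieldRegressor, pd.DataFrame]:
    """Train the yield regressor on (plot images, true yield MT/ha) pairs
    with the backbone frozen.

    Fused features are precomputed once (the backbone takes no gradient);
    the frozen contract is asserted: backbone weights are bit-identical
    before and after. A final batch smaller than ``batch_size`` is used as
    is and noted in the log.
    """
    if not train_plots:
        raise YieldNetError("no training plots")
    before = state_hash(backbone.backbone)
    fused = np.stack([_plot_fused(pi, backbone).fused for pi, _ in train_plots])
    y = np.array([t for _, t in train_plots], dtype=np.float32)
    reg = YieldRegressor(in_channels=fused.shape[-1], feat_shape=fused.shape[1:3],
                         cfg=cfg)
    if cfg.normalize_targets:
        reg.y_mean = float(y.mean())
        reg.y_sd = float(y.std()) or 1.0
    yn = (y - reg.y_mean) / reg.y_sd
    opt = Adam(reg.net.params(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    short_final = len(train_plots) % cfg.batch_size != 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_plots))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = reg.net.forward(fused[idx])[:, 0]
            err = pred - yn[idx]
            loss = float(np.mean(err**2))
            opt.zero_grad()
            reg.net.backward((2 * err / len(idx))[:, None])
            opt.step()
            losses.append(loss)
        rows.append({"epoch": epoch, "train_mse": float(np.mean(losses)),
                     "short_final_batch": short_final})
    after = state_hash(backbone.backbone)
    if before != after:  # pragma: no cover - guards a contract violation
        raise YieldNetError("backbone weights changed during regressor training")
    return reg, pd.DataFrame(rows)
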
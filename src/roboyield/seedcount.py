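"""Point-proposal seed counting.

Seed counting in a mature soybean canopy is a crowd-counting problem: scenes
are dense, seeds are small, and boxes are poor supervision. The model here is
a point-proposal network in the P2PNet family: a convolutional backbone
produces a stride-8 feature map; a point head predicts, for a fixed set of
reference points per feature cell, an (x, y) offset and a confidence logit.
Training matches proposals to ground-truth points one-to-one with the
Hungarian algorithm on a cost of Euclidean distance minus a score bonus, then
applies cross-entropy on matched/unmatched confidences plus an L2 penalty on
matched offsets. At inference, proposals below a score threshold are dropped
and near-duplicates are merged greedily through a k-d tree.

The backbone is a small configurable conv net (default four 3x3 blocks,
overall stride 8) sized for desk-scale training; the full-size architecture
it stands in for is a published crowd-counting backbone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import linregress

from ._net import Adam, Conv2D, Layer, MaxPool2, ReLU, Sequential, state_hash
from .points import PointSet

#: Named training-set combinations: a base annotated set, its sensor-effect
#: augmented copy, and an external set from a second camera/site.
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "ISU_NO_AUG": ("base",),
    "MIX_NO_AUG": ("base", "external"),
    "ISU_AUG": ("base", "base_aug"),
    "MIX_AUG": ("base", "base_aug", "external"),
}


@dataclass(frozen=True)
class CountModelConfig:
    """Backbone/head geometry and inference thresholds."""

    n_blocks: int = 4
    base_channels: int = 8
    stride: int = 8  # pooling in the first log2(stride) blocks
    kernel: int = 3
    proposal_density: int = 4  # reference points per feature cell (2x2)
    score_threshold: float = 0.5
    merge_radius: float = 8.0
    lambda_score: float = 1.0  # score bonus weight in the matching cost
    loc_weight: float = 0.02  # weight of the offset L2 loss
    pos_weight: float = 8.0  # BCE weight on matched proposals (imbalance)

    def __post_init__(self) -> None:
        n_pools = int(np.log2(self.stride))
        if 2**n_pools != self.stride:
            raise ValueError("stride must be a power of 2")
        if n_pools > self.n_blocks:
            raise ValueError("stride requires more pooling blocks than n_blocks")
        if int(np.sqrt(self.proposal_density)) ** 2 != self.proposal_density:
            raise ValueError("proposal_density must be a square number")


class CountModel:
    """Backbone + point head. Deterministic given its init seed."""

    def __init__(self, cfg: CountModelConfig = CountModelConfig(), seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        n_pools = int(np.log2(cfg.stride))
        layers: list[Layer] = []
        cin = 3
        for i in range(cfg.n_blocks):
            cout = cfg.base_channels * 2 ** min(i, 2)
            layers += [Conv2D(cin, cout, cfg.kernel, rng), ReLU()]
            if i < n_pools:
                layers.append(MaxPool2())
            cin = cout
        self.backbone = Sequential(layers)
        self.feature_channels = cin
        k = cfg.proposal_density
        self.head_offset = Conv2D(cin, 2 * k, 1, rng)
        self.head_logit = Conv2D(cin, k, 1, rng)
        # start near-neutral: small offsets, scores near 0.5
        self.head_offset.W.value *= 0.1
        self.head_logit.W.value *= 0.1

    # -- forward passes ----------------------------------------------------

    def forward(self, images: np.ndarray):
        """Batch forward; returns (features, offsets, logits).

        ``images`` is (N, H, W, 3) float32. Offsets are in pixels at image
        scale. Non-multiple-of-stride sizes are edge-padded inside the
        pooling layers (ceil division).
        """
        feats = self.backbone.forward(images.astype(np.float32))
        offsets = self.head_offset.forward(feats) * self.cfg.stride
        logits = self.head_logit.forward(feats)
        return feats, offsets, logits

    def backward(self, d_offsets: np.ndarray, d_logits: np.ndarray) -> None:
        dfeat = self.head_offset.backward(d_offsets * self.cfg.stride)
        dfeat = dfeat + self.head_logit.backward(d_logits)
        self.backbone.backward(dfeat)

    def params(self):
        return (self.backbone.params() + self.head_offset.params()
                + self.head_logit.params())

    def reference_points(self, feat_h: int, feat_w: int) -> np.ndarray:
        """(feat_h, feat_w, K, 2) reference (x, y) pixel positions: a
        sqrt(K) x sqrt(K) sub-grid within each stride cell."""
        s = self.cfg.stride
        g = int(np.sqrt(self.cfg.proposal_density))
        sub = (np.arange(g) + 0.5) / g * s
        sx, sy = np.meshgrid(sub, sub)
        sub_xy = np.stack([sx.ravel(), sy.ravel()], axis=-1)  # (K, 2)
        cx = np.arange(feat_w)[None, :, None, None] * s
        cy = np.arange(feat_h)[:, None, None, None] * s
        ref = np.zeros((feat_h, feat_w, self.cfg.proposal_density, 2))
        ref[..., 0] = cx[..., 0] + sub_xy[None, None, :, 0]
        ref[..., 1] = cy[..., 0] + sub_xy[None, None, :, 1]
        return ref


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


def extract_features(image: np.ndarray, model: CountModel) -> np.ndarray:
    """Feature map (H/stride, W/stride, C) of a single working-crop image."""
    feats, _, _ = model.forward(image[None])
    return feats[0]


def propose_points(
    image: np.ndarray, model: CountModel, score_threshold: float | None = None
) -> PointSet:
    """All point proposals of an image above the score threshold.

    Each reference point contributes one candidate at reference + predicted
    offset with a sigmoid-squashed confidence.
    """
    thr = model.cfg.score_threshold if score_threshold is None else score_threshold
    _, offsets, logits = model.forward(image[None])
    fh, fw, k = logits.shape[1], logits.shape[2], model.cfg.proposal_density
    ref = model.reference_points(fh, fw)
    off = offsets[0].reshape(fh, fw, k, 2)
    pts = (ref + off).reshape(-1, 2)
    scores = _sigmoid(logits[0].reshape(-1))
    keep = scores >= thr
    return PointSet(xy=pts[keep], scores=scores[keep])


def hungarian_match(
    pred_xy: np.ndarray, pred_scores: np.ndarray, truth_xy: np.ndarray,
    lambda_score: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one assignment of proposals to truth points minimising
    sum of (Euclidean distance - lambda * score); returns (pred_idx,
    truth_idx) arrays of the matched pairs."""
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return np.empty(0, int), np.empty(0, int)
    d = np.linalg.norm(pred_xy[:, None, :] - truth_xy[None, :, :], axis=-1)
    cost = d - lambda_score * pred_scores[:, None]
    return linear_sum_assignment(cost)


def match_loss(
    predicted: PointSet, truth: PointSet, lambda_score: float = 1.0,
    loc_weight: float = 0.02,
) -> float:
    """Matching loss of a prediction set against ground truth: Hungarian
    matching, then mean binary cross-entropy on matched (target 1) versus
    unmatched (target 0) confidences, plus ``loc_weight`` times the mean
    squared matched-offset distance. Empty vs empty is zero loss."""
    n = len(predicted)
    if n == 0 and len(truth) == 0:
        return 0.0
    scores = predicted.scores if predicted.scores is not None else np.ones(n)
    pi, ti = hungarian_match(predicted.xy, scores, truth.xy, lambda_score)
    targets = np.zeros(n)
    targets[pi] = 1.0
    eps = 1e-9
    if n:
        bce = -np.mean(targets * np.log(scores + eps)
                       + (1 - targets) * np.log(1 - scores + eps))
    else:
        bce = 0.0
    loc = 0.0
    if len(pi):
        loc = float(np.mean(np.sum((predicted.xy[pi] - truth.xy[ti]) ** 2, axis=-1)))
    return float(bce + loc_weight * loc)


def merge_duplicates(points: PointSet, radius: float) -> PointSet:
    """Greedy duplicate suppression: visit points by descending score (ties
    toward lower index), keep a point iff no already-kept point lies strictly
    within ``radius``; neighbour queries through a k-d tree."""
    if radius <= 0:
        raise ValueError("merge radius must be positive")
    n = len(points)
    if n == 0:
        return points
    scores = points.scores if points.scores is not None else np.ones(n)
    order = np.lexsort((np.arange(n), -scores))
    tree = cKDTree(points.xy)
    kept_mask = np.zeros(n, bool)
    for i in order:
        neigh = tree.query_ball_point(points.xy[i], radius)
        if any(kept_mask[j] and j != i
               and np.linalg.norm(points.xy[j] - points.xy[i]) < radius
               for j in neigh):
            continue
        kept_mask[i] = True
    keep = np.flatnonzero(kept_mask)
    return PointSet(
        xy=points.xy[keep],
        scores=scores[keep] if points.scores is not None else None,
        image_id=points.image_id,
    )


def count_seeds(image: np.ndarray, model: CountModel) -> tuple[int, PointSet]:
    """Count = number of surviving proposals after thresholding and duplicate
    merging."""
    proposals = propose_points(image, model)
    merged = merge_duplicates(proposals, model.cfg.merge_radius) if len(proposals) else proposals
    return len(merged), merged


@dataclass(frozen=True)
class CountMetrics:
    MSE: float
    MAE: float
    MAPE: float  # percent
    R2: float


def eval_counts(pred_counts, true_counts, mape_policy: str = "exclude_zero") -> CountMetrics:
    """MSE / MAE / MAPE (%) and the R² of the least-squares line of predicted
    on true counts. Zero true counts are excluded from MAPE with a warning
    (``mape_policy='exclude_zero'``) or raise (``'error'``)."""
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction and truth lengths differ")
    err = pred - true
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    nz = true != 0
    if not nz.all():
        if mape_policy == "error":
            raise ValueError("zero true count; MAPE undefined")
        warnings.warn(f"excluding {int((~nz).sum())} zero true counts from MAPE",
                      stacklevel=2)
    mape = float(np.mean(np.abs(err[nz] / true[nz])) * 100) if nz.any() else float("nan")
    if np.ptp(true) > 0 and np.ptp(pred) > 0:
        r2 = float(linregress(true, pred).rvalue ** 2)
    else:
        r2 = 0.0
    return CountMetrics(MSE=mse, MAE=mae, MAPE=mape, R2=r2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _training_step(model: CountModel, images: np.ndarray,
                   truths: list[PointSet], opt: Adam) -> float:
    """One batch: forward, match, analytic head gradients, backprop, Adam."""
    cfg = model.cfg
    _, offsets, logits = model.forward(images)
    n, fh, fw, k = logits.shape
    ref = model.reference_points(fh, fw)
    d_off = np.zeros_like(offsets)
    d_log = np.zeros_like(logits)
    total = 0.0
    n_props = fh * fw * k
    for b in range(n):
        off = offsets[b].reshape(fh, fw, k, 2)
        pts = (ref + off).reshape(-1, 2)
        scores = _sigmoid(logits[b].reshape(-1))
        truth = truths[b].xy
        pi, ti = hungarian_match(pts, scores, truth, cfg.lambda_score)
        targets = np.zeros(n_props)
        targets[pi] = 1.0
        eps = 1e-9
        wts = np.where(targets > 0, cfg.pos_weight, 1.0)
        bce = -np.mean(wts * (targets * np.log(scores + eps)
                              + (1 - targets) * np.log(1 - scores + eps)))
        d_log[b] = (wts * (scores - targets) / n_props).reshape(fh, fw, k)
        loc = 0.0
        if len(pi):
            diff = pts[pi] - truth[ti]
            loc = float(np.mean(np.sum(diff**2, axis=-1)))
            g = np.zeros((n_props, 2))
            g[pi] = cfg.loc_weight * 2.0 * diff / len(pi)
            d_off[b] = g.reshape(fh, fw, 2 * k)
        total += bce + cfg.loc_weight * loc
    opt.zero_grad()
    model.backward(d_off / n, d_log / n)
    opt.step()
    return total / n


def validation_mae(model: CountModel, data: list[tuple[np.ndarray, PointSet]]) -> float:
    pred = [count_seeds(img, model)[0] for img, _ in data]
    true = [len(pts) for _, pts in data]
    return float(np.mean(np.abs(np.array(pred) - np.array(true))))


def _snapshot(model: CountModel) -> list[np.ndarray]:
    return [p.value.copy() for p in model.params()]


def _restore(model: CountModel, snap: list[np.ndarray]) -> None:
    for p, v in zip(model.params(), snap):
        p.value[...] = v


def train_count_model(
    datasets: dict[str, list[tuple[np.ndarray, PointSet]]],
    combination: str,
    val_data: list[tuple[np.ndarray, PointSet]],
    model: CountModel | None = None,
    epochs: int = 10,
    lr: float = 1e-4,
    batch_size: int = 4,
    seed: int = 0,
) -> tuple[CountModel, pd.DataFrame]:
    """Train a counting model on a named dataset combination.

    ``datasets`` maps component names (``base``, ``base_aug``, ``external``)
    to lists of (image, PointSet); ``combination`` selects which components
    are pooled. The best checkpoint by validation MAE is restored before
    returning. Fully reproducible from ``seed``.
    """
    if combination not in COMBINATIONS:
        raise KeyError(f"unknown combination {combination!r}; "
                       f"choose from {sorted(COMBINATIONS)}")
    train: list[tuple[np.ndarray, PointSet]] = []
    for key in COMBINATIONS[combination]:
        if key not in datasets:
            raise KeyError(f"combination {combination} needs dataset {key!r}")
        train.extend(datasets[key])
    if not train:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    model = model or CountModel(seed=int(rng.integers(2**31)))
    opt = Adam(model.params(), lr=lr)
    log_rows = []
    best_mae, best_state = np.inf, _snapshot(model)
    for epoch in range(epochs):
        order = rng.permutation(len(train))
        losses = []
        for start in range(0, len(train), batch_size):
            idx = order[start : start + batch_size]
            images = np.stack([train[i][0] for i in idx])
            truths = [train[i][1] for i in idx]
            losses.append(_training_step(model, images, truths, opt))
        mae = validation_mae(model, val_data) if val_data else float("nan")
        log_rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                         "val_mae": mae})
        if val_data and mae < best_mae:
            best_mae, best_state = mae, _snapshot(model)
    if val_data:
        _restore(model, best_state)
    return model, pd.DataFrame(log_rows)
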
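"""Trainable ordinal scoring model for aortic segment crops.

The backbone is a small convolutional network (three 3x3 conv blocks with
ReLU and average pooling, global average pooling, a 64-dimensional linear
feature head and a scalar score head) written directly in numpy with
analytic backpropagation and an Adam optimizer, so training runs
deterministically on a single CPU.  It is trained with the combined
objective: mean absolute error on the predicted per-segment score plus
``lambda_rank`` times the contrastive rank-aware loss on the feature
vectors (see :mod:`aacscore.ranking`).

Three pipeline variants are provided for ablation:

* ``holistic`` — the backbone consumes the downsampled whole radiograph and
  regresses the total score (0-24) directly, with no landmark localization
  or aortic segmentation;
* ``segmented`` — per-segment crops from the landmark-driven aortic
  geometry, regression loss only (lambda_rank = 0);
* ``rank_aware`` — the full pipeline: segmented crops plus the contrastive
  rank-aware loss.

``SegmentScoreRegressor`` follows the scikit-learn estimator protocol
(``fit``/``predict``/``get_params``), taking crops as an (n, height, width)
array; ``train_pipeline``/``predict_aacs`` wrap it into the
phantom -> landmarks -> geometry -> score pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize
from sklearn.base import BaseEstimator, RegressorMixin

from . import geometry
from .kauppila import AACSRecord, SEGMENT_LEVELS, severity_class, total_aacs
from .landmarks import VertebraSet
from .phantom import Phantom
from .ranking import LossConfig, RankBatch, contrastive_rank_loss_and_grad

CROP_SHAPE = (48, 32)        # (height, width) of a segment crop
WHOLE_SHAPE = (96, 64)       # downsampled whole-frame input
FEATURE_DIM = 64


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30           # desk preset; full-scale protocol uses 200
    base_lr: float = 0.001
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 50
    batch_size: int = 24
    augmentations: frozenset = frozenset({"horizontal_flip",
                                          "brightness_contrast"})
    backbone: str = "tiny_cnn"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.base_lr <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, base_lr and batch_size must be positive")
        if not 0 < self.lr_decay_factor <= 1:
            raise ValueError("lr_decay_factor must lie in (0, 1]")
        if self.backbone == "resnet101":
            raise ValueError(
                "the resnet101 backbone requires an external deep-learning "
                "runtime and is not available in this build; use tiny_cnn")
        if self.backbone != "tiny_cnn":
            raise ValueError(f"unknown backbone {self.backbone!r}")
        object.__setattr__(self, "augmentations",
                           frozenset(self.augmentations))


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step-decay schedule: base_lr x factor^floor(epoch / decay_every)."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return config.base_lr * config.lr_decay_factor ** (
        epoch // config.lr_decay_every)


@dataclass(frozen=True)
class SegmentPrediction:
    level: str
    raw_score: float
    rounded_score: int
    feature: np.ndarray


def round_score(raw: float, lo: int = 0, hi: int = 6) -> int:
    """Round half away from zero, then clamp to [lo, hi]."""
    r = int(np.sign(raw) * np.floor(abs(raw) + 0.5))
    return int(np.clip(r, lo, hi))


# ---------------------------------------------------------------------------
# numpy CNN primitives

def _conv_forward(x, w, b):
    """3x3 same-padding convolution.  x: (N,C,H,W), w: (F,C,3,3), b: (F,)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N,C,H,W,3,3)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * wd, c * 9)
    out = cols @ w.reshape(f, c * 9).T + b
    return out.transpose(0, 2, 1).reshape(n, f, h, wd), cols


def _conv_backward(dout, cols, x_shape, w):
    n, c, h, wd = x_shape
    f = w.shape[0]
    dflat = dout.reshape(n, f, h * wd).transpose(0, 2, 1)  # (N,HW,F)
    dw = np.einsum("npf,npk->fk", dflat, cols).reshape(w.shape)
    db = dflat.sum(axis=(0, 1))
    dcols = dflat @ w.reshape(f, c * 9)                    # (N,HW,C*9)
    dcols = dcols.reshape(n, h, wd, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, wd + 2))
    for i in range(3):
        for j in range(3):
            dxp[:, :, i:i + h, j:j + wd] += dcols[:, :, :, :, i, j
                                                  ].transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_backward(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class _TinyCNN:
    """3-block conv net: (1->8->16->32 channels) + GAP + feature/score heads."""

    CHANNELS = (8, 16, 32)

    def __init__(self, input_shape: tuple[int, int], seed: int,
                 feature_dim: int = FEATURE_DIM):
        rng = np.random.default_rng(seed)
        self.input_shape = tuple(input_shape)
        c_in = 1
        self.params: dict[str, np.ndarray] = {}
        for i, c_out in enumerate(self.CHANNELS):
            fan_in = c_in * 9
            self.params[f"w{i}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3))
            self.params[f"b{i}"] = np.zeros(c_out)
            c_in = c_out
        self.params["w_feat"] = rng.normal(
            0.0, np.sqrt(1.0 / c_in), (c_in, feature_dim))
        self.params["b_feat"] = np.zeros(feature_dim)
        self.params["w_score"] = rng.normal(0.0, 0.1, feature_dim)
        self.params["b_score"] = np.zeros(1)

    def forward(self, x: np.ndarray, cache: dict | None = None):
        """x: (N, H, W) -> (features (N, D), scores (N,))."""
        h = x[:, None, :, :]
        caches = []
        for i in range(3):
            out, cols = _conv_forward(h, self.params[f"w{i}"],
                                      self.params[f"b{i}"])
            mask = out > 0
            act = out * mask
            caches.append((cols, h.shape, mask))
            h = act if i == 2 else _avgpool2(act)
        gap = h.mean(axis=(2, 3))                       # (N, C3)
        feat = gap @ self.params["w_feat"] + self.params["b_feat"]
        score = feat @ self.params["w_score"] + self.params["b_score"][0]
        if cache is not None:
            cache.update(caches=caches, gap=gap, feat=feat,
                         h_shape=h.shape)
        return feat, score

    def backward(self, cache: dict, dfeat: np.ndarray, dscore: np.ndarray
                 ) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        feat_total = dfeat + dscore[:, None] * self.params["w_score"]
        grads["w_score"] = cache["feat"].T @ dscore
        grads["b_score"] = np.array([dscore.sum()])
        grads["w_feat"] = cache["gap"].T @ feat_total
        grads["b_feat"] = feat_total.sum(axis=0)
        dgap = feat_total @ self.params["w_feat"].T
        n, c, hh, ww = cache["h_shape"]
        dh = np.broadcast_to(dgap[:, :, None, None] / (hh * ww),
                             (n, c, hh, ww)).copy()
        for i in (2, 1, 0):
            cols, x_shape, mask = cache["caches"][i]
            dact = dh if i == 2 else _avgpool2_backward(dh)
            dout = dact * mask
            dh, grads[f"w{i}"], grads[f"b{i}"] = _conv_backward(
                dout, cols, x_shape, self.params[f"w{i}"])
        return grads


class _Adam:
    def __init__(self, params: Mapping[str, np.ndarray],
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# estimator

class SegmentScoreRegressor(BaseEstimator, RegressorMixin):
    """Ordinal score regressor over image crops, scikit-learn style.

    Parameters mirror the training protocol: step-decayed Adam, MAE
    regression loss plus ``lambda_rank`` x contrastive rank-aware loss on
    the penultimate feature vectors.  ``fit`` consumes X of shape
    (n_samples, height, width) (gray values, any positive range) and
    integer scores y; fitted state lives in ``net_`` and the per-epoch
    ``log_``.
    """

    def __init__(self, epochs: int = 30, base_lr: float = 0.001,
                 lr_decay_factor: float = 0.5, lr_decay_every: int = 50,
                 batch_size: int = 24, tau: float = 0.1,
                 lambda_rank: float = 1.0, augment: bool = True,
                 score_range: tuple[int, int] = (0, 6), seed: int = 0):
        self.epochs = epochs
        self.base_lr = base_lr
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every = lr_decay_every
        self.batch_size = batch_size
        self.tau = tau
        self.lambda_rank = lambda_rank
        self.augment = augment
        self.score_range = score_range
        self.seed = seed

    def _train_config(self) -> TrainConfig:
        augs = ({"horizontal_flip", "brightness_contrast"}
                if self.augment else set())
        return TrainConfig(epochs=self.epochs, base_lr=self.base_lr,
                           lr_decay_factor=self.lr_decay_factor,
                           lr_decay_every=self.lr_decay_every,
                           batch_size=self.batch_size,
                           augmentations=frozenset(augs), seed=self.seed)

    @staticmethod
    def _normalize(x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) / 255.0 - 0.5

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SegmentScoreRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3 or len(X) != len(y):
            raise ValueError("X must be (n, height, width) aligned with y")
        if len(X) == 0:
            raise ValueError("empty training set")
        cfg = self._train_config()
        rng = np.random.default_rng(self.seed)
        net = _TinyCNN(X.shape[1:], seed=int(rng.integers(2**31 - 1)))
        opt = _Adam(net.params)
        loss_cfg = LossConfig(tau=self.tau, lambda_rank=self.lambda_rank)
        n = len(X)
        log = []
        for epoch in range(self.epochs):
            lr = lr_schedule(epoch, cfg)
            order = rng.permutation(n)
            mae_sum, lcr_sum, n_batches = 0.0, 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx].copy()
                yb = y[idx]
                if self.augment:
                    flip = rng.random(len(idx)) < 0.5
                    xb[flip] = xb[flip, :, ::-1]
                    gain = rng.uniform(0.85, 1.15, len(idx))
                    offs = rng.uniform(-12, 12, len(idx))
                    xb = xb * gain[:, None, None] + offs[:, None, None]
                xb = self._normalize(np.clip(xb, 0, 255))
                cache: dict = {}
                feat, score = net.forward(xb, cache)
                diffs = score - yb
                mae = float(np.mean(np.abs(diffs)))
                dscore = np.sign(diffs) / len(idx)
                if self.lambda_rank > 0 and len(idx) >= 2:
                    batch = RankBatch(features=feat, scores=yb.astype(int))
                    lcr, dfeat = contrastive_rank_loss_and_grad(
                        batch, loss_cfg.tau)
                    dfeat = loss_cfg.lambda_rank * dfeat
                else:
                    lcr, dfeat = 0.0, np.zeros_like(feat)
                grads = net.backward(cache, dfeat, dscore)
                opt.step(net.params, grads, lr)
                mae_sum += mae
                lcr_sum += lcr
                n_batches += 1
            log.append({"epoch": epoch, "lr": lr,
                        "mae": mae_sum / n_batches,
                        "l_cr": lcr_sum / n_batches,
                        "total": mae_sum / n_batches
                        + self.lambda_rank * lcr_sum / n_batches})
        self.net_ = net
        self.log_ = log
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def _forward(self, X: np.ndarray):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = self._normalize(np.asarray(X, dtype=float))
        return self.net_.forward(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous (raw) score predictions."""
        _, score = self._forward(X)
        return score

    def predict_rounded(self, X: np.ndarray) -> np.ndarray:
        lo, hi = self.score_range
        return np.array([round_score(s, lo, hi) for s in self.predict(X)])

    def features(self, X: np.ndarray) -> np.ndarray:
        feat, _ = self._forward(X)
        return feat

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.net_.params)
        manifest = {"params": self.get_params(),
                    "input_shape": list(self.net_.input_shape),
                    "weights": path.with_suffix(".npz").name,
                    "format": "aacscore-model-v1"}
        manifest["params"]["score_range"] = list(self.score_range)
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentScoreRegressor":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        params = manifest["params"]
        params["score_range"] = tuple(params["score_range"])
        est = cls(**params)
        net = _TinyCNN(tuple(manifest["input_shape"]), seed=0)
        with np.load(path.with_suffix(".npz")) as data:
            net.params = {k: data[k] for k in data.files}
        est.net_ = net
        est.log_ = []
        return est


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class ScoringPipeline:
    """A fitted variant: estimator + the preprocessing that feeds it."""

    variant: str                     # holistic | segmented | rank_aware
    estimator: SegmentScoreRegressor
    anterior_side: str = "left"

    def predict_record(self, image: np.ndarray,
                       vertebrae: VertebraSet | None = None
                       ) -> tuple[list[SegmentPrediction], AACSRecord]:
        if self.variant == "holistic":
            x = whole_frame_input(image)[None]
            raw = float(self.estimator.predict(x)[0])
            total = round_score(raw, 0, 24)
            rec = AACSRecord(segment_scores={}, total=total,
                             severity=severity_class(total))
            return [], rec
        if vertebrae is None:
            raise ValueError("segmented variants need vertebral landmarks")
        return predict_aacs(self.estimator, image, vertebrae,
                            self.anterior_side)

    def predict_totals(self, phantoms: Sequence[Phantom]) -> np.ndarray:
        totals = []
        for ph in phantoms:
            _, rec = self.predict_record(ph.image, ph.vertebrae)
            totals.append(rec.total)
        return np.array(totals)


def segment_crops(image: np.ndarray, vertebrae: VertebraSet,
                  anterior_side: str = "left",
                  crop_shape: tuple[int, int] = CROP_SHAPE
                  ) -> tuple[np.ndarray, list[str]]:
    """Four fixed-size aortic segment crops (L1..L4 order)."""
    segs = geometry.segments_from_landmarks(vertebrae, anterior_side)
    crops = np.stack([
        geometry.crop_aas(image, s, crop_shape[0], crop_shape[1])
        for s in segs
    ])
    return crops, [s.level for s in segs]


def whole_frame_input(image: np.ndarray,
                      shape: tuple[int, int] = WHOLE_SHAPE) -> np.ndarray:
    return resize(np.asarray(image, dtype=float), shape, order=1,
                  mode="constant", anti_aliasing=False, preserve_range=True)


def cohort_crop_dataset(cohort: Sequence[Phantom]
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(crops, per-segment scores) over a phantom cohort (4 per phantom)."""
    xs, ys = [], []
    for i, ph in enumerate(cohort):
        try:
            crops, levels = segment_crops(ph.image, ph.vertebrae,
                                          ph.config.anterior_side)
        except geometry.GeometryError as e:
            raise geometry.GeometryError(f"phantom {i}: {e}") from e
        xs.append(crops)
        ys.append([ph.gt_record.segment_scores[lv] for lv in levels])
    return np.concatenate(xs), np.concatenate(ys)


def train_pipeline(cohort: Sequence[Phantom],
                   config: TrainConfig | None = None,
                   loss: LossConfig | None = None,
                   variant: str = "rank_aware") -> ScoringPipeline:
    """Train one pipeline variant on a phantom cohort.

    Deterministic given the config seed.  The run log (per-epoch MAE and
    L_CR) is available on the returned estimator as ``log_``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if variant not in ("holistic", "segmented", "rank_aware"):
        raise ValueError(f"unknown variant {variant!r}")
    cfg = config or TrainConfig()
    loss = loss or LossConfig()
    lam = 0.0 if variant in ("holistic", "segmented") else loss.lambda_rank
    anterior = cohort[0].config.anterior_side
    if variant == "holistic":
        X = np.stack([whole_frame_input(ph.image) for ph in cohort])
        y = np.array([ph.gt_record.total for ph in cohort], dtype=float)
        score_range = (0, 24)
    else:
        X, y = cohort_crop_dataset(cohort)
        score_range = (0, 6)
    est = SegmentScoreRegressor(
        epochs=cfg.epochs, base_lr=cfg.base_lr,
        lr_decay_factor=cfg.lr_decay_factor,
        lr_decay_every=cfg.lr_decay_every, batch_size=cfg.batch_size,
        tau=loss.tau, lambda_rank=lam,
        augment=bool(cfg.augmentations), score_range=score_range,
        seed=cfg.seed)
    est.fit(X, y)
    return ScoringPipeline(variant=variant, estimator=est,
                           anterior_side=anterior)


def predict_aacs(estimator: SegmentScoreRegressor, image: np.ndarray,
                 vertebrae: VertebraSet, anterior_side: str = "left"
                 ) -> tuple[list[SegmentPrediction], AACSRecord]:
    """Score the four aortic segments of one radiograph and sum them."""
    crops, levels = segment_crops(image, vertebrae, anterior_side)
    raw = estimator.predict(crops)
    feats = estimator.features(crops)
    preds = [SegmentPrediction(level=lv, raw_score=float(r),
                               rounded_score=round_score(float(r)),
                               feature=feats[i])
             for i, (lv, r) in enumerate(zip(levels, raw))]
    record = total_aacs({p.level: p.rounded_score for p in preds})
    return preds, record


def ablation_variants() -> dict[str, dict]:
    """The three comparable configurations sharing backbone and schedule.

    ``holistic`` regresses the total score from the whole frame (no
    localization or segmentation); ``segmented`` adds landmark-driven
    aortic segmentation with a plain regression loss; ``rank_aware`` adds
    the contrastive rank-aware loss on top of ``segmented`` (identical
    forward pass, different training objective).
    """
    return {
        "holistic": {"variant": "holistic", "lambda_rank": 0.0},
        "segmented": {"variant": "segmented", "lambda_rank": 0.0},
        "rank_aware": {"variant": "rank_aware", "lambda_rank": 1.0},
    }


def constant_median_baseline(train_totals: Sequence[float],
                             test_totals: Sequence[float]) -> float:
    """Held-out MAE of always predicting the training-median total."""
    med = float(np.median(np.asarray(train_totals, dtype=float)))
    return float(np.mean(np.abs(np.asarray(test_totals, float) - med)))
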
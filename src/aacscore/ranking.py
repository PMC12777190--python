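"""Contrastive rank-aware loss for ordinal calcification scores.

Samples in a batch are aortic-segment feature vectors F_i with integer
Kauppila segment scores v_i (0-6).  For an anchor i and candidate positive
j, the negative set S_ij contains every other sample whose score distance
|v_i - v_k| (L1 on scores) strictly exceeds |v_i - v_j|: samples ranked
farther from the anchor than the positive.  Each ordered pair (i, j)
contributes an InfoNCE-style term

    -log  exp(sim(F_i, F_j)/tau) / sum_{k in {j} u S_ij} exp(sim(F_i, F_k)/tau)

with cosine similarity and temperature tau, and the loss averages over
anchors and positives: L_CR = 1/N sum_i 1/(N-1) sum_{j != i} term(i, j).
A pair with an empty negative set contributes exactly zero (the denominator
collapses to the numerator), which also makes L_CR identically zero for
N = 2.  The combined training objective adds L_CR, weighted by
lambda_rank, to the mean-absolute-error regression loss on the predicted
segment scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RankBatch:
    """Feature vectors paired with per-segment scores."""

    features: np.ndarray  # (N, D)
    scores: np.ndarray    # (N,) integers 0-6

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=float)
        s = np.asarray(self.scores)
        if f.ndim != 2 or f.shape[0] != s.shape[0]:
            raise ValueError("features must be (N, D) aligned with scores")
        if f.shape[0] < 2:
            raise ValueError("a rank batch needs N >= 2 samples")
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite feature values")
        object.__setattr__(self, "features", f)
        object.__setattr__(self, "scores", np.asarray(s, dtype=int))

    @property
    def n(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class LossConfig:
    tau: float = 0.1
    lambda_rank: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.lambda_rank < 0:
            raise ValueError("lambda_rank must be nonnegative")


def score_distance(score_i: int, score_j: int) -> int:
    """L1 distance between two segment scores."""
    return abs(int(score_i) - int(score_j))


def negative_set(batch: RankBatch, anchor: int, positive: int) -> set[int]:
    """Indices k != anchor with score_distance(anchor, k) > (anchor, positive)."""
    if anchor == positive:
        raise ValueError("anchor and positive must differ")
    d_pos = score_distance(batch.scores[anchor], batch.scores[positive])
    return {
        k for k in range(batch.n)
        if k != anchor
        and score_distance(batch.scores[anchor], batch.scores[k]) > d_pos
    }


def _unit_rows(features: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(features, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm feature vector: cosine undefined")
    return features / norms


def contrastive_rank_loss(batch: RankBatch, tau: float = 0.1) -> float:
    loss, _ = contrastive_rank_loss_and_grad(batch, tau)
    return loss


def contrastive_rank_loss_and_grad(batch: RankBatch, tau: float = 0.1
                                   ) -> tuple[float, np.ndarray]:
    """L_CR and its analytic gradient with respect to the raw features.

    The gradient flows through the cosine similarity (and hence through the
    row normalization), so scaling a feature vector leaves both the loss
    and the normalized gradient direction unchanged.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    f = batch.features
    n = batch.n
    scores = batch.scores
    norms = np.linalg.norm(f, axis=1)
    u = _unit_rows(f)
    cos = u @ u.T
    dist = np.abs(scores[:, None] - scores[None, :])

    weight = 1.0 / (n * (n - 1))
    loss = 0.0
    dcos = np.zeros((n, n))  # dL/dcos accumulated over pairs
    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            members = (dist[i] > dist[i, j])
            members[i] = False
            members[j] = True
            sims = cos[i, members] / tau
            m = sims.max()
            e = np.exp(sims - m)
            z = e.sum()
            p = e / z
            idx = np.flatnonzero(members)
            j_pos = int(np.searchsorted(idx, j))
            loss += weight * -(sims[j_pos] - m - np.log(z))
            dcos[i, idx] += weight * (p - (idx == j)) / tau

    a = dcos + dcos.T
    np.fill_diagonal(a, 0.0)
    row = (a * cos).sum(axis=1)
    grad = (a @ u - row[:, None] * u) / norms[:, None]
    return float(loss), grad


def combined_loss(predicted_scores: np.ndarray, true_scores: np.ndarray,
                  batch: RankBatch, config: LossConfig) -> float:
    """MAE regression loss + lambda_rank * L_CR."""
    pred = np.asarray(predicted_scores, dtype=float)
    true = np.asarray(true_scores, dtype=float)
    if pred.shape != true.shape:
        raise ValueError("prediction/target length mismatch")
    mae = float(np.mean(np.abs(pred - true)))
    if config.lambda_rank == 0:
        return mae
    return mae + config.lambda_rank * contrastive_rank_loss(batch, config.tau)
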
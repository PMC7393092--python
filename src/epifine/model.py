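"""Two-layer CNN with uncertainty-weighted loss for block classification.

The network treats an association block as a bag of SNPs (multiple-instance
learning).  Layer 1 applies K filters of length M to each SNP's binary
feature vector (a 1-D convolution with stride 1 over the SNP axis, i.e. a
shared dense map per SNP) followed by ReLU; layer 2 combines the K pattern
activations with a single weight vector and a sigmoid, yielding a per-SNP
score in (0, 1).  Max-pooling over the block's unmasked slots gives the
block score: the bag is positive if its best instance is.

Training minimizes

    LOSS = NLL + lambda1 * ||w||_1 + lambda2 * ||w||_2^2
    NLL  = -(1/B) * sum_m W_m * (Y_m log f_m + (1 - Y_m) log(1 - f_m))

where W_m is the block's uncertainty weight (tiered by minimum p-value for
true cases, 2 for controls) and f_m the max-pooled block score.  Penalties
cover both layers' weight vectors, not biases.  Optimization is mini-batch
gradient descent with momentum; filters may be initialized by a tied-weight
denoising autoencoder trained on individual SNP feature vectors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, roc_auc_score

from .blocks import SplitAssignment
from .features import FeatureTensor, concat_tensors

SCORE_EPS = 1e-7  # clamp for log safety inside the NLL


@dataclass
class ModelConfig:
    feature_dim: int
    n_filters: int = 50
    n_slots: int = 30
    lambda1: float = 0.02
    lambda2: float = 1e-3
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 100
    max_epochs: int = 1000
    patience: int = 50
    ae_corruption: float = 0.2
    ae_epochs: int = 50
    n_restarts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.feature_dim < 1 or self.batch_size < 1:
            raise ValueError("n_filters, feature_dim and batch_size must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if not 0.0 <= self.ae_corruption < 1.0:
            raise ValueError("ae_corruption must lie in [0, 1)")


@dataclass
class ModelParams:
    filter_bank: np.ndarray  # (K, M)
    filter_bias: np.ndarray  # (K,)
    combiner: np.ndarray  # (K,)
    combiner_bias: float

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.filter_bank.copy(),
            self.filter_bias.copy(),
            self.combiner.copy(),
            float(self.combiner_bias),
        )


@dataclass
class PredictionResult:
    per_snp_scores: np.ndarray  # (B, N), NaN where masked
    per_block_score: np.ndarray  # (B,)


@dataclass
class TrainReport:
    train_losses: list[float]
    val_losses: list[float]
    stopped_epoch: int
    best_epoch: int
    best_val_loss: float
    config: ModelConfig
    seed: int


def init_params(config: ModelConfig, seed: int | None = None) -> ModelParams:
    """Small random weight initialization with zero biases; seeded.

    The combiner starts nonnegative (half-normal) so that, with ReLU
    activations, a SNP's initial score grows with how strongly it matches
    the filter bank: max-pooling then selects pattern-rich SNPs from the
    first epoch instead of arbitrary slots, which markedly stabilizes
    optimization.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    k, m = config.n_filters, config.feature_dim
    return ModelParams(
        filter_bank=rng.normal(0.0, 0.1 / np.sqrt(m), size=(k, m)),
        filter_bias=np.zeros(k),
        combiner=np.abs(rng.normal(0.0, 0.1 / np.sqrt(k), size=k)),
        combiner_bias=0.0,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def pretrain_autoencoder(
    snp_vectors: np.ndarray, config: ModelConfig, seed: int | None = None
) -> np.ndarray:
    """Denoising-autoencoder pretraining of the first-layer filters.

    A tied-weight autoencoder encodes each binary SNP feature vector x
    through h = sigmoid(W x~ + b) — where x~ is x with entries zeroed
    independently at rate ``ae_corruption`` — and reconstructs
    x^ = sigmoid(W' h + c), minimizing elementwise cross-entropy against
    the uncorrupted x.  Returns the learned K x M encoder weights, used as
    the starting filter bank.
    """
    vec = np.asarray(snp_vectors, dtype=float)
    if vec.ndim != 2 or vec.shape[0] == 0:
        raise ValueError("snp_vectors must be a nonempty (n, M) array")
    n, m = vec.shape
    k = config.n_filters
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w = rng.normal(0.0, 0.1 / np.sqrt(m), size=(k, m))
    b = np.zeros(k)
    c = np.zeros(m)
    vw, vb, vc = np.zeros_like(w), np.zeros_like(b), np.zeros_like(c)
    lr, mom = config.learning_rate, config.momentum
    batch = min(config.batch_size, n)
    for _ in range(config.ae_epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            x = vec[order[start : start + batch]]
            keep = rng.random(x.shape) >= config.ae_corruption
            xt = x * keep
            h = _sigmoid(xt @ w.T + b)  # (b, K)
            xhat = _sigmoid(h @ w + c)  # (b, M)
            # cross-entropy gradient: d/dz = xhat - x
            dz2 = (xhat - x) / x.shape[0]
            dc = dz2.sum(axis=0)
            dh = dz2 @ w.T
            dz1 = dh * h * (1.0 - h)
            db = dz1.sum(axis=0)
            dw = dz1.T @ xt + h.T @ dz2  # tied weights: both paths contribute
            vw = mom * vw - lr * dw
            vb = mom * vb - lr * db
            vc = mom * vc - lr * dc
            w += vw
            b += vb
            c += vc
    return w


def reconstruction_loss(w: np.ndarray, snp_vectors: np.ndarray) -> float:
    """Cross-entropy reconstruction loss of the tied autoencoder (no corruption)."""
    x = np.asarray(snp_vectors, dtype=float)
    h = _sigmoid(x @ w.T)
    xhat = np.clip(_sigmoid(h @ w), SCORE_EPS, 1.0 - SCORE_EPS)
    return float(-(x * np.log(xhat) + (1 - x) * np.log(1 - xhat)).sum(axis=1).mean())


def _as_batch(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Promote a single (N, M) block to a (1, N, M) batch."""
    values = np.asarray(values)
    mask = np.asarray(mask).astype(bool)
    if values.ndim == 2:
        values = values[None]
        mask = mask[None] if mask.ndim == 1 else mask
    return values, mask


def _snp_scores(
    params: ModelParams, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slot scores s and hidden activations h for (B, N, M) inputs."""
    x = np.asarray(values, dtype=float)
    h = np.maximum(x @ params.filter_bank.T + params.filter_bias, 0.0)  # (B, N, K)
    s = _sigmoid(h @ params.combiner + params.combiner_bias)  # (B, N)
    return s, h


def forward(params: ModelParams, values: np.ndarray, mask: np.ndarray) -> PredictionResult:
    """Score each unmasked SNP slot and max-pool to block scores.

    Per-SNP score: sigmoid(combiner . ReLU(filter_bank . x + filter_bias)
    + combiner_bias); block score: max over the block's unmasked slots.
    """
    values, mask = _as_batch(values, mask)
    if values.shape[2] != params.filter_bank.shape[1]:
        raise ValueError(
            f"feature dim {values.shape[2]} != model dim {params.filter_bank.shape[1]}"
        )
    if not mask.any(axis=1).all():
        raise ValueError("every block needs at least one unmasked slot")
    s, _ = _snp_scores(params, values)
    per_snp = np.where(mask, s, np.nan)
    per_block = np.nanmax(per_snp, axis=1)
    return PredictionResult(per_snp_scores=per_snp, per_block_score=per_block)


def _penalty(params: ModelParams, config: ModelConfig) -> float:
    l1 = np.abs(params.filter_bank).sum() + np.abs(params.combiner).sum()
    l2 = (params.filter_bank**2).sum() + (params.combiner**2).sum()
    return float(config.lambda1 * l1 + config.lambda2 * l2)


def compute_loss(
    params: ModelParams,
    values: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    config: ModelConfig,
) -> float:
    """Uncertainty-weighted cross-entropy plus elastic-net penalty.

    Block scores are clamped to [1e-7, 1 - 1e-7] before the logarithm;
    penalties cover both layers' weights, never biases.
    """
    f = np.clip(
        forward(params, values, mask).per_block_score, SCORE_EPS, 1.0 - SCORE_EPS
    )
    y = np.asarray(labels, dtype=float)
    w = np.asarray(weights, dtype=float)
    nll = -(w * (y * np.log(f) + (1.0 - y) * np.log(1.0 - f))).mean()
    return float(nll + _penalty(params, config))


def loss_and_gradients(
    params: ModelParams,
    values: np.ndarray,
    mask: np.ndarray,
    labels: np.ndarray,
    weights: np.ndarray,
    config: ModelConfig,
) -> tuple[float, ModelParams]:
    """Loss plus analytic gradients (returned in a ModelParams container).

    Backpropagation routes each block's gradient through its max-pooled
    slot only; the L1 term contributes its subgradient sign(w).
    """
    x, mask = _as_batch(np.asarray(values, dtype=float), mask)
    y = np.asarray(labels, dtype=float)
    wts = np.asarray(weights, dtype=float)
    nb = x.shape[0]
    s, h = _snp_scores(params, x)
    s_masked = np.where(mask, s, -np.inf)
    jstar = np.argmax(s_masked, axis=1)  # (B,)
    f = s[np.arange(nb), jstar]
    fc = np.clip(f, SCORE_EPS, 1.0 - SCORE_EPS)
    nll = -(wts * (y * np.log(fc) + (1.0 - y) * np.log(1.0 - fc))).mean()
    loss = nll + _penalty(params, config)

    # dNLL/dz at the winning slot, z the pre-sigmoid score (standard
    # sigmoid-CE simplification, exact when f is inside the clamp range)
    dz = (wts / nb) * (f - y)  # (B,)
    h_star = h[np.arange(nb), jstar]  # (B, K)
    x_star = x[np.arange(nb), jstar]  # (B, M)
    d_comb = h_star.T @ dz
    d_cbias = float(dz.sum())
    dh = np.outer(dz, params.combiner) * (h_star > 0)  # (B, K), ReLU gate
    d_fb = dh.T @ x_star
    d_fbias = dh.sum(axis=0)

    d_fb += config.lambda1 * np.sign(params.filter_bank) + 2.0 * config.lambda2 * params.filter_bank
    d_comb += config.lambda1 * np.sign(params.combiner) + 2.0 * config.lambda2 * params.combiner
    return float(loss), ModelParams(d_fb, d_fbias, d_comb, d_cbias)


def _train_single(
    tr: FeatureTensor,
    va: FeatureTensor,
    config: ModelConfig,
    seed: int,
    pretrain: bool,
) -> tuple[ModelParams, TrainReport]:
    """One optimization run from one seeded initialization."""
    rng = np.random.default_rng(seed)
    params = init_params(config, seed)
    if pretrain and config.ae_epochs > 0:
        vectors, _ = tr.snp_vectors()
        params.filter_bank = pretrain_autoencoder(vectors, config, seed)

    x_tr = tr.values.astype(float)
    vel = ModelParams(
        np.zeros_like(params.filter_bank),
        np.zeros_like(params.filter_bias),
        np.zeros_like(params.combiner),
        0.0,
    )
    train_losses: list[float] = []
    val_losses: list[float] = []
    best_val = np.inf
    best_epoch = 0
    best_params = params.copy()
    epochs_without_improvement = 0
    stopped = config.max_epochs
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(tr.n_blocks)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, tr.n_blocks, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = loss_and_gradients(
                params, x_tr[idx], tr.mask[idx], tr.labels[idx], tr.weights[idx], config
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss = {loss}"
                )
            vel.filter_bank = config.momentum * vel.filter_bank - config.learning_rate * grads.filter_bank
            vel.filter_bias = config.momentum * vel.filter_bias - config.learning_rate * grads.filter_bias
            vel.combiner = config.momentum * vel.combiner - config.learning_rate * grads.combiner
            vel.combiner_bias = config.momentum * vel.combiner_bias - config.learning_rate * grads.combiner_bias
            params.filter_bank += vel.filter_bank
            params.filter_bias += vel.filter_bias
            params.combiner += vel.combiner
            params.combiner_bias += vel.combiner_bias
            epoch_loss += loss
            n_batches += 1
        train_losses.append(epoch_loss / n_batches)
        val_loss = compute_loss(params, va.values, va.mask, va.labels, va.weights, config)
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_epoch = epoch
            best_params = params.copy()
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= config.patience:
                stopped = epoch
                break
    else:
        stopped = config.max_epochs
    report = TrainReport(
        train_losses=train_losses,
        val_losses=val_losses,
        stopped_epoch=stopped,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        config=config,
        seed=seed,
    )
    return best_params, report


def train(
    true_tensor: FeatureTensor,
    control_tensor: FeatureTensor,
    config: ModelConfig,
    assignment: SplitAssignment | None = None,
    pretrain: bool = True,
) -> tuple[ModelParams, TrainReport]:
    """Train on the chromosome-based train split with early stopping.

    True and control blocks are merged and split by chromosome; batches mix
    both kinds uniformly at random each epoch (seeded).  Validation loss is
    monitored every epoch; each run stops after ``patience`` epochs without
    improvement.  ``n_restarts`` independent runs are launched from seeds
    derived from ``config.seed``, and the run with the lowest validation
    loss wins — restart selection on the held-out chromosomes, the same
    protocol used for hyperparameter choice.  Deterministic given the
    config.
    """
    merged = concat_tensors(true_tensor, control_tensor)
    tr, va, _ = merged.split(assignment)
    if tr.n_blocks == 0 or va.n_blocks == 0:
        raise ValueError("train and validation splits must be nonempty")
    n_restarts = max(1, config.n_restarts)
    seeds = [
        int(s) for s in
        np.random.SeedSequence(config.seed).generate_state(n_restarts) % (2**31)
    ]
    best: tuple[ModelParams, TrainReport] | None = None
    for seed in seeds:
        params, report = _train_single(tr, va, config, seed, pretrain)
        if best is None or report.best_val_loss < best[1].best_val_loss:
            best = (params, report)
    assert best is not None
    return best


def random_search(
    true_tensor: FeatureTensor,
    control_tensor: FeatureTensor,
    base_config: ModelConfig,
    param_space: dict[str, Sequence],
    n_trials: int = 10,
    assignment: SplitAssignment | None = None,
) -> tuple[ModelParams, TrainReport]:
    """Random hyperparameter search scored on the validation chromosomes.

    ``param_space`` maps ModelConfig field names to candidate values; each
    trial draws one value per field (seeded by ``base_config.seed``) and
    trains with a single restart.  Returns the best trial's parameters and
    report (its config echo records the winning settings).
    """
    rng = np.random.default_rng(base_config.seed)
    best: tuple[ModelParams, TrainReport] | None = None
    for trial in range(n_trials):
        overrides = {k: v[rng.integers(len(v))] for k, v in param_space.items()}
        cfg = replace(base_config, n_restarts=1, seed=int(rng.integers(2**31)), **overrides)
        params, report = train(true_tensor, control_tensor, cfg, assignment)
        if best is None or report.best_val_loss < best[1].best_val_loss:
            best = (params, report)
    assert best is not None
    return best


def evaluate(params: ModelParams, tensor: FeatureTensor) -> dict:
    """Block-level AUC and F1 at the fixed 0.5 threshold.

    AUC is the rank-based probability that a random true block outscores a
    random control block (ties count 1/2); true cases are the positive
    class.
    """
    y = np.asarray(tensor.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation requires both true and control blocks")
    scores = forward(params, tensor.values, tensor.mask).per_block_score
    pred = (scores > 0.5).astype(int)
    return {
        "auc": float(roc_auc_score(y, scores)),
        "f1": float(f1_score(y, pred, pos_label=1, zero_division=0.0)),
        "threshold": 0.5,
        "n_true": int((y == 1).sum()),
        "n_control": int((y == 0).sum()),
    }


def predict_snp_scores(params: ModelParams, tensor: FeatureTensor) -> pd.DataFrame:
    """Per-SNP prediction scores as a (block_id, snp_id, score, is_lead) table."""
    if tensor.n_blocks == 0:
        return pd.DataFrame(columns=["block_id", "snp_id", "score", "is_lead"])
    if tensor.n_features != params.filter_bank.shape[1]:
        raise ValueError(
            f"tensor has {tensor.n_features} features but model expects "
            f"{params.filter_bank.shape[1]}"
        )
    res = forward(params, tensor.values, tensor.mask)
    rows = []
    for b in range(tensor.n_blocks):
        for j in range(tensor.n_slots):
            if tensor.mask[b, j]:
                rows.append(
                    (
                        tensor.block_ids[b],
                        tensor.snp_ids[b][j],
                        float(res.per_snp_scores[b, j]),
                        bool(tensor.lead_mask[b, j]),
                    )
                )
    return pd.DataFrame(rows, columns=["block_id", "snp_id", "score", "is_lead"])


def save_checkpoint(
    path: str | Path,
    params: ModelParams,
    config: ModelConfig,
    feature_names: Sequence[str],
) -> None:
    """Portable JSON checkpoint: config echo, parameters, feature axis."""
    payload = {
        "config": asdict(config),
        "feature_names": list(feature_names),
        "params": {
            "filter_bank": params.filter_bank.tolist(),
            "filter_bias": params.filter_bias.tolist(),
            "combiner": params.combiner.tolist(),
            "combiner_bias": params.combiner_bias,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, list[str]]:
    payload = json.loads(Path(path).read_text())
    p = payload["params"]
    params = ModelParams(
        np.array(p["filter_bank"], dtype=float),
        np.array(p["filter_bias"], dtype=float),
        np.array(p["combiner"], dtype=float),
        float(p["combiner_bias"]),
    )
    return params, ModelConfig(**payload["config"]), payload["feature_names"]
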
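"""Training loop, best-epoch checkpointing and evaluation.

The loss is the per-cell sum of squared errors over the N proteins, averaged
over the cells of a batch (so its magnitude does not depend on batch size).
Training keeps the parameters of the epoch with the smallest epoch-level
training loss — a running-minimum checkpoint, not the final epoch; there is
no separate validation split.  Evaluation reports per-protein MSE and
Pearson correlation across test cells with mean/SD summaries, and the
best-of-k protocol selects, per protein, the minimum MSE and maximum PCC
across independently seeded runs (each metric independently).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor
from .model import ModelConfig, forward, forward_t, init_params

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "RunResult",
    "mse_loss",
    "train",
    "select_best_epoch",
    "predict_from_checkpoint",
    "compute_metrics",
    "evaluate",
    "best_of_runs",
    "ablate",
]


@dataclass
class TrainConfig:
    """Optimization hyperparameters (published defaults).

    epochs=350, batch_size=32, learning_rate=1e-6 with Adam.  ``seed`` drives
    parameter initialization and the per-epoch batch shuffle.
    """

    epochs: int = 350
    batch_size: int = 32
    learning_rate: float = 1e-6
    seed: int = 0
    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class Checkpoint:
    """Parameter snapshot of the best epoch seen so far."""

    params: dict[str, np.ndarray]
    epoch: int
    loss: float
    model_config: ModelConfig
    priors: np.ndarray | None = field(default=None, repr=False)
    seed: int | None = None

    def save(self, path) -> None:
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        if self.priors is not None:
            arrays["priors"] = self.priors
        meta = {
            "epoch": int(self.epoch),
            "loss": float(self.loss),
            "seed": self.seed,
            "model_config": self.model_config.to_dict(),
        }
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            params = {
                k[len("param::"):]: f[k] for k in f.files if k.startswith("param::")
            }
            priors = f["priors"] if "priors" in f.files else None
        return cls(
            params=params,
            epoch=meta["epoch"],
            loss=meta["loss"],
            model_config=ModelConfig.from_dict(meta["model_config"]),
            priors=priors,
            seed=meta.get("seed"),
        )


@dataclass
class RunResult:
    """Per-protein test metrics plus summaries over proteins.

    PCC for a protein that is constant across test cells (in truth or
    prediction) is undefined; it is stored as NaN and excluded from the
    mean/SD.  SDs use the sample (n-1) convention.
    """

    protein_ids: list[str]
    mse: np.ndarray
    pcc: np.ndarray
    checkpoint_epoch: int | None = None
    checkpoint_loss: float | None = None
    seed: int | None = None

    @property
    def mse_mean(self) -> float:
        return float(np.mean(self.mse))

    @property
    def mse_sd(self) -> float:
        return float(np.std(self.mse, ddof=1))

    @property
    def pcc_mean(self) -> float:
        return float(np.nanmean(self.pcc))

    @property
    def pcc_sd(self) -> float:
        return float(np.nanstd(self.pcc, ddof=1))


def mse_loss(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Per-cell sum of squared errors over proteins, averaged over cells."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.ndim == 1:
        y_true = y_true[None, :]
        y_pred = y_pred[None, :]
    return float(((y_pred - y_true) ** 2).sum(axis=1).mean())


def _mse_loss_t(y_true: np.ndarray, pred: Tensor) -> Tensor:
    diff = pred - Tensor(y_true)
    return (diff * diff).sum(axis=1).mean()


class _Adam:
    def __init__(self, params: dict[str, Tensor], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, params: dict[str, Tensor]) -> None:
        c = self.cfg
        self.t += 1
        for k, p in params.items():
            g = p.grad
            if g is None:
                continue
            if c.optimizer == "sgd":
                p.data -= c.learning_rate * g
                continue
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g**2
            m_hat = self.m[k] / (1 - c.beta1**self.t)
            v_hat = self.v[k] / (1 - c.beta2**self.t)
            p.data -= c.learning_rate * m_hat / (np.sqrt(v_hat) + c.eps)


def train(
    expr: np.ndarray,
    protein: np.ndarray,
    priors: np.ndarray | None,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[Checkpoint, list[float]]:
    """Optimize the model; return the best-epoch checkpoint and loss history.

    The checkpoint holds the parameters of the epoch with minimum epoch-level
    training loss (mean of batch losses), ties keeping the earlier epoch.
    Two calls with identical inputs and config are bit-identical.
    """
    x = np.asarray(expr, dtype=np.float64)
    y = np.asarray(protein, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError(f"inconsistent train matrices: {x.shape} vs {y.shape}")
    if x.shape[0] == 0:
        raise ValueError("training split is empty")
    if y.shape[1] != model_config.n_proteins:
        raise ValueError(
            f"protein matrix has {y.shape[1]} proteins, model expects "
            f"{model_config.n_proteins}"
        )
    train_config.validate()

    ss = np.random.SeedSequence(train_config.seed)
    init_rng, shuffle_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    params = init_params(model_config, init_rng)
    opt = _Adam(params, train_config)

    n_cells = x.shape[0]
    bs = min(train_config.batch_size, n_cells)
    best: Checkpoint | None = None
    history: list[float] = []
    priors_arr = None if priors is None else np.asarray(priors, dtype=np.float64)

    for epoch in range(train_config.epochs):
        order = shuffle_rng.permutation(n_cells)
        batch_losses = []
        for start in range(0, n_cells, bs):
            idx = order[start : start + bs]
            pred = forward_t(x[idx], params, model_config, priors_arr)
            loss = _mse_loss_t(y[idx], pred)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch {start // bs + 1}"
                )
            for p in params.values():
                p.grad = None
            loss.backward()
            opt.step(params)
            batch_losses.append(float(loss.data))
        epoch_loss = float(np.mean(batch_losses))
        history.append(epoch_loss)
        if best is None or epoch_loss < best.loss:
            best = Checkpoint(
                params={k: p.data.copy() for k, p in params.items()},
                epoch=epoch,
                loss=epoch_loss,
                model_config=model_config,
                priors=priors_arr,
                seed=train_config.seed,
            )
    return best, history


def select_best_epoch(history: Sequence[float]) -> int:
    """Index of the minimum epoch loss; ties keep the earliest epoch."""
    if len(history) == 0:
        raise ValueError("empty loss history")
    return int(np.argmin(history))


def predict_from_checkpoint(ckpt: Checkpoint, expr: np.ndarray) -> np.ndarray:
    """Deterministic prediction of a cells x N abundance matrix."""
    x = np.asarray(expr, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != ckpt.model_config.n_genes:
        raise ValueError(
            f"gene dimension mismatch: checkpoint expects "
            f"{ckpt.model_config.n_genes} genes, input has "
            f"{x.shape[1] if x.ndim == 2 else 'non-matrix'}"
        )
    params = {k: Tensor(v) for k, v in ckpt.params.items()}
    return forward(x, params, ckpt.model_config, ckpt.priors)


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    protein_ids: Sequence[str] | None = None,
) -> RunResult:
    """Per-protein MSE (mean over cells) and Pearson correlation across cells."""
    y = np.asarray(y_true, dtype=np.float64)
    pred = np.asarray(y_pred, dtype=np.float64)
    if pred.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {pred.shape}, truth {y.shape}")
    n = y.shape[1]
    ids = list(protein_ids) if protein_ids is not None else [f"P{i}" for i in range(n)]
    mse = ((pred - y) ** 2).mean(axis=0)
    pcc = np.full(n, np.nan)
    for i in range(n):
        if np.std(y[:, i]) == 0 or np.std(pred[:, i]) == 0:
            warnings.warn(
                f"protein {ids[i]} is constant across test cells; "
                "PCC undefined and excluded from summaries"
            )
            continue
        pcc[i] = np.corrcoef(y[:, i], pred[:, i])[0, 1]
    return RunResult(protein_ids=ids, mse=mse, pcc=pcc)


def evaluate(
    ckpt: Checkpoint,
    expr: np.ndarray,
    protein: np.ndarray,
    protein_ids: Sequence[str] | None = None,
) -> RunResult:
    """Per-protein MSE and Pearson correlation on a held-out split."""
    y = np.asarray(protein, dtype=np.float64)
    if y.shape[0] == 0:
        raise ValueError("test split is empty")
    pred = predict_from_checkpoint(ckpt, expr)
    result = compute_metrics(y, pred, protein_ids)
    result.checkpoint_epoch = ckpt.epoch
    result.checkpoint_loss = ckpt.loss
    result.seed = ckpt.seed
    return result


def best_of_runs(results: Sequence[RunResult], k: int | None = None) -> RunResult:
    """Per protein, minimum MSE and maximum PCC across runs, independently."""
    results = list(results)
    if not results:
        raise ValueError("best_of_runs needs at least one result")
    if k is not None and len(results) != k:
        raise ValueError(f"expected {k} runs, got {len(results)}")
    ids = results[0].protein_ids
    for r in results:
        if r.protein_ids != ids:
            raise ValueError("all runs must score the same proteins")
    mse = np.min(np.stack([r.mse for r in results]), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        pcc = np.nanmax(np.stack([r.pcc for r in results]), axis=0)
    return RunResult(protein_ids=list(ids), mse=mse, pcc=pcc)


def ablate(
    expr_train: np.ndarray,
    protein_train: np.ndarray,
    expr_test: np.ndarray,
    protein_test: np.ndarray,
    priors: np.ndarray,
    feature_names: Sequence[str],
    model_config: ModelConfig,
    train_config: TrainConfig,
    repeats: int = 5,
    protein_ids: Sequence[str] | None = None,
) -> list[dict]:
    """Prior-knowledge ablation: no prior, each channel alone, all merged.

    Each condition is trained ``repeats`` times with distinct seeds; per
    condition the summary is the midpoint between the maximum and minimum of
    the run scores (mean PCC and mean MSE over proteins) plus the half-range
    (max minus midpoint).
    """
    priors = np.asarray(priors, dtype=np.float64)
    conditions: list[tuple[str, np.ndarray | None]] = [("no_prior", None)]
    conditions += [
        (name, priors[i : i + 1]) for i, name in enumerate(feature_names)
    ]
    conditions.append(("merged", priors))

    rows = []
    for name, sub in conditions:
        cfg = ModelConfig.from_dict(
            {
                **model_config.to_dict(),
                "use_prior": sub is not None,
                "n_prior_features": 1 if sub is None else sub.shape[0],
            }
        )
        pccs, mses = [], []
        for r in range(repeats):
            tc = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + r})
            ckpt, _ = train(expr_train, protein_train, sub, cfg, tc)
            res = evaluate(ckpt, expr_test, protein_test, protein_ids)
            pccs.append(res.pcc_mean)
            mses.append(res.mse_mean)
        pccs, mses = np.asarray(pccs), np.asarray(mses)
        rows.append(
            {
                "condition": name,
                "pcc_mid": float((pccs.max() + pccs.min()) / 2),
                "pcc_half_range": float(pccs.max() - (pccs.max() + pccs.min()) / 2),
                "mse_mid": float((mses.max() + mses.min()) / 2),
                "mse_half_range": float(mses.max() - (mses.max() + mses.min()) / 2),
                "n_runs": repeats,
            }
        )
    return rows
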
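"""The RNA-to-protein graph neural network.

Per cell, the forward pass is

1. RNA encoder: two fully-connected layers G -> h1 -> h2 (defaults 1024, 128)
   with a PReLU(0.25) between them, giving the cell's RNA representation;
2. per-protein heads: N independent affine maps h2 -> d_r, one protein
   feature vector each (rows of V_r);
3. node construction: node i is the concatenation of its head output with
   row i of the fixed knowledge embedding V_k, so the node matrix V is
   N x d with d = d_r + d_k;
4. graph propagation: one round V^e = sigmoid(A V W) with a trainable dense
   adjacency A (N x N) and relation matrix W (d x d);
5. predictor: a single affine map d -> 1 applied to every node row, passed
   through PReLU with fixed negative slope 0.25 so that predicted (CLR-like,
   log-scale) abundances can be negative.

The adjacency is not masked, normalized or given self-loops by default; an
optional 0/1 mask restricting its support to prior edges is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import numpy as np

from ._autodiff import Tensor, concat
from .knowledge import init_knowledge_params, knowledge_embedding_t

__all__ = [
    "ModelConfig",
    "prelu",
    "init_params",
    "forward",
    "forward_t",
    "encode_rna",
    "build_nodes",
    "propagate",
    "predict_abundance",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the published setting: encoder hidden sizes 1024/128,
    d_r = 64, d_c = 32, PReLU slope 0.25, dense trainable adjacency, one
    shared d -> 1 predictor, knowledge column-encoders shared across the M
    prior channels.
    """

    n_genes: int
    n_proteins: int
    n_prior_features: int = 5
    hidden: tuple[int, int] = (1024, 128)
    d_r: int = 64
    d_c: int = 32
    prelu_slope: float = 0.25
    use_prior: bool = True
    share_encoders: bool = True
    per_protein_predictor: bool = False
    adjacency_mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def d_k(self) -> int:
        """Knowledge-embedding width d_k = N * d_c (0 when priors are off)."""
        return self.n_proteins * self.d_c if self.use_prior else 0

    @property
    def d(self) -> int:
        """Node width d = d_r + d_k."""
        return self.d_r + self.d_k

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        if min(self.n_genes, self.d_r, self.d_c, *self.hidden) < 1:
            raise ValueError("all layer sizes must be positive")
        if self.use_prior and self.n_prior_features < 1:
            raise ValueError("use_prior requires at least one prior feature")
        if self.adjacency_mask is not None:
            mask = np.asarray(self.adjacency_mask)
            if mask.shape != (self.n_proteins, self.n_proteins):
                raise ValueError("adjacency_mask must be N x N")

    def to_dict(self) -> dict:
        out = asdict(self)
        mask = out.pop("adjacency_mask")
        out["adjacency_mask"] = None if mask is None else np.asarray(mask).tolist()
        out["hidden"] = list(self.hidden)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["hidden"] = tuple(d["hidden"])
        if d.get("adjacency_mask") is not None:
            d["adjacency_mask"] = np.asarray(d["adjacency_mask"], dtype=float)
        return cls(**d)


def prelu(x, slope: float = 0.25):
    """Parametric ReLU: x for x >= 0, slope * x otherwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, slope * x)
    return out.item() if out.ndim == 0 else out


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    """Seeded fan-in-scaled uniform initialization of every trainable tensor."""
    config.validate()
    g, n = config.n_genes, config.n_proteins
    h1, h2 = config.hidden
    d = config.d

    def t(arr):
        return Tensor(arr, requires_grad=True)

    params = {
        "enc1_W": t(_uniform(rng, (g, h1), g)),
        "enc1_b": t(_uniform(rng, (h1,), g)),
        "enc2_W": t(_uniform(rng, (h1, h2), h1)),
        "enc2_b": t(_uniform(rng, (h2,), h1)),
        # N independent heads h2 -> d_r, stored as one block-diagonal-free map
        "heads_W": t(_uniform(rng, (h2, n * config.d_r), h2)),
        "heads_b": t(_uniform(rng, (n * config.d_r,), h2)),
        "A": t(_uniform(rng, (n, n), n)),
        "W": t(_uniform(rng, (d, d), d)),
    }
    if config.per_protein_predictor:
        params["out_W"] = t(_uniform(rng, (n, d), d))
        params["out_b"] = t(_uniform(rng, (n,), d))
    else:
        params["out_W"] = t(_uniform(rng, (d, 1), d))
        params["out_b"] = t(_uniform(rng, (1,), d))
    if config.use_prior:
        params.update(
            init_knowledge_params(
                n, config.d_c, config.n_prior_features, rng, config.share_encoders
            )
        )
    return params


# ---------------------------------------------------------------------------
# differentiable forward pass
# ---------------------------------------------------------------------------


def forward_t(
    expr_batch: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    priors: np.ndarray | None = None,
) -> Tensor:
    """Forward pass of a B x G batch to B x N predicted abundances."""
    x = np.asarray(expr_batch, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != config.n_genes:
        raise ValueError(
            f"expected batch of shape (B, {config.n_genes}), got {x.shape}"
        )
    b = x.shape[0]
    n, slope = config.n_proteins, config.prelu_slope

    h = (Tensor(x) @ params["enc1_W"] + params["enc1_b"]).prelu(slope)
    rep = h @ params["enc2_W"] + params["enc2_b"]

    vr = (rep @ params["heads_W"] + params["heads_b"]).reshape(b, n, config.d_r)

    if config.use_prior:
        if priors is None:
            raise ValueError("model was configured with priors but none were given")
        vk = knowledge_embedding_t(priors, params)
        vk_b = vk.reshape(1, n, config.d_k).broadcast_to((b, n, config.d_k))
        nodes = concat([vr, vk_b], axis=2)
    else:
        nodes = vr

    a = params["A"]
    if config.adjacency_mask is not None:
        a = a * Tensor(np.asarray(config.adjacency_mask, dtype=np.float64))
    ve = (a @ nodes @ params["W"]).sigmoid()

    if config.per_protein_predictor:
        y = (ve * params["out_W"]).sum(axis=2) + params["out_b"]
    else:
        y = (ve @ params["out_W"]).reshape(b, n) + params["out_b"]
    return y.prelu(slope)


def forward(
    expr_batch: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Non-differentiable forward pass (same computation as :func:`forward_t`)."""
    return forward_t(expr_batch, params, config, priors).data


# ---------------------------------------------------------------------------
# stand-alone stage functions (numpy in, numpy out)
# ---------------------------------------------------------------------------


def encode_rna(
    expr_batch: np.ndarray,
    w1: np.ndarray,
    b1: np.ndarray,
    w2: np.ndarray,
    b2: np.ndarray,
    slope: float = 0.25,
) -> np.ndarray:
    """Two-layer RNA encoder: B x G -> B x h2, PReLU between the layers."""
    x = np.asarray(expr_batch, dtype=np.float64)
    if x.shape[1] != np.asarray(w1).shape[0]:
        raise ValueError(
            f"gene dimension mismatch: batch has {x.shape[1]}, "
            f"encoder expects {np.asarray(w1).shape[0]}"
        )
    return prelu(x @ w1 + b1, slope) @ w2 + b2


def build_nodes(
    rep: np.ndarray,
    heads_w: np.ndarray,
    heads_b: np.ndarray,
    vk: np.ndarray,
) -> np.ndarray:
    """Assemble B node matrices (N x d): per-protein head output ⊕ V_k row.

    ``heads_w`` is h2 x (N * d_r) holding N independent affine maps; ``vk``
    (N x d_k) is broadcast across cells, so within one forward pass columns
    d_r+1..d are identical for every cell.
    """
    rep = np.asarray(rep, dtype=np.float64)
    b = rep.shape[0]
    heads_w = np.asarray(heads_w, dtype=np.float64)
    vk = np.asarray(vk, dtype=np.float64)
    n = vk.shape[0]
    if heads_w.shape[1] % n:
        raise ValueError(
            f"head output width {heads_w.shape[1]} is not divisible by "
            f"the {n} proteins of the knowledge embedding"
        )
    vr = rep @ heads_w + np.asarray(heads_b, dtype=np.float64)
    vr = vr.reshape(b, n, heads_w.shape[1] // n)
    vk_b = np.broadcast_to(vk, (b, *vk.shape))
    return np.concatenate([vr, vk_b], axis=2)


def propagate(nodes: np.ndarray, adjacency: np.ndarray, relation: np.ndarray) -> np.ndarray:
    """One graph-propagation round, sigmoid(A V W); output in (0, 1)."""
    v = np.asarray(nodes, dtype=np.float64)
    a = np.asarray(adjacency, dtype=np.float64)
    w = np.asarray(relation, dtype=np.float64)
    n, d = v.shape[-2], v.shape[-1]
    if a.shape != (n, n) or w.shape != (d, d):
        raise ValueError(
            f"non-conforming shapes: A {a.shape}, V {v.shape}, W {w.shape}"
        )
    return 1.0 / (1.0 + np.exp(-(a @ v @ w)))


def predict_abundance(
    nodes_e: np.ndarray, out_w: np.ndarray, out_b: np.ndarray, slope: float = 0.25
) -> np.ndarray:
    """Predictor: affine d -> 1 per node row, then PReLU; length-N output."""
    v = np.asarray(nodes_e, dtype=np.float64)
    out_w = np.asarray(out_w, dtype=np.float64).reshape(-1)
    if v.shape[-1] != out_w.shape[0]:
        raise ValueError(
            f"node width {v.shape[-1]} does not match predictor input {out_w.shape[0]}"
        )
    return prelu(v @ out_w + np.asarray(out_b, dtype=np.float64), slope)
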
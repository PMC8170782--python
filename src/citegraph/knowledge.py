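"""Prior-knowledge embedding of protein–protein association scores.

M prior-feature channels (e.g. STRING evidence channels: experimental,
database, text mining, combined score, co-occurrence) each give a symmetric
N x N score matrix over the N target proteins.  The embedding turns them into
one fixed matrix ``V_k`` with one d_k-dimensional row per protein:

1. *encoding* — each of the N columns of a channel matrix is passed through
   each of N shared single-layer affine networks (N -> d_c), producing an
   N x N x d_c tensor per channel;
2. *attention merge* — channels are combined with softmax attention weights
   (one scalar per channel, from the mean elu of its encoded tensor), a
   per-channel d_c x d_c mixing matrix, a 1/M average, and a final elu;
3. *per-protein re-weighting* — the merged tensor is split into N blocks
   (N x d_c, one per protein), each re-scaled by a softmax attention weight
   over proteins, mixed by a per-protein d_c x d_c matrix and elu-activated;
4. *concatenation* — the N blocks are concatenated column-wise into
   ``V_k`` of shape N x (N * d_c), so d_k = N * d_c.

Attention coefficients are computed from the blocks *before* re-weighting,
which keeps the per-protein step a single, well-defined pass.

All functions exist in two flavours: a differentiable one over
:class:`~citegraph._autodiff.Tensor` (suffix ``_t``) used inside training,
and a plain-numpy wrapper with the same math for direct use and testing.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, concat, softmax, stack

__all__ = [
    "elu",
    "init_knowledge_params",
    "encode_features",
    "attention_merge",
    "reweight_per_protein",
    "concat_embedding",
    "knowledge_embedding",
    "save_embedding",
    "load_embedding",
]


def elu(x):
    """Exponential linear unit: x for x >= 0, exp(x) - 1 otherwise."""
    x = np.asarray(x, dtype=np.float64)
    out = np.where(x >= 0, x, np.expm1(x))
    return out.item() if out.ndim == 0 else out


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def init_knowledge_params(
    n_proteins: int,
    d_c: int,
    n_features: int,
    rng: np.random.Generator,
    share_encoders: bool = True,
) -> dict[str, Tensor]:
    """Seeded random initialization of all knowledge-embedding weights.

    ``enc_W[p]`` / ``enc_b[p]`` is the p-th column-encoder network (N -> d_c);
    with ``share_encoders=False`` a separate set of N encoders is kept per
    prior channel.  ``W_a[i]`` mixes channel i during the attention merge and
    ``W_k[j]`` mixes protein j's block during re-weighting (both d_c x d_c).
    """
    n, m = n_proteins, n_features
    enc_shape = (n, d_c, n) if share_encoders else (m, n, d_c, n)
    bias_shape = (n, d_c) if share_encoders else (m, n, d_c)
    params = {
        "enc_W": Tensor(_uniform_init(rng, enc_shape, n), requires_grad=True),
        "enc_b": Tensor(_uniform_init(rng, bias_shape, n), requires_grad=True),
        "W_a": Tensor(_uniform_init(rng, (m, d_c, d_c), d_c), requires_grad=True),
        "W_k": Tensor(_uniform_init(rng, (n, d_c, d_c), d_c), requires_grad=True),
    }
    return params


# ---------------------------------------------------------------------------
# differentiable pipeline
# ---------------------------------------------------------------------------


def encode_features_t(priors: np.ndarray, params: dict[str, Tensor]) -> list[Tensor]:
    """Encode M prior matrices into M tensors of shape N x N x d_c.

    ``out[i][p, q, :] = enc_W[p] @ priors[i][:, q] + enc_b[p]`` — network p
    applied to column q of channel i.
    """
    priors = np.asarray(priors, dtype=np.float64)
    if priors.ndim != 3 or priors.shape[1] != priors.shape[2]:
        raise ValueError(f"priors must be M x N x N, got {priors.shape}")
    m, n, _ = priors.shape
    enc_w, enc_b = params["enc_W"], params["enc_b"]
    shared = enc_w.ndim == 3
    if (enc_w.shape[-1] != n) or (not shared and enc_w.shape[0] != m):
        raise ValueError(
            f"encoder weights {enc_w.shape} do not match priors {priors.shape}"
        )
    encoded = []
    for i in range(m):
        w_i = enc_w if shared else enc_w[i]
        b_i = enc_b if shared else enc_b[i]
        # (N, d_c, N) @ (N, N) -> (N, d_c, N); entry [p, :, q] = W_p @ C[:, q]
        raw = w_i @ Tensor(priors[i]) + b_i.reshape(n, -1, 1)
        encoded.append(raw.transpose(0, 2, 1))
    return encoded


def attention_merge_t(
    encoded: Sequence[Tensor], w_a: Tensor
) -> tuple[Tensor, Tensor]:
    """Merge M encoded channels into one N x N x d_c tensor.

    Returns ``(merged, coefficients)``; coefficients are a softmax over the M
    channels of the mean elu of each encoded tensor, and the merge is
    ``elu((1/M) * sum_i a_i * (encoded_i @ W_a[i]))``.
    """
    m = len(encoded)
    if m == 0:
        raise ValueError("need at least one encoded prior feature")
    if w_a.shape[0] != m:
        raise ValueError(f"W_a has {w_a.shape[0]} channel matrices, need {m}")
    scores = stack([t.elu().mean() for t in encoded])
    coeffs = softmax(scores)
    total = None
    for i in range(m):
        term = coeffs[i] * (encoded[i] @ w_a[i])
        total = term if total is None else total + term
    merged = (total * (1.0 / m)).elu()
    return merged, coeffs


def reweight_per_protein_t(
    merged: Tensor, w_k: Tensor
) -> tuple[list[Tensor], Tensor]:
    """Split the merged tensor into N per-protein blocks and re-weight them.

    Block j is ``merged[j]`` (N x d_c).  Attention over proteins is a softmax
    of the mean elu of each block; block j becomes
    ``elu(a_j * (block_j @ W_k[j]))``.
    """
    n = merged.shape[0]
    if w_k.shape[0] != n:
        raise ValueError(f"W_k has {w_k.shape[0]} matrices, need {n}")
    blocks = [merged[j] for j in range(n)]
    scores = stack([b.elu().mean() for b in blocks])
    coeffs = softmax(scores)
    out = [(coeffs[j] * (blocks[j] @ w_k[j])).elu() for j in range(n)]
    return out, coeffs


def concat_embedding_t(blocks: Sequence[Tensor]) -> Tensor:
    """Column-wise concatenation of N blocks (N x d_c) into V_k (N x N*d_c)."""
    n = len(blocks)
    for b in blocks:
        if b.shape != blocks[0].shape:
            raise ValueError("all re-weighted blocks must share one shape")
        if b.shape[0] != n:
            raise ValueError(
                f"expected {n} blocks of {n} rows, got block shape {b.shape}"
            )
    return concat(blocks, axis=1)


def knowledge_embedding_t(priors: np.ndarray, params: dict[str, Tensor]) -> Tensor:
    """Full pipeline: encode, attention-merge, re-weight, concatenate."""
    encoded = encode_features_t(priors, params)
    merged, _ = attention_merge_t(encoded, params["W_a"])
    blocks, _ = reweight_per_protein_t(merged, params["W_k"])
    return concat_embedding_t(blocks)


# ---------------------------------------------------------------------------
# plain-numpy wrappers
# ---------------------------------------------------------------------------


def encode_features(priors: np.ndarray, params: dict[str, Tensor]) -> list[np.ndarray]:
    return [t.data for t in encode_features_t(priors, params)]


def attention_merge(
    encoded: Sequence[np.ndarray], w_a
) -> tuple[np.ndarray, np.ndarray]:
    merged, coeffs = attention_merge_t(
        [Tensor(e) for e in encoded], Tensor(np.asarray(w_a, dtype=np.float64))
    )
    return merged.data, coeffs.data


def reweight_per_protein(merged, w_k) -> tuple[list[np.ndarray], np.ndarray]:
    blocks, coeffs = reweight_per_protein_t(
        Tensor(np.asarray(merged, dtype=np.float64)),
        Tensor(np.asarray(w_k, dtype=np.float64)),
    )
    return [b.data for b in blocks], coeffs.data


def concat_embedding(blocks: Sequence[np.ndarray]) -> np.ndarray:
    return concat_embedding_t([Tensor(b) for b in blocks]).data


def knowledge_embedding(priors: np.ndarray, params: dict[str, Tensor]) -> np.ndarray:
    return knowledge_embedding_t(priors, params).data


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------


def save_embedding(
    path,
    matrix: np.ndarray,
    d_c: int,
    feature_names: Sequence[str],
) -> None:
    """Write V_k plus a self-describing header (N, d_c, feature names) to .npz."""
    matrix = np.asarray(matrix, dtype=np.float64)
    meta = {
        "n_proteins": int(matrix.shape[0]),
        "d_c": int(d_c),
        "feature_names": list(feature_names),
    }
    np.savez(path, matrix=matrix, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8))


def load_embedding(path) -> tuple[np.ndarray, dict]:
    with np.load(path) as f:
        matrix = f["matrix"]
        meta = json.loads(bytes(f["meta"]).decode())
    if matrix.shape != (meta["n_proteins"], meta["n_proteins"] * meta["d_c"]):
        raise ValueError("embedding matrix shape disagrees with its header")
    return matrix, meta
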
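"""Independent straight-line transcription of the model equations.

Everything here is written with explicit Python loops and scalar math on raw
numpy weight arrays — no code is shared with the package's vectorized,
autodiff-based implementation.  It serves as the oracle for the end-to-end
forward-pass equivalence tests.
"""

import math

import numpy as np


def elu_s(x: float) -> float:
    return x if x >= 0 else math.exp(x) - 1.0


def prelu_s(x: float, slope: float = 0.25) -> float:
    return x if x >= 0 else slope * x


def sigmoid_s(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def oracle_knowledge_embedding(priors, enc_w, enc_b, w_a, w_k):
    """V_k from M prior matrices: encode, attention-merge, re-weight, concat."""
    m, n, _ = priors.shape
    d_c = enc_w.shape[1]

    # encoding: network p applied to column q of channel i
    encoded = np.zeros((m, n, n, d_c))
    for i in range(m):
        for p in range(n):
            for q in range(n):
                for r in range(d_c):
                    acc = enc_b[p][r]
                    for s in range(n):
                        acc += enc_w[p][r][s] * priors[i][s][q]
                    encoded[i][p][q][r] = acc

    # channel attention: softmax over channels of the mean elu
    scores = []
    for i in range(m):
        total = 0.0
        for p in range(n):
            for q in range(n):
                for r in range(d_c):
                    total += elu_s(encoded[i][p][q][r])
        scores.append(total / (n * n * d_c))
    denom = sum(math.exp(s) for s in scores)
    a_c = [math.exp(s) / denom for s in scores]

    # merge: elu of the 1/M-weighted sum of a_i * (encoded_i mixed by W_a[i])
    merged = np.zeros((n, n, d_c))
    for p in range(n):
        for q in range(n):
            for r in range(d_c):
                acc = 0.0
                for i in range(m):
                    mixed = 0.0
                    for s in range(d_c):
                        mixed += encoded[i][p][q][s] * w_a[i][s][r]
                    acc += a_c[i] * mixed
                merged[p][q][r] = elu_s(acc / m)

    # per-protein attention from the pre-weighting blocks
    block_scores = []
    for j in range(n):
        total = 0.0
        for q in range(n):
            for r in range(d_c):
                total += elu_s(merged[j][q][r])
        block_scores.append(total / (n * d_c))
    denom = sum(math.exp(s) for s in block_scores)
    a_k = [math.exp(s) / denom for s in block_scores]

    blocks = np.zeros((n, n, d_c))
    for j in range(n):
        for q in range(n):
            for r in range(d_c):
                mixed = 0.0
                for s in range(d_c):
                    mixed += merged[j][q][s] * w_k[j][s][r]
                blocks[j][q][r] = elu_s(a_k[j] * mixed)

    # concatenation: row i of V_k is block_1[i] ⊕ ... ⊕ block_N[i]
    vk = np.zeros((n, n * d_c))
    for i in range(n):
        col = 0
        for j in range(n):
            for r in range(d_c):
                vk[i][col] = blocks[j][i][r]
                col += 1
    return vk


def oracle_forward(x, priors, weights, d_r, d_c, slope=0.25):
    """Full forward pass for a B x G batch, loop by loop.

    ``weights`` maps the package's parameter names to raw numpy arrays.
    """
    b, g = x.shape
    n = priors.shape[1]
    vk = oracle_knowledge_embedding(
        priors, weights["enc_W"], weights["enc_b"], weights["W_a"], weights["W_k"]
    )
    d_k = n * d_c
    d = d_r + d_k

    w1, b1 = weights["enc1_W"], weights["enc1_b"]
    w2, b2 = weights["enc2_W"], weights["enc2_b"]
    h1, h2 = w1.shape[1], w2.shape[1]

    out = np.zeros((b, n))
    for c in range(b):
        # two-layer encoder with PReLU between the layers
        hid = [
            prelu_s(sum(x[c][i] * w1[i][j] for i in range(g)) + b1[j], slope)
            for j in range(h1)
        ]
        rep = [
            sum(hid[i] * w2[i][j] for i in range(h1)) + b2[j] for j in range(h2)
        ]

        # per-protein heads, then node rows v_i = v_r_i ⊕ v_k_i
        nodes = np.zeros((n, d))
        for i in range(n):
            for r in range(d_r):
                col = i * d_r + r
                nodes[i][r] = (
                    sum(rep[s] * weights["heads_W"][s][col] for s in range(h2))
                    + weights["heads_b"][col]
                )
            for r in range(d_k):
                nodes[i][d_r + r] = vk[i][r]

        # one propagation round: sigmoid(A V W)
        av = np.zeros((n, d))
        for i in range(n):
            for j in range(d):
                av[i][j] = sum(
                    weights["A"][i][s] * nodes[s][j] for s in range(n)
                )
        ve = np.zeros((n, d))
        for i in range(n):
            for j in range(d):
                ve[i][j] = sigmoid_s(
                    sum(av[i][s] * weights["W"][s][j] for s in range(d))
                )

        # shared predictor d -> 1, PReLU output
        for i in range(n):
            z = (
                sum(ve[i][s] * weights["out_W"][s][0] for s in range(d))
                + weights["out_b"][0]
            )
            out[c][i] = prelu_s(z, slope)
    return out
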
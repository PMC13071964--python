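"""Independent brute-force reference implementations used by the tests.

These are written against the mathematical definitions directly (explicit
loops over batch, rows, columns and heads) and share no code with the
vectorized modules they check.
"""

import numpy as np


def softmax_1d(v):
    e = np.exp(v - v.max())
    return e / e.sum()


def ada_reference(x, w_qkv, b_qkv, w_proj, b_proj, heads):
    """Nested-loop axial decomposed attention.

    x: (B, H, W, C); w_qkv: (C, 3C); w_proj: (2C, C).
    The temporal branch attends across W within each frequency row, the
    frequency branch across H within each time column; both scaled by
    1/sqrt(d_k); outputs concatenated on channels and projected to C.
    """
    b, hh, ww, c = x.shape
    d = c // heads
    scale = 1.0 / np.sqrt(d)
    qkv = x @ w_qkv + b_qkv
    q, k, v = qkv[..., :c], qkv[..., c : 2 * c], qkv[..., 2 * c :]

    score_t = np.zeros_like(q)
    for bi in range(b):
        for h in range(hh):
            for m in range(heads):
                sl = slice(m * d, (m + 1) * d)
                for i in range(ww):
                    logits = np.array(
                        [scale * q[bi, h, i, sl] @ k[bi, h, j, sl] for j in range(ww)]
                    )
                    weights = softmax_1d(logits)
                    score_t[bi, h, i, sl] = sum(
                        weights[j] * v[bi, h, j, sl] for j in range(ww)
                    )

    score_f = np.zeros_like(q)
    for bi in range(b):
        for w in range(ww):
            for m in range(heads):
                sl = slice(m * d, (m + 1) * d)
                for i in range(hh):
                    logits = np.array(
                        [scale * q[bi, i, w, sl] @ k[bi, j, w, sl] for j in range(hh)]
                    )
                    weights = softmax_1d(logits)
                    score_f[bi, i, w, sl] = sum(
                        weights[j] * v[bi, j, w, sl] for j in range(hh)
                    )

    fused = np.concatenate([score_t, score_f], axis=-1)
    return fused @ w_proj + b_proj


def standard_mha_reference(tokens, w_qkv, b_qkv, heads):
    """Plain multi-head self-attention over a token sequence (N, C); returns
    the pre-projection attention output (N, C)."""
    n, c = tokens.shape
    d = c // heads
    scale = 1.0 / np.sqrt(d)
    qkv = tokens @ w_qkv + b_qkv
    q, k, v = qkv[:, :c], qkv[:, c : 2 * c], qkv[:, 2 * c :]
    out = np.zeros((n, c))
    for m in range(heads):
        sl = slice(m * d, (m + 1) * d)
        logits = scale * q[:, sl] @ k[:, sl].T
        weights = np.apply_along_axis(softmax_1d, 1, logits)
        out[:, sl] = weights @ v[:, sl]
    return out
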
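"""Independent reference implementations used to cross-check the package.

These deliberately share no code with gazetune: dot products are explicit
index loops and update rules are transcribed line by line.
"""

import numpy as np


def scalar_sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def scalar_lstm_oracle(xs, w, h0, C0):
    """Scalar-loop transcription of the LSTM gate equations.

    ``w`` carries per-gate weights (Wxu/Whu/bu, Wxi/Whi/bi, Wxf/Whf/bf,
    Wxo/Who/bo); returns the (h, C) trajectory over the input sequence.
    """
    H = len(w.bu)
    d = len(xs[0])
    h, C = list(h0), list(C0)
    out = []
    for x in xs:
        u, i_, f, O, Cn, hn = [], [], [], [], [], []
        for j in range(H):
            zu = w.bu[j]; zi = w.bi[j]; zf = w.bf[j]; zo = w.bo[j]
            for k in range(d):
                zu += w.Wxu[k, j] * x[k]
                zi += w.Wxi[k, j] * x[k]
                zf += w.Wxf[k, j] * x[k]
                zo += w.Wxo[k, j] * x[k]
            for k in range(H):
                zu += w.Whu[k, j] * h[k]
                zi += w.Whi[k, j] * h[k]
                zf += w.Whf[k, j] * h[k]
                zo += w.Who[k, j] * h[k]
            u.append(np.tanh(zu))
            i_.append(scalar_sigmoid(zi))
            f.append(scalar_sigmoid(zf))
            O.append(scalar_sigmoid(zo))
        for j in range(H):
            Cn.append(f[j] * C[j] + i_[j] * u[j])
            hn.append(O[j] * np.tanh(Cn[j]))
        h, C = hn, Cn
        out.append((np.array(h), np.array(C)))
    return out


def bilstm_output_oracle(X, weights):
    """Per-step combined output HT = Wxh fh + Whh bh + bh, via the scalar
    cell oracle run left-to-right and right-to-left."""
    T = len(X)
    H = len(weights.fwd.bu)
    fwd = scalar_lstm_oracle(X, weights.fwd, np.zeros(H), np.zeros(H))
    bwd = scalar_lstm_oracle(X[::-1], weights.bwd, np.zeros(H), np.zeros(H))
    fh = np.array([s[0] for s in fwd])
    bh = np.array([s[0] for s in bwd])[::-1]
    return fh @ weights.Wxh + bh @ weights.Whh + weights.bh


def crossover_oracle(positions, best, l, Tmax, rng, bernoulli=False):
    """Line-by-line transcription of the interactive-crossover update."""
    n = len(positions)
    cf = (1.0 - l / Tmax) ** (2.0 * l / Tmax)
    perm = rng.permutation(n)
    k1, k2 = perm[: n // 2], perm[n // 2:]
    if bernoulli:
        c1 = rng.integers(0, 2, size=(n // 2, 1)).astype(float)
        c2 = rng.integers(0, 2, size=(n // 2, 1)).astype(float)
    else:
        c1 = rng.random((n // 2, 1))
        c2 = rng.random((n // 2, 1))
    out = positions.copy()
    for i in range(n // 2):
        a, b = positions[k1[i]], positions[k2[i]]
        out[k1[i]] = a + cf * (best - a) + c1[i] * (a - b)
        out[k2[i]] = b + cf * (best - b) + c2[i] * (b - a)
    return np.clip(out, 0.0, 1.0)


def pairwise_auroc(pos_scores, neg_scores):
    """O(n^2) concordant-pair AUROC with half credit for ties."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))
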
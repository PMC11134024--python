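"""Bidirectional LSTM sequence classifier, written out from the gate equations.

Each direction runs a standard LSTM cell

    u_t = tanh(W_xu x_t + W_hu h_prev + b_u)      (candidate)
    i_t = sigma(W_xi x_t + W_hi h_prev + b_i)     (input gate)
    f_t = sigma(W_xf x_t + W_hf h_prev + b_f)     (forget gate)
    C_t = f_t * C_prev + i_t * u_t                (memory cell)
    O_t = sigma(W_xo x_t + W_ho h_prev + b_o)     (output gate)
    h_t = O_t * tanh(C_t)

with the forward pass reading the window left-to-right and the backward pass
right-to-left. The per-step outputs are combined by a weighted sum

    HT_t = W_xh fh_t + W_hh bh_t + b_h

(a concatenation combiner is available behind ``combine='concat'``), followed
by dropout on HT and a linear softmax head over the event classes. Training
minimizes cross-entropy plus an L2 penalty on all weight matrices (never
biases) by mini-batch gradient descent; backpropagation through time is
implemented by hand and validated against numerical gradients in the test
suite.

Supervision is per time step when per-step labels are available (every
sample of a gaze window carries a true event label, so the loss averages
over all steps), or at the window's center step when a single label per
window is given. A window's hard prediction is always read at its center
step.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import pathlib
import warnings

import numpy as np

__all__ = [
    "Hyperparameters",
    "LSTMDirectionWeights",
    "BiLSTMWeights",
    "BiLSTMClassifier",
    "lstm_cell_step",
    "bilstm_forward",
    "midpoint_hyperparameters",
]


@dataclass(frozen=True)
class Hyperparameters:
    """The four tuned training hyperparameters and their admissible domains."""

    dropout: float = 0.1
    learning_rate: float = 0.01
    l2: float = 0.003
    max_epoch: int = 20

    DOMAIN = {
        "dropout": (0.1, 0.4),
        "learning_rate": (0.003, 0.1),
        "l2": (0.003, 0.1),
        "max_epoch": (5, 10, 15, 20),
    }

    def __post_init__(self):
        lo, hi = self.DOMAIN["dropout"]
        if not lo <= self.dropout <= hi:
            raise ValueError(f"dropout must lie in [{lo}, {hi}]")
        lo, hi = self.DOMAIN["learning_rate"]
        if not lo <= self.learning_rate <= hi:
            raise ValueError(f"learning_rate must lie in [{lo}, {hi}]")
        lo, hi = self.DOMAIN["l2"]
        if not lo <= self.l2 <= hi:
            raise ValueError(f"l2 must lie in [{lo}, {hi}]")
        if self.max_epoch not in self.DOMAIN["max_epoch"]:
            raise ValueError("max_epoch must be one of {5, 10, 15, 20}")


def midpoint_hyperparameters() -> Hyperparameters:
    """Center of the search space (categorical dim at its middle bin)."""
    return Hyperparameters(dropout=0.25, learning_rate=0.0515, l2=0.0515, max_epoch=15)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMDirectionWeights:
    """Per-gate parameters of one LSTM direction."""

    Wxu: np.ndarray
    Whu: np.ndarray
    bu: np.ndarray
    Wxi: np.ndarray
    Whi: np.ndarray
    bi: np.ndarray
    Wxf: np.ndarray
    Whf: np.ndarray
    bf: np.ndarray
    Wxo: np.ndarray
    Who: np.ndarray
    bo: np.ndarray

    @classmethod
    def init(cls, d_in: int, d_hidden: int, rng: np.random.Generator):
        def wx():
            return rng.normal(0, np.sqrt(1.0 / d_in), (d_in, d_hidden))

        def wh():
            return rng.normal(0, np.sqrt(1.0 / d_hidden), (d_hidden, d_hidden))

        z = np.zeros(d_hidden)
        return cls(wx(), wh(), z.copy(), wx(), wh(), z.copy(),
                   wx(), wh(), np.ones(d_hidden), wx(), wh(), z.copy())

    def matrices(self):
        return [self.Wxu, self.Whu, self.Wxi, self.Whi,
                self.Wxf, self.Whf, self.Wxo, self.Who]


@dataclass
class BiLSTMWeights:
    """Both directions plus the combiner (HT) and softmax head."""

    fwd: LSTMDirectionWeights
    bwd: LSTMDirectionWeights
    Wxh: np.ndarray  # combiner weight on the forward stream
    Whh: np.ndarray  # combiner weight on the backward stream
    bh: np.ndarray
    Wout: np.ndarray
    bout: np.ndarray

    def matrices(self):
        return (self.fwd.matrices() + self.bwd.matrices()
                + [self.Wxh, self.Whh, self.Wout])


@dataclass
class CellState:
    """One LSTM step's state, with gate activations exposed for inspection."""

    h: np.ndarray
    C: np.ndarray
    u: np.ndarray
    i: np.ndarray
    f: np.ndarray
    O: np.ndarray


def lstm_cell_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    C_prev: np.ndarray,
    w: LSTMDirectionWeights,
) -> CellState:
    """One LSTM cell update; identical algebra for either direction."""
    x_t, h_prev, C_prev = map(np.atleast_2d, (x_t, h_prev, C_prev))
    u = np.tanh(x_t @ w.Wxu + h_prev @ w.Whu + w.bu)
    i = _sigmoid(x_t @ w.Wxi + h_prev @ w.Whi + w.bi)
    f = _sigmoid(x_t @ w.Wxf + h_prev @ w.Whf + w.bf)
    C = f * C_prev + i * u
    O = _sigmoid(x_t @ w.Wxo + h_prev @ w.Who + w.bo)
    h = O * np.tanh(C)
    return CellState(h=h, C=C, u=u, i=i, f=f, O=O)


def _stack_gates(w: LSTMDirectionWeights):
    """Concatenate the per-gate weights (u, i, f, O order) for batched steps."""
    Wx = np.concatenate([w.Wxu, w.Wxi, w.Wxf, w.Wxo], axis=1)
    Wh = np.concatenate([w.Whu, w.Whi, w.Whf, w.Who], axis=1)
    b = np.concatenate([w.bu, w.bi, w.bf, w.bo])
    return Wx, Wh, b


# --- recurrence kernels -----------------------------------------------------
# The sequential time loops are the training hot spot; they are compiled with
# numba when available and fall back to equivalent numpy loops otherwise.
# All surrounding matmuls (input projections, weight gradients) are hoisted
# out of the loops and batched.


def _fwd_rec_py(XW, Wh, order):
    """Gate recurrence. XW: (B, T, 4H) pre-activations from the input path.

    Returns hidden states plus all gate activations (u, i, f, O), cell states
    and tanh(C), each (B, T, H), for reuse in backpropagation.
    """
    B, T, H4 = XW.shape
    H = H4 // 4
    hs = np.zeros((B, T, H))
    U = np.zeros((B, T, H))
    I = np.zeros((B, T, H))
    Fg = np.zeros((B, T, H))
    O = np.zeros((B, T, H))
    C = np.zeros((B, T, H))
    TC = np.zeros((B, T, H))
    h = np.zeros((B, H))
    C_prev = np.zeros((B, H))
    for k in range(T):
        t = order[k]
        Z = XW[:, t] + h @ Wh
        u = np.tanh(Z[:, :H])
        i = 1.0 / (1.0 + np.exp(-Z[:, H : 2 * H]))
        f = 1.0 / (1.0 + np.exp(-Z[:, 2 * H : 3 * H]))
        o = 1.0 / (1.0 + np.exp(-Z[:, 3 * H :]))
        c = f * C_prev + i * u
        tc = np.tanh(c)
        h = o * tc
        U[:, t], I[:, t], Fg[:, t], O[:, t] = u, i, f, o
        C[:, t], TC[:, t], hs[:, t] = c, tc, h
        C_prev = c
    return hs, U, I, Fg, O, C, TC


def _bwd_rec_py(dh_all, U, I, Fg, O, C, TC, WhT, order):
    """BPTT gate-gradient recurrence; returns dZ for every step, (B, T, 4H)."""
    B, T, H = dh_all.shape
    dZ_all = np.zeros((B, T, 4 * H))
    dh_carry = np.zeros((B, H))
    dC = np.zeros((B, H))
    zero_prev = np.zeros((B, H))
    for k in range(T - 1, -1, -1):
        t = order[k]
        C_prev = C[:, order[k - 1]] if k > 0 else zero_prev
        dh = dh_carry + dh_all[:, t]
        dO = dh * TC[:, t] * O[:, t] * (1 - O[:, t])
        dCt = dC + dh * O[:, t] * (1 - TC[:, t] ** 2)
        df = dCt * C_prev * Fg[:, t] * (1 - Fg[:, t])
        di = dCt * U[:, t] * I[:, t] * (1 - I[:, t])
        du = dCt * I[:, t] * (1 - U[:, t] ** 2)
        dZt = np.concatenate((du, di, df, dO), axis=1)
        dZ_all[:, t] = dZt
        dh_carry = dZt @ WhT
        dC = dCt * Fg[:, t]
    return dZ_all


try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    _fwd_rec = _njit(cache=False)(_fwd_rec_py)
    _bwd_rec = _njit(cache=False)(_bwd_rec_py)
except Exception:  # pragma: no cover
    _fwd_rec, _bwd_rec = _fwd_rec_py, _bwd_rec_py


def _direction_pass(X: np.ndarray, w: LSTMDirectionWeights, reverse: bool):
    """Run one direction over (B, T, d); returns hs plus gate tensors."""
    B, T, d = X.shape
    Wx, Wh, b = _stack_gates(w)
    XW = (X.reshape(B * T, d) @ Wx + b).reshape(B, T, -1)
    order = np.arange(T - 1, -1, -1) if reverse else np.arange(T)
    return _fwd_rec(np.ascontiguousarray(XW), np.ascontiguousarray(Wh), order), order


def _run_direction(X: np.ndarray, w: LSTMDirectionWeights, reverse: bool):
    """All hidden states of one direction. X: (B, T, d). Returns (B, T, H)."""
    (hs, *_), _ = _direction_pass(X, w, reverse)
    return hs


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def bilstm_forward(
    sequence: np.ndarray, weights: BiLSTMWeights, combine: str = "sum"
) -> np.ndarray:
    """Per-step class probabilities for one sequence (T, d) -> (T, K)."""
    X = np.asarray(sequence, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("sequence must be a non-empty (T, d) array")
    fh = _run_direction(X[None], weights.fwd, reverse=False)
    bh = _run_direction(X[None], weights.bwd, reverse=True)
    if combine == "sum":
        HT = fh @ weights.Wxh + bh @ weights.Whh + weights.bh
    elif combine == "concat":
        HT = np.concatenate([fh, bh], axis=-1) @ np.vstack(
            [weights.Wxh, weights.Whh]
        ) + weights.bh
    else:
        raise ValueError("combine must be 'sum' or 'concat'")
    logits = HT @ weights.Wout + weights.bout
    return _softmax(logits)[0]


class BiLSTMClassifier:
    """Windowed gaze-event classifier around the BiLSTM equations.

    Parameters
    ----------
    input_dim : per-time-step feature width.
    hidden : LSTM hidden width (also the HT combiner width).
    n_classes : number of event classes.
    combine : 'sum' (weighted-sum combiner) or 'concat'.
    """

    def __init__(
        self,
        input_dim: int,
        hidden: int = 32,
        n_classes: int = 3,
        seed: int = 0,
        combine: str = "sum",
    ):
        if combine not in ("sum", "concat"):
            raise ValueError("combine must be 'sum' or 'concat'")
        self.input_dim = input_dim
        self.hidden = hidden
        self.n_classes = n_classes
        self.seed = seed
        self.combine = combine
        rng = np.random.default_rng(seed)
        ht_in = hidden
        self.w = BiLSTMWeights(
            fwd=LSTMDirectionWeights.init(input_dim, hidden, rng),
            bwd=LSTMDirectionWeights.init(input_dim, hidden, rng),
            Wxh=rng.normal(0, np.sqrt(1.0 / hidden), (hidden, ht_in)),
            Whh=rng.normal(0, np.sqrt(1.0 / hidden), (hidden, ht_in)),
            bh=np.zeros(ht_in),
            Wout=rng.normal(0, np.sqrt(1.0 / ht_in), (ht_in, n_classes)),
            bout=np.zeros(n_classes),
        )
        self.trained = False
        self.history: list[dict] = []

    # ----- forward ---------------------------------------------------------

    def _combine(self, fh: np.ndarray, bh: np.ndarray) -> np.ndarray:
        """HT for all steps. fh, bh: (B, T, H) -> (B, T, H)."""
        if self.combine == "sum":
            return fh @ self.w.Wxh + bh @ self.w.Whh + self.w.bh
        return np.concatenate([fh, bh], axis=-1) @ np.vstack(
            [self.w.Wxh, self.w.Whh]
        ) + self.w.bh

    def _direction_backward(self, X, pass_out, order, dh_all, w):
        """BPTT through one direction given per-step hidden gradients.

        ``dh_all`` is (B, T, H); zero rows mean the step carries no direct
        loss signal (it still receives recurrent gradient). The gate-gradient
        recurrence runs in a compiled kernel; all weight-gradient matmuls are
        batched over the full (B*T) axis.
        """
        H = self.hidden
        hs, U, I, Fg, O, C, TC = pass_out
        _, Wh, _ = _stack_gates(w)
        dZ_all = _bwd_rec(
            np.ascontiguousarray(dh_all), U, I, Fg, O, C, TC,
            np.ascontiguousarray(Wh.T), order,
        )
        B, T, d = X.shape
        dZ_flat = dZ_all.reshape(B * T, 4 * H)
        gWx = X.reshape(B * T, d).T @ dZ_flat
        h_prev = np.zeros_like(hs)
        h_prev[:, order[1:]] = hs[:, order[:-1]]
        gWh = h_prev.reshape(B * T, H).T @ dZ_flat
        gb = dZ_flat.sum(0)
        return {
            "Wxu": gWx[:, :H], "Wxi": gWx[:, H : 2 * H],
            "Wxf": gWx[:, 2 * H : 3 * H], "Wxo": gWx[:, 3 * H :],
            "Whu": gWh[:, :H], "Whi": gWh[:, H : 2 * H],
            "Whf": gWh[:, 2 * H : 3 * H], "Who": gWh[:, 3 * H :],
            "bu": gb[:H], "bi": gb[H : 2 * H],
            "bf": gb[2 * H : 3 * H], "bo": gb[3 * H :],
        }

    def loss_and_grads(
        self,
        X: np.ndarray,
        y: np.ndarray,
        l2: float,
        dropout_mask: np.ndarray | None = None,
    ):
        """Cross-entropy + L2 loss and all parameter gradients.

        ``y`` with shape (B,) supervises the center step only; shape (B, T)
        supervises every step, averaging the cross-entropy over all
        supervised positions.
        """
        y = np.asarray(y, dtype=int)
        B, T, _ = X.shape
        if y.ndim == 1:
            Y = np.zeros((B, T), dtype=int)
            step_mask = np.zeros((B, T))
            Y[:, T // 2] = y
            step_mask[:, T // 2] = 1.0
        else:
            Y = y
            step_mask = np.ones((B, T))
        n_sup = step_mask.sum()

        fpass, forder = _direction_pass(X, self.w.fwd, reverse=False)
        bpass, border = _direction_pass(X, self.w.bwd, reverse=True)
        fh, bh = fpass[0], bpass[0]
        HT = self._combine(fh, bh)
        HTd = HT * dropout_mask[:, None, :] if dropout_mask is not None else HT
        logits = HTd @ self.w.Wout + self.w.bout
        probs = _softmax(logits)
        picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], Y]
        ce = -float((step_mask * np.log(picked + 1e-12)).sum() / n_sup)
        l2_term = l2 * sum(float((M**2).sum()) for M in self.w.matrices())
        loss = ce + l2_term

        dlogits = probs.copy()
        dlogits[np.arange(B)[:, None], np.arange(T)[None, :], Y] -= 1.0
        dlogits *= step_mask[:, :, None] / n_sup
        K = self.n_classes
        gWout = HTd.reshape(-1, self.hidden).T @ dlogits.reshape(-1, K)
        gbout = dlogits.sum(axis=(0, 1))
        dHT = dlogits @ self.w.Wout.T
        if dropout_mask is not None:
            dHT = dHT * dropout_mask[:, None, :]
        if self.combine == "sum":
            H = self.hidden
            gWxh = fh.reshape(-1, H).T @ dHT.reshape(-1, H)
            gWhh = bh.reshape(-1, H).T @ dHT.reshape(-1, H)
            dfh = dHT @ self.w.Wxh.T
            dbh = dHT @ self.w.Whh.T
        else:
            H = self.hidden
            comb = np.vstack([self.w.Wxh, self.w.Whh])
            both = np.concatenate([fh, bh], axis=-1)
            gcomb = both.reshape(-1, 2 * H).T @ dHT.reshape(-1, H)
            gWxh, gWhh = gcomb[:H], gcomb[H:]
            dboth = dHT @ comb.T
            dfh, dbh = dboth[..., :H], dboth[..., H:]
        gbh = dHT.sum(axis=(0, 1))

        gf = self._direction_backward(X, fpass, forder, dfh, self.w.fwd)
        gb = self._direction_backward(X, bpass, border, dbh, self.w.bwd)

        grads = {
            "fwd": gf, "bwd": gb,
            "Wxh": gWxh, "Whh": gWhh, "bh": gbh, "Wout": gWout, "bout": gbout,
        }
        # L2 acts on weight matrices only
        for name, g in (("Wxh", gWxh), ("Whh", gWhh), ("Wout", gWout)):
            g += 2.0 * l2 * getattr(self.w, name)
        for dgrads, dw in ((gf, self.w.fwd), (gb, self.w.bwd)):
            for k in dgrads:
                if k.startswith("W"):
                    dgrads[k] += 2.0 * l2 * getattr(dw, k)
        return loss, grads

    def _apply_grads(self, grads, lr: float) -> None:
        for k, g in grads["fwd"].items():
            setattr(self.w.fwd, k, getattr(self.w.fwd, k) - lr * g)
        for k, g in grads["bwd"].items():
            setattr(self.w.bwd, k, getattr(self.w.bwd, k) - lr * g)
        for k in ("Wxh", "Whh", "bh", "Wout", "bout"):
            setattr(self.w, k, getattr(self.w, k) - lr * grads[k])

    # ----- training --------------------------------------------------------

    def train(
        self,
        X: np.ndarray,
        y: np.ndarray,
        hp: Hyperparameters,
        seed: int = 0,
        batch_size: int = 32,
        val: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> list[dict]:
        """Mini-batch gradient descent for exactly ``hp.max_epoch`` epochs.

        ``y`` may be per-window labels (n,) — center-step supervision — or
        per-step labels (n, T). Returns the per-epoch history (mean loss,
        optional validation accuracy), also stored on ``self.history``.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be (n_windows, T, d)")
        if y.ndim == 2 and y.shape != X.shape[:2]:
            raise ValueError("per-step labels must be (n_windows, T)")
        if len(np.unique(y)) < 2:
            warnings.warn("training data contains a single class; fit is degenerate",
                          stacklevel=2)
        rng = np.random.default_rng(seed)
        n = len(X)
        self.history = []
        # the L2 penalty enters the objective once per epoch: its gradient is
        # distributed uniformly over the epoch's mini-batch updates, so the
        # effective weight decay depends on l2 and epochs but not on how many
        # batches an epoch happens to contain
        l2_eff = hp.l2 / max(1, int(np.ceil(n / batch_size)))
        for _ in range(hp.max_epoch):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                idx = order[s : s + batch_size]
                xb, yb = X[idx], y[idx]
                mask = None
                if hp.dropout > 0:
                    keep = 1.0 - hp.dropout
                    mask = (rng.random((len(idx), self.hidden)) < keep) / keep
                loss, grads = self.loss_and_grads(xb, yb, l2_eff, mask)
                self._apply_grads(grads, hp.learning_rate)
                losses.append(loss)
            entry = {"loss": float(np.mean(losses))}
            if val is not None:
                entry["val_accuracy"] = float(
                    np.mean(self.predict(val[0])[1] == val[1])
                )
            self.history.append(entry)
        self.trained = True
        return self.history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """(n, K) center-step class probabilities (no dropout at inference)."""
        if not self.trained:
            raise RuntimeError("model has not been trained")
        X = np.asarray(X, dtype=float)
        center = X.shape[1] // 2
        probs = []
        for s in range(0, len(X), 256):
            xb = X[s : s + 256]
            fh = _run_direction(xb, self.w.fwd, reverse=False)
            bh = _run_direction(xb, self.w.bwd, reverse=True)
            HT = self._combine(fh, bh)[:, center, :]
            probs.append(_softmax(HT @ self.w.Wout + self.w.bout))
        return np.vstack(probs)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Probabilities plus hard labels; ties break toward the lower index."""
        p = self.predict_proba(X)
        return p, np.argmax(p, axis=1)

    # ----- persistence ------------------------------------------------------

    def save(self, path: str | pathlib.Path, hp: Hyperparameters | None = None) -> None:
        path = pathlib.Path(path)
        arrays = {"Wxh": self.w.Wxh, "Whh": self.w.Whh, "bh": self.w.bh,
                  "Wout": self.w.Wout, "bout": self.w.bout}
        for pre, dw in (("f", self.w.fwd), ("b", self.w.bwd)):
            for k in ("Wxu", "Whu", "bu", "Wxi", "Whi", "bi",
                      "Wxf", "Whf", "bf", "Wxo", "Who", "bo"):
                arrays[f"{pre}_{k}"] = getattr(dw, k)
        np.savez(path, **arrays)
        side = {"input_dim": self.input_dim, "hidden": self.hidden,
                "n_classes": self.n_classes, "seed": self.seed,
                "combine": self.combine, "trained": self.trained}
        if hp is not None:
            side["hyperparameters"] = hp.__dict__
        path.with_suffix(".json").write_text(json.dumps(side, indent=1))
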
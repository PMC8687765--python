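"""Bidirectional LSTM sequence classifier, implemented directly in NumPy.

One LSTM cell step computes

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)        input gate
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)        forget gate
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)        output gate
    g_t = tanh   (W_c x_t + U_c h_{t-1} + b_c)        candidate memory
    C_t = f_t * C_{t-1} + i_t * g_t
    h_t = o_t * tanh(C_t)

Two independent cells consume the beat segment left-to-right and
right-to-left; their hidden states are merged per timestep by a weighted
sum

    H_t = W_fwd h_fwd_t + W_bwd h_bwd_t + b

(the conventional concatenation merge is available via
``combine_mode="concat"``).  A linear head plus softmax yields one
five-class probability vector per beat, trained with mean per-beat
categorical cross-entropy, optionally plus an L1/L2 penalty or an external
differentiable penalty (tree regularization lives in
:mod:`rhythmbeat.tree_regularization`).

Gradients are exact backpropagation-through-time, verified against finite
differences in the test suite; optimisation is Adam.  Everything runs in
float64.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .aami import N_CLASSES
from .heartbeat_dataset import BeatSegment

__all__ = [
    "LSTMCellParams",
    "BiLSTMParams",
    "TrainConfig",
    "init_bilstm_params",
    "lstm_cell_step",
    "bilstm_forward",
    "classify_segment",
    "base_loss",
    "loss_and_grads",
    "train_bilstm",
    "predict_beats",
    "penalty_l1",
    "penalty_l2",
]

_CELL_FIELDS = ("W_i", "W_f", "W_o", "W_c",
                "U_i", "U_f", "U_o", "U_c",
                "b_i", "b_f", "b_o", "b_c")


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclasses.dataclass
class LSTMCellParams:
    """All weight matrices and biases of one LSTM cell."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self):
        H, D = self.W_i.shape
        for name in _CELL_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            want = (H, D) if name.startswith("W") else (
                (H, H) if name.startswith("U") else (H,))
            if arr.shape != want:
                raise ValueError(f"{name} has shape {arr.shape}, expected {want}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1]

    @classmethod
    def zeros(cls, input_size: int, hidden_size: int) -> "LSTMCellParams":
        kw = {}
        for name in _CELL_FIELDS:
            shape = ((hidden_size, input_size) if name.startswith("W")
                     else (hidden_size, hidden_size) if name.startswith("U")
                     else (hidden_size,))
            kw[name] = np.zeros(shape)
        return cls(**kw)


@dataclasses.dataclass
class BiLSTMParams:
    """Forward/backward cells, the per-timestep merge, and the softmax head."""

    forward_cell: LSTMCellParams
    backward_cell: LSTMCellParams
    W_fwd_out: Optional[np.ndarray]
    W_bwd_out: Optional[np.ndarray]
    b_comb: Optional[np.ndarray]
    head_W: np.ndarray
    head_b: np.ndarray
    combine_mode: str = "weighted_sum"

    def __post_init__(self):
        if self.combine_mode not in ("weighted_sum", "concat"):
            raise ValueError(f"unknown combine_mode: {self.combine_mode!r}")
        self.head_W = np.asarray(self.head_W, dtype=float)
        self.head_b = np.asarray(self.head_b, dtype=float)
        H = self.forward_cell.hidden_size
        if self.combine_mode == "weighted_sum":
            self.W_fwd_out = np.asarray(self.W_fwd_out, dtype=float)
            self.W_bwd_out = np.asarray(self.W_bwd_out, dtype=float)
            self.b_comb = np.asarray(self.b_comb, dtype=float)
            K = self.W_fwd_out.shape[0]
            if self.W_fwd_out.shape != (K, H) or self.W_bwd_out.shape != (K, H):
                raise ValueError("combination weight shapes inconsistent")
            if self.b_comb.shape != (K,) or self.head_W.shape[1] != K:
                raise ValueError("combination/head shapes inconsistent")
        else:
            if self.head_W.shape[1] != 2 * H:
                raise ValueError("concat mode requires head input of 2*hidden")

    @property
    def n_classes(self) -> int:
        return self.head_W.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.forward_cell.hidden_size

    def _arrays(self):
        for cell in (self.forward_cell, self.backward_cell):
            for name in _CELL_FIELDS:
                yield getattr(cell, name)
        if self.combine_mode == "weighted_sum":
            yield self.W_fwd_out
            yield self.W_bwd_out
            yield self.b_comb
        yield self.head_W
        yield self.head_b

    def flatten(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self._arrays()])

    @property
    def n_params(self) -> int:
        return sum(a.size for a in self._arrays())

    def set_flat(self, vec: np.ndarray) -> None:
        """Overwrite all parameter arrays from a flat vector (in place)."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_params:
            raise ValueError("flat vector has wrong size")
        pos = 0
        for a in self._arrays():
            a[...] = vec[pos: pos + a.size].reshape(a.shape)
            pos += a.size

    def copy(self) -> "BiLSTMParams":
        other = self.zeros_like(self)
        other.set_flat(self.flatten())
        return other

    @staticmethod
    def zeros_like(p: "BiLSTMParams") -> "BiLSTMParams":
        H, D = p.forward_cell.W_i.shape
        K = p.head_W.shape[1]
        if p.combine_mode == "weighted_sum":
            comb = (np.zeros((K, H)), np.zeros((K, H)), np.zeros(K))
        else:
            comb = (None, None, None)
        return BiLSTMParams(
            forward_cell=LSTMCellParams.zeros(D, H),
            backward_cell=LSTMCellParams.zeros(D, H),
            W_fwd_out=comb[0], W_bwd_out=comb[1], b_comb=comb[2],
            head_W=np.zeros_like(p.head_W), head_b=np.zeros_like(p.head_b),
            combine_mode=p.combine_mode,
        )


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer_id: str = "adam"
    hidden_size: int = 64
    timestep: int = 15
    regularizer: str = "none"
    lam: float = 0.0
    seed: int = 0
    combine_mode: str = "weighted_sum"

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.hidden_size,
               self.timestep) < 1:
            raise ValueError("epochs, batch_size, hidden_size, timestep >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.regularizer not in ("none", "L1", "L2", "tree"):
            raise ValueError(f"unknown regularizer: {self.regularizer!r}")
        if self.optimizer_id != "adam":
            raise ValueError("only the adam optimizer is implemented")


def init_bilstm_params(input_dim: int, hidden_size: int = 64,
                       n_classes: int = N_CLASSES,
                       combined_size: Optional[int] = None,
                       combine_mode: str = "weighted_sum",
                       rng: Optional[np.random.Generator] = None) -> BiLSTMParams:
    """Uniform(-1/sqrt(fan_in), +) init; forget-gate biases start at 1."""
    rng = rng if rng is not None else np.random.default_rng(0)
    H = hidden_size
    K = combined_size or H

    def u(shape, fan_in):
        s = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-s, s, size=shape)

    def cell():
        kw = {}
        for name in _CELL_FIELDS:
            if name.startswith("W"):
                kw[name] = u((H, input_dim), input_dim)
            elif name.startswith("U"):
                kw[name] = u((H, H), H)
            else:
                kw[name] = np.zeros(H)
        kw["b_f"] = np.ones(H)
        return LSTMCellParams(**kw)

    if combine_mode == "weighted_sum":
        comb = (u((K, H), H), u((K, H), H), np.zeros(K))
        head_in = K
    else:
        comb = (None, None, None)
        head_in = 2 * H
    return BiLSTMParams(
        forward_cell=cell(), backward_cell=cell(),
        W_fwd_out=comb[0], W_bwd_out=comb[1], b_comb=comb[2],
        head_W=u((n_classes, head_in), head_in), head_b=np.zeros(n_classes),
        combine_mode=combine_mode,
    )


def lstm_cell_step(x_t, h_prev, c_prev, p: LSTMCellParams):
    """One cell update; returns (h_t, C_t).  Accepts vectors or batches."""
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(h_prev))
            and np.all(np.isfinite(c_prev))):
        raise ValueError("non-finite inputs to lstm_cell_step")
    i = _sigmoid(x_t @ p.W_i.T + h_prev @ p.U_i.T + p.b_i)
    f = _sigmoid(x_t @ p.W_f.T + h_prev @ p.U_f.T + p.b_f)
    o = _sigmoid(x_t @ p.W_o.T + h_prev @ p.U_o.T + p.b_o)
    g = np.tanh(x_t @ p.W_c.T + h_prev @ p.U_c.T + p.b_c)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def _run_direction(X: np.ndarray, cell: LSTMCellParams):
    """Unrolled forward pass of one direction; caches gate activations."""
    B, T, _ = X.shape
    H = cell.hidden_size
    hs = np.zeros((B, T + 1, H))
    cs = np.zeros((B, T + 1, H))
    gates = {k: np.zeros((B, T, H)) for k in ("i", "f", "o", "g", "tc")}
    h = hs[:, 0]
    c = cs[:, 0]
    for t in range(T):
        x = X[:, t]
        i = _sigmoid(x @ cell.W_i.T + h @ cell.U_i.T + cell.b_i)
        f = _sigmoid(x @ cell.W_f.T + h @ cell.U_f.T + cell.b_f)
        o = _sigmoid(x @ cell.W_o.T + h @ cell.U_o.T + cell.b_o)
        g = np.tanh(x @ cell.W_c.T + h @ cell.U_c.T + cell.b_c)
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t + 1] = h
        cs[:, t + 1] = c
        for k, v in zip(("i", "f", "o", "g", "tc"), (i, f, o, g, tc)):
            gates[k][:, t] = v
    return hs, cs, gates


def _direction_backward(X, cell: LSTMCellParams, hs, cs, gates, dH):
    """BPTT through one direction given external per-timestep gradients dH."""
    B, T, _ = X.shape
    g_cell = LSTMCellParams.zeros(cell.input_size, cell.hidden_size)
    dh_next = np.zeros((B, cell.hidden_size))
    dc_next = np.zeros((B, cell.hidden_size))
    for t in range(T - 1, -1, -1):
        i = gates["i"][:, t]
        f = gates["f"][:, t]
        o = gates["o"][:, t]
        g = gates["g"][:, t]
        tc = gates["tc"][:, t]
        c_prev = cs[:, t]
        h_prev = hs[:, t]
        x = X[:, t]

        dh = dH[:, t] + dh_next
        da_o = dh * tc * o * (1.0 - o)
        dc = dh * o * (1.0 - tc * tc) + dc_next
        da_f = dc * c_prev * f * (1.0 - f)
        da_i = dc * g * i * (1.0 - i)
        da_c = dc * i * (1.0 - g * g)

        for name, da in (("i", da_i), ("f", da_f), ("o", da_o), ("c", da_c)):
            getattr(g_cell, f"W_{name}")[...] += da.T @ x
            getattr(g_cell, f"U_{name}")[...] += da.T @ h_prev
            getattr(g_cell, f"b_{name}")[...] += da.sum(axis=0)

        dh_next = (da_i @ cell.U_i + da_f @ cell.U_f
                   + da_o @ cell.U_o + da_c @ cell.U_c)
        dc_next = dc * f
    return g_cell


def _forward_full(X: np.ndarray, p: BiLSTMParams):
    """Full forward pass; returns probs plus everything needed for backward."""
    hs_f, cs_f, gates_f = _run_direction(X, p.forward_cell)
    Xr = X[:, ::-1]
    hs_b, cs_b, gates_b = _run_direction(Xr, p.backward_cell)
    Hf = hs_f[:, 1:]
    Hb = hs_b[:, 1:][:, ::-1]  # align so Hb[:, t] saw x_t .. x_{T-1}
    if p.combine_mode == "weighted_sum":
        comb = Hf @ p.W_fwd_out.T + Hb @ p.W_bwd_out.T + p.b_comb
    else:
        comb = np.concatenate([Hf, Hb], axis=-1)
    logits = comb @ p.head_W.T + p.head_b
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=-1, keepdims=True)
    cache = dict(hs_f=hs_f, cs_f=cs_f, gates_f=gates_f,
                 hs_b=hs_b, cs_b=cs_b, gates_b=gates_b,
                 Hf=Hf, Hb=Hb, comb=comb, Xr=Xr)
    return probs, cache


def _as_batch(X) -> tuple[np.ndarray, bool]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        return X[None], True
    if X.ndim != 3:
        raise ValueError("expected a (t, d) or (batch, t, d) input")
    return X, False


def bilstm_forward(segment_inputs, p: BiLSTMParams) -> np.ndarray:
    """Combined per-timestep hidden states H_1..H_t (before the head)."""
    X, squeeze = _as_batch(segment_inputs)
    _, cache = _forward_full(X, p)
    comb = cache["comb"]
    return comb[0] if squeeze else comb


def classify_segment(segment, p: BiLSTMParams) -> np.ndarray:
    """Per-beat softmax probabilities over (N, S, V, F, Q) for one segment."""
    X = segment.feature_matrix() if isinstance(segment, BeatSegment) else segment
    X, squeeze = _as_batch(X)
    probs, _ = _forward_full(X, p)
    return probs[0] if squeeze else probs


def loss_and_grads(X, y, p: BiLSTMParams):
    """Mean per-beat cross-entropy and exact parameter gradients.

    X: (batch, t, d); y: (batch, t) integer class labels.
    Returns (ce, grads-as-BiLSTMParams, probs).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3 or y.shape != X.shape[:2]:
        raise ValueError("X must be (batch, t, d) with y of shape (batch, t)")
    probs, cache = _forward_full(X, p)
    B, T, C = probs.shape
    M = B * T
    picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], y]
    ce = float(-np.log(np.maximum(picked, 1e-300)).mean())

    onehot = np.zeros_like(probs)
    onehot[np.arange(B)[:, None], np.arange(T)[None, :], y] = 1.0
    dlogits = (probs - onehot) / M

    grads = BiLSTMParams.zeros_like(p)
    comb = cache["comb"]
    grads.head_W[...] = np.einsum("btc,btk->ck", dlogits, comb)
    grads.head_b[...] = dlogits.sum(axis=(0, 1))
    dcomb = dlogits @ p.head_W

    Hf, Hb = cache["Hf"], cache["Hb"]
    if p.combine_mode == "weighted_sum":
        grads.W_fwd_out[...] = np.einsum("btk,bth->kh", dcomb, Hf)
        grads.W_bwd_out[...] = np.einsum("btk,bth->kh", dcomb, Hb)
        grads.b_comb[...] = dcomb.sum(axis=(0, 1))
        dHf = dcomb @ p.W_fwd_out
        dHb = dcomb @ p.W_bwd_out
    else:
        H = p.hidden_size
        dHf = dcomb[..., :H]
        dHb = dcomb[..., H:]

    gf = _direction_backward(X, p.forward_cell, cache["hs_f"], cache["cs_f"],
                             cache["gates_f"], dHf)
    gb = _direction_backward(cache["Xr"], p.backward_cell, cache["hs_b"],
                             cache["cs_b"], cache["gates_b"], dHb[:, ::-1])
    grads.forward_cell = gf
    grads.backward_cell = gb
    return ce, grads, probs


def penalty_l1(p: BiLSTMParams) -> tuple[float, np.ndarray]:
    flat = p.flatten()
    return float(np.abs(flat).sum()), np.sign(flat)


def penalty_l2(p: BiLSTMParams) -> tuple[float, np.ndarray]:
    flat = p.flatten()
    return float((flat * flat).sum()), 2.0 * flat


def _segment_arrays(segments: Sequence[BeatSegment]):
    return [(s.feature_matrix(), np.array([int(l) for l in s.labels]))
            for s in segments]


def base_loss(segments, p: BiLSTMParams, cfg: TrainConfig) -> float:
    """Mean per-beat cross-entropy plus lambda * (L1 | L2) penalty.

    ``segments`` is a list of BeatSegments (mixed lengths allowed) or a
    prebuilt ``(X, y)`` pair.
    """
    if isinstance(segments, tuple):
        pairs = [segments]
    else:
        if len(segments) == 0:
            raise ValueError("empty batch")
        pairs = _segment_arrays(segments)
    tot_nll = 0.0
    tot_beats = 0
    for X, y in pairs:
        Xb, _ = _as_batch(X)
        yb = np.atleast_2d(np.asarray(y, dtype=int))
        probs, _ = _forward_full(Xb, p)
        B, T, _ = probs.shape
        picked = probs[np.arange(B)[:, None], np.arange(T)[None, :], yb]
        tot_nll += float(-np.log(np.maximum(picked, 1e-300)).sum())
        tot_beats += B * T
    ce = tot_nll / tot_beats
    if cfg.lam > 0 and cfg.regularizer == "L1":
        ce += cfg.lam * penalty_l1(p)[0]
    elif cfg.lam > 0 and cfg.regularizer == "L2":
        ce += cfg.lam * penalty_l2(p)[0]
    return ce


class _Adam:
    def __init__(self, n: int, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.m = np.zeros(n)
        self.v = np.zeros(n)
        self.t = 0
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps

    def step(self, flat: np.ndarray, grad: np.ndarray) -> np.ndarray:
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad * grad
        mh = self.m / (1 - self.b1 ** self.t)
        vh = self.v / (1 - self.b2 ** self.t)
        return flat - self.lr * mh / (np.sqrt(vh) + self.eps)


def _make_batches(seg_arrays, order, batch_size):
    """Equal-length batches in randomised order; partial-length segments
    form their own (possibly small) batches so no padding is ever needed."""
    buckets: dict[int, list[int]] = {}
    batches: list[list[int]] = []
    for idx in order:
        T = seg_arrays[idx][0].shape[0]
        buckets.setdefault(T, []).append(idx)
        if len(buckets[T]) == batch_size:
            batches.append(buckets.pop(T))
    batches.extend(buckets.values())
    return batches


def _builtin_penalty(cfg: TrainConfig) -> Optional[Callable]:
    if cfg.lam <= 0 or cfg.regularizer in ("none", "tree"):
        return None
    base = penalty_l1 if cfg.regularizer == "L1" else penalty_l2
    lam = cfg.lam

    def fn(p):
        val, grad = base(p)
        return lam * val, lam * grad

    return fn


def train_bilstm(segments: Sequence[BeatSegment], cfg: TrainConfig,
                 penalty_fn: Optional[Callable] = None,
                 epoch_hook: Optional[Callable] = None):
    """Mini-batch Adam training; returns (params, per-epoch history).

    ``penalty_fn(params) -> (value, flat_grad | None)`` overrides the
    built-in L1/L2 penalty (used by tree regularization).  ``epoch_hook``
    runs after each epoch and may return a dict merged into that epoch's
    history row; it must not touch the training RNG stream.
    """
    if len(segments) == 0:
        raise ValueError("no training segments")
    rng = np.random.default_rng(cfg.seed)
    seg_arrays = _segment_arrays(segments)
    input_dim = seg_arrays[0][0].shape[1]
    params = init_bilstm_params(input_dim, cfg.hidden_size,
                                combine_mode=cfg.combine_mode, rng=rng)
    if penalty_fn is None:
        penalty_fn = _builtin_penalty(cfg)
    flat = params.flatten()
    adam = _Adam(flat.size, cfg.learning_rate)
    history: list[dict] = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(seg_arrays))
        nll_sum = 0.0
        beats = 0
        pen_last = 0.0
        for batch_idx in _make_batches(seg_arrays, order, cfg.batch_size):
            X = np.stack([seg_arrays[i][0] for i in batch_idx])
            y = np.stack([seg_arrays[i][1] for i in batch_idx])
            ce, grads, _ = loss_and_grads(X, y, params)
            g = grads.flatten()
            if penalty_fn is not None:
                pen_last, pgrad = penalty_fn(params)
                if pgrad is not None:
                    g = g + pgrad
            flat = adam.step(flat, g)
            params.set_flat(flat)
            nll_sum += ce * X.shape[0] * X.shape[1]
            beats += X.shape[0] * X.shape[1]
        row = {"epoch": epoch, "loss": nll_sum / beats, "penalty": pen_last}
        if epoch_hook is not None:
            extra = epoch_hook(epoch, params)
            if extra:
                row.update(extra)
        history.append(row)
    return params, history


def predict_beats(segments: Sequence[BeatSegment], p: BiLSTMParams,
                  batch_size: int = 256):
    """(true, predicted, probabilities) per beat, in segment order."""
    seg_arrays = _segment_arrays(segments)
    n_beats = sum(a[0].shape[0] for a in seg_arrays)
    offsets = np.cumsum([0] + [a[0].shape[0] for a in seg_arrays])
    y_true = np.concatenate([a[1] for a in seg_arrays]) if n_beats else np.empty(0, int)
    y_pred = np.empty(n_beats, dtype=int)
    probs_out = np.empty((n_beats, p.n_classes))
    buckets: dict[int, list[int]] = {}
    for i, (X, _) in enumerate(seg_arrays):
        buckets.setdefault(X.shape[0], []).append(i)
    for T, idxs in buckets.items():
        for start in range(0, len(idxs), batch_size):
            chunk = idxs[start: start + batch_size]
            X = np.stack([seg_arrays[i][0] for i in chunk])
            probs, _ = _forward_full(X, p)
            for j, i in enumerate(chunk):
                probs_out[offsets[i]: offsets[i + 1]] = probs[j]
                y_pred[offsets[i]: offsets[i + 1]] = probs[j].argmax(axis=-1)
    return y_true, y_pred, probs_out
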
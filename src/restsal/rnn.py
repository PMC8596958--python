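"""Two-layer additive bidirectional LSTM regression, written from scratch.

The architecture maps a standardized T x R session to one scalar: two BiLSTM
stages whose forward- and backward-direction outputs are *added* per timestep,
temporal mean pooling of the second stage, and an affine head. Initial hidden
and cell states are learnable, and each direction-LSTM carries a single gate
bias vector, which is the convention under which the default full-scale
architecture (360 inputs, 256 hidden units) has exactly 2,316,545 learnable
parameters: 632,320 per direction-LSTM in the first stage, 525,824 in the
second, and 257 in the affine head.

Everything is NumPy. Reverse-mode gradients (backpropagation through time)
are implemented analytically and produce both parameter gradients (for
training with Adam plus decoupled weight decay) and input gradients (the
saliencies the interpretation machinery is built on). Member ensembles are
trained with a leading "member" axis on every parameter tensor so that one
batched matrix multiply advances all members at once; members share the data
order and crop draws and differ by their initialization seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _kernels

__all__ = [
    "ArchitectureSpec",
    "ParamCount",
    "TrainingConfig",
    "count_parameters",
    "EnsembleParams",
    "init_ensemble",
    "forward_batch",
    "backward_batch",
    "predict_matrix",
    "ensemble_predict",
    "input_gradients",
    "train_ensemble",
]

_GATES = 4  # input, forget, candidate, output


@dataclass(frozen=True)
class ArchitectureSpec:
    """Shape of the regression network.

    Defaults are the full-scale architecture (360-region parcellation, 256
    hidden units). Desk-scale analyses use :meth:`desk_scale`.
    """

    input_dim: int = 360
    hidden_dim: int = 256

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_dim < 1:
            raise ValueError("input_dim and hidden_dim must be >= 1")

    @classmethod
    def desk_scale(cls, input_dim: int = 60, hidden_dim: int = 12) -> "ArchitectureSpec":
        return cls(input_dim=input_dim, hidden_dim=hidden_dim)


@dataclass(frozen=True)
class ParamCount:
    per_direction_lstm_layer1: int
    per_direction_lstm_layer2: int
    affine: int
    total: int


def count_parameters(spec: ArchitectureSpec) -> ParamCount:
    """Exact learnable-parameter accounting.

    Per direction-LSTM with input size d and hidden size h: 4h(d+h) weights,
    4h gate biases, and 2h learnable initial hidden/cell states, i.e.
    4h(d+h) + 6h. The affine head adds h + 1.
    """
    d, h = spec.input_dim, spec.hidden_dim
    layer1 = _GATES * h * (d + h) + 6 * h
    layer2 = _GATES * h * (h + h) + 6 * h
    affine = h + 1
    return ParamCount(layer1, layer2, affine, 2 * layer1 + 2 * layer2 + affine)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization scheme for one ensemble.

    ``learning_rate`` and ``weight_decay`` (decoupled, applied to weight
    matrices only) default to 5e-4 each; sequences are randomly cropped by up
    to ``max_crop`` timesteps independently at each end of every batch.
    ``ensemble_size`` defaults to 50 members at full scale; desk-scale runs
    use :meth:`desk_scale`.
    """

    epochs: int = 50
    learning_rate: float = 5e-4
    weight_decay: float = 5e-4
    max_crop: int = 20
    batch_size: int = 32
    ensemble_size: int = 50
    seed: int = 0
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.ensemble_size) < 1:
            raise ValueError("epochs, batch_size and ensemble_size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0 or self.max_crop < 0:
            raise ValueError("invalid optimization constants")

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainingConfig":
        base = dict(
            epochs=12,
            learning_rate=3e-3,
            weight_decay=5e-4,
            max_crop=5,
            batch_size=64,
            ensemble_size=5,
            seed=0,
            dtype="float32",
        )
        base.update(overrides)
        return cls(**base)


# parameter keys: per layer l in {1,2}, direction d in {f,b}:
#   W{l}{d}: (M, 4h, d_in+h) combined input+recurrent weights
#   b{l}{d}: (M, 4h) gate biases
#   h0{l}{d}, c0{l}{d}: (M, h) learnable initial states
# head_w: (M, h), head_b: (M,)
_LAYERS = ((1, "f"), (1, "b"), (2, "f"), (2, "b"))


def _keys() -> list[str]:
    out = []
    for l, d in _LAYERS:
        out += [f"W{l}{d}", f"b{l}{d}", f"h0{l}{d}", f"c0{l}{d}"]
    return out + ["head_w", "head_b"]


@dataclass
class EnsembleParams:
    """Stacked parameters of an ensemble: leading axis indexes members."""

    spec: ArchitectureSpec
    arrays: dict[str, np.ndarray]
    member_seeds: list[int] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return self.arrays["head_b"].shape[0]

    def members(self, idx) -> "EnsembleParams":
        """View selecting a subset of members (int, slice or index array)."""
        if isinstance(idx, int):
            idx = [idx]
        arrays = {k: v[idx] for k, v in self.arrays.items()}
        seeds = [self.member_seeds[i] for i in np.arange(len(self.member_seeds))[idx]] \
            if self.member_seeds else []
        return EnsembleParams(self.spec, arrays, seeds)

    def astype(self, dtype) -> "EnsembleParams":
        return EnsembleParams(
            self.spec,
            {k: v.astype(dtype) for k, v in self.arrays.items()},
            list(self.member_seeds),
        )

    def n_parameters(self) -> int:
        return int(sum(v[0].size for v in self.arrays.values()))

    @staticmethod
    def stack(ensembles: list["EnsembleParams"]) -> "EnsembleParams":
        """Concatenate several ensembles (same spec) along the member axis."""
        spec = ensembles[0].spec
        arrays = {
            k: np.concatenate([e.arrays[k] for e in ensembles], axis=0)
            for k in ensembles[0].arrays
        }
        seeds = [s for e in ensembles for s in e.member_seeds]
        return EnsembleParams(spec, arrays, seeds)


def init_ensemble(
    spec: ArchitectureSpec,
    member_seeds: list[int],
    dtype=np.float64,
) -> EnsembleParams:
    """Glorot-uniform weights, zero biases and initial states, per member."""
    h = spec.hidden_dim
    per_member: list[dict[str, np.ndarray]] = []
    for seed in member_seeds:
        rng = np.random.default_rng(np.random.SeedSequence(int(seed) & 0x7FFFFFFF))
        arrs: dict[str, np.ndarray] = {}
        for l, d in _LAYERS:
            din = spec.input_dim if l == 1 else h
            fan_in, fan_out = din + h, _GATES * h
            limit = math.sqrt(6.0 / (fan_in + fan_out))
            arrs[f"W{l}{d}"] = rng.uniform(-limit, limit, size=(_GATES * h, din + h))
            arrs[f"b{l}{d}"] = np.zeros(_GATES * h)
            arrs[f"h0{l}{d}"] = np.zeros(h)
            arrs[f"c0{l}{d}"] = np.zeros(h)
        limit = math.sqrt(6.0 / (h + 1))
        arrs["head_w"] = rng.uniform(-limit, limit, size=h)
        arrs["head_b"] = np.zeros(())
        per_member.append(arrs)
    stacked = {
        k: np.stack([m[k] for m in per_member]).astype(dtype) for k in _keys()
    }
    return EnsembleParams(spec, stacked, list(member_seeds))


def _fwd_loop_np(Gx, WhT, h0, c0):
    """NumPy reference for the recurrent forward loop (see _kernels)."""
    M, T, B, h4 = Gx.shape
    h = h4 // 4
    h3 = 3 * h
    dtype = Gx.dtype
    hprev = np.broadcast_to(h0[:, None, :], (M, B, h)).astype(dtype)
    cprev = np.broadcast_to(c0[:, None, :], (M, B, h)).astype(dtype)
    SIG = np.empty((M, T, B, h3), dtype=dtype)  # i, f, o post-activation
    G = np.empty((M, T, B, h), dtype=dtype)  # candidate (tanh)
    TC = np.empty_like(G)
    CP = np.empty_like(G)
    HP = np.empty_like(G)
    for t in range(T):
        a = Gx[:, t] + hprev @ WhT
        sig = expit(a[..., :h3])
        g = np.tanh(a[..., h3:])
        c = sig[..., h : 2 * h] * cprev + sig[..., :h] * g
        tc = np.tanh(c)
        SIG[:, t] = sig
        G[:, t] = g
        TC[:, t] = tc
        CP[:, t] = cprev
        HP[:, t] = hprev
        hprev = sig[..., 2 * h : h3] * tc
        cprev = c
    H = SIG[..., 2 * h : h3] * TC
    return H, SIG, G, TC, CP, HP


def _bwd_loop_np(SIG, G, TC, CP, Wh, dH):
    """NumPy reference for the recurrent backward loop (see _kernels)."""
    M, T, B, h = dH.shape
    h3 = 3 * h
    DA = np.empty((M, T, B, _GATES * h), dtype=SIG.dtype)
    dh_next = np.zeros((M, B, h), dtype=SIG.dtype)
    dc_next = np.zeros((M, B, h), dtype=SIG.dtype)
    for t in range(T - 1, -1, -1):
        sig = SIG[:, t]
        i = sig[..., :h]
        f = sig[..., h : 2 * h]
        o = sig[..., 2 * h : h3]
        g, tc, cprev = G[:, t], TC[:, t], CP[:, t]
        dh = dH[:, t] + dh_next
        dc = dc_next + dh * o * (1.0 - tc * tc)
        da = DA[:, t]
        da[..., :h] = dc * g
        da[..., h : 2 * h] = dc * cprev
        da[..., 2 * h : h3] = dh * tc
        da[..., :h3] *= sig * (1.0 - sig)
        da[..., h3:] = dc * i * (1.0 - g * g)
        dc_next = dc * f
        dh_next = da @ Wh  # (M,B,h)
    dh0 = dh_next.sum(axis=1)
    dc0 = dc_next.sum(axis=1)
    return DA, dh0, dc0


def _lstm_forward(W, b, h0, c0, X):
    """One direction-LSTM over X (M,T,B,din) -> outputs (M,T,B,h) + cache.

    Time-major layout keeps every per-step slice contiguous; the input
    projection for all timesteps is a single batched GEMM and only the
    recurrent projection stays inside the time loop.
    """
    M, T, B, din = X.shape
    h = h0.shape[-1]
    Wx = W[:, :, :din]
    WhT = np.ascontiguousarray(W[:, :, din:].transpose(0, 2, 1))  # (M,h,4h)
    Gx = np.matmul(X.reshape(M, T * B, din), Wx.transpose(0, 2, 1)).reshape(
        M, T, B, _GATES * h
    )
    Gx += b[:, None, None, :]
    # the vectorized NumPy loop wins here: the gates are transcendental-bound
    H, SIG, G, TC, CP, HP = _fwd_loop_np(Gx, WhT, h0, c0)
    return H, (X, SIG, G, TC, CP, HP)


def _lstm_backward(W, cache, dH, din: int, use_numba: bool | None = None):
    """Reverse-mode through one direction-LSTM.

    dH is the gradient w.r.t. the per-timestep outputs (M,T,B,h). Returns
    gradients for (W, b, h0, c0) and for the layer input X.
    """
    X, SIG, G, TC, CP, HP = cache
    M, T, B, h = dH.shape
    Wx = W[:, :, :din]
    Wh = np.ascontiguousarray(W[:, :, din:])
    fast = _kernels.HAVE_NUMBA if use_numba is None else use_numba
    if fast:
        DA, dh0, dc0 = _kernels.bwd_loop(
            SIG, G, TC, CP, Wh, np.ascontiguousarray(dH)
        )
    else:
        DA, dh0, dc0 = _bwd_loop_np(SIG, G, TC, CP, Wh, dH)
    DAf = DA.reshape(M, T * B, _GATES * h)
    dWx = DAf.transpose(0, 2, 1) @ X.reshape(M, T * B, din)
    dWh = DAf.transpose(0, 2, 1) @ HP.reshape(M, T * B, h)
    dW = np.concatenate([dWx, dWh], axis=2)
    db = DA.sum(axis=(1, 2))
    dX = (DAf @ Wx).reshape(M, T, B, din)
    return dW, db, dh0, dc0, dX


def _stack_directions(arrays, layer: int):
    """Forward- and backward-direction parameters stacked along members.

    The backward direction is realized as a forward pass over the
    time-reversed sequence, so both directions of a layer advance in one
    batched computation.
    """
    return tuple(
        np.concatenate([arrays[f"{k}{layer}f"], arrays[f"{k}{layer}b"]], axis=0)
        for k in ("W", "b", "h0", "c0")
    )


def forward_batch(params: EnsembleParams, X: np.ndarray):
    """Scalar predictions for a batch of sessions, for every member.

    X has shape (B, T, input_dim) (shared across members) or
    (M, B, T, input_dim) (member-specific inputs). Returns ``(pred, cache)``
    with pred of shape (M, B).
    """
    spec = params.spec
    a = params.arrays
    X = np.asarray(X, dtype=a["head_w"].dtype)
    M = params.n_members
    if X.ndim == 3 and X.shape[-1] == spec.input_dim:
        Xt = X.transpose(1, 0, 2)  # time-major (T,B,d)
        Xf = np.broadcast_to(Xt[None], (M,) + Xt.shape)
    elif X.ndim == 4 and X.shape[0] == M and X.shape[-1] == spec.input_dim:
        Xf = X.transpose(0, 2, 1, 3)  # (M,T,B,d)
    else:
        raise ValueError(
            f"expected input of shape (B, T, {spec.input_dim}) or "
            f"({M}, B, T, {spec.input_dim}), got {X.shape}"
        )
    T = Xf.shape[1]
    X2 = np.concatenate([Xf, Xf[:, ::-1]], axis=0)  # (2M,T,B,d)
    W1, b1, h01, c01 = _stack_directions(a, 1)
    H1, c1 = _lstm_forward(W1, b1, h01, c01, X2)
    S1 = H1[:M] + H1[M:, ::-1]
    X2b = np.concatenate([S1, S1[:, ::-1]], axis=0)
    W2, b2, h02, c02 = _stack_directions(a, 2)
    H2, c2 = _lstm_forward(W2, b2, h02, c02, X2b)
    S2 = H2[:M] + H2[M:, ::-1]
    pooled = S2.mean(axis=1)  # (M,B,h)
    pred = np.einsum("mbh,mh->mb", pooled, a["head_w"]) + a["head_b"][:, None]
    cache = {"c1": c1, "c2": c2, "W1": W1, "W2": W2, "pooled": pooled, "T": T}
    return pred, cache


def backward_batch(params: EnsembleParams, cache, dpred: np.ndarray):
    """Gradients of ``sum(dpred * pred)`` w.r.t. parameters and inputs."""
    a = params.arrays
    spec = params.spec
    h = spec.hidden_dim
    M = params.n_members
    T = cache["T"]
    pooled = cache["pooled"]
    grads: dict[str, np.ndarray] = {}
    grads["head_w"] = np.einsum("mb,mbh->mh", dpred, pooled)
    grads["head_b"] = dpred.sum(axis=1)
    dpooled = dpred[:, :, None] * a["head_w"][:, None, :] / T  # (M,B,h)
    dS2 = np.broadcast_to(
        dpooled[:, None, :, :], (pooled.shape[0], T) + pooled.shape[1:]
    )
    dH2 = np.concatenate([dS2, dS2], axis=0)  # constant in t: reversal is a no-op
    dW2, db2, dh02, dc02, dX2b = _lstm_backward(cache["W2"], cache["c2"], dH2, h)
    dS1 = dX2b[:M] + dX2b[M:, ::-1]
    dH1 = np.concatenate([dS1, dS1[:, ::-1]], axis=0)
    dW1, db1, dh01, dc01, dX2 = _lstm_backward(
        cache["W1"], cache["c1"], dH1, spec.input_dim
    )
    dX = (dX2[:M] + dX2[M:, ::-1]).transpose(0, 2, 1, 3)  # back to (M,B,T,d)
    for layer, (dW, db, dh0, dc0) in (
        (1, (dW1, db1, dh01, dc01)),
        (2, (dW2, db2, dh02, dc02)),
    ):
        grads[f"W{layer}f"], grads[f"W{layer}b"] = dW[:M], dW[M:]
        grads[f"b{layer}f"], grads[f"b{layer}b"] = db[:M], db[M:]
        grads[f"h0{layer}f"], grads[f"h0{layer}b"] = dh0[:M], dh0[M:]
        grads[f"c0{layer}f"], grads[f"c0{layer}b"] = dc0[:M], dc0[M:]
    return grads, dX


def predict_matrix(
    params: EnsembleParams, X: np.ndarray, chunk: int = 128
) -> np.ndarray:
    """Per-member scalar predictions, shape (M, B).

    Large batches are processed in chunks to bound the cache working set.
    """
    X = np.asarray(X)
    out = np.empty((params.n_members, X.shape[0]))
    for start in range(0, X.shape[0], chunk):
        pred, _ = forward_batch(params, X[start : start + chunk])
        out[:, start : start + pred.shape[1]] = pred
    return out


def ensemble_predict(params: EnsembleParams, sessions) -> float:
    """Flat mean over members and sessions of the per-session scalars."""
    X = np.stack([np.asarray(s) for s in sessions])
    if X.shape[0] < 1 or params.n_members < 1:
        raise ValueError("need at least one member and one session")
    return float(predict_matrix(params, X).mean())


def input_gradients(params: EnsembleParams, X: np.ndarray) -> np.ndarray:
    """Gradient of each session's scalar output w.r.t. its (standardized)
    input, per member: shape (M, B, T, input_dim)."""
    pred, cache = forward_batch(params, X)
    ones = np.ones_like(pred)
    _, dX = backward_batch(params, cache, ones)
    if not np.all(np.isfinite(dX)):
        bad = np.flatnonzero(~np.isfinite(dX).all(axis=(1, 2, 3)))
        raise FloatingPointError(f"non-finite gradient for member(s) {bad.tolist()}")
    return dX


_DECAYED = tuple(f"W{l}{d}" for l, d in _LAYERS) + ("head_w",)


def train_ensemble(
    spec: ArchitectureSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
    n_members: int | None = None,
) -> tuple[EnsembleParams, np.ndarray]:
    """Train an ensemble with Adam and decoupled weight decay.

    Parameters
    ----------
    X
        Training sessions, shape (N, T, input_dim); each session is a
        separate sample (sessions of one subject share its target).
    y
        Per-session targets (the subject's adjusted trait), shape (N,).
    config
        Optimization constants. ``config.seed`` determines member
        initializations, the per-epoch shuffle and the crop draws, so the
        same seed reproduces bit-identical parameters.

    Returns
    -------
    (params, loss_history)
        Trained stacked parameters and the per-epoch mean training MSE
        averaged over members.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must have shape (N, T, input_dim)")
    N, T, _ = X.shape
    if N < 2:
        raise ValueError("need at least 2 training samples")
    if y.shape != (N,):
        raise ValueError("y must have one target per training sample")
    if 2 * config.max_crop >= T:
        raise ValueError("max_crop too large for the sequence length")
    M = n_members if n_members is not None else config.ensemble_size
    dtype = np.dtype(config.dtype)
    root = np.random.SeedSequence(int(config.seed) & 0x7FFFFFFF)
    member_ss, data_ss = root.spawn(2)
    member_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in member_ss.spawn(M)]
    params = init_ensemble(spec, member_seeds, dtype=dtype)
    data_streams = data_ss.spawn(M + 1)
    # independent per-member shuffles keep member errors decorrelated, which
    # is what makes ensembling reduce variance; crops are drawn per batch
    order_rngs = [np.random.default_rng(s) for s in data_streams[:M]]
    rng = np.random.default_rng(data_streams[M])

    Xd = X.astype(dtype, copy=False)
    yd = y.astype(dtype, copy=False)
    m_state = {k: np.zeros_like(v) for k, v in params.arrays.items()}
    v_state = {k: np.zeros_like(v) for k, v in params.arrays.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    lr, wd = config.learning_rate, config.weight_decay
    loss_history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        orders = np.stack([r.permutation(N) for r in order_rngs])  # (M,N)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, N, config.batch_size):
            idx = orders[:, start : start + config.batch_size]  # (M,B)
            lo = int(rng.integers(0, config.max_crop + 1))
            hi = int(rng.integers(0, config.max_crop + 1))
            xb = Xd[idx][:, :, lo : T - hi if hi else T]  # (M,B,T',d)
            yb = yd[idx]
            pred, cache = forward_batch(params, xb)
            err = pred - yb
            loss = float((err * err).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {n_batches}"
                )
            epoch_loss += loss
            n_batches += 1
            dpred = (2.0 / idx.shape[1]) * err
            grads, _ = backward_batch(params, cache, dpred)
            step += 1
            bc1 = 1.0 - beta1**step
            bc2 = 1.0 - beta2**step
            for k, p in params.arrays.items():
                gk = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * gk
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * gk * gk
                update = (m_state[k] / bc1) / (np.sqrt(v_state[k] / bc2) + eps)
                if k in _DECAYED and wd:
                    p -= lr * wd * p
                p -= lr * update
        loss_history[epoch] = epoch_loss / max(n_batches, 1)
    return params, loss_history
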
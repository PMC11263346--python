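"""Predictive networks modulated by context vectors.

Three model families share one interface (``forward`` / ``train_step``):

* :class:`FFNet` — a one-hidden-layer feedforward network whose hidden
  layer receives an additive, learnable projection of a context vector
  (the context-to-hidden pathway).  Lesioning zeroes that pathway at
  evaluation time.
* :class:`GRUNet` — a gated recurrent unit whose input is the observation
  concatenated with the context vector, with a linear readout.
* :class:`SEMEnsemble` — one independent expert network per latent cause,
  the mixture-of-experts scheme of the SEM framework.

Everything is plain numpy with analytic gradients and online SGD: the
models are tiny (tens of units) and trained one observation at a time,
so autodiff frameworks buy nothing here.  Gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

import json

import numpy as np

__all__ = [
    "FFNet",
    "GRUNet",
    "SEMEnsemble",
    "ff_forward",
    "gru_step",
    "train_step",
    "sem_select_or_spawn",
]

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a**2),
    "relu": (lambda z: np.maximum(z, 0.0), lambda a: (a > 0).astype(float)),
}


def _uniform_init(rng: np.random.Generator, shape: tuple[int, ...], scale: float) -> np.ndarray:
    fan_in = shape[-1]
    bound = scale / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Adam:
    """Per-parameter adaptive steps (Adam).  Equalizes effective learning
    across pathways whose raw gradient scales differ by orders of
    magnitude (e.g. a high-norm context vector vs a scalar input)."""

    def __init__(self, beta1=0.9, beta2=0.999, eps=1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, net, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            m = self.m.get(k, 0.0) * b1 + (1 - b1) * g
            v = self.v.get(k, 0.0) * b2 + (1 - b2) * g**2
            self.m[k], self.v[k] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            setattr(net, k, getattr(net, k) - lr * mhat / (np.sqrt(vhat) + self.eps))


def _apply_update(net, grads: dict[str, np.ndarray], lr: float) -> None:
    if net.optimizer == "adam":
        net._adam.step(net, grads, lr)
    else:
        for k, g in grads.items():
            setattr(net, k, getattr(net, k) - lr * g)


class FFNet:
    """Feedforward predictor: hidden = act(W_in x + W_ctx c + b), linear readout.

    ``W_ctx`` (the context-to-hidden pathway) is trainable; the context
    vectors themselves are fixed.  ``forward(..., lesioned=True)`` removes
    the ``W_ctx c`` term, probing what the shared pathway alone encodes.
    """

    def __init__(
        self,
        in_dim: int,
        ctx_dim: int,
        out_dim: int,
        hidden_dim: int = 64,
        activation: str = "tanh",
        init_scale: float = 1.0,
        rng: np.random.Generator | None = None,
        ctx_init_scale: float | None = None,
        optimizer: str = "sgd",
    ):
        """``ctx_init_scale`` sets the initial spread of the context-to-hidden
        pathway separately from the rest (default: same as ``init_scale``).
        A large value gives each (near-orthogonal) context vector a strong,
        distinct hidden activation shift from the outset, which is what
        shields earlier contexts' mappings from later training."""
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = np.random.default_rng(0) if rng is None else rng
        self.in_dim, self.ctx_dim, self.out_dim = in_dim, ctx_dim, out_dim
        self.hidden_dim = hidden_dim
        self.activation = activation
        if ctx_init_scale is None:
            ctx_init_scale = init_scale
        self.W_in = _uniform_init(rng, (hidden_dim, in_dim), init_scale)
        self.W_ctx = _uniform_init(rng, (hidden_dim, max(ctx_dim, 1)), ctx_init_scale)[:, :ctx_dim]
        self.b_h = np.zeros(hidden_dim)
        self.W_out = _uniform_init(rng, (out_dim, hidden_dim), init_scale)
        self.b_out = np.zeros(out_dim)
        if optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        self.optimizer = optimizer
        if optimizer == "adam":
            self._adam = _Adam()

    def forward(self, x: np.ndarray, c: np.ndarray | None, lesioned: bool = False) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        if x.shape != (self.in_dim,):
            raise ValueError(f"expected input of shape ({self.in_dim},), got {x.shape}")
        pre = self.W_in @ x + self.b_h
        if not lesioned and self.ctx_dim > 0:
            c = np.asarray(c, dtype=float)
            if c.shape != (self.ctx_dim,):
                raise ValueError(f"expected context of shape ({self.ctx_dim},), got {c.shape}")
            pre = pre + self.W_ctx @ c
        act, _ = _ACTIVATIONS[self.activation]
        return self.W_out @ act(pre) + self.b_out

    def train_step(
        self, x: np.ndarray, c: np.ndarray | None, target: np.ndarray, learning_rate: float
    ) -> float:
        """One SGD step on MSE(forward(x, c), target); returns pre-update loss."""
        if learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        target = np.atleast_1d(np.asarray(target, dtype=float))
        act, dact = _ACTIVATIONS[self.activation]
        pre = self.W_in @ x + self.b_h
        use_ctx = self.ctx_dim > 0 and c is not None
        if use_ctx:
            c = np.asarray(c, dtype=float)
            pre = pre + self.W_ctx @ c
        h = act(pre)
        y = self.W_out @ h + self.b_out
        err = y - target
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"diverged: loss={loss}, |y|max={np.abs(y).max()}")
        dy = 2.0 * err / err.size
        dh = self.W_out.T @ dy
        dpre = dh * dact(h)
        grads = {
            "W_out": np.outer(dy, h), "b_out": dy,
            "W_in": np.outer(dpre, x), "b_h": dpre,
        }
        if use_ctx:
            grads["W_ctx"] = np.outer(dpre, c)
        _apply_update(self, grads, learning_rate)
        return loss

    # -- checkpointing -------------------------------------------------
    _PARAMS = ("W_in", "W_ctx", "b_h", "W_out", "b_out")

    def to_dict(self) -> dict:
        meta = dict(
            kind="ff", in_dim=self.in_dim, ctx_dim=self.ctx_dim, out_dim=self.out_dim,
            hidden_dim=self.hidden_dim, activation=self.activation,
        )
        meta["params"] = {k: getattr(self, k).tolist() for k in self._PARAMS}
        return meta

    @classmethod
    def from_dict(cls, d: dict) -> "FFNet":
        net = cls(d["in_dim"], d["ctx_dim"], d["out_dim"], d["hidden_dim"], d["activation"])
        for k, v in d["params"].items():
            setattr(net, k, np.asarray(v, dtype=float))
        return net


def ff_forward(params: FFNet, x: np.ndarray, c: np.ndarray | None, lesioned: bool = False) -> np.ndarray:
    """Functional form of :meth:`FFNet.forward`."""
    return params.forward(x, c, lesioned=lesioned)


class GRUNet:
    """GRU with context concatenated to the input and a linear readout.

    Gate dynamics, with ``u = [h_prev, x, c]``::

        update = sigmoid(W_z u + b_z)        # write gate; forget gate is 1-update
        r      = sigmoid(W_r u + b_r)
        h_cand = tanh(W [r*h_prev, x, c] + b_h)
        h      = (1-update)*h_prev + update*h_cand

    Note: the conventional gate symbol z is called ``update`` throughout to
    avoid a clash with the latent-cause assignment variable.
    """

    def __init__(
        self,
        in_dim: int,
        ctx_dim: int,
        out_dim: int,
        hidden_dim: int = 32,
        init_scale: float = 1.0,
        rng: np.random.Generator | None = None,
        optimizer: str = "sgd",
    ):
        rng = np.random.default_rng(0) if rng is None else rng
        self.in_dim, self.ctx_dim, self.out_dim = in_dim, ctx_dim, out_dim
        self.hidden_dim = hidden_dim
        D = hidden_dim + in_dim + ctx_dim
        self.W_z = _uniform_init(rng, (hidden_dim, D), init_scale)
        self.W_r = _uniform_init(rng, (hidden_dim, D), init_scale)
        self.W = _uniform_init(rng, (hidden_dim, D), init_scale)
        self.b_z = np.zeros(hidden_dim)
        self.b_r = np.zeros(hidden_dim)
        self.b_h = np.zeros(hidden_dim)
        self.W_out = _uniform_init(rng, (out_dim, hidden_dim), init_scale)
        self.b_out = np.zeros(out_dim)
        if optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {optimizer!r}")
        self.optimizer = optimizer
        if optimizer == "adam":
            self._adam = _Adam()

    def init_hidden(self) -> np.ndarray:
        return np.zeros(self.hidden_dim)

    def _check(self, x: np.ndarray, c: np.ndarray, h_prev: np.ndarray):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        c = np.atleast_1d(np.asarray(c, dtype=float)) if self.ctx_dim else np.empty(0)
        h_prev = np.asarray(h_prev, dtype=float)
        if x.shape != (self.in_dim,) or c.shape != (self.ctx_dim,) or h_prev.shape != (self.hidden_dim,):
            raise ValueError(
                f"shape mismatch: x{x.shape} c{c.shape} h{h_prev.shape}, expected "
                f"({self.in_dim},) ({self.ctx_dim},) ({self.hidden_dim},)"
            )
        return x, c, h_prev

    def step(self, x: np.ndarray, c: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        x, c, h_prev = self._check(x, c, h_prev)
        u = np.concatenate([h_prev, x, c])
        update = _sigmoid(self.W_z @ u + self.b_z)
        r = _sigmoid(self.W_r @ u + self.b_r)
        v = np.concatenate([r * h_prev, x, c])
        h_cand = np.tanh(self.W @ v + self.b_h)
        return (1.0 - update) * h_prev + update * h_cand

    def readout(self, h: np.ndarray) -> np.ndarray:
        return self.W_out @ h + self.b_out

    def forward(self, x: np.ndarray, c: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        """Predicted next observation after consuming (x, c) from h_prev."""
        return self.readout(self.step(x, c, h_prev))

    def train_step(
        self,
        x: np.ndarray,
        c: np.ndarray,
        target: np.ndarray,
        h_prev: np.ndarray,
        learning_rate: float,
    ) -> float:
        """One SGD step on MSE through a single GRU step (truncated BPTT-1).

        ``h_prev`` is treated as a constant; returns the pre-update loss.
        """
        if learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        x, c, h_prev = self._check(x, c, h_prev)
        target = np.atleast_1d(np.asarray(target, dtype=float))
        H = self.hidden_dim
        u = np.concatenate([h_prev, x, c])
        update = _sigmoid(self.W_z @ u + self.b_z)
        r = _sigmoid(self.W_r @ u + self.b_r)
        v = np.concatenate([r * h_prev, x, c])
        h_cand = np.tanh(self.W @ v + self.b_h)
        h = (1.0 - update) * h_prev + update * h_cand
        y = self.W_out @ h + self.b_out
        err = y - target
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise FloatingPointError(f"diverged: loss={loss}")
        dy = 2.0 * err / err.size
        dh = self.W_out.T @ dy
        d_update = dh * (h_cand - h_prev)
        d_cand = dh * update
        da_cand = d_cand * (1.0 - h_cand**2)          # through tanh
        dv = self.W.T @ da_cand
        dr = dv[:H] * h_prev
        da_r = dr * r * (1.0 - r)
        da_z = d_update * update * (1.0 - update)
        grads = {
            "W_out": np.outer(dy, h), "b_out": dy,
            "W": np.outer(da_cand, v), "b_h": da_cand,
            "W_r": np.outer(da_r, u), "b_r": da_r,
            "W_z": np.outer(da_z, u), "b_z": da_z,
        }
        _apply_update(self, grads, learning_rate)
        return loss

    _PARAMS = ("W_z", "W_r", "W", "b_z", "b_r", "b_h", "W_out", "b_out")

    def to_dict(self) -> dict:
        meta = dict(
            kind="gru", in_dim=self.in_dim, ctx_dim=self.ctx_dim, out_dim=self.out_dim,
            hidden_dim=self.hidden_dim,
        )
        meta["params"] = {k: getattr(self, k).tolist() for k in self._PARAMS}
        return meta

    @classmethod
    def from_dict(cls, d: dict) -> "GRUNet":
        net = cls(d["in_dim"], d["ctx_dim"], d["out_dim"], d["hidden_dim"])
        for k, v in d["params"].items():
            setattr(net, k, np.asarray(v, dtype=float))
        return net


def gru_step(params: GRUNet, x: np.ndarray, c: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`GRUNet.step`."""
    return params.step(x, c, h_prev)


def train_step(network, x_in, c, target, learning_rate: float, h_prev=None) -> float:
    """Dispatch one online SGD step to either network family."""
    if isinstance(network, GRUNet):
        if h_prev is None:
            h_prev = network.init_hidden()
        return network.train_step(x_in, c, target, h_prev, learning_rate)
    return network.train_step(x_in, c, target, learning_rate)


class SEMEnsemble:
    """One independent expert network per latent cause.

    Experts are created lazily by :meth:`select_or_spawn`, each freshly
    initialized from the shared recipe with an independent draw; experts
    never share weights, so training one cannot touch another.
    """

    def __init__(self, factory):
        """``factory(rng) -> network`` builds a fresh expert."""
        self.factory = factory
        self.experts: list = []

    def __len__(self) -> int:
        return len(self.experts)

    def select_or_spawn(self, map_lc: int, init_rng: np.random.Generator):
        if not 0 <= map_lc <= len(self.experts):
            raise ValueError(f"expert index {map_lc} out of range for size {len(self.experts)}")
        if map_lc == len(self.experts):
            self.experts.append(self.factory(init_rng))
        return self.experts[map_lc]


def sem_select_or_spawn(ensemble: SEMEnsemble, map_lc: int, init_rng: np.random.Generator):
    """Functional form of :meth:`SEMEnsemble.select_or_spawn`."""
    return ensemble.select_or_spawn(map_lc, init_rng)


def save_checkpoint(network, path) -> None:
    """Write a JSON checkpoint that round-trips parameters exactly."""
    with open(path, "w") as fh:
        json.dump(network.to_dict(), fh)


def load_checkpoint(path):
    with open(path) as fh:
        d = json.load(fh)
    return {"ff": FFNet, "gru": GRUNet}[d["kind"]].from_dict(d)
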
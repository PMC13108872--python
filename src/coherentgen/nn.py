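"""Minimal feed-forward neural-network core.

Implements exactly what the diffusion noise predictors and the
autoencoder embedders need: dense layers, batch normalization, ReLU,
sinusoidal time embeddings, masked per-modality condition projections and
an Adam optimizer — all in double-precision numpy with hand-written
backpropagation, so training and inference are deterministic functions of
the seed on any platform.

Parameters live in flat dicts of ndarrays, which keeps checkpointing a
plain ``np.savez`` of named arrays plus JSON metadata.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "time_embedding",
    "Dense",
    "BatchNorm",
    "Adam",
    "NoisePredictorMLP",
    "Autoencoder",
]


def time_embedding(t, dim: int) -> np.ndarray:
    """Sinusoidal positional embedding of timestep(s) ``t``.

    Uses ``dim/2`` geometrically spaced frequencies
    ``f_i = 10000 ** (-(i + 1) / (dim / 2))``, interleaved as
    ``[sin(t f_1), cos(t f_1), sin(t f_2), ...]``; every component lies in
    [-1, 1].  ``t`` may be a scalar or a vector; the result has shape
    ``(..., dim)``.
    """
    if dim % 2 != 0:
        raise ValueError(f"embedding dim must be even, got {dim}")
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    half = dim // 2
    freqs = 10000.0 ** (-(np.arange(1, half + 1, dtype=np.float64)) / half)
    angles = t[..., None] * freqs
    out = np.empty(t.shape + (dim,), dtype=np.float64)
    out[..., 0::2] = np.sin(angles)
    out[..., 1::2] = np.cos(angles)
    return out


class Dense:
    """Fully connected layer ``y = x W + b`` with cached backward pass."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, name: str):
        # He-style fan-in scaling; fine for the ReLU stacks used here
        scale = np.sqrt(2.0 / d_in)
        self.W = rng.standard_normal((d_in, d_out)) * scale
        self.b = np.zeros(d_out)
        self.name = name
        self._x = None
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ g
        self.gb = g.sum(axis=0)
        return g @ self.W.T

    def params(self) -> Dict[str, np.ndarray]:
        return {f"{self.name}.W": self.W, f"{self.name}.b": self.b}

    def grads(self) -> Dict[str, np.ndarray]:
        return {f"{self.name}.W": self.gW, f"{self.name}.b": self.gb}


class BatchNorm:
    """Batch normalization with running statistics for evaluation mode."""

    def __init__(self, dim: int, name: str, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv_std
            self._cache = (xhat, inv_std)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv_std
        return self.gamma * xhat + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = g.shape[0]
        self.ggamma = (g * xhat).sum(axis=0)
        self.gbeta = g.sum(axis=0)
        gx_hat = g * self.gamma
        return (
            inv_std / n
        ) * (n * gx_hat - gx_hat.sum(axis=0) - xhat * (gx_hat * xhat).sum(axis=0))

    def params(self) -> Dict[str, np.ndarray]:
        return {
            f"{self.name}.gamma": self.gamma,
            f"{self.name}.beta": self.beta,
            f"{self.name}.running_mean": self.running_mean,
            f"{self.name}.running_var": self.running_var,
        }

    def grads(self) -> Dict[str, np.ndarray]:
        return {f"{self.name}.gamma": self.ggamma, f"{self.name}.beta": self.gbeta}


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: Dict[str, np.ndarray] = {}
        self.v: Dict[str, np.ndarray] = {}
        self.step_count = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.step_count += 1
        t = self.step_count
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**t)
            vhat = self.v[k] / (1 - self.beta2**t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class NoisePredictorMLP:
    """MLP noise predictor for conditional diffusion over latent vectors.

    Input is the concatenation ``[x_t | time-embedding | condition
    embeddings]``.  Each hidden layer is linear -> batch-norm -> ReLU, and
    the sinusoidal time embedding is re-concatenated with every hidden
    layer's output so the timestep signal survives depth.  Each
    conditioning modality has its own linear projection to
    ``cond_embed_dim``; an absent modality contributes an exact zero block
    regardless of the values supplied for it.

    Parameters
    ----------
    D : int
        Dimension of the target latent space (input and output).
    cond_dims : dict
        Ordered map modality name -> that modality's latent dimension.
        The concatenation order of condition blocks is the iteration
        order of this dict and is fixed at construction.
    """

    def __init__(
        self,
        D: int,
        cond_dims: Dict[str, int],
        n_hidden_layers: int = 4,
        hidden_size: int = 256,
        time_embed_dim: int = 64,
        cond_embed_dim: int = 16,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.D = D
        self.cond_names: List[str] = list(cond_dims)
        self.cond_dims = dict(cond_dims)
        self.time_embed_dim = time_embed_dim
        self.cond_embed_dim = cond_embed_dim
        self.n_hidden_layers = n_hidden_layers
        self.hidden_size = hidden_size

        self.cond_proj = {
            name: Dense(cond_dims[name], cond_embed_dim, rng, f"cond.{name}")
            for name in self.cond_names
        }
        in_dim = D + time_embed_dim + cond_embed_dim * len(self.cond_names)
        self.hidden: List[Dense] = []
        self.norms: List[BatchNorm] = []
        d = in_dim
        for i in range(n_hidden_layers):
            self.hidden.append(Dense(d, hidden_size, rng, f"h{i}"))
            self.norms.append(BatchNorm(hidden_size, f"bn{i}"))
            d = hidden_size + time_embed_dim  # time embedding re-injected
        self.out = Dense(d, D, rng, "out")
        self._cache = None

    # ------------------------------------------------------------------
    def _cond_block(self, conditions, n: int, train: bool):
        """Project conditions into the concatenated embedding block.

        ``conditions`` maps modality name -> (values (n, d_m) or None,
        present mask (n,) bool).  Missing names are treated as absent.
        """
        blocks = []
        masks = []
        for name in self.cond_names:
            values, present = (None, None)
            if conditions and name in conditions:
                values, present = conditions[name]
            if values is None:
                block = np.zeros((n, self.cond_embed_dim))
                mask = np.zeros(n, dtype=bool)
            else:
                values = np.asarray(values, dtype=np.float64)
                if values.shape != (n, self.cond_dims[name]):
                    raise ValueError(
                        f"condition {name!r} has shape {values.shape}, expected "
                        f"({n}, {self.cond_dims[name]})"
                    )
                mask = (
                    np.ones(n, dtype=bool) if present is None else np.asarray(present, bool)
                )
                block = self.cond_proj[name].forward(values, train)
                block = np.where(mask[:, None], block, 0.0)
            blocks.append(block)
            masks.append(mask)
        if blocks:
            return np.concatenate(blocks, axis=1), masks
        return np.zeros((n, 0)), masks

    def forward(self, xt: np.ndarray, t, conditions=None) -> np.ndarray:
        """Evaluation-mode prediction (batch-norm uses running statistics)."""
        xt = np.asarray(xt, dtype=np.float64)
        n = xt.shape[0]
        if xt.shape[1] != self.D:
            raise ValueError(f"xt has dimension {xt.shape[1]}, expected {self.D}")
        t_arr = np.broadcast_to(np.asarray(t, dtype=np.float64), (n,))
        temb = time_embedding(t_arr, self.time_embed_dim)
        cond_block, _ = self._cond_block(conditions, n, train=False)
        h = np.concatenate([xt, temb, cond_block], axis=1)
        for dense, bn in zip(self.hidden, self.norms):
            h = dense.forward(h, False)
            h = bn.forward(h, False)
            h = np.maximum(h, 0.0)
            h = np.concatenate([h, temb], axis=1)
        return self.out.forward(h, False)

    def backward(self, g_out: np.ndarray) -> None:
        """Backprop from d(loss)/d(output); fills every layer's grads."""
        n, masks = self._cache
        g = self.out.backward(g_out)
        for dense, bn in zip(reversed(self.hidden), reversed(self.norms)):
            g = g[:, : self.hidden_size]  # drop the re-injected time block
            relu_out = bn._relu_out
            g = g * (relu_out > 0)
            g = bn.backward(g)
            g = dense.backward(g)
        # split the input gradient back into condition blocks
        offset = self.D + self.time_embed_dim
        for name, mask in zip(self.cond_names, masks):
            blk = g[:, offset : offset + self.cond_embed_dim]
            if mask.any():
                self.cond_proj[name].backward(np.where(mask[:, None], blk, 0.0))
            else:
                self.cond_proj[name].gW[:] = 0.0
                self.cond_proj[name].gb[:] = 0.0
            offset += self.cond_embed_dim

    def _train_forward(self, xt, t, conditions):
        """Training-mode pass; caches post-ReLU activations for backward()."""
        xt = np.asarray(xt, dtype=np.float64)
        n = xt.shape[0]
        t_arr = np.broadcast_to(np.asarray(t, dtype=np.float64), (n,))
        temb = time_embedding(t_arr, self.time_embed_dim)
        cond_block, masks = self._cond_block(conditions, n, train=True)
        h = np.concatenate([xt, temb, cond_block], axis=1)
        for dense, bn in zip(self.hidden, self.norms):
            h = dense.forward(h, True)
            h = bn.forward(h, True)
            h = np.maximum(h, 0.0)
            bn._relu_out = h
            h = np.concatenate([h, temb], axis=1)
        out = self.out.forward(h, True)
        self._cache = (n, masks)
        return out

    # ------------------------------------------------------------------
    def _layers(self):
        return [*self.cond_proj.values(), *self.hidden, *self.norms, self.out]

    def params(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for layer in self._layers():
            out.update(layer.params())
        return out

    def grads(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for layer in self._layers():
            out.update(layer.grads())
        return out

    def set_params(self, params: Dict[str, np.ndarray]) -> None:
        own = self.params()
        for k, v in params.items():
            own[k][...] = v

    def config(self) -> dict:
        return {
            "D": self.D,
            "cond_dims": self.cond_dims,
            "n_hidden_layers": self.n_hidden_layers,
            "hidden_size": self.hidden_size,
            "time_embed_dim": self.time_embed_dim,
            "cond_embed_dim": self.cond_embed_dim,
        }

    @classmethod
    def from_config(cls, cfg: dict) -> "NoisePredictorMLP":
        return cls(
            D=cfg["D"],
            cond_dims=cfg["cond_dims"],
            n_hidden_layers=cfg["n_hidden_layers"],
            hidden_size=cfg["hidden_size"],
            time_embed_dim=cfg["time_embed_dim"],
            cond_embed_dim=cfg["cond_embed_dim"],
        )


class Autoencoder:
    """Symmetric MLP autoencoder used for per-modality latent embedding.

    One hidden layer per side (``d -> hidden -> latent -> hidden -> d``),
    ReLU activations, reconstruction-MSE objective, Adam, early stopping
    on validation loss.
    """

    def __init__(self, d_in: int, latent_dim: int, hidden: int = 128, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.d_in, self.latent_dim, self.hidden_dim = d_in, latent_dim, hidden
        self.enc1 = Dense(d_in, hidden, rng, "enc1")
        self.enc2 = Dense(hidden, latent_dim, rng, "enc2")
        self.dec1 = Dense(latent_dim, hidden, rng, "dec1")
        self.dec2 = Dense(hidden, d_in, rng, "dec2")

    def encode(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.maximum(self.enc1.forward(x, train), 0.0)
        if train:
            self._h_enc = h
        return self.enc2.forward(h, train)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        h = np.maximum(self.dec1.forward(z, train), 0.0)
        if train:
            self._h_dec = h
        return self.dec2.forward(h, train)

    def _layers(self):
        return [self.enc1, self.enc2, self.dec1, self.dec2]

    def params(self):
        out = {}
        for l in self._layers():
            out.update(l.params())
        return out

    def grads(self):
        out = {}
        for l in self._layers():
            out.update(l.grads())
        return out

    def fit(
        self,
        X_train: np.ndarray,
        X_val: np.ndarray,
        lr: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 500,
        patience: int = 20,
        seed: int = 0,
    ) -> List[float]:
        """Train to reconstruct ``X_train``; early-stop on ``X_val`` MSE.

        Returns the per-epoch validation-loss history; the parameters of
        the best epoch are restored before returning.
        """
        rng = np.random.default_rng(seed)
        opt = Adam(lr=lr)
        n = X_train.shape[0]
        best = np.inf
        best_params = None
        bad = 0
        history: List[float] = []
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = X_train[idx]
                z = self.encode(xb, train=True)
                xr = self.decode(z, train=True)
                g = 2.0 * (xr - xb) / xb.size
                gh = self.dec2.backward(g)
                gh = gh * (self._h_dec > 0)
                gz = self.dec1.backward(gh)
                gh = self.enc2.backward(gz)
                gh = gh * (self._h_enc > 0)
                self.enc1.backward(gh)
                opt.step(self.params(), self.grads())
            val_loss = float(np.mean((self.decode(self.encode(X_val)) - X_val) ** 2))
            history.append(val_loss)
            if val_loss < best - 1e-9:
                best = val_loss
                best_params = {k: v.copy() for k, v in self.params().items()}
                bad = 0
            else:
                bad += 1
                if bad >= patience:
                    break
        if best_params is not None:
            own = self.params()
            for k, v in best_params.items():
                own[k][...] = v
        return history
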
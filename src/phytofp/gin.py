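"""A compact Graph Isomorphism Network in numpy.

Each layer aggregates neighbour states by summation (plus a learned linear
term over incident bond features) and transforms the result with a two-layer
ReLU MLP; whole-molecule readout is sum pooling followed by a linear softmax
classifier.  Sum aggregation plus sum pooling makes the network invariant to
atom input order and, per the Weisfeiler-Lehman argument, maximally
discriminative among message-passing architectures.

Training is full-batch Adam on the softmax cross-entropy, with inverted
dropout on the MLP hidden activations.  Training arithmetic is float32;
inference runs in float64, so predictions are atom-order invariant far below
any practical tolerance.  Every random draw is seeded, so runs are
reproducible bit-for-bit on one platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .molgraph import GraphBatch

__all__ = ["GinConfig", "GinNetwork"]

_DTYPE = np.float32


@dataclass(frozen=True)
class GinConfig:
    """Architecture and optimization hyperparameters.

    ``n_layers`` message-passing rounds of width ``hidden``; dropout applies
    to MLP hidden activations during training only.
    """

    n_layers: int = 5
    hidden: int = 64
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 100
    weight_scale: float = 0.1

    def to_json(self) -> str:
        return json.dumps(self.__dict__)

    @classmethod
    def from_json(cls, text: str) -> "GinConfig":
        return cls(**json.loads(text))


class _BatchOps:
    """Sparse operators and projected edge features for one graph batch.

    ``edge_proj`` is the per-node sum of incident bond-feature vectors,
    (N, edge_dim); computing it once removes all per-epoch edge-incidence
    sparse products (the edge contribution becomes ``edge_proj @ We``).
    """

    def __init__(self, batch: GraphBatch, dtype=_DTYPE):
        n = batch.node_x.shape[0]
        m = batch.edge_index.shape[0]
        if m:
            rows = np.r_[batch.edge_index[:, 0], batch.edge_index[:, 1]]
            cols = np.r_[batch.edge_index[:, 1], batch.edge_index[:, 0]]
            self.adj = sp.coo_matrix(
                (np.ones(2 * m, dtype=dtype), (rows, cols)), shape=(n, n)
            ).tocsr()
            inc = sp.coo_matrix(
                (np.ones(2 * m, dtype=dtype), (rows, np.r_[np.arange(m), np.arange(m)])),
                shape=(n, m),
            ).tocsr()
            self.edge_proj = np.asarray(inc @ np.asarray(batch.edge_x, dtype=dtype), dtype=dtype)
        else:
            self.adj = sp.csr_matrix((n, n), dtype=dtype)
            self.edge_proj = np.zeros((n, batch.edge_x.shape[1]), dtype=dtype)
        self.pool = sp.coo_matrix(
            (np.ones(n, dtype=dtype), (batch.graph_ids, np.arange(n))),
            shape=(batch.n_graphs, n),
        ).tocsr()
        self.node_x = np.asarray(batch.node_x, dtype=dtype)
        self.dtype = dtype


@dataclass
class GinNetwork:
    """Trainable GIN graph classifier over a fixed label set."""

    config: GinConfig
    node_dim: int
    edge_dim: int
    n_classes: int
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        s = cfg.weight_scale
        ps: dict[str, np.ndarray] = {}
        din = self.node_dim
        for l in range(cfg.n_layers):
            ps[f"We{l}"] = rng.normal(scale=s, size=(self.edge_dim, din)).astype(_DTYPE)
            ps[f"W1{l}"] = rng.normal(scale=s, size=(din, cfg.hidden)).astype(_DTYPE)
            ps[f"b1{l}"] = np.zeros(cfg.hidden, dtype=_DTYPE)
            ps[f"W2{l}"] = rng.normal(scale=s, size=(cfg.hidden, cfg.hidden)).astype(_DTYPE)
            ps[f"b2{l}"] = np.zeros(cfg.hidden, dtype=_DTYPE)
            din = cfg.hidden
        ps["Wo"] = rng.normal(scale=s, size=(cfg.hidden, self.n_classes)).astype(_DTYPE)
        ps["bo"] = np.zeros(self.n_classes, dtype=_DTYPE)
        self.params = ps

    # ------------------------------------------------------------------ forward

    def _forward(self, ops: _BatchOps, dropout_rng: np.random.Generator | None = None):
        """Return (probabilities, cache).  Dropout is active iff a rng is given."""
        dtype = ops.dtype
        ps = self.params
        if ps and ps["bo"].dtype != dtype:
            ps = {k: v.astype(dtype) for k, v in ps.items()}
        cfg = self.config
        h = ops.node_x
        cache = []
        for l in range(cfg.n_layers):
            z = h + ops.adj @ h + ops.edge_proj @ ps[f"We{l}"]
            z1 = z @ ps[f"W1{l}"] + ps[f"b1{l}"]
            h1 = np.maximum(z1, 0.0)
            mask = None
            if dropout_rng is not None and cfg.dropout > 0:
                keep = _DTYPE(1.0 - cfg.dropout)
                mask = (dropout_rng.random(h1.shape, dtype=_DTYPE) < keep) / keep
                h1 *= mask
            z2 = h1 @ ps[f"W2{l}"] + ps[f"b2{l}"]
            h2 = np.maximum(z2, 0.0)
            cache.append((z, z1, h1, z2, mask))
            h = h2
        pooled = ops.pool @ h
        logits = (pooled @ ps["Wo"] + ps["bo"]).astype(np.float64)
        shifted = logits - logits.max(axis=1, keepdims=True)
        ex = np.exp(shifted)
        prob = ex / ex.sum(axis=1, keepdims=True)
        return prob, (cache, pooled)

    def predict_proba(self, batch: GraphBatch) -> np.ndarray:
        """(n_graphs, n_classes) softmax probabilities; rows sum to 1."""
        prob, _ = self._forward(_BatchOps(batch, dtype=np.float64))
        return prob

    # ----------------------------------------------------------------- training

    def _gradients(self, ops: _BatchOps, y: np.ndarray,
                   dropout_rng: np.random.Generator | None):
        ps = self.params
        prob, (cache, pooled) = self._forward(ops, dropout_rng)
        n = len(y)
        loss = float(-np.mean(np.log(np.clip(prob[np.arange(n), y], 1e-12, None))))
        grads: dict[str, np.ndarray] = {}
        dlog = (prob.astype(_DTYPE))
        dlog[np.arange(n), y] -= 1.0
        dlog /= _DTYPE(n)
        grads["Wo"] = pooled.T @ dlog
        grads["bo"] = dlog.sum(axis=0)
        dh = ops.pool.T @ (dlog @ ps["Wo"].T)
        for l in reversed(range(self.config.n_layers)):
            z, z1, h1, z2, mask = cache[l]
            dz2 = dh * (z2 > 0)
            grads[f"W2{l}"] = h1.T @ dz2
            grads[f"b2{l}"] = dz2.sum(axis=0)
            dh1 = dz2 @ ps[f"W2{l}"].T
            if mask is not None:
                dh1 *= mask
            dz1 = dh1 * (z1 > 0)
            grads[f"W1{l}"] = z.T @ dz1
            grads[f"b1{l}"] = dz1.sum(axis=0)
            dz = dz1 @ ps[f"W1{l}"].T
            grads[f"We{l}"] = ops.edge_proj.T @ dz
            dh = dz + ops.adj @ dz  # adjacency is symmetric
        return loss, grads

    def fit(self, batch: GraphBatch, y: np.ndarray, seed: int,
            verbose: bool = False) -> list[float]:
        """Full-batch Adam training; returns the per-epoch loss trace."""
        rng = np.random.default_rng(seed)
        self.init_params(rng)
        ops = _BatchOps(batch)
        cfg = self.config
        y = np.asarray(y)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(v_) for k, v_ in self.params.items()}
        beta1, beta2, eps = _DTYPE(0.9), _DTYPE(0.999), _DTYPE(1e-8)
        lr = _DTYPE(cfg.learning_rate)
        drop_rng = (
            np.random.default_rng(int(rng.integers(2**31))) if cfg.dropout > 0 else None
        )
        losses: list[float] = []
        for t in range(1, cfg.epochs + 1):
            loss, grads = self._gradients(ops, y, drop_rng)
            losses.append(loss)
            bc1 = _DTYPE(1.0 - 0.9**t)
            bc2 = _DTYPE(1.0 - 0.999**t)
            for k in self.params:
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                self.params[k] -= lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + eps)
            if verbose and t % 25 == 0:
                print(f"epoch {t:4d}  loss {loss:.4f}")
        return losses

    # -------------------------------------------------------------- persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "gin_config.json").write_text(self.config.to_json())
        meta = {"node_dim": self.node_dim, "edge_dim": self.edge_dim,
                "n_classes": self.n_classes}
        (directory / "gin_meta.json").write_text(json.dumps(meta))
        np.savez(directory / "gin_params.npz", **self.params)

    @classmethod
    def load(cls, directory: str | Path) -> "GinNetwork":
        directory = Path(directory)
        config = GinConfig.from_json((directory / "gin_config.json").read_text())
        meta = json.loads((directory / "gin_meta.json").read_text())
        with np.load(directory / "gin_params.npz") as npz:
            params = {k: npz[k] for k in npz.files}
        return cls(config=config, params=params, **meta)
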
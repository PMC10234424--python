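"""Structural Deep Network Embedding (SDNE) of the bridge network.

A deep autoencoder maps each node's adjacency row x_i through sigmoid layers
to a latent code y_i (the embedding) and back to a reconstruction x̂_i.  The
objective couples three terms:

* second-order proximity — the reconstruction error ||(X̂ - X) ⊙ B||_F² with
  b_ij = β > 1 wherever x_ij ≠ 0, so observed edges are penalized harder than
  the (many) zeros of a sparse network;
* first-order proximity — α · Σ_ij s_ij ||y_i - y_j||², pulling the codes of
  adjacent nodes together (equivalently 2α·tr(YᵀLY) with L the graph
  Laplacian);
* an L2 weight regularizer ν · ½ Σ_k (||W(k)||² + ||Ŵ(k)||²), biases excluded.

Gradients are computed analytically (plain backpropagation in numpy) and
minimized full-batch with Adam.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import BHNet

logger = logging.getLogger(__name__)

EMBED_DIM = 128


@dataclass
class SdneConfig:
    """Hyperparameters of the embedding.

    ``layer_dims`` are the encoder hidden sizes, ending at the embedding
    dimension.  ``alpha`` weights the first-order (Laplacian) term, ``beta``
    is the reconstruction reweight on non-zero adjacency entries (must exceed
    1 or the term degenerates to plain reconstruction), ``nu`` the weight
    decay.  Defaults sit in the ranges customary for deep network-embedding
    autoencoders on networks of a few hundred to a few thousand nodes.
    """

    layer_dims: list[int] = field(default_factory=lambda: [256, EMBED_DIM])
    alpha: float = 0.05
    beta: float = 5.0
    nu: float = 1e-4
    learning_rate: float = 1e-3
    epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 1:
            raise ValueError("beta must exceed 1")
        if self.alpha < 0 or self.nu < 0:
            raise ValueError("alpha and nu must be non-negative")
        if not self.layer_dims:
            raise ValueError("layer_dims must be non-empty")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SdneModel:
    """Encoder/decoder weights; the decoder mirrors the encoder layer sizes."""

    enc_W: list[np.ndarray]
    enc_b: list[np.ndarray]
    dec_W: list[np.ndarray]
    dec_b: list[np.ndarray]

    @classmethod
    def init(cls, input_dim: int, layer_dims: list[int], rng: np.random.Generator) -> "SdneModel":
        dims = [input_dim] + list(layer_dims)
        enc_W, enc_b = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
            enc_W.append(rng.uniform(-scale, scale, size=(d_in, d_out)))
            enc_b.append(np.zeros(d_out))
        rev = dims[::-1]
        dec_W, dec_b = [], []
        for d_in, d_out in zip(rev[:-1], rev[1:]):
            scale = np.sqrt(6.0 / (d_in + d_out))
            dec_W.append(rng.uniform(-scale, scale, size=(d_in, d_out)))
            dec_b.append(np.zeros(d_out))
        return cls(enc_W, enc_b, dec_W, dec_b)

    @property
    def params(self) -> list[np.ndarray]:
        return self.enc_W + self.enc_b + self.dec_W + self.dec_b

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        enc_acts = [X]
        for W, b in zip(self.enc_W, self.enc_b):
            enc_acts.append(_sigmoid(enc_acts[-1] @ W + b))
        dec_acts = [enc_acts[-1]]
        for W, b in zip(self.dec_W, self.dec_b):
            dec_acts.append(_sigmoid(dec_acts[-1] @ W + b))
        return enc_acts, dec_acts


def encode(model: SdneModel, X: np.ndarray) -> np.ndarray:
    """Forward pass through the encoder: y(k) = σ(W(k) y(k-1) + b(k))."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.enc_W[0].shape[0]:
        raise ValueError(
            f"input dim {X.shape[1]} != encoder input {model.enc_W[0].shape[0]}")
    h = X
    for W, b in zip(model.enc_W, model.enc_b):
        h = _sigmoid(h @ W + b)
    return h


def decode(model: SdneModel, Y: np.ndarray) -> np.ndarray:
    """Mirror forward pass reconstructing adjacency rows from codes."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != model.dec_W[0].shape[0]:
        raise ValueError(
            f"code dim {Y.shape[1]} != decoder input {model.dec_W[0].shape[0]}")
    h = Y
    for W, b in zip(model.dec_W, model.dec_b):
        h = _sigmoid(h @ W + b)
    return h


# ---------------------------------------------------------------------------
# Loss terms
# ---------------------------------------------------------------------------

def penalty_matrix(X: np.ndarray, beta: float) -> np.ndarray:
    if beta <= 1:
        raise ValueError("beta must exceed 1")
    B = np.ones_like(X, dtype=float)
    B[X != 0] = beta
    return B


def loss_second_order(X: np.ndarray, X_hat: np.ndarray, beta: float) -> float:
    """Reweighted reconstruction error ||(X̂ - X) ⊙ B||_F²."""
    X, X_hat = np.asarray(X, float), np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError("shape mismatch")
    B = penalty_matrix(X, beta)
    return float(np.sum(((X_hat - X) * B) ** 2))


def loss_first_order(S: np.ndarray, Y: np.ndarray) -> float:
    """Laplacian smoothness Σ_ij s_ij ||y_i - y_j||² over both ordered pairs."""
    S, Y = np.asarray(S, float), np.asarray(Y, float)
    if S.shape[0] != S.shape[1] or S.shape[0] != Y.shape[0]:
        raise ValueError("shape mismatch")
    deg = S.sum(axis=1)
    # 2·tr(Yᵀ L Y) with L = D - S; equals the explicit double sum for symmetric S
    return float(2.0 * (np.sum(deg[:, None] * Y * Y) - np.sum(Y * (S @ Y))))


def loss_reg(model: SdneModel) -> float:
    """½ Σ_k ||W(k)||_F² + ||Ŵ(k)||_F², biases excluded."""
    return float(0.5 * sum(np.sum(W ** 2) for W in model.enc_W + model.dec_W))


def loss_total(
    S: np.ndarray, model: SdneModel, config: SdneConfig
) -> dict[str, float]:
    """Joint objective L = L_2nd + α·L_1st + ν·L_reg with its components."""
    S = np.asarray(S, float)
    Y = encode(model, S)
    X_hat = decode(model, Y)
    l2 = loss_second_order(S, X_hat, config.beta)
    l1 = loss_first_order(S, Y)
    lr = loss_reg(model)
    return {
        "second_order": l2,
        "first_order": l1,
        "reg": lr,
        "total": l2 + config.alpha * l1 + config.nu * lr,
    }


# ---------------------------------------------------------------------------
# Gradients (backpropagation)
# ---------------------------------------------------------------------------

def gradients(S: np.ndarray, model: SdneModel, config: SdneConfig) -> list[np.ndarray]:
    """Analytic gradient of the joint objective w.r.t. ``model.params``.

    Layout matches :attr:`SdneModel.params`:
    enc_W..., enc_b..., dec_W..., dec_b... .
    """
    S = np.asarray(S, float)
    X = S
    enc_acts, dec_acts = model._forward(X)
    Y, X_hat = enc_acts[-1], dec_acts[-1]

    B = penalty_matrix(X, config.beta)
    # d L2nd / d X_hat
    delta = 2.0 * (X_hat - X) * B * B
    dec_dW, dec_db = [], []
    for k in range(len(model.dec_W) - 1, -1, -1):
        a_out, a_in = dec_acts[k + 1], dec_acts[k]
        dz = delta * a_out * (1.0 - a_out)  # sigmoid'
        dec_dW.append(a_in.T @ dz + config.nu * model.dec_W[k])
        dec_db.append(dz.sum(axis=0))
        delta = dz @ model.dec_W[k].T
    dec_dW.reverse()
    dec_db.reverse()

    # first-order term contributes 4·α·L·Y at the code layer
    deg = S.sum(axis=1)
    L_Y = deg[:, None] * Y - S @ Y
    delta = delta + 4.0 * config.alpha * L_Y

    enc_dW, enc_db = [], []
    for k in range(len(model.enc_W) - 1, -1, -1):
        a_out, a_in = enc_acts[k + 1], enc_acts[k]
        dz = delta * a_out * (1.0 - a_out)
        enc_dW.append(a_in.T @ dz + config.nu * model.enc_W[k])
        enc_db.append(dz.sum(axis=0))
        delta = dz @ model.enc_W[k].T
    enc_dW.reverse()
    enc_db.reverse()

    return enc_dW + enc_db + dec_dW + dec_db


def numerical_gradients(
    S: np.ndarray, model: SdneModel, config: SdneConfig, eps: float = 1e-6
) -> list[np.ndarray]:
    """Central-difference gradient of the joint objective; test oracle for
    :func:`gradients` on small instances (O(#params) loss evaluations)."""
    grads = []
    for p in model.params:
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_total(S, model, config)["total"]
            p[idx] = orig - eps
            lm = loss_total(S, model, config)["total"]
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads.append(g)
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(
    net: BHNet,
    config: SdneConfig | None = None,
    *,
    return_history: bool = False,
) -> np.ndarray | tuple[np.ndarray, SdneModel, list[dict[str, float]]]:
    """Learn the n x 128 embedding of all network nodes.

    Full-batch Adam on the joint objective; the input of node i is row i of
    the adjacency matrix.  Returns the code-layer activations, row-aligned
    with the network node index.  Deterministic given ``config.seed``.
    """
    config = config or SdneConfig()
    S = net.dense()
    rng = np.random.default_rng(config.seed)
    model = SdneModel.init(net.n, config.layer_dims, rng)

    params = model.params
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    history: list[dict[str, float]] = []

    initial = loss_total(S, model, config)
    history.append(initial)
    for epoch in range(1, config.epochs + 1):
        grads = gradients(S, model, config)
        for i, (p, g) in enumerate(zip(params, grads)):
            m[i] = b1 * m[i] + (1 - b1) * g
            v[i] = b2 * v[i] + (1 - b2) * g * g
            mhat = m[i] / (1 - b1 ** epoch)
            vhat = v[i] / (1 - b2 ** epoch)
            p -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if epoch % 20 == 0 or epoch == config.epochs:
            cur = loss_total(S, model, config)
            if not np.isfinite(cur["total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {cur}")
            history.append(cur)
            logger.info("epoch %d: total=%.4f 2nd=%.4f 1st=%.4f reg=%.4f",
                        epoch, cur["total"], cur["second_order"],
                        cur["first_order"], cur["reg"])

    Y = encode(model, S)
    if not np.isfinite(Y).all():
        raise FloatingPointError("non-finite embedding values")
    if return_history:
        return Y, model, history
    return Y
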
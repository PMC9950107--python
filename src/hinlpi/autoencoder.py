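"""Sparse autoencoder that lifts node embeddings from d to 2d dimensions.

A single sigmoid hidden layer of width 2d is trained to reconstruct the
input through a linear output layer, with a KL-divergence penalty pushing
each hidden unit's mean activation toward a small target rho:

    J = (1/2N) sum_i ||x_hat_i - x_i||^2  +  beta * sum_j KL(rho || rho_hat_j)

    KL(rho || q) = rho log(rho/q) + (1-rho) log((1-rho)/(1-q))

The encoded table (hidden activations, values in (0,1)) is the lifted
feature set handed to the classifiers. The stage is optional in the
pipeline; the base evaluation runs on the raw d-dimensional embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .io_formats import EmbeddingTable

_ACT_EPS = 1e-10  # keeps rho_hat away from {0,1} inside the KL logs


@dataclass
class AEParams:
    W1: np.ndarray  # (d_in, d_hidden) encoder weights
    b1: np.ndarray  # (d_hidden,)
    W2: np.ndarray  # (d_hidden, d_in) decoder weights
    b2: np.ndarray  # (d_in,)
    rho: float
    beta: float

    def __post_init__(self) -> None:
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0,1)")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def d_in(self) -> int:
        return self.W1.shape[0]

    @property
    def d_hidden(self) -> int:
        return self.W1.shape[1]


def _forward(params: AEParams, X: np.ndarray):
    hidden = expit(X @ params.W1 + params.b1)
    recon = hidden @ params.W2 + params.b2
    return hidden, recon


def kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    """sum_j KL(rho || rho_hat_j); >= 0, zero iff rho_hat_j == rho for all j."""
    q = np.clip(rho_hat, _ACT_EPS, 1.0 - _ACT_EPS)
    return float(
        np.sum(rho * np.log(rho / q) + (1 - rho) * np.log((1 - rho) / (1 - q)))
    )


def ae_loss(params: AEParams, X: np.ndarray) -> float:
    hidden, recon = _forward(params, X)
    n = X.shape[0]
    mse = float(np.sum((recon - X) ** 2)) / (2.0 * n)
    if params.beta == 0:
        return mse
    return mse + params.beta * kl_sparsity(params.rho, hidden.mean(axis=0))


def ae_gradients(params: AEParams, X: np.ndarray):
    """Analytic full-batch gradients of :func:`ae_loss`."""
    n = X.shape[0]
    hidden, recon = _forward(params, X)
    delta_out = (recon - X) / n  # (n, d_in)
    gW2 = hidden.T @ delta_out
    gb2 = delta_out.sum(axis=0)
    back = delta_out @ params.W2.T  # (n, d_hidden)
    if params.beta > 0:
        rho_hat = np.clip(hidden.mean(axis=0), _ACT_EPS, 1.0 - _ACT_EPS)
        kl_grad = params.beta * (
            -params.rho / rho_hat + (1.0 - params.rho) / (1.0 - rho_hat)
        ) / n
        back = back + kl_grad  # broadcast over samples
    delta_hidden = back * hidden * (1.0 - hidden)
    gW1 = X.T @ delta_hidden
    gb1 = delta_hidden.sum(axis=0)
    return gW1, gb1, gW2, gb2


def ae_init(d_in: int, d_hidden: int, rho: float, beta: float, seed: int) -> AEParams:
    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(d_in)
    return AEParams(
        rng.uniform(-scale, scale, (d_in, d_hidden)),
        np.zeros(d_hidden),
        rng.uniform(-scale, scale, (d_hidden, d_in)),
        np.zeros(d_in),
        rho,
        beta,
    )


def ae_train(
    embeddings: EmbeddingTable,
    rho: float = 0.05,
    beta: float = 0.1,
    epochs: int = 500,
    lr: float = 0.5,
    seed: int = 0,
    d_hidden: int | None = None,
) -> AEParams:
    """Full-batch gradient descent on the sparse reconstruction loss;
    the hidden width defaults to twice the input dimension (the d -> 2d
    lift). Deterministic under ``seed``."""
    if len(embeddings) < 2:
        raise ValueError("need at least 2 embedding rows")
    X = embeddings.vectors
    d_in = X.shape[1]
    params = ae_init(d_in, d_hidden or 2 * d_in, rho, beta, seed)
    for _ in range(epochs):
        gW1, gb1, gW2, gb2 = ae_gradients(params, X)
        params.W1 -= lr * gW1
        params.b1 -= lr * gb1
        params.W2 -= lr * gW2
        params.b2 -= lr * gb2
    return params


def ae_encode(params: AEParams, embeddings: EmbeddingTable) -> EmbeddingTable:
    """Hidden activations per node: same ids, doubled dimension (by
    default), every value in (0,1). Pure function of the trained params."""
    if embeddings.dim != params.d_in:
        raise ValueError(
            f"input dimension {embeddings.dim} != encoder dimension {params.d_in}"
        )
    hidden = expit(embeddings.vectors @ params.W1 + params.b1)
    return EmbeddingTable(list(embeddings.ids), hidden)
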
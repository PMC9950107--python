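"""Three-layer relation-prediction network and its SGD trainer.

The model scores whether a relation r (a meta-path pattern) holds between a
source node m and a target node n:

    Pr(r | m, n) = sigmoid( sum_k  WM[m,k] * WN[n,k] * f01(WR[r])_k )

where WM, WN are source/target node latent matrices, WR the relation latent
matrix, and f01 the elementwise logistic sigmoid that confines the relation
vector to (0, 1) — nodes and relations live in different representation
spaces, and the squashed relation vector acts as a soft coordinate mask on
the Hadamard product of the node vectors. The hidden layer applies no
further nonlinearity; the output layer sums the masked product and squashes
with a sigmoid, making the whole thing a differentiable binary classifier.

Training *ascends* the per-tuple Bernoulli log-likelihood

    log O(m,n,r) = B log Pr(r|m,n) + (1 - B) log(1 - Pr(r|m,n))

by stochastic gradient steps that touch only the three rows involved. With
e = label - p and h = f01(WR[r]):

    d/dWM[m] = e * (WN[n] ⊙ h)
    d/dWN[n] = e * (WM[m] ⊙ h)
    d/dWR[r] = e * (WM[m] ⊙ WN[n] ⊙ h ⊙ (1 - h))

A positive tuple may indicate several relations at once (its multi-hot y);
its objective and gradients are the sums of the per-relation terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .hetnet import HeteroNetwork
from .io_formats import EmbeddingTable
from .metapath import RelationSet, TrainingTuple

EPS = 1e-12  # probability clip inside logs; documented saturation handling


@dataclass
class TrainConfig:
    """Training hyperparameters. The embedding dimension defaults to 64
    (the pipeline's pre-autoencoder width); learning rate, epochs and the
    uniform init half-width 0.5/d are implementation choices."""

    d: int = 64
    lr: float = 0.025
    epochs: int = 5
    seed: int = 0
    init_scale: float | None = None  # default 0.5 / d
    # exported node embedding: the mean (WM+WN)/2 carries both the node's
    # source and target roles, so downstream pair features retain the
    # bilinear source-target link signal the model scores with; WM or WN
    # alone are available as switches
    export: str = "mean"

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.export not in ("WM", "WN", "mean"):
            raise ValueError("export must be WM, WN or mean")

    @property
    def scale(self) -> float:
        return 0.5 / self.d if self.init_scale is None else self.init_scale


@dataclass
class ModelParams:
    """Latent matrices plus the index maps tying rows to node ids and
    relation positions."""

    WM: np.ndarray  # (num nodes, d): node-as-source vectors
    WN: np.ndarray  # (num nodes, d): node-as-target vectors
    WR: np.ndarray  # (|R|, d): relation vectors (pre-squash)
    node_ids: list[str]
    relation_set: RelationSet
    node_index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.node_index = {v: i for i, v in enumerate(self.node_ids)}
        if self.WM.shape != self.WN.shape:
            raise ValueError("WM and WN shapes differ")
        if self.WM.shape[0] != len(self.node_ids):
            raise ValueError("WM rows do not match node count")
        if self.WR.shape[0] != len(self.relation_set):
            raise ValueError("WR rows do not match relation count")

    @property
    def d(self) -> int:
        return self.WM.shape[1]

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.WM.copy(), self.WN.copy(), self.WR.copy(),
            list(self.node_ids), self.relation_set,
        )


def f01(v: np.ndarray) -> np.ndarray:
    """Elementwise logistic sigmoid: confines each coordinate to (0, 1)."""
    return expit(np.asarray(v, dtype=float))


def init_params(
    node_ids: Sequence[str], relation_set: RelationSet, config: TrainConfig
) -> ModelParams:
    rng = np.random.default_rng(config.seed)
    shape_nodes = (len(node_ids), config.d)
    shape_rel = (len(relation_set), config.d)
    s = config.scale
    return ModelParams(
        rng.uniform(-s, s, shape_nodes),
        rng.uniform(-s, s, shape_nodes),
        rng.uniform(-s, s, shape_rel),
        list(node_ids),
        relation_set,
    )


def forward_prob(params: ModelParams, m: str, n: str, r: int) -> float:
    """Pr(r | m, n) for one relation index."""
    mi, ni = params.node_index[m], params.node_index[n]
    if not 0 <= r < len(params.relation_set):
        raise IndexError(f"relation index {r} out of range")
    h = f01(params.WR[r])
    s = float(np.dot(params.WM[mi], params.WN[ni] * h))
    return float(expit(s))


def tuple_log_objective(params: ModelParams, tup: TrainingTuple) -> float:
    """Bernoulli log-likelihood of the tuple, summed over its indicated
    relations; always <= 0. Probabilities are clipped to [EPS, 1-EPS]
    before the log so saturation yields a large finite value, not NaN."""
    total = 0.0
    for r in tup.relation_indices:
        p = forward_prob(params, tup.m, tup.n, r)
        p = min(max(p, EPS), 1.0 - EPS)
        total += tup.label * np.log(p) + (1 - tup.label) * np.log(1.0 - p)
    return float(total)


def sgd_step(params: ModelParams, tup: TrainingTuple, lr: float) -> ModelParams:
    """One in-place ascent step on the tuple's log-objective; only rows
    WM[m], WN[n] and the indicated WR rows change. Gradients for all
    indicated relations are computed from pre-step values."""
    if lr <= 0:
        raise ValueError("lr must be positive")
    mi, ni = params.node_index[tup.m], params.node_index[tup.n]
    wm = params.WM[mi].copy()
    wn = params.WN[ni].copy()
    grad_m = np.zeros_like(wm)
    grad_n = np.zeros_like(wn)
    grad_r: dict[int, np.ndarray] = {}
    for r in tup.relation_indices:
        h = f01(params.WR[r])
        p = expit(float(np.dot(wm, wn * h)))
        e = tup.label - p
        grad_m += e * (wn * h)
        grad_n += e * (wm * h)
        grad_r[r] = e * (wm * wn * h * (1.0 - h))
    params.WM[mi] += lr * grad_m
    params.WN[ni] += lr * grad_n
    for r, g in grad_r.items():
        params.WR[r] += lr * g
    return params


def train(
    network: HeteroNetwork,
    relation_set: RelationSet,
    tuples: Sequence[TrainingTuple],
    config: TrainConfig,
) -> tuple[ModelParams, list[float]]:
    """SGD over ``config.epochs`` shuffled passes; returns the trained
    parameters and the per-epoch mean log-objective trace (each tuple's
    objective evaluated just before its update). Deterministic under
    ``config.seed``."""
    if not tuples:
        raise ValueError("empty tuple list")
    params = init_params(network.nodes(), relation_set, config)
    rng = np.random.default_rng(config.seed + 1)
    rel_idx = [t.relation_indices for t in tuples]
    node_index = params.node_index
    WM, WN, WR = params.WM, params.WN, params.WR
    lr = config.lr
    trace: list[float] = []
    order = np.arange(len(tuples))
    for _ in range(config.epochs):
        rng.shuffle(order)
        total = 0.0
        for idx in order:
            tup = tuples[idx]
            mi, ni = node_index[tup.m], node_index[tup.n]
            wm = WM[mi]
            wn = WN[ni]
            label = tup.label
            grad_m = 0.0
            grad_n = 0.0
            for r in rel_idx[idx]:
                h = expit(WR[r])
                masked = wn * h
                p = expit(float(wm @ masked))
                e = label - p
                grad_m = grad_m + e * masked
                grad_n = grad_n + e * (wm * h)
                WR[r] += lr * (e * (wm * wn * h * (1.0 - h)))
                pc = min(max(p, EPS), 1.0 - EPS)
                total += (
                    np.log(pc) if label else np.log(1.0 - pc)
                )
            WM[mi] = wm + lr * grad_m
            WN[ni] = wn + lr * grad_n
        trace.append(total / len(tuples))
    return params, trace


def node_embeddings(params: ModelParams, which: str = "mean") -> EmbeddingTable:
    """Exported per-node embedding table: the mean of the source and
    target matrices by default (WM or WN alone on request)."""
    if which == "WM":
        mat = params.WM
    elif which == "WN":
        mat = params.WN
    elif which == "mean":
        mat = (params.WM + params.WN) / 2.0
    else:
        raise ValueError(f"unknown embedding choice {which!r}")
    return EmbeddingTable(list(params.node_ids), mat.copy())


def training_trace_csv(trace: Sequence[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch,mean_log_objective\n")
        for i, v in enumerate(trace):
            fh.write(f"{i},{v!r}\n")
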
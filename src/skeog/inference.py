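"""Walk aggregation over the edge tensor, pair classification, and losses.

The edge tensor V^(l) holds one d_z-vector per node pair, representing the
aggregate of length-l paths between them (zero = no path representation).
One walk step combines two length-l paths through every intermediate node k:

    f(v_ik, v_kj) = sigmoid(v_ik * (W v_kj))          (elementwise)
    v_ij^(2l)     = alpha v_ij^(l)
                    + (1 - alpha) sum_{k not in {i,j}} f(v_ik^(l), v_kj^(l))

After each step V is re-symmetrised by averaging (i,j) with (j,i), keeping
the undirected-graph contract. Iterating log2(L) steps yields length-L path
representations; entity-pair entries of V^(L) feed a softmax classifier.

The training loss interpolates mean cross-entropy with a differentiable
soft F-measure surrogate, 1 - 2*sum(p*y) / (sum(p) + sum(y) + beta),
computed one-vs-rest over the non-null labels and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "WalkParams", "PairClassifier", "LossConfig", "walk_step",
    "aggregate_walks", "classify_pairs", "cross_entropy", "soft_f_loss",
    "total_loss",
]


@dataclass
class WalkParams:
    W: Tensor                  # (d_z, d_z)
    alpha: float = 0.8
    final_length: int = 4

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        L = self.final_length
        if L < 2 or L & (L - 1):
            raise ValueError("final_length must be a power of 2, >= 2")


class PairClassifier:
    """Linear map d_z -> |label_set| followed by softmax."""

    def __init__(self, d_z: int, n_labels: int, seed: int):
        rng = np.random.default_rng(seed)
        self.W = ag.parameter(rng, (n_labels, d_z), 1.0 / np.sqrt(d_z))
        self.b = Tensor(np.zeros(n_labels), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


@dataclass
class LossConfig:
    lambda_ce: float = 0.7
    beta: float = 1e-8

    def __post_init__(self):
        if not 0.0 <= self.lambda_ce <= 1.0:
            raise ValueError("lambda_ce must be in [0, 1]")


def walk_step(V: Tensor, W: Tensor, alpha: float) -> Tensor:
    """One doubling step: length-l edge tensor -> length-2l edge tensor."""
    n, _, d = V.shape
    WV = (V.reshape(n * n, d) @ W.transpose()).reshape(n, n, d)  # WV[k,j] = W v_kj
    # full sum over k, then remove the k=i and k=j terms
    F_all = (V.reshape(n, n, 1, d) * WV.reshape(1, n, n, d)).sigmoid()  # [i,k,j]
    S = F_all.sum(axis=1)
    diag = np.arange(n)
    Vd = V[diag, diag]                                           # (n, d)
    WVd = WV[diag, diag]
    S = S - (Vd.reshape(n, 1, d) * WV).sigmoid()                 # k = i
    S = S - (V * WVd.reshape(1, n, d)).sigmoid()                 # k = j
    # diagonal entries (i == j) had their single excluded term removed twice
    fix = (Vd * WVd).sigmoid() * 0.5
    S = S + ag.scatter_pairs(fix, diag, diag, n)
    out = V * alpha + S * (1.0 - alpha)
    return (out + out.transpose(1, 0, 2)) * 0.5


def aggregate_walks(V1: Tensor, params: WalkParams) -> Tensor:
    """Iterate walk steps 1 -> 2 -> ... -> final_length."""
    L = params.final_length
    if L < 2 or L & (L - 1):
        raise ValueError("final_length must be a power of 2, >= 2")
    V = V1
    length = 1
    while length < L:
        V = walk_step(V, params.W, params.alpha)
        length *= 2
    return V


def classify_pairs(V_L: Tensor, pair_nodes: list[tuple[int, int]],
                   classifier: PairClassifier) -> Tensor:
    """Softmax label distribution for each candidate entity-node pair."""
    n = V_L.shape[0]
    for i, j in pair_nodes:
        if not (0 <= i < n and 0 <= j < n):
            raise KeyError(f"pair ({i}, {j}) not in graph of {n} nodes")
    rows = np.array([p[0] for p in pair_nodes])
    cols = np.array([p[1] for p in pair_nodes])
    feats = V_L[rows, cols]                                      # (n_pairs, d_z)
    logits = feats @ classifier.W.transpose() + classifier.b
    return ag.softmax(logits, axis=1)


def cross_entropy(probs: Tensor, gold_idx: np.ndarray) -> Tensor:
    rows = np.arange(len(gold_idx))
    picked = probs[rows, np.asarray(gold_idx)]
    return -(picked + 1e-12).log().mean()


def soft_f_loss(prob_positive: Tensor, gold_binary: np.ndarray,
                beta: float = 1e-8) -> Tensor:
    """Differentiable 1 - softF1 on one positive class; in [0, 1]."""
    y = np.asarray(gold_binary, dtype=float)
    if prob_positive.shape[0] != y.shape[0]:
        raise ValueError("prediction/gold length mismatch")
    tp = (prob_positive * Tensor(y)).sum()
    denom = prob_positive.sum() + float(y.sum()) + beta
    return 1.0 - (tp * 2.0) / denom


def total_loss(probs: Tensor, gold_idx: np.ndarray, null_index: int,
               config: LossConfig) -> Tensor:
    """lambda_ce * cross-entropy + (1 - lambda_ce) * soft-F (one-vs-rest
    over non-null labels, averaged)."""
    gold_idx = np.asarray(gold_idx)
    ce = cross_entropy(probs, gold_idx)
    if config.lambda_ce >= 1.0:
        return ce
    n_labels = probs.shape[1]
    terms = []
    for lab in range(n_labels):
        if lab == null_index:
            continue
        terms.append(soft_f_loss(probs[:, lab], (gold_idx == lab).astype(float),
                                 config.beta))
    soft = terms[0]
    for t in terms[1:]:
        soft = soft + t
    soft = soft * (1.0 / len(terms))
    if config.lambda_ce <= 0.0:
        return soft
    return ce * config.lambda_ce + soft * (1.0 - config.lambda_ce)
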
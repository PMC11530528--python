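"""Network-scale model p_theta: GIN message passing over the interaction
network, common-neighbor-aware pair prediction, pseudo-edge augmentation,
and the M-step training objective.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import (
    AdamW,
    BatchNorm1d,
    Dropout,
    Linear,
    MLP,
    Module,
    Tensor,
)
from .graph_io import OBSERVED, PSEUDO, InteractionNetwork, Link
from .structure_scale import PairPrediction, _cross_entropy


@dataclass
class NetworkModelParams:
    blocks: int = 2
    hidden: int = 32
    dropout: float = 0.1
    use_norm: bool = True

    def __post_init__(self):
        if self.blocks < 1:
            raise ValueError("block count must be >= 1")
        if self.hidden <= 0:
            raise ValueError("hidden width must be positive")


@dataclass
class AugmentedNetwork:
    """Base network plus thresholded pseudo edges (base left unmodified)."""

    base: InteractionNetwork
    pseudo_edges: List[Tuple[int, int, float]]
    threshold_t: float

    def adjacency(self) -> np.ndarray:
        a = self.base.adjacency(include_pseudo=False)
        for i, j, _ in self.pseudo_edges:
            a[i, j] = 1.0
            a[j, i] = 1.0
        return a

    def as_network(self) -> InteractionNetwork:
        """Copy of the base network with pseudo links appended."""
        net = copy.deepcopy(self.base)
        existing = {l.pair for l in net.links}
        for i, j, prob in self.pseudo_edges:
            if (i, j) in existing:
                continue
            label = np.zeros(net.n_classes)
            label[0] = 1.0
            net.links.append(
                Link(i=i, j=j, label=label, status=PSEUDO, confidence=prob)
            )
        return InteractionNetwork(
            entity_ids=net.entity_ids,
            label_space=net.label_space,
            n_classes=net.n_classes,
            links=net.links,
        )


# ----------------------------------------------------------------------
# Graph primitives
# ----------------------------------------------------------------------

def common_neighbors(A: np.ndarray, i: int, j: int) -> np.ndarray:
    """Indices in N(i) ∩ N(j) under adjacency A."""
    if i == j:
        raise ValueError("common neighbors undefined for i == j")
    A = np.asarray(A)
    return np.flatnonzero((A[i] > 0) & (A[j] > 0))


def gin_network_layer(H: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Pre-transform GIN block update: H_v + Σ_{u∈N(v)} H_u (numpy view).

    The learnable transform, activation and normalization live in
    :class:`NetworkModel`; this exposes the aggregation rule itself for
    oracle checks.
    """
    H = np.asarray(H, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    if A.shape[0] != H.shape[0]:
        raise ValueError(
            f"dimension mismatch: H has {H.shape[0]} rows, "
            f"A is {A.shape[0]} x {A.shape[1]}"
        )
    return H + A @ H


# ----------------------------------------------------------------------
# Pseudo-edge augmentation
# ----------------------------------------------------------------------

def augment_with_pseudo_edges(
    network: InteractionNetwork,
    q_probs: Dict[Tuple[int, int], float],
    t: float,
) -> AugmentedNetwork:
    """Add pseudo edges for every scored pair with probability > 1 − t.

    Observed links are never duplicated; t = 0 is the identity
    augmentation. The pseudo-edge set is monotone in t.
    """
    if not 0.0 <= t < 1.0:
        raise ValueError(f"t must be in [0, 1), got {t}")
    threshold = 1.0 - t
    observed = {
        l.pair for l in network.links if l.status == OBSERVED
    }
    pseudo = []
    for (i, j), prob in q_probs.items():
        if i == j:
            continue
        pair = (min(i, j), max(i, j))
        if pair in observed:
            continue
        if prob > threshold:
            pseudo.append((pair[0], pair[1], float(prob)))
    pseudo.sort()
    return AugmentedNetwork(
        base=network, pseudo_edges=pseudo, threshold_t=t
    )


# ----------------------------------------------------------------------
# Network model
# ----------------------------------------------------------------------

class NetworkModel(Module):
    """GIN blocks over the interaction adjacency + NCN pair predictor.

    Each block computes BatchNorm(ReLU(H + A·H)) followed by a two-layer
    update MLP. Initial node attributes concatenate the structure-scale
    embeddings H^(0) with a learned per-entity embedding (the network
    scale's own identity parameters). The pair score concatenates
    MLP(h_i ⊙ h_j) with the sum of final-layer representations of common
    neighbors of (i, j); an empty common-neighbor set contributes a zero
    vector.
    """

    def __init__(self, in_dim: int, n_entities: int, n_classes: int,
                 params: NetworkModelParams, rng: np.random.Generator,
                 head: str = "sigmoid", entity_dim: int = 16):
        super().__init__()
        self.params = params
        self.head = head
        self.entity_dim = entity_dim
        self.entity_embedding = (
            None if entity_dim == 0 else
            ad.Parameter(0.1 * rng.standard_normal((n_entities, entity_dim)))
        )
        self.input_proj = Linear(in_dim + entity_dim, params.hidden, rng)
        self.block_mlps = [
            MLP([params.hidden, params.hidden, params.hidden], rng)
            for _ in range(params.blocks)
        ]
        self.norms = [
            BatchNorm1d(params.hidden) if params.use_norm else None
            for _ in range(params.blocks)
        ]
        self.dropout = Dropout(params.dropout, rng)
        self.pair_mlp = MLP([params.hidden, params.hidden, params.hidden], rng)
        self.out = Linear(2 * params.hidden, n_classes, rng)

    def node_representations(self, H0, A: np.ndarray,
                             entity_embeddings=None) -> Tensor:
        A_sp = sp.csr_matrix(np.asarray(A, dtype=np.float64))
        if not isinstance(H0, Tensor):
            H0 = Tensor(np.asarray(H0, dtype=np.float64))
        if self.entity_embedding is not None:
            emb = (
                self.entity_embedding
                if entity_embeddings is None
                else entity_embeddings
            )
            if not isinstance(emb, Tensor):
                emb = Tensor(np.asarray(emb, dtype=np.float64))
            H0 = ad.concat([H0, emb], axis=1)
        h = self.input_proj(H0)
        for mlp, norm in zip(self.block_mlps, self.norms):
            h = (h + ad.sparse_matmul(A_sp, h)).relu()
            if norm is not None:
                h = norm(h)
            h = mlp(h)
            h = self.dropout(h)
        return h

    def pair_logits(self, h: Tensor, A: np.ndarray,
                    pairs: np.ndarray) -> Tensor:
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        A = np.asarray(A, dtype=np.float64)
        emb_i = h.gather_rows(pairs[:, 0])
        emb_j = h.gather_rows(pairs[:, 1])
        pair_term = self.pair_mlp(emb_i * emb_j)
        # common-neighbor sums for all pairs at once: (A_i ∘ A_j) @ H
        cn_indicator = (A[pairs[:, 0]] > 0) & (A[pairs[:, 1]] > 0)
        cn_sp = sp.csr_matrix(cn_indicator.astype(np.float64))
        cn_term = ad.sparse_matmul(cn_sp, h)
        return self.out(ad.concat([pair_term, cn_term], axis=1))

    def probabilities(self, logits: Tensor) -> np.ndarray:
        if self.head == "sigmoid":
            return logits.sigmoid().numpy()
        return np.exp(ad.log_softmax(logits).numpy())

    def predict_pairs(self, H0: np.ndarray, A: np.ndarray,
                      pairs: np.ndarray,
                      entity_embeddings=None) -> np.ndarray:
        self.eval()
        h = self.node_representations(
            H0, A, entity_embeddings=entity_embeddings
        )
        logits = self.pair_logits(h, A, pairs)
        return self.probabilities(logits)


def ncn_predict(i: int, j: int, H0: np.ndarray, A: np.ndarray,
                model: NetworkModel) -> PairPrediction:
    """Single-pair NCN prediction (symmetric in i and j)."""
    if i == j:
        raise ValueError("cannot predict a self-interaction")
    probs = model.predict_pairs(H0, A, np.array([[i, j]]))
    model.eval()
    h = model.node_representations(H0, A)
    logits = model.pair_logits(h, A, np.array([[i, j]]))
    return PairPrediction(
        link=(i, j),
        label_distribution=probs.ravel(),
        logits=logits.numpy().ravel(),
    )


# ----------------------------------------------------------------------
# M-step objective and training
# ----------------------------------------------------------------------

def mstep_loss(
    logits_observed: Optional[Tensor],
    observed_labels: Optional[np.ndarray],
    logits_unobserved: Optional[Tensor],
    pseudo_labels: Optional[np.ndarray],
    beta: float,
    head: str = "sigmoid",
) -> Tensor:
    """β · distillation CE against E-step pseudo-labels + (1−β) · supervised CE."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0,1], got {beta}")
    have_pseudo = (
        logits_unobserved is not None
        and pseudo_labels is not None
        and logits_unobserved.shape[0] > 0
    )
    have_observed = (
        logits_observed is not None and logits_observed.shape[0] > 0
    )
    if not have_observed and not have_pseudo:
        raise ValueError("loss needs at least one nonempty term")
    if not have_pseudo:
        return _cross_entropy(logits_observed, observed_labels, head)
    if not have_observed:
        return _cross_entropy(logits_unobserved, pseudo_labels, head) * beta
    distill = _cross_entropy(logits_unobserved, pseudo_labels, head)
    supervised = _cross_entropy(logits_observed, observed_labels, head)
    return distill * beta + supervised * (1.0 - beta)


def train_mstep(
    model: NetworkModel,
    H0: np.ndarray,
    A: np.ndarray,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    unobserved_pairs: np.ndarray,
    pseudo_labels: Optional[np.ndarray],
    beta: float,
    epochs: int,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    optimizer: Optional[AdamW] = None,
) -> tuple:
    """Full-batch M-step epochs over the (augmented) adjacency.

    Returns (loss history, p_theta label distributions on unobserved pairs).
    """
    train_pairs = np.asarray(train_pairs, dtype=np.intp).reshape(-1, 2)
    if train_pairs.shape[0] == 0:
        raise ValueError("M-step requires observed links")
    unobserved_pairs = np.asarray(
        unobserved_pairs, dtype=np.intp
    ).reshape(-1, 2)
    opt = optimizer or AdamW(
        model.parameters(), lr=lr, weight_decay=weight_decay
    )
    losses = []
    model.train()
    for _ in range(epochs):
        h = model.node_representations(H0, A)
        logits_obs = model.pair_logits(h, A, train_pairs)
        logits_unobs = None
        if pseudo_labels is not None and unobserved_pairs.shape[0] > 0:
            logits_unobs = model.pair_logits(h, A, unobserved_pairs)
        loss = mstep_loss(
            logits_obs, train_labels, logits_unobs, pseudo_labels,
            beta, model.head,
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    model.eval()
    p_probs = (
        model.predict_pairs(H0, A, unobserved_pairs)
        if unobserved_pairs.shape[0] > 0
        else np.zeros((0, model.out.weight.shape[1]))
    )
    return losses, p_probs
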
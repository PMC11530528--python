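"""Structure-scale model q_phi: entity-graph encoders, readout, pair
classifier, and the E-step training objective.

Three encoder families are provided: a normalized-adjacency GCN for
residue contact graphs, a geometric message-passing encoder over k-NN
graphs with relative-coordinate features, and a GIN for atom/bond graphs.
All operate on a disjoint union of entity graphs so one forward pass
embeds the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from . import _autodiff as ad
from ._autodiff import (
    AdamW,
    BatchNorm1d,
    Dropout,
    LayerNorm,
    Linear,
    MLP,
    Module,
    Parameter,
    Tensor,
)
from .graph_io import MolecularGraph, build_knn_graph


@dataclass
class StructureEncoderParams:
    """Configuration for a structure-scale encoder stack."""

    encoder_kind: str = "gcn"  # gcn | geometric | gin
    layers: int = 2
    hidden: int = 32
    dropout: float = 0.1
    self_loops: bool = True  # GCN normalization over A + I
    use_norm: bool = True
    knn_k: int = 8  # geometric encoder neighborhood size

    def __post_init__(self):
        if self.layers < 1:
            raise ValueError("layer count must be >= 1")
        if self.hidden <= 0:
            raise ValueError("hidden width must be positive")
        if self.encoder_kind not in ("gcn", "geometric", "gin"):
            raise ValueError(f"unknown encoder kind {self.encoder_kind!r}")


@dataclass
class PairPrediction:
    link: Tuple[int, int]
    label_distribution: np.ndarray
    logits: np.ndarray


# ----------------------------------------------------------------------
# Graph batching (disjoint union)
# ----------------------------------------------------------------------

class GraphBatch:
    """Disjoint union of entity graphs for one entity kind."""

    def __init__(self, graphs: Sequence[MolecularGraph]):
        if not graphs:
            raise ValueError("empty graph batch")
        sizes = [g.n_nodes for g in graphs]
        if any(s == 0 for s in sizes):
            raise ValueError("graphs must have at least one node")
        offsets = np.cumsum([0] + sizes[:-1])
        self.n_graphs = len(graphs)
        self.n_nodes = int(sum(sizes))
        self.node_graph = np.repeat(np.arange(self.n_graphs), sizes)
        self.node_features = np.concatenate(
            [g.node_features for g in graphs], axis=0
        )
        edge_chunks = [
            g.edges + off for g, off in zip(graphs, offsets) if g.n_edges
        ]
        self.edges = (
            np.concatenate(edge_chunks, axis=0)
            if edge_chunks else np.zeros((0, 2), dtype=np.int64)
        )
        feat_chunks = [g.edge_features for g in graphs if g.n_edges]
        self.edge_features = (
            np.concatenate(feat_chunks, axis=0)
            if feat_chunks else np.zeros((0, 0))
        )
        if all(g.coords is not None for g in graphs):
            self.coords = np.concatenate([g.coords for g in graphs], axis=0)
        else:
            self.coords = None
        self._graphs = list(graphs)
        self._offsets = offsets
        self._cache: dict = {}

    def normalized_adjacency(self, self_loops: bool = True) -> sp.csr_matrix:
        key = ("norm_adj", self_loops)
        if key not in self._cache:
            n = self.n_nodes
            if self.edges.size:
                rows = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
                cols = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
                data = np.ones(rows.size)
                a = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
            else:
                a = sp.csr_matrix((n, n))
            if self_loops:
                a = a + sp.identity(n, format="csr")
            deg = np.asarray(a.sum(axis=1)).ravel()
            with np.errstate(divide="ignore"):
                dinv = 1.0 / np.sqrt(deg)
            dinv[~np.isfinite(dinv)] = 0.0
            d = sp.diags(dinv)
            self._cache[key] = (d @ a @ d).tocsr()
        return self._cache[key]

    def directed_edges(self) -> np.ndarray:
        """Both directions of each undirected edge, as (src, dst) rows."""
        if "directed" not in self._cache:
            if self.edges.size:
                self._cache["directed"] = np.concatenate(
                    [self.edges, self.edges[:, ::-1]], axis=0
                )
            else:
                self._cache["directed"] = np.zeros((0, 2), dtype=np.int64)
        return self._cache["directed"]

    def knn_edges(self, k: int) -> np.ndarray:
        key = ("knn", k)
        if key not in self._cache:
            if self.coords is None:
                raise ValueError("geometric encoder requires coordinates")
            chunks = []
            for g, off in zip(self._graphs, self._offsets):
                kk = min(k, g.n_nodes - 1)
                if kk < 1:
                    continue
                chunks.append(build_knn_graph(g.coords, kk) + off)
            self._cache[key] = (
                np.concatenate(chunks, axis=0)
                if chunks else np.zeros((0, 2), dtype=np.int64)
            )
        return self._cache[key]


# ----------------------------------------------------------------------
# Encoders
# ----------------------------------------------------------------------

class GCNEncoder(Module):
    """Stack of BatchNorm(ReLU(Â h W)) layers, Â = D̃^{-1/2}(A+I)D̃^{-1/2}."""

    def __init__(self, in_dim: int, params: StructureEncoderParams,
                 rng: np.random.Generator):
        super().__init__()
        self.params = params
        dims = [in_dim] + [params.hidden] * params.layers
        self.linears = [
            Linear(a, b, rng, bias=False) for a, b in zip(dims[:-1], dims[1:])
        ]
        self.norms = [
            BatchNorm1d(params.hidden) if params.use_norm else None
            for _ in range(params.layers)
        ]
        self.dropout = Dropout(params.dropout, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        a_hat = batch.normalized_adjacency(self.params.self_loops)
        h = Tensor(batch.node_features)
        for linear, norm in zip(self.linears, self.norms):
            h = ad.sparse_matmul(a_hat, h) @ linear.weight
            h = h.relu()
            if norm is not None:
                h = norm(h)
            h = self.dropout(h)
        return h


def _rbf_expand(dist: np.ndarray, n_basis: int = 16,
                d_max: float = 20.0) -> np.ndarray:
    """Gaussian radial basis expansion of distances on [0, d_max] Å."""
    centers = np.linspace(0.0, d_max, n_basis)
    width = d_max / n_basis
    return np.exp(-((dist[:, None] - centers[None, :]) / width) ** 2)


def _chain_vectors(coords: np.ndarray,
                   node_graph: np.ndarray) -> np.ndarray:
    """Per-node chain geometry, translation invariant: forward/backward
    unit vectors, distances to the chain neighbors, and the bending
    angle cosine between them (9 columns)."""
    n = coords.shape[0]
    fwd = np.zeros((n, 3))
    bwd = np.zeros((n, 3))
    d_fwd = np.zeros(n)
    d_bwd = np.zeros(n)
    same_fwd = np.zeros(n, dtype=bool)
    same_fwd[:-1] = node_graph[:-1] == node_graph[1:]
    same_bwd = np.zeros(n, dtype=bool)
    same_bwd[1:] = node_graph[1:] == node_graph[:-1]
    diff = np.zeros((n, 3))
    diff[:-1] = coords[1:] - coords[:-1]
    norms = np.linalg.norm(diff, axis=1, keepdims=True)
    unit = np.divide(diff, norms, out=np.zeros_like(diff), where=norms > 0)
    fwd[same_fwd] = unit[same_fwd]
    bwd[same_bwd] = -unit[np.roll(same_bwd, -1)]
    d_fwd[same_fwd] = norms.ravel()[same_fwd]
    d_bwd[same_bwd] = norms.ravel()[np.roll(same_bwd, -1)]
    angle = np.sum(fwd * bwd, axis=1)
    return np.concatenate(
        [fwd, bwd,
         d_fwd[:, None] / 10.0, d_bwd[:, None] / 10.0, angle[:, None]],
        axis=1,
    )


class GeometricEncoder(Module):
    """Geometric message passing over k-NN edges.

    Per-edge message = MLP(concat(h_j, e_{j→i})); node update =
    LayerNorm(h_i + Dropout(Σ_j messages)). Edge features combine an RBF
    distance expansion, the unit displacement direction, and a chain
    orientation term — all built from relative coordinates only.
    """

    def __init__(self, in_dim: int, params: StructureEncoderParams,
                 rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.n_rbf = 16
        node_geo = 9  # chain direction vectors, distances, bend angle
        edge_dim = self.n_rbf + 3 + 1
        self.input_proj = Linear(in_dim + node_geo, params.hidden, rng)
        self.message_mlps = [
            MLP([params.hidden + edge_dim, params.hidden, params.hidden], rng)
            for _ in range(params.layers)
        ]
        self.norms = [LayerNorm(params.hidden) for _ in range(params.layers)]
        self.dropout = Dropout(params.dropout, rng)

    def _edge_features(self, batch: GraphBatch,
                       edges: np.ndarray) -> np.ndarray:
        coords = batch.coords
        src, dst = edges[:, 0], edges[:, 1]
        delta = coords[src] - coords[dst]
        dist = np.linalg.norm(delta, axis=1)
        direction = np.divide(
            delta, dist[:, None], out=np.zeros_like(delta),
            where=dist[:, None] > 0,
        )
        chain = _chain_vectors(coords, batch.node_graph)
        orient = np.sum(chain[src, :3] * chain[dst, :3], axis=1)
        return np.concatenate(
            [_rbf_expand(dist, self.n_rbf), direction, orient[:, None]],
            axis=1,
        )

    def __call__(self, batch: GraphBatch) -> Tensor:
        if batch.coords is None:
            raise ValueError("geometric encoder requires coordinates")
        edges = batch.knn_edges(self.params.knn_k)
        chain = _chain_vectors(batch.coords, batch.node_graph)
        h = self.input_proj(
            Tensor(np.concatenate([batch.node_features, chain], axis=1))
        )
        if edges.size == 0:
            for norm in self.norms:
                h = norm(h)
            return h
        e_feat = Tensor(self._edge_features(batch, edges))
        src, dst = edges[:, 0], edges[:, 1]
        for mlp, norm in zip(self.message_mlps, self.norms):
            messages = mlp(ad.concat([h.gather_rows(src), e_feat], axis=1))
            agg = ad.segment_sum(messages, dst, batch.n_nodes)
            h = norm(h + self.dropout(agg))
        return h


class GINEncoder(Module):
    """GIN with edge features: h_v ← MLP(h_v + Σ_u ReLU(h_u + W_e e_uv))."""

    def __init__(self, in_dim: int, edge_dim: int,
                 params: StructureEncoderParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.input_proj = Linear(in_dim, params.hidden, rng)
        self.update_mlps = [
            MLP([params.hidden, params.hidden, params.hidden], rng)
            for _ in range(params.layers)
        ]
        self.edge_projs = [
            Linear(edge_dim, params.hidden, rng, bias=False)
            if edge_dim > 0 else None
            for _ in range(params.layers)
        ]
        self.norms = [
            BatchNorm1d(params.hidden) if params.use_norm else None
            for _ in range(params.layers)
        ]
        self.dropout = Dropout(params.dropout, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        h = self.input_proj(Tensor(batch.node_features))
        directed = batch.directed_edges()
        if batch.edge_features.size:
            e_both = Tensor(
                np.concatenate([batch.edge_features] * 2, axis=0)
            )
        else:
            e_both = None
        for mlp, eproj, norm in zip(
            self.update_mlps, self.edge_projs, self.norms
        ):
            if directed.size:
                src, dst = directed[:, 0], directed[:, 1]
                msg = h.gather_rows(src)
                if e_both is not None and eproj is not None:
                    msg = (msg + eproj(e_both)).relu()
                agg = ad.segment_sum(msg, dst, batch.n_nodes)
                h = mlp(h + agg)
            else:
                h = mlp(h)
            if norm is not None:
                h = norm(h)
            h = self.dropout(h)
        return h


def encode_structure_gcn(graph: MolecularGraph,
                         encoder: GCNEncoder) -> np.ndarray:
    """Node embeddings of one graph under a (trained) GCN encoder."""
    if graph.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    return encoder(GraphBatch([graph])).numpy()


def encode_structure_geometric(graph: MolecularGraph,
                               encoder: "GeometricEncoder") -> np.ndarray:
    if graph.coords is None:
        raise ValueError("geometric encoder requires coordinates")
    return encoder(GraphBatch([graph])).numpy()


def encode_drug_gin(graph: MolecularGraph,
                    encoder: "GINEncoder") -> np.ndarray:
    if graph.n_nodes == 0:
        raise ValueError("cannot encode an empty graph")
    return encoder(GraphBatch([graph])).numpy()


def make_encoder(in_dim: int, edge_dim: int,
                 params: StructureEncoderParams,
                 rng: np.random.Generator) -> Module:
    if params.encoder_kind == "gcn":
        return GCNEncoder(in_dim, params, rng)
    if params.encoder_kind == "geometric":
        return GeometricEncoder(in_dim, params, rng)
    return GINEncoder(in_dim, edge_dim, params, rng)


# ----------------------------------------------------------------------
# Readout and pair classifier
# ----------------------------------------------------------------------

def readout(node_embeddings: Tensor, node_graph: Optional[np.ndarray] = None,
            n_graphs: Optional[int] = None) -> Tensor:
    """Sum-pool node embeddings into graph embeddings (permutation invariant)."""
    if node_embeddings.shape[0] == 0:
        raise ValueError("cannot read out an empty embedding matrix")
    if node_graph is None:
        return node_embeddings.sum(axis=0)
    return ad.segment_sum(node_embeddings, node_graph, n_graphs)


class PairClassifier(Module):
    """MLP on the elementwise product h_i ⊙ h_j, then a per-class head."""

    def __init__(self, hidden: int, n_classes: int, rng: np.random.Generator,
                 head: str = "sigmoid"):
        super().__init__()
        if head not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown head {head!r}")
        self.mlp = MLP([hidden, hidden, hidden], rng)
        self.out = Linear(hidden, n_classes, rng)
        self.head = head

    def logits(self, emb_i: Tensor, emb_j: Tensor) -> Tensor:
        return self.out(self.mlp(emb_i * emb_j))

    def probabilities(self, logits: Tensor) -> np.ndarray:
        if self.head == "sigmoid":
            return logits.sigmoid().numpy()
        return np.exp(ad.log_softmax(logits).numpy())


def predict_pair_q(emb_i: np.ndarray, emb_j: np.ndarray,
                   classifier: PairClassifier,
                   link: Tuple[int, int] = (0, 1)) -> PairPrediction:
    emb_i = np.asarray(emb_i, dtype=np.float64)
    emb_j = np.asarray(emb_j, dtype=np.float64)
    if emb_i.shape != emb_j.shape:
        raise ValueError(
            f"embedding width mismatch: {emb_i.shape} vs {emb_j.shape}"
        )
    classifier.eval()
    logits = classifier.logits(
        Tensor(emb_i.reshape(1, -1)), Tensor(emb_j.reshape(1, -1))
    )
    probs = classifier.probabilities(logits)
    return PairPrediction(
        link=link,
        label_distribution=probs.ravel(),
        logits=logits.numpy().ravel(),
    )


# ----------------------------------------------------------------------
# Structure-scale model and E-step training
# ----------------------------------------------------------------------

class StructureModel(Module):
    """Per-kind encoders + sum readout + symmetric pair classifier."""

    def __init__(self, graphs: Sequence[MolecularGraph], n_classes: int,
                 params: StructureEncoderParams, rng: np.random.Generator,
                 head: str = "sigmoid"):
        super().__init__()
        self.params = params
        self.n_entities = len(graphs)
        kinds = sorted({g.entity_kind for g in graphs})
        self.kinds = kinds
        self.batches: Dict[str, GraphBatch] = {}
        self._entity_order: Dict[str, np.ndarray] = {}
        self.encoders: List[Module] = []
        self._encoder_by_kind: Dict[str, Module] = {}
        inverse = np.zeros(self.n_entities, dtype=np.intp)
        pos = 0
        for kind in kinds:
            idx = np.array(
                [i for i, g in enumerate(graphs) if g.entity_kind == kind],
                dtype=np.intp,
            )
            kind_graphs = [graphs[i] for i in idx]
            batch = GraphBatch(kind_graphs)
            self.batches[kind] = batch
            self._entity_order[kind] = idx
            inverse[idx] = pos + np.arange(len(idx))
            pos += len(idx)
            in_dim = batch.node_features.shape[1]
            edge_dim = (
                batch.edge_features.shape[1] if batch.edge_features.size else 0
            )
            kind_params = params
            if kind == "drug" and params.encoder_kind != "gin":
                kind_params = StructureEncoderParams(
                    encoder_kind="gin",
                    layers=params.layers,
                    hidden=params.hidden,
                    dropout=params.dropout,
                    use_norm=params.use_norm,
                )
            enc = make_encoder(in_dim, edge_dim, kind_params, rng)
            self.encoders.append(enc)
            self._encoder_by_kind[kind] = enc
        self._inverse = inverse
        self.classifier = PairClassifier(params.hidden, n_classes, rng, head)

    def entity_embeddings(self) -> Tensor:
        """Graph-level embeddings for every entity, in entity index order."""
        chunks = []
        for kind in self.kinds:
            batch = self.batches[kind]
            node_emb = self._encoder_by_kind[kind](batch)
            chunks.append(readout(node_emb, batch.node_graph, batch.n_graphs))
        stacked = ad.concat(chunks, axis=0) if len(chunks) > 1 else chunks[0]
        return stacked.gather_rows(self._inverse)

    def pair_logits(self, embeddings: Tensor,
                    pairs: np.ndarray) -> Tensor:
        pairs = np.asarray(pairs, dtype=np.intp).reshape(-1, 2)
        emb_i = embeddings.gather_rows(pairs[:, 0])
        emb_j = embeddings.gather_rows(pairs[:, 1])
        return self.classifier.logits(emb_i, emb_j)

    def predict_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Eval-mode label distributions for (i, j) pairs, shape (P, C)."""
        self.eval()
        emb = self.entity_embeddings()
        logits = self.pair_logits(emb, pairs)
        return self.classifier.probabilities(logits)


# ----------------------------------------------------------------------
# Losses
# ----------------------------------------------------------------------

def _cross_entropy(logits: Tensor, targets: np.ndarray, head: str) -> Tensor:
    """Mean-per-link cross-entropy against (soft) targets."""
    targets = np.asarray(targets, dtype=np.float64).reshape(logits.shape)
    if head == "softmax":
        logp = ad.log_softmax(logits)
        return -(Tensor(targets) * logp).sum(axis=1).mean()
    # numerically stable BCE-with-logits:
    #   max(x,0) - x*t + log(1 + exp(-|x|))
    x = logits
    relu_x = x.relu()
    abs_x = x.relu() + (-x).relu()
    softplus = (1.0 + (-abs_x).exp()).log()
    per_cell = relu_x - x * Tensor(targets) + softplus
    return per_cell.mean(axis=1).mean()


def estep_loss(
    logits_observed: Optional[Tensor],
    observed_labels: Optional[np.ndarray],
    logits_unobserved: Optional[Tensor],
    pseudo_labels: Optional[np.ndarray],
    alpha: float,
    head: str = "sigmoid",
) -> Tensor:
    """α · distillation CE on unobserved links + (1−α) · supervised CE.

    With an empty pseudo set (iteration 0) the loss degenerates to the
    pure supervised term.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0,1], got {alpha}")
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
        return _cross_entropy(logits_unobserved, pseudo_labels, head) * alpha
    distill = _cross_entropy(logits_unobserved, pseudo_labels, head)
    supervised = _cross_entropy(logits_observed, observed_labels, head)
    return distill * alpha + supervised * (1.0 - alpha)


def train_estep(
    model: StructureModel,
    train_pairs: np.ndarray,
    train_labels: np.ndarray,
    unobserved_pairs: np.ndarray,
    pseudo_labels: Optional[np.ndarray],
    alpha: float,
    epochs: int,
    lr: float = 1e-3,
    weight_decay: float = 1e-4,
    optimizer: Optional[AdamW] = None,
) -> tuple:
    """Full-batch E-step epochs; returns (loss history, q on unobserved)."""
    train_pairs = np.asarray(train_pairs, dtype=np.intp).reshape(-1, 2)
    if train_pairs.shape[0] == 0:
        raise ValueError("E-step requires observed links")
    unobserved_pairs = np.asarray(
        unobserved_pairs, dtype=np.intp
    ).reshape(-1, 2)
    head = model.classifier.head
    opt = optimizer or AdamW(
        model.parameters(), lr=lr, weight_decay=weight_decay
    )
    losses = []
    model.train()
    for _ in range(epochs):
        emb = model.entity_embeddings()
        logits_obs = model.pair_logits(emb, train_pairs)
        logits_unobs = None
        if pseudo_labels is not None and unobserved_pairs.shape[0] > 0:
            logits_unobs = model.pair_logits(emb, unobserved_pairs)
        loss = estep_loss(
            logits_obs, train_labels, logits_unobs, pseudo_labels,
            alpha, head,
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    model.eval()
    q_probs = (
        model.predict_pairs(unobserved_pairs)
        if unobserved_pairs.shape[0] > 0
        else np.zeros((0, model.classifier.out.weight.shape[1]))
    )
    return losses, q_probs
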
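"""Alternating variational-EM driver coupling the structure-scale and
network-scale models with mutual pseudo-label supervision, plus the
jointly-optimized ablation baseline and single-scale trainers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import AdamW
from .evaluation import auprc, best_f1
from .graph_io import (
    OBSERVED,
    UNOBSERVED,
    InteractionNetwork,
    Link,
    MolecularGraph,
)
from .network_scale import (
    AugmentedNetwork,
    NetworkModel,
    NetworkModelParams,
    augment_with_pseudo_edges,
    train_mstep,
)
from .structure_scale import (
    StructureEncoderParams,
    StructureModel,
    train_estep,
)
from .synthetic_data import SyntheticSpec, generate_multiscale_network, \
    sample_negative_pairs


@dataclass
class TrainConfig:
    alpha: float = 0.5
    beta: float = 0.5
    t: float = 0.3
    max_em_iterations: int = 8
    epochs_per_step: int = 20
    seed: int = 0
    encoder_kind: str = "gcn"
    encoder_layers: int = 2
    hidden: int = 32
    network_blocks: int = 2
    network_hidden: int = 32
    network_entity_dim: int = 64
    dropout: float = 0.2
    lr: float = 1e-2
    weight_decay: float = 1e-3
    patience: int = 2
    min_delta: float = 1e-3
    val_fraction: float = 0.1
    deterministic: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0,1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0,1]")
        if not 0.0 <= self.t < 1.0:
            raise ValueError("t must be in [0,1)")
        if self.max_em_iterations < 1:
            raise ValueError("max_em_iterations must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")

    def encoder_params(self) -> StructureEncoderParams:
        return StructureEncoderParams(
            encoder_kind=self.encoder_kind,
            layers=self.encoder_layers,
            hidden=self.hidden,
            dropout=self.dropout,
        )

    def network_params(self) -> NetworkModelParams:
        return NetworkModelParams(
            blocks=self.network_blocks,
            hidden=self.network_hidden,
            dropout=self.dropout,
        )


# ----------------------------------------------------------------------
# Dataset container
# ----------------------------------------------------------------------

@dataclass
class MultiScaleDataset:
    """Entity graphs + interaction network + sampled negative pairs.

    Positive links carry observed/unobserved statuses inside `network`.
    Negative pairs are split into a training pool (paired with observed
    links) and a test pool (paired with unobserved links).
    """

    graphs: List[MolecularGraph]
    network: InteractionNetwork
    neg_train: List[Tuple[int, int]]
    neg_test: List[Tuple[int, int]]
    truth: Optional[dict] = None

    @classmethod
    def from_spec(cls, spec: SyntheticSpec) -> "MultiScaleDataset":
        graphs, network, truth = generate_multiscale_network(spec)
        n_obs = len(network.links_with_status(OBSERVED))
        n_unobs = len(network.links_with_status(UNOBSERVED))
        neg_train = sample_negative_pairs(
            network, n_obs, seed=spec.seed + 101
        )
        neg_test = sample_negative_pairs(
            network, n_unobs, seed=spec.seed + 202, exclude=neg_train
        )
        return cls(
            graphs=graphs,
            network=network,
            neg_train=neg_train,
            neg_test=neg_test,
            truth=truth,
        )

    @property
    def n_classes(self) -> int:
        return self.network.n_classes

    def observed_pairs_labels(self) -> tuple:
        """(pairs, labels) over observed links plus training negatives."""
        pairs, labels = [], []
        for link in self.network.links_with_status(OBSERVED):
            pairs.append(link.pair)
            labels.append(link.label)
        for pair in self.neg_train:
            pairs.append(pair)
            labels.append(np.zeros(self.n_classes))
        return (
            np.asarray(pairs, dtype=np.intp),
            np.asarray(labels, dtype=np.float64),
        )

    def unobserved_pool(self) -> np.ndarray:
        """Candidate pairs whose labels are hidden (test positives + negatives)."""
        pairs = [l.pair for l in self.network.links_with_status(UNOBSERVED)]
        pairs.extend(self.neg_test)
        return np.asarray(pairs, dtype=np.intp).reshape(-1, 2)

    def test_labels(self) -> np.ndarray:
        labels = [
            l.label for l in self.network.links_with_status(UNOBSERVED)
        ]
        labels.extend(
            np.zeros(self.n_classes) for _ in self.neg_test
        )
        return np.asarray(labels, dtype=np.float64)


# ----------------------------------------------------------------------
# EM state
# ----------------------------------------------------------------------

@dataclass
class EMState:
    iteration: int
    structure_model: StructureModel
    network_model: NetworkModel
    config: TrainConfig
    val_history: List[float]
    predictions: np.ndarray  # p_theta on the unobserved pool
    q_predictions: np.ndarray  # q_phi on the unobserved pool
    unobserved_pairs: np.ndarray
    structural_embeddings: np.ndarray  # H^(0) fed to the network model
    adjacency: np.ndarray  # final (augmented) adjacency
    base_adjacency: np.ndarray  # observed-only training adjacency
    augmented: Optional[AugmentedNetwork]
    pseudo_provenance: List[Tuple[str, int]] = field(default_factory=list)
    estep_losses: List[List[float]] = field(default_factory=list)
    mstep_losses: List[List[float]] = field(default_factory=list)


def check_convergence(
    history: Sequence[float], patience: int, min_delta: float
) -> bool:
    """True when the monitored metric has not improved by >= min_delta
    for `patience` consecutive iterations."""
    if len(history) == 0:
        raise ValueError("history must be nonempty")
    best = history[0]
    stale = 0
    for value in history[1:]:
        if value >= best + min_delta:
            stale = 0
        else:
            stale += 1
        best = max(best, value)
    return stale >= patience


# ----------------------------------------------------------------------
# Shared construction helpers (fixed seed derivation so that a decoupled
# EM run is parameter-identical to independently trained models)
# ----------------------------------------------------------------------

def build_structure_model(dataset: MultiScaleDataset,
                          config: TrainConfig) -> StructureModel:
    rng = np.random.default_rng(config.seed)
    head = "sigmoid"
    return StructureModel(
        dataset.graphs, dataset.n_classes, config.encoder_params(), rng,
        head=head,
    )

def build_network_model(dataset: MultiScaleDataset,
                        config: TrainConfig) -> NetworkModel:
    rng = np.random.default_rng(config.seed + 7919)
    return NetworkModel(
        config.hidden, dataset.network.n_entities, dataset.n_classes,
        config.network_params(), rng, head="sigmoid",
        entity_dim=config.network_entity_dim,
    )


def _validation_split(dataset: MultiScaleDataset, config: TrainConfig):
    """Hold out val_fraction of the supervised pairs for convergence
    monitoring; they never contribute gradient steps or adjacency edges."""
    pairs, labels = dataset.observed_pairs_labels()
    rng = np.random.default_rng(config.seed + 104729)
    n = pairs.shape[0]
    n_val = max(2, int(round(config.val_fraction * n)))
    # stratify: ensure both positives and negatives in the monitor set
    pos = np.flatnonzero(labels.max(axis=1) >= 0.5)
    neg = np.flatnonzero(labels.max(axis=1) < 0.5)
    n_val_pos = max(1, int(round(n_val * len(pos) / max(1, n))))
    n_val_neg = max(1, n_val - n_val_pos)
    val_idx = np.concatenate([
        rng.choice(pos, size=min(n_val_pos, len(pos)), replace=False),
        rng.choice(neg, size=min(n_val_neg, len(neg)), replace=False),
    ])
    mask = np.ones(n, dtype=bool)
    mask[val_idx] = False
    return pairs[mask], labels[mask], pairs[~mask], labels[~mask]


def _train_adjacency(dataset: MultiScaleDataset,
                     train_pairs: np.ndarray) -> InteractionNetwork:
    """Network restricted to observed positive links in the training split."""
    train_set = {tuple(p) for p in train_pairs.tolist()}
    links = []
    for link in dataset.network.links_with_status(OBSERVED):
        if link.pair in train_set and link.label.max() >= 0.5:
            links.append(Link(i=link.i, j=link.j, label=link.label.copy()))
    return InteractionNetwork(
        entity_ids=list(dataset.network.entity_ids),
        label_space=dataset.network.label_space,
        n_classes=dataset.n_classes,
        links=links,
    )


def _existence_probability(q_probs: np.ndarray) -> np.ndarray:
    """Link-existence probability from per-class label distributions."""
    q_probs = np.atleast_2d(q_probs)
    return q_probs.max(axis=1)


def _val_metric(probs: np.ndarray, labels: np.ndarray,
                label_space: str) -> float:
    if label_space == "binary":
        return auprc(probs.ravel(), labels.ravel())
    return best_f1(probs, labels)


# ----------------------------------------------------------------------
# The EM loop
# ----------------------------------------------------------------------

def run_em(dataset: MultiScaleDataset, config: TrainConfig) -> EMState:
    """Alternate E-step (structure scale) and M-step (network scale) with
    mutual pseudo-label supervision and pseudo-edge graph completion."""
    if not dataset.network.links_with_status(OBSERVED):
        raise ValueError("dataset has no observed links")

    model_s = build_structure_model(dataset, config)
    model_n = build_network_model(dataset, config)
    opt_s = AdamW(model_s.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)
    opt_n = AdamW(model_n.parameters(), lr=config.lr,
                  weight_decay=config.weight_decay)

    train_pairs, train_labels, val_pairs, val_labels = _validation_split(
        dataset, config
    )
    unobs = dataset.unobserved_pool()
    train_net = _train_adjacency(dataset, train_pairs)

    history: List[float] = []
    provenance: List[Tuple[str, int]] = []
    estep_losses, mstep_losses = [], []
    pseudo_from_m: Optional[np.ndarray] = None
    augmented = None
    p_probs = np.zeros((unobs.shape[0], dataset.n_classes))
    q_probs = np.zeros_like(p_probs)
    H0 = None
    A = None

    k = 0
    for k in range(config.max_em_iterations):
        # E-step: fit q_phi on observed labels + M-step pseudo-labels
        losses_e, q_probs = train_estep(
            model_s, train_pairs, train_labels, unobs, pseudo_from_m,
            config.alpha, config.epochs_per_step, lr=config.lr,
            weight_decay=config.weight_decay, optimizer=opt_s,
        )
        estep_losses.append(losses_e)
        if pseudo_from_m is not None:
            provenance.append(("m->e", k))

        # pseudo-edge completion of the network from q_phi's predictions
        q_exist = _existence_probability(q_probs)
        q_map = {
            (int(i), int(j)): float(p)
            for (i, j), p in zip(unobs.tolist(), q_exist)
        }
        augmented = augment_with_pseudo_edges(train_net, q_map, config.t)
        A = augmented.adjacency()

        # M-step: fit p_theta over the augmented network with E-step
        # pseudo-labels; initial node attributes come from q_phi
        model_s.eval()
        H0 = model_s.entity_embeddings().numpy()
        losses_m, p_probs = train_mstep(
            model_n, H0, A, train_pairs, train_labels, unobs, q_probs,
            config.beta, config.epochs_per_step, lr=config.lr,
            weight_decay=config.weight_decay, optimizer=opt_n,
        )
        mstep_losses.append(losses_m)
        provenance.append(("e->m", k))

        val_probs = model_n.predict_pairs(H0, A, val_pairs)
        history.append(
            _val_metric(val_probs, val_labels, dataset.network.label_space)
        )
        if check_convergence(history, config.patience, config.min_delta):
            break

        # pseudo-labels for the next E-step come from this M-step
        pseudo_from_m = p_probs

    return EMState(
        iteration=k,
        structure_model=model_s,
        network_model=model_n,
        config=config,
        val_history=history,
        predictions=p_probs,
        q_predictions=q_probs,
        unobserved_pairs=unobs,
        structural_embeddings=H0,
        adjacency=A,
        base_adjacency=train_net.adjacency(include_pseudo=False),
        augmented=augmented,
        pseudo_provenance=provenance,
        estep_losses=estep_losses,
        mstep_losses=mstep_losses,
    )


# ----------------------------------------------------------------------
# Jointly optimized baseline
# ----------------------------------------------------------------------

def run_joint_baseline(dataset: MultiScaleDataset,
                       config: TrainConfig) -> EMState:
    """Single combined objective: structure embeddings feed the network
    model end-to-end; no pseudo-labels, no augmentation. Uses the same
    total epoch budget as `run_em` for fair comparison."""
    if not dataset.network.links_with_status(OBSERVED):
        raise ValueError("dataset has no observed links")
    model_s = build_structure_model(dataset, config)
    model_n = build_network_model(dataset, config)
    params = model_s.parameters() + model_n.parameters()
    opt = AdamW(params, lr=config.lr, weight_decay=config.weight_decay)

    train_pairs, train_labels, val_pairs, val_labels = _validation_split(
        dataset, config
    )
    unobs = dataset.unobserved_pool()
    train_net = _train_adjacency(dataset, train_pairs)
    A = train_net.adjacency(include_pseudo=False)

    from .network_scale import mstep_loss

    history: List[float] = []
    total_epochs = config.epochs_per_step * config.max_em_iterations
    model_s.train()
    model_n.train()
    for epoch in range(total_epochs):
        emb = model_s.entity_embeddings()
        h = model_n.node_representations(emb, A)
        logits = model_n.pair_logits(h, A, train_pairs)
        loss = mstep_loss(
            logits, train_labels, None, None, 0.0, model_n.head
        )
        opt.zero_grad()
        loss.backward()
        opt.step()
        if (epoch + 1) % config.epochs_per_step == 0:
            model_s.eval()
            model_n.eval()
            H0 = model_s.entity_embeddings().numpy()
            val_probs = model_n.predict_pairs(H0, A, val_pairs)
            history.append(
                _val_metric(
                    val_probs, val_labels, dataset.network.label_space
                )
            )
            model_s.train()
            model_n.train()

    model_s.eval()
    model_n.eval()
    H0 = model_s.entity_embeddings().numpy()
    p_probs = model_n.predict_pairs(H0, A, unobs)
    q_probs = model_s.predict_pairs(unobs)
    return EMState(
        iteration=config.max_em_iterations - 1,
        structure_model=model_s,
        network_model=model_n,
        config=config,
        val_history=history,
        predictions=p_probs,
        q_predictions=q_probs,
        unobserved_pairs=unobs,
        structural_embeddings=H0,
        adjacency=A,
        base_adjacency=A.copy(),
        augmented=None,
        pseudo_provenance=[],
    )


# ----------------------------------------------------------------------
# Single-scale trainers
# ----------------------------------------------------------------------

def train_structure_only(dataset: MultiScaleDataset,
                         config: TrainConfig) -> tuple:
    """Supervised structure-scale model; returns (model, probs on pool)."""
    model = build_structure_model(dataset, config)
    train_pairs, train_labels, _, _ = _validation_split(dataset, config)
    unobs = dataset.unobserved_pool()
    total_epochs = config.epochs_per_step * config.max_em_iterations
    _, probs = train_estep(
        model, train_pairs, train_labels, unobs, None, 0.0,
        total_epochs, lr=config.lr, weight_decay=config.weight_decay,
    )
    return model, probs


def train_network_only(dataset: MultiScaleDataset,
                       config: TrainConfig) -> tuple:
    """Supervised network-scale model with zeroed structural input: only
    the model's own entity embeddings and the topology carry signal."""
    model = build_network_model(dataset, config)
    H0 = np.zeros((dataset.network.n_entities, config.hidden))
    train_pairs, train_labels, _, _ = _validation_split(dataset, config)
    unobs = dataset.unobserved_pool()
    train_net = _train_adjacency(dataset, train_pairs)
    A = train_net.adjacency(include_pseudo=False)
    total_epochs = config.epochs_per_step * config.max_em_iterations
    _, probs = train_mstep(
        model, H0, A, train_pairs, train_labels, unobs, None, 0.0,
        total_epochs, lr=config.lr, weight_decay=config.weight_decay,
    )
    return model, probs


# ----------------------------------------------------------------------
# Utilization-rate evaluation of a trained multi-scale state
# ----------------------------------------------------------------------

def utilization_report(state: EMState, dataset: MultiScaleDataset,
                       metric: str = "best_f1", mode: str = "refit",
                       refit_epochs: Optional[int] = None):
    """Per-scale utilization rates of a trained multi-scale model.

    The single-scale models M0/M1 are obtained from the multi-scale model
    by replacing one scale's input with its feature mean:

    * no-structure (M1): structural embeddings -> their mean row, and the
      adjacency reverts to the observed-only graph (pseudo edges were
      derived from the structure scale, so they are removed with it);
    * no-network (M0): adjacency -> empty (no message passing, no common
      neighbors) and the network scale's own entity embeddings -> their
      mean row.

    mode="refit" (default) briefly re-fits the network-scale model on the
    ablated inputs before scoring, so the ablation measures lost
    information rather than out-of-distribution collapse of frozen
    activations; mode="inference" evaluates the frozen model directly.
    """
    import copy

    from .evaluation import UtilizationReport, utilization_rate
    from .evaluation import auroc as _auroc

    metric_fns = {"best_f1": best_f1, "auprc": auprc, "auroc": _auroc}
    fn = metric_fns[metric]
    labels = dataset.test_labels()
    pool = state.unobserved_pairs
    config = state.config
    model = state.network_model

    f_multi = fn(state.predictions, labels)

    H0 = state.structural_embeddings
    H_mean = np.tile(H0.mean(axis=0, keepdims=True), (H0.shape[0], 1))
    A_zero = np.zeros_like(state.adjacency)
    emb_mean = None
    if model.entity_embedding is not None:
        e = model.entity_embedding.numpy()
        emb_mean = np.tile(e.mean(axis=0, keepdims=True), (e.shape[0], 1))

    def ablated_metric(H: np.ndarray, A: np.ndarray, entity_emb) -> float:
        m = model
        if mode == "refit":
            m = copy.deepcopy(model)
            if entity_emb is not None and m.entity_embedding is not None:
                m.entity_embedding.data = entity_emb.copy()
            train_pairs, train_labels, _, _ = _validation_split(
                dataset, config
            )
            n_epochs = (
                refit_epochs if refit_epochs is not None
                else config.epochs_per_step
            )
            train_mstep(
                m, H, A, train_pairs, train_labels,
                np.zeros((0, 2), dtype=np.intp), None, 0.0,
                n_epochs, lr=config.lr,
                weight_decay=config.weight_decay,
            )
            entity_emb = None
        return fn(
            m.predict_pairs(H, A, pool, entity_embeddings=entity_emb),
            labels,
        )

    f_no_struct = ablated_metric(H_mean, state.base_adjacency, None)
    f_no_net = ablated_metric(H0, A_zero, emb_mean)

    return UtilizationReport(
        u_structure=utilization_rate(f_multi, f_no_struct),
        u_network=utilization_rate(f_multi, f_no_net),
        f_multi=f_multi,
        f_no_structure=f_no_struct,
        f_no_network=f_no_net,
    )
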
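"""Synthetic multi-scale networks with planted, tunable signal at both
scales, plus link-split strategies and negative-pair sampling.

Each entity draws a latent class. Its structural graph is an
Erdős–Rényi background with a class-specific motif planted (with
fidelity ``rho_struct``) and class-correlated node features; links form
with probability given by a class-mixing matrix (with fidelity
``rho_net``). Setting either fidelity to zero removes the corresponding
scale's signal entirely, which is what makes null-model sanity checks
possible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .graph_io import (
    OBSERVED,
    UNOBSERVED,
    InteractionNetwork,
    Link,
    MolecularGraph,
    canonicalize_edges,
)

# 4-6 node motif templates, one per latent class (edge lists).
MOTIF_VOCABULARY: Tuple[Tuple[Tuple[int, int], ...], ...] = (
    # triangle with a pendant node
    ((0, 1), (1, 2), (0, 2), (2, 3)),
    # 5-cycle
    ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4)),
    # 4-clique
    ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)),
    # 6-path
    ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5)),
    # star on 5 nodes
    ((0, 1), (0, 2), (0, 3), (0, 4)),
)


def _default_mixing(n_classes: int) -> np.ndarray:
    """Assortative link-probability matrix: dense within a class."""
    m = np.full((n_classes, n_classes), 0.004)
    np.fill_diagonal(m, 0.4)
    return m


@dataclass
class SyntheticSpec:
    n_entities: int = 300
    n_classes: int = 10
    mixing: Optional[np.ndarray] = None  # K x K link probabilities
    rho_struct: float = 0.9
    rho_net: float = 0.9
    graph_size_range: Tuple[int, int] = (15, 30)
    background_density: float = 0.12
    feature_dim: int = 16
    feature_noise: float = 0.35
    signal_strength: float = 1.5
    candidate_fraction: float = 1.0  # fraction of all pairs examined
    hidden_fraction: float = 0.3
    label_space: str = "binary"
    seed: int = 0

    def __post_init__(self):
        if self.mixing is None:
            self.mixing = _default_mixing(self.n_classes)
        self.mixing = np.asarray(self.mixing, dtype=np.float64)
        if self.mixing.shape != (self.n_classes, self.n_classes):
            raise ValueError("mixing matrix must be K x K")
        if np.any(self.mixing < 0) or np.any(self.mixing > 1):
            raise ValueError("mixing entries must be probabilities")
        if not 0 < self.hidden_fraction < 1:
            raise ValueError("hidden fraction must be in (0, 1)")
        for rho in (self.rho_struct, self.rho_net):
            if not 0.0 <= rho <= 1.0:
                raise ValueError("fidelity parameters must be in [0, 1]")
        if not 0.0 < self.candidate_fraction <= 1.0:
            raise ValueError("candidate fraction must be in (0, 1]")
        if self.graph_size_range[0] < 2:
            raise ValueError("graphs need at least 2 nodes")
        max_motif = max(
            max(max(e) for e in motif) + 1 for motif in MOTIF_VOCABULARY
        )
        if self.graph_size_range[0] < max_motif:
            raise ValueError(
                f"minimum graph size {self.graph_size_range[0]} is smaller "
                f"than the largest motif ({max_motif} nodes)"
            )


def imbalance_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Preset where the network scale is easy and the structure scale
    noisy, reproducing the greedy-learning pathology at desk scale."""
    kwargs = dict(
        rho_net=1.0,
        rho_struct=0.9,
        hidden_fraction=0.45,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


# ----------------------------------------------------------------------
# Generation
# ----------------------------------------------------------------------

def _plant_motif(
    n_nodes: int,
    motif: Sequence[Tuple[int, int]],
    background_density: float,
    rng: np.random.Generator,
) -> np.ndarray:
    motif_size = max(max(e) for e in motif) + 1
    if motif_size > n_nodes:
        raise ValueError("motif larger than graph")
    # ER background
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = rng.random(iu.size) < background_density
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    # plant motif on randomly chosen nodes (node identification)
    anchor = rng.choice(n_nodes, size=motif_size, replace=False)
    for a, b in motif:
        edges.append((int(anchor[a]), int(anchor[b])))
    return canonicalize_edges(edges), anchor


def generate_multiscale_network(
    spec: SyntheticSpec,
) -> Tuple[List[MolecularGraph], InteractionNetwork, dict]:
    """Generate (entity graphs, interaction network, ground truth).

    Deterministic given ``spec.seed``. The truth dict records latent
    classes, the class actually planted in each graph, and full labels
    for every generated link.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_entities
    k = spec.n_classes
    classes = rng.integers(0, k, size=n)

    # --- entity structural graphs ---------------------------------
    graphs: List[MolecularGraph] = []
    planted = np.empty(n, dtype=np.int64)
    for e in range(n):
        if rng.random() < spec.rho_struct:
            z = int(classes[e])
        else:
            z = int(rng.integers(0, k))
        planted[e] = z
        size = int(
            rng.integers(spec.graph_size_range[0], spec.graph_size_range[1] + 1)
        )
        motif = MOTIF_VOCABULARY[z % len(MOTIF_VOCABULARY)]
        edges, anchor = _plant_motif(
            size, motif, spec.background_density, rng
        )
        feats = spec.feature_noise * rng.standard_normal(
            (size, spec.feature_dim)
        )
        feats[anchor, z % spec.feature_dim] += spec.signal_strength
        graphs.append(
            MolecularGraph(
                entity_id=f"E{e:04d}",
                entity_kind="generic",
                node_features=feats,
                edges=edges,
            )
        )

    # --- interaction links ----------------------------------------
    # Every candidate pair is labeled by the class-mixing matrix with
    # probability rho_net, and by the matched base rate otherwise, so
    # rho_net dials informativeness without changing link density.
    iu, ju = np.triu_indices(n, k=1)
    if spec.candidate_fraction < 1.0:
        keep = rng.random(iu.size) < spec.candidate_fraction
        iu, ju = iu[keep], ju[keep]
    p_mix = spec.mixing[classes[iu], classes[ju]]
    p_base = float(p_mix.mean())
    faithful = rng.random(iu.size) < spec.rho_net
    p_pair = np.where(faithful, p_mix, p_base)
    is_link = rng.random(iu.size) < p_pair
    links: List[Link] = []
    truth_labels: Dict[Tuple[int, int], int] = {}
    for i, j, label in zip(iu.tolist(), ju.tolist(), is_link.tolist()):
        truth_labels[(i, j)] = int(label)
        if label:
            links.append(Link(i=i, j=j, label=np.array([1.0])))

    # --- hide a fraction of links ---------------------------------
    n_hidden = int(round(spec.hidden_fraction * len(links)))
    hidden_idx = rng.choice(len(links), size=n_hidden, replace=False)
    for h in hidden_idx:
        links[h].status = UNOBSERVED
        links[h].confidence = 0.0

    network = InteractionNetwork(
        entity_ids=[g.entity_id for g in graphs],
        label_space=spec.label_space,
        n_classes=1,
        links=links,
    )
    truth = {
        "classes": classes,
        "planted_classes": planted,
        "labels": truth_labels,
    }
    return graphs, network, truth


# ----------------------------------------------------------------------
# Splits and negative sampling
# ----------------------------------------------------------------------

def split_links(
    network: InteractionNetwork,
    strategy: str,
    test_fraction: float,
    seed: int = 0,
) -> Dict[str, list]:
    """Partition links into train/test pair lists.

    random: uniform link sample. bfs/dfs: grow a node set by traversal
    from a random seed node until links incident to it reach the test
    fraction; those links are the test set.
    """
    if not 0 < test_fraction < 1:
        raise ValueError(f"test fraction must be in (0,1): {test_fraction}")
    if strategy not in ("random", "bfs", "dfs"):
        raise ValueError(f"unknown split strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    pairs = [l.pair for l in network.links]
    n_test = int(round(test_fraction * len(pairs)))

    if strategy == "random":
        idx = rng.permutation(len(pairs))
        test = [pairs[i] for i in idx[:n_test]]
        train = [pairs[i] for i in idx[n_test:]]
        return {"train": train, "test": test,
                "visited_nodes": []}

    adj: Dict[int, list] = {}
    for i, j in pairs:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    for v in adj:
        adj[v].sort()

    nodes_with_links = sorted(adj)
    visited: list = []
    visited_set: set = set()
    test_set: set = set()
    frontier: list = []

    def incident_links(node_set: set) -> set:
        return {p for p in pairs if p[0] in node_set or p[1] in node_set}

    while len(test_set) < n_test:
        if not frontier:
            remaining = [v for v in nodes_with_links if v not in visited_set]
            if not remaining:
                break
            start = int(rng.choice(remaining))
            frontier = [start]
        if strategy == "bfs":
            node = frontier.pop(0)
        else:
            node = frontier.pop()
        if node in visited_set:
            continue
        visited_set.add(node)
        visited.append(node)
        frontier.extend(
            v for v in adj.get(node, []) if v not in visited_set
        )
        test_set = incident_links(visited_set)

    train = [p for p in pairs if p not in test_set]
    return {
        "train": train,
        "test": sorted(test_set),
        "visited_nodes": visited,
    }


def sample_negative_pairs(
    network: InteractionNetwork,
    count: int,
    seed: int = 0,
    exclude: Optional[Sequence[Tuple[int, int]]] = None,
) -> List[Tuple[int, int]]:
    """Uniform sample (without replacement) of non-linked unordered pairs."""
    rng = np.random.default_rng(seed)
    n = network.n_entities
    taken = {l.pair for l in network.links}
    if exclude:
        taken |= {(min(i, j), max(i, j)) for i, j in exclude}
    iu, ju = np.triu_indices(n, k=1)
    codes = [
        (int(i), int(j)) for i, j in zip(iu, ju) if (i, j) not in taken
    ]
    if count > len(codes):
        raise ValueError(
            f"requested {count} negative pairs but only {len(codes)} "
            f"non-linked pairs exist"
        )
    idx = rng.choice(len(codes), size=count, replace=False)
    return [codes[i] for i in sorted(idx.tolist())]
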